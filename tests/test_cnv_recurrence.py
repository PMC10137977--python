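"""CNV call QC, reciprocal-overlap merging, recurrence/rarity filters and
the read-depth deletion scanner."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from q22screen.cnv_recurrence import (
    CnvCall,
    DepthProfile,
    classify_rare_cnv,
    cluster_and_merge,
    qc_filter_calls,
    reciprocal_overlap,
    recurrence_candidates,
    scan_depth_for_deletion,
)
from q22screen.synthetic_cohort import simulate_cnv_calls, simulate_depth_profile


def call(sample="s1", start=0, end=10_000, ctype="DUP", p=0.001, q0=0.1):
    return CnvCall(sample, start, end, ctype, p, q0)


class TestQc:
    @pytest.mark.parametrize(
        "p,size,q0,kept",
        [
            (0.005, 5_000, 0.2, True),
            (0.01, 5_000, 0.2, False),   # p strictly below 0.01
            (0.005, 800, 0.2, False),
            (0.005, 1_000, 0.2, False),  # size strictly above 1 kb
            (0.005, 1_001, 0.2, True),
            (0.005, 5_000, 0.6, False),
            (0.005, 5_000, 0.5, True),   # q0 <= 0.5 inclusive
        ],
    )
    def test_thresholds(self, p, size, q0, kept):
        c = call(start=0, end=size, p=p, q0=q0)
        assert (qc_filter_calls([c]) == [c]) is kept


class TestReciprocalOverlap:
    def test_identical_is_one(self):
        assert reciprocal_overlap((5, 105), (5, 105)) == 1.0

    def test_half_overlap_is_not_concordant(self):
        assert reciprocal_overlap((0, 100), (50, 150)) == pytest.approx(0.5)
        a, b = call(start=0, end=100), call(sample="s2", start=50, end=150)
        assert cluster_and_merge([a, b]) != cluster_and_merge([a])  # two clusters
        assert len(cluster_and_merge([a, b])) == 2

    def test_eighty_percent_concordant(self):
        assert reciprocal_overlap((0, 10_000), (2_000, 12_000)) == pytest.approx(0.8)

    @given(
        a0=st.integers(0, 1_000), al=st.integers(1, 1_000),
        b0=st.integers(0, 1_000), bl=st.integers(1, 1_000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_bounded(self, a0, al, b0, bl):
        a, b = (a0, a0 + al), (b0, b0 + bl)
        ro = reciprocal_overlap(a, b)
        assert ro == reciprocal_overlap(b, a)
        assert 0.0 <= ro <= 1.0
        if ro == 1.0:
            assert a == b


class TestMerge:
    def test_single_call_is_its_own_cluster(self):
        c = call()
        (m,) = cluster_and_merge([c])
        assert m.interval == c.interval and m.supporting_samples == {c.sample_id}

    def test_outer_bounds(self):
        a = call(sample="s1", start=0, end=10_000)
        b = call(sample="s2", start=2_000, end=12_000)
        (m,) = cluster_and_merge([a, b])
        assert m.interval == (0, 12_000)

    def test_type_separation(self):
        a = call(sample="s1", ctype="DUP")
        b = call(sample="s2", ctype="DEL")
        assert len(cluster_and_merge([a, b])) == 2

    def test_idempotent_and_covering(self):
        rng = np.random.default_rng(0)
        calls = []
        for i in range(40):
            s = int(rng.integers(0, 500_000))
            ln = int(rng.integers(2_000, 50_000))
            calls.append(call(sample=f"s{i % 10}", start=s, end=s + ln,
                              ctype="DUP" if i % 2 else "DEL"))
        merged = cluster_and_merge(calls)
        for m in merged:
            for member in m.members:
                assert m.start <= member.start and member.end <= m.end
        # re-merging the merged output is a fixed point
        as_calls = [
            call(sample=f"m{i}", start=m.start, end=m.end, ctype=m.cnv_type)
            for i, m in enumerate(merged)
        ]
        again = cluster_and_merge(as_calls)
        assert sorted((m.interval, m.cnv_type) for m in again) == sorted(
            set((m.interval, m.cnv_type) for m in merged)
        )


class TestRecurrence:
    def merged(self, n_samples, start=0, end=50_000, ctype="DUP"):
        calls = [call(sample=f"c{i}", start=start, end=end, ctype=ctype)
                 for i in range(n_samples)]
        return cluster_and_merge(calls)

    def test_twelve_of_nineteen_passes_sixty_percent(self):
        cands = recurrence_candidates(self.merged(12), n_cases=19, threshold=0.6)
        assert len(cands) == 1
        assert cands[0].recurrence_rate == pytest.approx(12 / 19)

    def test_eleven_of_nineteen_depends_on_threshold(self):
        merged = self.merged(11)
        assert len(recurrence_candidates(merged, 19, threshold=0.5)) == 1
        assert len(recurrence_candidates(merged, 19, threshold=0.6)) == 0

    def test_parent_concordant_call_excludes(self):
        merged = self.merged(12)
        parent = call(sample="father", start=1_000, end=49_000)
        assert recurrence_candidates(merged, 19, [parent], threshold=0.6) == []
        far_parent = call(sample="father", start=400_000, end=450_000)
        assert len(recurrence_candidates(merged, 19, [far_parent], threshold=0.6)) == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        calls = []
        for i in range(60):
            s = int(rng.integers(0, 300_000))
            calls.append(call(sample=f"s{rng.integers(0, 19)}", start=s, end=s + 20_000))
        merged = cluster_and_merge(calls)
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            cur = {(m.start, m.end) for m in recurrence_candidates(merged, 19, threshold=thr)}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_zero_cases_raises(self):
        with pytest.raises(ValueError):
            recurrence_candidates(self.merged(1), n_cases=0)


class TestRarity:
    def track(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "frequency"])

    def test_no_overlap_is_rare(self):
        t = self.track([("22", 500_000, 600_000, 0.2)])
        assert classify_rare_cnv((0, 10_000), t)

    def test_exactly_half_covered_is_rare(self):
        t = self.track([("22", 0, 5_000, 0.05)])
        assert classify_rare_cnv((0, 10_000), t)

    def test_mostly_covered_is_not_rare(self):
        t = self.track([("22", 0, 8_000, 0.05)])
        assert not classify_rare_cnv((0, 10_000), t)

    def test_low_frequency_regions_ignored(self):
        t = self.track([("22", 0, 10_000, 0.005)])
        assert classify_rare_cnv((0, 10_000), t)

    def test_union_not_sum_of_overlapping_records(self):
        # two overlapping common records cover only 40% jointly
        t = self.track([("22", 0, 3_000, 0.05), ("22", 1_000, 4_000, 0.05)])
        assert classify_rare_cnv((0, 10_000), t)

    def test_adding_common_regions_never_restores_rarity(self):
        base = [("22", 0, 8_000, 0.05)]
        assert not classify_rare_cnv((0, 10_000), self.track(base))
        assert not classify_rare_cnv(
            (0, 10_000), self.track(base + [("22", 8_000, 10_000, 0.05)])
        )


class TestPlantedDuplication:
    def test_carrier_probability_extremes(self, small_config):
        cfg0 = dataclasses.replace(
            small_config, cnv=dataclasses.replace(small_config.cnv, carrier_prob=0.0)
        )
        df0 = simulate_cnv_calls(cfg0)
        ds, de = cfg0.cnv.dup_interval
        near = df0[(df0.cnv_type == "DUP") & (abs(df0.start - ds) <= cfg0.cnv.boundary_jitter)
                   & (abs(df0.end - de) <= cfg0.cnv.boundary_jitter)]
        assert near.empty

        cfg1 = dataclasses.replace(
            small_config,
            cnv=dataclasses.replace(
                small_config.cnv, carrier_prob=1.0, boundary_jitter=0,
                noise_calls_per_sample=0.0,
            ),
            include_trio=False,
        )
        df1 = simulate_cnv_calls(cfg1)
        assert len(df1) == cfg1.n_cases
        assert (df1.start == ds).all() and (df1.end == de).all()

    def test_carrier_fraction_matches_binomial_expectation(self, small_config):
        """Mean observed carrier fraction over many seeds ~ carrier_prob."""
        p = 0.65
        n_seeds = 500
        fracs = []
        for seed in range(n_seeds):
            cfg = dataclasses.replace(
                small_config,
                seed=seed,
                include_trio=False,
                cnv=dataclasses.replace(
                    small_config.cnv, carrier_prob=p, noise_calls_per_sample=0.0
                ),
            )
            df = simulate_cnv_calls(cfg)
            fracs.append(df.sample_id.nunique() / cfg.n_cases)
        se = np.sqrt(p * (1 - p) / (small_config.n_cases * n_seeds))
        assert abs(np.mean(fracs) - p) <= 3 * se


class TestDeletionScan:
    def test_flat_profile_has_no_calls(self):
        prof = DepthProfile("s", 100, np.full(20_000, 80.0))
        assert scan_depth_for_deletion(prof) == []

    def test_uniformly_reduced_profile_is_undetectable(self):
        # no within-sample contrast: normalization makes it flat 1.0x
        prof = DepthProfile("s", 100, np.full(20_000, 40.0))
        assert scan_depth_for_deletion(prof) == []

    def test_zero_median_raises(self):
        prof = DepthProfile("s", 100, np.zeros(20_000))
        with pytest.raises(ValueError):
            scan_depth_for_deletion(prof)

    def test_short_profile_raises(self):
        prof = DepthProfile("s", 100, np.full(100, 80.0))
        with pytest.raises(ValueError):
            scan_depth_for_deletion(prof, min_length=500_000)

    def test_recovers_planted_deletion(self, small_config):
        cfg = dataclasses.replace(small_config, seed=2)
        prof = simulate_depth_profile(cfg, "child")
        dels = scan_depth_for_deletion(prof, min_length=200_000)
        assert len(dels) == 1
        (d,) = dels
        s, e = cfg.deletion.interval
        assert abs(d.start - s) <= 2 * cfg.bin_size
        assert abs(d.end - e) <= 2 * cfg.bin_size
        assert 0.45 <= d.mean_normalized_depth <= 0.55

    def test_noiseless_child_profile_is_exact(self, small_config):
        cfg = dataclasses.replace(small_config, depth_cv=0.0)
        prof = simulate_depth_profile(cfg, "child")
        s, e = cfg.deletion.interval
        inside = prof.depths[s // 100:e // 100]
        assert (inside == cfg.mean_depth * 0.5).all()
        outside = np.concatenate([prof.depths[: s // 100], prof.depths[e // 100:]])
        assert (outside == cfg.mean_depth).all()
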