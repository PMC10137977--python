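"""Hard-filter semantics and the prioritization cascade."""

import pytest

from q22screen.variant_prioritization import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    PREDICTORS,
    FilterThresholds,
    VariantAnnotation,
    VariantRecord,
    apply_site_filters,
    classify_consequence,
    classify_novelty,
    compute_maf,
    flag_trio_absent,
    prioritize_variants,
)

NOMINAL_SNP = {
    "QD": 20.0, "FS": 5.0, "SOR": 1.0, "MQ": 60.0,
    "MQRankSum": 0.0, "ReadPosRankSum": 0.0,
}


def snp(pos=100, metrics=None, genotypes=None, **overrides):
    m = dict(NOMINAL_SNP)
    m.update(overrides)
    if metrics is not None:
        m = metrics
    return VariantRecord("22", pos, "A", "G", "SNP", m, genotypes or {"s1": HET})


def indel(pos=200, **overrides):
    m = {"QD": 20.0, "FS": 5.0, "SOR": 1.0, "InbreedingCoeff": 0.0,
         "ReadPosRankSum": 0.0}
    m.update(overrides)
    return VariantRecord("22", pos, "AT", "A", "indel", m, {"s1": HET})


def annotation(key="22:100:A:G", gene="G1", fclass="nonsynonymous",
               in_dbsnp=True, in_1000g=True, af1=0.001, af2=0.001,
               n_damaging=0, n_missing=0):
    calls = {}
    for i, p in enumerate(PREDICTORS):
        if i < n_damaging:
            calls[p] = "damaging"
        elif i < n_damaging + n_missing:
            calls[p] = "missing"
        else:
            calls[p] = "tolerated"
    return VariantAnnotation(key, gene, fclass, in_dbsnp, in_1000g, af1, af2, calls)


class TestSiteFilters:
    @pytest.mark.parametrize(
        "record,kept,reason",
        [
            (snp(QD=1.5), False, "QD"),
            (snp(QD=2.0), True, None),  # strict inequality boundary
            (snp(FS=150.0), False, "FS"),
            (indel(FS=150.0), True, None),  # indel FS cutoff is 200
            (indel(FS=250.0), False, "FS"),
            (snp(SOR=4.0), True, None),
            (snp(SOR=4.5), False, "SOR"),
            (snp(MQ=39.9), False, "MQ"),
            (snp(MQRankSum=-13.0), False, "MQRankSum"),
            (indel(InbreedingCoeff=-0.9), False, "InbreedingCoeff"),
            (indel(ReadPosRankSum=-19.0), True, None),
            (snp(ReadPosRankSum=-19.0), False, "ReadPosRankSum"),
        ],
    )
    def test_rule_boundaries(self, record, kept, reason):
        retained, failures = apply_site_filters([record])
        assert (len(retained) == 1) is kept
        if not kept:
            assert reason in failures[record.key]

    def test_missing_metric_is_not_a_violation(self):
        rec = snp(metrics={})  # no metrics at all: nothing to violate
        retained, failures = apply_site_filters([rec])
        assert retained == [rec] and failures == {}

    def test_multiple_violations_all_reported(self):
        rec = snp(QD=1.0, MQ=10.0)
        _, failures = apply_site_filters([rec])
        assert set(failures[rec.key]) == {"QD", "MQ"}

    def test_unknown_vtype_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds().rules_for("SV")

    def test_order_independence(self):
        recs = [snp(pos=i, QD=1.0 if i % 3 == 0 else 20.0) for i in range(1, 30)]
        fwd, _ = apply_site_filters(recs)
        rev, _ = apply_site_filters(recs[::-1])
        assert {r.key for r in fwd} == {r.key for r in rev}


class TestRecordInvariants:
    def test_vtype_allele_consistency(self):
        with pytest.raises(ValueError):
            VariantRecord("22", 1, "AT", "A", "SNP", {}, {})
        with pytest.raises(ValueError):
            VariantRecord("22", 1, "A", "G", "indel", {}, {})
        with pytest.raises(ValueError):
            VariantRecord("22", 0, "A", "G", "SNP", {}, {})
        with pytest.raises(ValueError):
            VariantRecord("22", 1, "A", "A", "SNP", {}, {})


class TestMaf:
    def test_all_hom_ref_is_zero(self):
        rec = snp(genotypes={f"s{i}": HOM_REF for i in range(5)})
        assert compute_maf(rec, [f"s{i}" for i in range(5)]) == 0.0

    def test_het_allele_count(self):
        gts = {f"s{i}": HET if i < 3 else HOM_REF for i in range(19)}
        rec = snp(genotypes=gts)
        assert compute_maf(rec, list(gts)) == pytest.approx(3 / 38)

    def test_folding(self):
        rec = snp(genotypes={"a": HOM_ALT, "b": HOM_REF})
        assert compute_maf(rec, ["a", "b"]) == 0.5

    def test_all_missing_raises(self):
        rec = snp(genotypes={"a": MISSING})
        with pytest.raises(ValueError):
            compute_maf(rec, ["a"])


class TestNovelty:
    def test_absent_from_both_catalogues_is_novel(self):
        ann = annotation(in_dbsnp=False, in_1000g=False, af1=None, af2=None)
        assert classify_novelty(ann) == "novel"

    def test_low_frequency_known_is_rare(self):
        assert classify_novelty(annotation(af1=0.005, af2=0.008)) == "rare"

    def test_at_cutoff_is_rare_inclusive(self):
        assert classify_novelty(annotation(af1=0.01, af2=0.01)) == "rare"

    def test_common_is_excluded(self):
        assert classify_novelty(annotation(af1=0.05, af2=None)) == "excluded"

    def test_known_without_frequencies_treated_as_rare(self):
        ann = annotation(in_dbsnp=True, in_1000g=False, af1=None, af2=None)
        assert classify_novelty(ann) == "rare"


class TestConsequence:
    @pytest.mark.parametrize(
        "fclass,n_damaging,expected",
        [
            ("stop_gain", 0, "LoF"),
            ("frameshift", 0, "LoF"),
            ("splice", 0, "LoF"),
            ("nonsynonymous", 2, "missense_damaging"),
            ("nonsynonymous", 1, "other"),
            ("nonsynonymous", 8, "missense_damaging"),
            ("synonymous", 8, "other"),
            ("unknown", 0, "other"),
        ],
    )
    def test_classes(self, fclass, n_damaging, expected):
        assert classify_consequence(annotation(fclass=fclass, n_damaging=n_damaging)) == expected

    def test_missing_predictors_never_vote(self):
        # 1 damaging + 7 missing stays below the 2-vote threshold
        ann = annotation(fclass="nonsynonymous", n_damaging=1, n_missing=7)
        assert classify_consequence(ann) == "other"


class TestTrioAbsence:
    def trio_rec(self, child, father, mother):
        return snp(genotypes={"c": child, "f": father, "m": mother})

    def test_de_novo_like(self):
        assert flag_trio_absent(self.trio_rec(HET, HOM_REF, HOM_REF), "c", "f", "m")

    def test_inherited(self):
        assert not flag_trio_absent(self.trio_rec(HET, HET, HOM_REF), "c", "f", "m")

    def test_missing_parent_is_conservative(self):
        assert not flag_trio_absent(self.trio_rec(HET, HOM_REF, MISSING), "c", "f", "m")

    def test_child_without_alt(self):
        assert not flag_trio_absent(self.trio_rec(HOM_REF, HOM_REF, HOM_REF), "c", "f", "m")

    def test_unknown_sample_raises(self):
        with pytest.raises(ValueError):
            flag_trio_absent(self.trio_rec(HET, HOM_REF, HOM_REF), "c", "f", "x")


class TestCascade:
    def test_empty_input(self):
        out, funnel = prioritize_variants([], {})
        assert out == [] and funnel["input"] == 0 and funnel["lof_or_damaging"] == 0

    def test_hand_built_fixture(self):
        """10 variants, exactly 3 pass all stages by construction."""
        recs, anns = [], {}

        def add(pos, *, qd=20.0, fclass="stop_gain", dbsnp=False, g1000=False,
                af=None, n_damaging=0):
            r = snp(pos=pos, QD=qd, genotypes={"s1": HET})
            recs.append(r)
            anns[r.key] = annotation(
                key=r.key, fclass=fclass, in_dbsnp=dbsnp, in_1000g=g1000,
                af1=af, af2=af, n_damaging=n_damaging,
            )

        add(1, fclass="stop_gain")                              # pass (LoF, novel)
        add(2, fclass="nonsynonymous", n_damaging=3)            # pass (damaging)
        add(3, fclass="splice", dbsnp=True, g1000=True, af=0.002)  # pass (rare LoF)
        add(4, qd=1.0)                                          # site filter
        add(5, fclass="synonymous")                             # consequence
        add(6, fclass="nonsynonymous", n_damaging=1)            # 1 vote
        add(7, dbsnp=True, g1000=True, af=0.2)                  # common
        add(8, fclass="unknown")                                # consequence
        add(9, qd=1.5, fclass="stop_gain")                      # site filter
        add(10, fclass="nonsynonymous", n_damaging=0)           # 0 votes
        out, funnel = prioritize_variants(recs, anns)
        assert len(out) == 3
        assert funnel == {
            "input": 10, "site_pass": 8, "novel_or_rare": 7, "lof_or_damaging": 3,
        }

    def test_funnel_is_monotone_and_matches_naive_oracle(self, small_config):
        """The cascade equals a naive rule-by-rule reimplementation."""
        from q22screen.synthetic_cohort import simulate_cohort_variants

        records, annotations, _ = simulate_cohort_variants(small_config)
        out, funnel = prioritize_variants(records, annotations)
        stages = ["input", "site_pass", "novel_or_rare", "lof_or_damaging"]
        values = [funnel[s] for s in stages]
        assert values == sorted(values, reverse=True)

        # independent naive oracle
        snp_rules = {"QD": (2.0, "<"), "FS": (60.0, ">"), "SOR": (4.0, ">"),
                     "MQ": (40.0, "<"), "MQRankSum": (-12.5, "<"),
                     "ReadPosRankSum": (-8.0, "<")}
        indel_rules = {"QD": (2.0, "<"), "FS": (200.0, ">"), "SOR": (10.0, ">"),
                       "InbreedingCoeff": (-0.8, "<"), "ReadPosRankSum": (-20.0, "<")}
        expected = set()
        for rec in records:
            rules = snp_rules if rec.vtype == "SNP" else indel_rules
            bad = False
            for name, (cut, op) in rules.items():
                if name in rec.metrics:
                    v = rec.metrics[name]
                    if (op == "<" and v < cut) or (op == ">" and v > cut):
                        bad = True
            if bad:
                continue
            ann = annotations[rec.key]
            if not ann.in_dbsnp and not ann.in_1000g:
                pass  # novel
            else:
                fs = [f for f in (ann.af_eas_1000g, ann.af_exac_eas) if f is not None]
                if any(f > 0.01 for f in fs):
                    continue
            lof = ann.functional_class in ("stop_gain", "frameshift", "splice")
            dmg = (
                ann.functional_class == "nonsynonymous"
                and sum(v == "damaging" for v in ann.predictor_calls.values()) >= 2
            )
            if lof or dmg:
                expected.add(rec.key)
        assert {v.key for v in out} == expected

    def test_missing_annotation_raises(self):
        rec = snp()
        with pytest.raises(ValueError):
            prioritize_variants([rec], {})

    def test_trio_filter_drops_inherited(self):
        rec = snp(genotypes={"c": HET, "f": HET, "m": HOM_REF})
        anns = {rec.key: annotation(key=rec.key, fclass="stop_gain",
                                    in_dbsnp=False, in_1000g=False,
                                    af1=None, af2=None)}
        out, funnel = prioritize_variants(
            [rec], anns, trio=("c", "f", "m"), require_parent_absent=True
        )
        assert out == [] and funnel["parent_absent"] == 0
        out2, _ = prioritize_variants([rec], anns, trio=("c", "f", "m"))
        assert len(out2) == 1 and out2[0].absent_in_parents is False
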