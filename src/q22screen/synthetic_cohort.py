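"""Seeded synthetic-cohort generator for every pipeline input.

Emulates the statistical structure of a targeted 22q11.2-style screen so
the whole pipeline is testable without controlled-access data: a
multi-sample variant set over 19 cases + 103 controls (+ an optional
trio), per-variant annotations with population frequencies and eight
predictor verdicts, per-sample CNV call sets with a plantable recurrent
duplication, binned read-depth profiles with a ~3 Mb heterozygous deletion
in the trio child, a DGV-style population CNV frequency track, a clinical
phenotype table and triplicate qPCR Ct measurements.

Every generator is fully deterministic under a fixed
:class:`~q22screen.config.SimulationConfig` seed; each uses its own
purpose-bound RNG stream so stages can be regenerated independently.

What the generator does *not* emulate: read-level data, linkage
disequilibrium / haplotype structure, and realistic per-gene mutation-rate
variation. Variants are independent across sites given their allele
frequencies.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .cnv_recurrence import DepthProfile
from .variant_prioritization import (
    FUNCTIONAL_CLASSES,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    PREDICTORS,
    VariantAnnotation,
    VariantRecord,
)

__all__ = [
    "sample_manifest",
    "simulate_cohort_variants",
    "simulate_cnv_calls",
    "simulate_depth_profile",
    "simulate_frequency_track",
    "simulate_phenotypes",
    "simulate_qpcr",
]

_BASES = np.array(list("ACGT"))


def sample_manifest(config: SimulationConfig) -> dict:
    """Sample ids by role: cases, controls and the optional trio."""
    manifest = {
        "cases": [f"case{i + 1:02d}" for i in range(config.n_cases)],
        "controls": [f"ctrl{i + 1:03d}" for i in range(config.n_controls)],
        "trio": None,
    }
    if config.include_trio:
        manifest["trio"] = {"child": "child01", "father": "father01", "mother": "mother01"}
    return manifest


def _case_allele_prob(af: np.ndarray, multiplier: np.ndarray) -> np.ndarray:
    """Per-allele carrier probability in cases under an odds multiplier."""
    odds = multiplier * af / (1.0 - af)
    return odds / (1.0 + odds)


def simulate_cohort_variants(
    config: SimulationConfig,
) -> tuple[list[VariantRecord], dict[str, VariantAnnotation], dict]:
    """Simulate the multi-sample variant set, annotations and manifest.

    Sites get unique positions inside gene intervals, a population allele
    frequency from a rare-shifted beta law (with a ``common_fraction`` of
    common sites), GATK-style QC metrics (a ``qc_fail_fraction`` of sites
    violates one hard-filter rule), genotypes in Hardy-Weinberg proportions
    (case carrier odds multiplied for ``enriched_genes``), Mendelian trio
    transmission with a de-novo rate, and annotations whose predictor
    verdicts are conditionally independent given a latent truly-deleterious
    flag.
    """
    genes = sorted(config.gene_intervals)
    if not genes:
        raise ValueError("gene map is empty")
    for g in config.enriched_genes:
        if g not in config.gene_intervals:
            raise ValueError(f"enriched gene {g!r} not in the gene map")

    rng = np.random.default_rng(config.stream_seed("variants"))
    n = config.n_variants
    manifest = sample_manifest(config)
    cases = manifest["cases"]
    controls = manifest["controls"]
    trio = manifest["trio"]

    # positions within gene intervals, unique
    gene_idx = rng.integers(0, len(genes), size=n)
    starts = np.array([config.gene_intervals[g][0] for g in genes])
    ends = np.array([config.gene_intervals[g][1] for g in genes])
    pos = rng.integers(starts[gene_idx], ends[gene_idx]) + 1  # 1-based
    seen: set[int] = set()
    for i in range(n):
        while int(pos[i]) in seen:
            pos[i] = rng.integers(starts[gene_idx[i]], ends[gene_idx[i]]) + 1
        seen.add(int(pos[i]))
    order = np.argsort(pos, kind="stable")
    pos, gene_idx = pos[order], gene_idx[order]

    is_indel = rng.random(n) < config.indel_fraction

    # population allele frequencies
    a, b = config.af_beta
    af = rng.beta(a, b, size=n)
    af = np.clip(af, 5e-5, 0.999)
    common = rng.random(n) < config.common_fraction
    af[common] = rng.uniform(*config.common_af_range, size=int(common.sum()))

    # genotype dosages ------------------------------------------------
    mult = np.array(
        [config.enriched_genes.get(genes[gi], 1.0) for gi in gene_idx]
    )
    p_case = _case_allele_prob(af, mult)
    dos_cases = rng.binomial(2, p_case, size=(len(cases), n))
    dos_controls = rng.binomial(2, af, size=(len(controls), n))
    blocks = [dos_cases, dos_controls]
    sample_ids = list(cases) + list(controls)
    if trio:
        dos_parents = rng.binomial(2, af, size=(2, n))
        transmit = rng.binomial(1, dos_parents[0] / 2.0) + rng.binomial(
            1, dos_parents[1] / 2.0
        )
        de_novo = rng.random(n) < config.de_novo_rate
        dos_child = np.minimum(transmit + de_novo.astype(int), 2)
        blocks += [dos_parents, dos_child[None, :]]
        sample_ids += [trio["father"], trio["mother"], trio["child"]]
    dosage = np.vstack(blocks)
    missing = rng.random(dosage.shape) < config.missing_gt_prob

    # site QC metrics -------------------------------------------------
    metrics = _simulate_metrics(rng, n, is_indel, config.qc_fail_fraction,
                                config.metric_missing_prob)

    # alleles ---------------------------------------------------------
    refs, alts = _simulate_alleles(rng, n, is_indel)

    # annotations -----------------------------------------------------
    novel = rng.random(n) < config.novel_fraction
    in_dbsnp = ~novel
    in_1000g = in_dbsnp & (rng.random(n) < 0.9)
    af_missing = in_dbsnp & (rng.random(n) < config.af_missing_prob)
    af_noise = np.clip(af * (1.0 + rng.normal(0.0, 0.1, size=n)), 0.0, 1.0)
    af_noise2 = np.clip(af * (1.0 + rng.normal(0.0, 0.1, size=n)), 0.0, 1.0)
    deleterious = rng.random(n) < config.deleterious_fraction
    func_class = _simulate_classes(rng, is_indel)
    pred_u = rng.random((n, len(PREDICTORS)))
    pred_missing = rng.random((n, len(PREDICTORS))) < config.predictor_missing_prob
    damaging_p = np.where(
        deleterious, config.predictor_damaging_prob, config.predictor_false_prob
    )

    code = {0: HOM_REF, 1: HET, 2: HOM_ALT}
    records: list[VariantRecord] = []
    annotations: dict[str, VariantAnnotation] = {}
    for i in range(n):
        genotypes = {}
        for s, sid in enumerate(sample_ids):
            genotypes[sid] = MISSING if missing[s, i] else code[int(dosage[s, i])]
        rec = VariantRecord(
            chrom=config.chrom,
            pos=int(pos[i]),
            ref=refs[i],
            alt=alts[i],
            vtype="indel" if is_indel[i] else "SNP",
            metrics=metrics[i],
            genotypes=genotypes,
        )
        records.append(rec)
        if func_class[i] == "nonsynonymous":
            calls = {
                p: "missing"
                if pred_missing[i, j]
                else ("damaging" if pred_u[i, j] < damaging_p[i] else "tolerated")
                for j, p in enumerate(PREDICTORS)
            }
        else:
            calls = {p: "missing" for p in PREDICTORS}
        annotations[rec.key] = VariantAnnotation(
            key=rec.key,
            gene=genes[gene_idx[i]],
            functional_class=func_class[i],
            in_dbsnp=bool(in_dbsnp[i]),
            in_1000g=bool(in_1000g[i]),
            af_eas_1000g=None if (novel[i] or af_missing[i]) else round(float(af_noise[i]), 6),
            af_exac_eas=None if (novel[i] or af_missing[i]) else round(float(af_noise2[i]), 6),
            predictor_calls=calls,
        )
    full_manifest = {"samples": manifest, "seed": config.seed, "config": config.to_dict()}
    return records, annotations, full_manifest


def _simulate_classes(rng: np.random.Generator, is_indel: np.ndarray) -> list[str]:
    n = is_indel.size
    snp_classes = ["synonymous", "nonsynonymous", "stop_gain", "splice", "unknown"]
    snp_p = [0.35, 0.45, 0.05, 0.05, 0.10]
    indel_classes = ["frameshift", "splice", "nonsynonymous", "unknown"]
    indel_p = [0.45, 0.05, 0.20, 0.30]
    out = np.empty(n, dtype=object)
    snp_mask = ~is_indel
    out[snp_mask] = rng.choice(snp_classes, size=int(snp_mask.sum()), p=snp_p)
    out[is_indel] = rng.choice(indel_classes, size=int(is_indel.sum()), p=indel_p)
    assert set(out) <= set(FUNCTIONAL_CLASSES)
    return list(out)


def _simulate_alleles(
    rng: np.random.Generator, n: int, is_indel: np.ndarray
) -> tuple[list[str], list[str]]:
    base_i = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    extra_i = rng.integers(0, 4, size=n)
    ins = rng.random(n) < 0.5
    refs, alts = [], []
    for i in range(n):
        b = _BASES[base_i[i]]
        if not is_indel[i]:
            refs.append(b)
            alts.append(_BASES[(base_i[i] + alt_shift[i]) % 4])
        elif ins[i]:
            refs.append(b)
            alts.append(b + _BASES[extra_i[i]])
        else:
            refs.append(b + _BASES[extra_i[i]])
            alts.append(b)
    return refs, alts


_SNP_FAIL = {
    "QD": lambda rng: rng.uniform(0.0, 1.9),
    "FS": lambda rng: rng.uniform(61.0, 150.0),
    "SOR": lambda rng: rng.uniform(4.1, 9.0),
    "MQ": lambda rng: rng.uniform(10.0, 39.0),
    "MQRankSum": lambda rng: rng.uniform(-20.0, -13.0),
    "ReadPosRankSum": lambda rng: rng.uniform(-15.0, -8.5),
}
_INDEL_FAIL = {
    "QD": lambda rng: rng.uniform(0.0, 1.9),
    "FS": lambda rng: rng.uniform(201.0, 400.0),
    "SOR": lambda rng: rng.uniform(10.1, 20.0),
    "InbreedingCoeff": lambda rng: rng.uniform(-1.0, -0.85),
    "ReadPosRankSum": lambda rng: rng.uniform(-30.0, -20.5),
}


def _simulate_metrics(
    rng: np.random.Generator,
    n: int,
    is_indel: np.ndarray,
    fail_fraction: float,
    missing_prob: float,
) -> list[dict[str, float]]:
    """Nominal GATK-style site metrics; a fraction violates one rule."""
    fail = rng.random(n) < fail_fraction
    out: list[dict[str, float]] = []
    for i in range(n):
        m = {
            "QD": float(np.clip(rng.normal(22.0, 6.0), 2.1, 45.0)),
            "FS": float(rng.uniform(0.0, 20.0)),
            "SOR": float(rng.uniform(0.3, 2.5)),
            "MQ": float(np.clip(rng.normal(59.0, 2.0), 40.1, 70.0)),
            "MQRankSum": float(np.clip(rng.normal(0.0, 1.5), -12.0, 12.0)),
            "ReadPosRankSum": float(np.clip(rng.normal(0.0, 1.5), -7.5, 7.5)),
            "InbreedingCoeff": float(np.clip(rng.normal(0.0, 0.1), -0.75, 0.9)),
        }
        # rank-sum style annotations are genuinely absent at some sites
        for k in ("MQRankSum", "ReadPosRankSum", "InbreedingCoeff"):
            if rng.random() < missing_prob:
                m.pop(k)
        if fail[i]:
            rules = _INDEL_FAIL if is_indel[i] else _SNP_FAIL
            name = list(rules)[rng.integers(0, len(rules))]
            m[name] = float(rules[name](rng))
        out.append({k: round(v, 3) for k, v in m.items()})
    return out


# ---------------------------------------------------------------------
# CNV calls


def simulate_cnv_calls(config: SimulationConfig) -> pd.DataFrame:
    """Per-sample CNV call table (CNVnator-style fields).

    Carrier cases receive the planted recurrent duplication with jittered
    boundaries (still mutually concordant at >50% reciprocal overlap);
    parents carry it with ``parent_carrier_prob``. Noise calls are scattered
    elsewhere with realistic length spectrum; a configurable fraction
    deliberately fails call-level QC. Columns: sample_id, role, chrom,
    start, end, cnv_type, p_value, q0_fraction, normalized_rd.
    """
    p = config.cnv
    ds, de = p.dup_interval
    if not (0 <= ds < de <= config.region_length):
        raise ValueError(f"recurrent duplication locus {ds}-{de} outside region")
    rng = np.random.default_rng(config.stream_seed("cnv"))
    manifest = sample_manifest(config)
    rows: list[dict] = []

    def planted_dup(sample_id: str, role: str) -> dict:
        j = p.boundary_jitter
        start = ds + int(rng.integers(-j, j + 1)) if j else ds
        end = de + int(rng.integers(-j, j + 1)) if j else de
        return dict(
            sample_id=sample_id,
            role=role,
            chrom=config.chrom,
            start=start,
            end=end,
            cnv_type="DUP",
            p_value=float(rng.uniform(1e-6, 0.009)),
            q0_fraction=float(rng.uniform(0.0, 0.3)),
            normalized_rd=float(rng.normal(1.5, 0.05)),
        )

    def noise_calls(sample_id: str, role: str) -> list[dict]:
        k = rng.poisson(p.noise_calls_per_sample)
        calls = []
        for _ in range(k):
            length = int(np.clip(np.exp(rng.normal(math.log(9_000), 0.8)), 200, 300_000))
            start = int(rng.integers(0, max(1, config.region_length - length)))
            call = dict(
                sample_id=sample_id,
                role=role,
                chrom=config.chrom,
                start=start,
                end=start + length,
                cnv_type="DUP" if rng.random() < 0.6 else "DEL",
                p_value=float(rng.uniform(1e-6, 0.009)),
                q0_fraction=float(rng.uniform(0.0, 0.45)),
                normalized_rd=float(rng.normal(1.0, 0.3)),
            )
            if rng.random() < p.qc_fail_fraction:
                mode = rng.integers(0, 3)
                if mode == 0:
                    call["p_value"] = float(rng.uniform(0.011, 0.5))
                elif mode == 1:
                    call["end"] = call["start"] + int(rng.integers(100, 1_000))
                else:
                    call["q0_fraction"] = float(rng.uniform(0.51, 1.0))
            calls.append(call)
        return calls

    for sid in manifest["cases"]:
        if rng.random() < p.carrier_prob:
            rows.append(planted_dup(sid, "case"))
        rows.extend(noise_calls(sid, "case"))
    trio = manifest["trio"]
    if trio:
        for role_name, sid in (("father", trio["father"]), ("mother", trio["mother"])):
            if rng.random() < p.parent_carrier_prob:
                rows.append(planted_dup(sid, role_name))
            rows.extend(noise_calls(sid, role_name))
        if p.include_child_deletion_call:
            s, e = config.deletion.interval
            rows.append(
                dict(
                    sample_id=trio["child"],
                    role="child",
                    chrom=config.chrom,
                    start=s,
                    end=e,
                    cnv_type="DEL",
                    p_value=1e-6,
                    q0_fraction=float(rng.uniform(0.0, 0.2)),
                    normalized_rd=float(rng.normal(0.5, 0.03)),
                )
            )
        rows.extend(noise_calls(trio["child"], "child"))
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "role",
            "chrom",
            "start",
            "end",
            "cnv_type",
            "p_value",
            "q0_fraction",
            "normalized_rd",
        ],
    )
    return df.sort_values(["sample_id", "start", "end"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------
# depth profiles


def simulate_depth_profile(
    config: SimulationConfig, role: str = "case", sample_id: str | None = None
) -> DepthProfile:
    """Binned read-depth profile with negative-binomial overdispersion.

    Bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)``. For ``role="child"``
    bins inside the configured deletion interval have their expectation
    scaled by the deletion depth ratio (0.5 for a heterozygous loss).
    ``depth_cv = 0`` gives noiseless (exact-expectation) profiles.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    roles = ("case", "control", "father", "mother", "child")
    if role not in roles:
        raise ValueError(f"unknown role {role!r}")
    rng = np.random.default_rng(config.stream_seed("depth", roles.index(role)))
    n_bins = math.ceil(config.region_length / config.bin_size)
    mean = np.full(n_bins, config.mean_depth, dtype=float)
    if role == "child":
        s, e = config.deletion.interval
        b0 = s // config.bin_size
        b1 = math.ceil(e / config.bin_size)
        mean[b0:b1] *= config.deletion.depth_ratio
    if config.depth_cv == 0:
        depths = mean.copy()
    else:
        # dispersion k from the cv at full depth: var = mu + mu^2/k
        mu0 = config.mean_depth
        excess = (config.depth_cv * mu0) ** 2 - mu0
        if excess <= 0:
            depths = rng.poisson(mean).astype(float)
        else:
            k = mu0**2 / excess
            depths = rng.negative_binomial(k, k / (k + mean)).astype(float)
    return DepthProfile(
        sample_id=sample_id or f"{role}01",
        bin_size=config.bin_size,
        depths=depths,
    )


# ---------------------------------------------------------------------
# DGV-style frequency track


def simulate_frequency_track(
    config: SimulationConfig, n_common: int = 30, n_rare: int = 30
) -> pd.DataFrame:
    """Population CNV frequency track (chrom, start, end, frequency).

    Common records (frequency > 1%) avoid the planted duplication locus so
    the planted candidate stays classifiable as rare; rare records are
    scattered freely.
    """
    rng = np.random.default_rng(config.stream_seed("track"))
    ds, de = config.cnv.dup_interval
    margin = 50_000
    rows = []
    for _ in range(n_common):
        length = int(np.clip(np.exp(rng.normal(math.log(20_000), 0.7)), 1_000, 200_000))
        while True:
            start = int(rng.integers(0, max(1, config.region_length - length)))
            if start + length <= ds - margin or start >= de + margin:
                break
        rows.append((config.chrom, start, start + length, float(rng.uniform(0.02, 0.25))))
    for _ in range(n_rare):
        length = int(np.clip(np.exp(rng.normal(math.log(20_000), 0.7)), 1_000, 200_000))
        start = int(rng.integers(0, max(1, config.region_length - length)))
        rows.append((config.chrom, start, start + length, float(rng.uniform(5e-4, 0.008))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "frequency"])
    return df.sort_values(["start", "end"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------
# phenotypes and qPCR


_SIDES = ("L", "R", "B")
_DEGREES = ("I", "II", "III")
_LESIONS = ("VSD", "ASD", "TOF", "PDA", "PFO", "TI", "PI", "PH")


def simulate_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Synthetic clinical table for the discovery cohort.

    One row per sporadic case (plus the trio child when enabled) with sex,
    age, ear laterality, microtia degree and one or two cardiac lesions,
    drawn with the male excess and degree-II predominance typical of
    microtia cohorts. Schema matches the packaged reference cohort
    (:func:`q22screen.validation_reporting.load_reference_cohort`).
    """
    rng = np.random.default_rng(config.stream_seed("phenotypes"))
    rows = []
    n = config.n_cases + (1 if config.include_trio else 0)
    for i in range(n):
        familial = config.include_trio and i == n - 1
        lesions = list(
            rng.choice(_LESIONS, size=1 + int(rng.random() < 0.2), replace=False,
                       p=[0.35, 0.2, 0.15, 0.08, 0.07, 0.05, 0.05, 0.05])
        )
        rows.append(
            dict(
                patient_id=i + 1,
                sex="M" if rng.random() < 0.72 else "F",
                age=int(np.clip(np.exp(rng.normal(math.log(10), 0.5)), 1, 40)),
                ear_side=str(rng.choice(_SIDES, p=[0.35, 0.55, 0.10])),
                microtia_degree=str(rng.choice(_DEGREES, p=[0.30, 0.57, 0.13])),
                cardiac=";".join(lesions),
                other_anomalies="",
                familial_child=familial,
            )
        )
    return pd.DataFrame(rows)


def simulate_qpcr(config: SimulationConfig) -> pd.DataFrame:
    """Triplicate qPCR Ct table for the validation cohort.

    Each sample gets three target-probe and three reference-probe Ct
    replicates. A carrier's target Ct is shifted by
    ``ct_shift_per_extra_copy`` cycles per extra-copy unit relative to the
    diploid baseline; the first control is the designated diploid
    calibrator. With ``replicate_sd = 0`` replicates are exact.
    """
    q = config.qpcr
    rng = np.random.default_rng(config.stream_seed("qpcr"))
    rows = []

    def sample_rows(sid: str, group: str, carrier_prob: float, calibrator: bool):
        carrier = (not calibrator) and rng.random() < carrier_prob
        extra = q.extra_copies if carrier else 0
        male_p = q.case_male_prob if group == "case" else q.control_male_prob
        age_mean = q.case_age_mean if group == "case" else q.control_age_mean
        dct_true = q.base_dct + q.ct_shift_per_extra_copy * extra
        ref = q.ref_ct_mean + rng.normal(0.0, 0.3)
        row = dict(
            sample_id=sid,
            group=group,
            age=float(np.clip(rng.normal(age_mean, q.age_sd), 0.5, 90.0)),
            sex="M" if rng.random() < male_p else "F",
            is_calibrator=calibrator,
            true_extra_copies=extra,
        )
        for r in range(3):
            row[f"ct_reference_{r + 1}"] = round(ref + rng.normal(0.0, q.replicate_sd), 4)
            row[f"ct_target_{r + 1}"] = round(
                ref + dct_true + rng.normal(0.0, q.replicate_sd), 4
            )
        rows.append(row)

    for i in range(config.validation_n_controls):
        sample_rows(f"vctrl{i + 1:03d}", "control", q.control_carrier_prob, i == 0)
    for i in range(config.validation_n_cases):
        sample_rows(f"vcase{i + 1:03d}", "case", q.case_carrier_prob, False)
    return pd.DataFrame(rows)
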