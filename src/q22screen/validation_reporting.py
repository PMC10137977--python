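"""qPCR ddCt copy-number estimation, covariate-adjusted group comparison,
and clinical cohort summaries.

The ddCt method turns triplicate cycle-threshold (Ct) measurements into a
relative copy number per sample: dCt = mean target Ct minus mean reference
Ct; ddCt = dCt minus the diploid calibrator's dCt; relative copy number
= ``2 * 2^(-ddCt)`` (anchored so the calibrator is exactly 2 copies,
making duplication/deletion thresholds interpretable). Group differences
in copy number are assessed by ordinary least squares adjusted for age and
sex, with a two-sided t-test on the group coefficient.

Cohort summaries tabulate counts and half-up two-decimal percentages of
sex, microtia degree, ear laterality and cardiac lesions over the selected
patient denominator (sporadic patients only by default; the familial
child is excluded). Multi-lesion patients count once per lesion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import round_half_up

__all__ = [
    "QpcrSample",
    "RelativeCopyNumber",
    "load_reference_cohort",
    "qpcr_samples_from_frame",
    "ddct_relative_cn",
    "cn_group_regression",
    "summarize_cohort",
    "variant_spectrum",
    "write_report",
]


@dataclass
class QpcrSample:
    """One qPCR-assayed sample: triplicate target and reference Ct values."""

    sample_id: str
    group: str  # "case" | "control"
    age: float
    sex: str  # "M" | "F"
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]
    is_calibrator: bool = False

    def __post_init__(self) -> None:
        for cts in (self.ct_target, self.ct_reference):
            if any(c <= 0 or not np.isfinite(c) for c in cts):
                raise ValueError(f"Ct values must be positive and finite: {cts}")


@dataclass(frozen=True)
class RelativeCopyNumber:
    """ddCt result; the calibrator has ddCt = 0 and rel_cn = 2 by
    construction."""

    sample_id: str
    dct: float
    ddct: float
    rel_cn: float


def load_reference_cohort() -> pd.DataFrame:
    """The packaged reference clinical table: 20 patients with microtia and
    CHD (19 sporadic plus the nuclear-family child)."""
    with resources.files("q22screen.data").joinpath("clinical_features.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False, dtype={"other_anomalies": str})
    df["familial_child"] = df["familial_child"].astype(str).str.lower() == "true"
    return df


def qpcr_samples_from_frame(df: pd.DataFrame) -> list[QpcrSample]:
    """Build :class:`QpcrSample` objects from a wide triplicate Ct table."""
    out = []
    for r in df.itertuples(index=False):
        out.append(
            QpcrSample(
                sample_id=str(r.sample_id),
                group=str(r.group),
                age=float(r.age),
                sex=str(r.sex),
                ct_target=tuple(float(getattr(r, f"ct_target_{i}")) for i in (1, 2, 3)),
                ct_reference=tuple(
                    float(getattr(r, f"ct_reference_{i}")) for i in (1, 2, 3)
                ),
                is_calibrator=bool(r.is_calibrator),
            )
        )
    return out


def ddct_relative_cn(batch: Sequence[QpcrSample]) -> list[RelativeCopyNumber]:
    """Relative copy number for every sample in a batch via ddCt.

    Replicates are aggregated by arithmetic mean before dCt. At least one
    calibrator must be present (its mean dCt anchors ddCt = 0); each sample
    needs all three replicates of both probes.
    """
    calibrators = [s for s in batch if s.is_calibrator]
    if not calibrators:
        raise ValueError("no calibrator sample in the batch")
    for s in batch:
        if len(s.ct_target) != 3 or len(s.ct_reference) != 3:
            raise ValueError(f"sample {s.sample_id}: expected 3 replicates per probe")
    dct = {s.sample_id: float(np.mean(s.ct_target) - np.mean(s.ct_reference)) for s in batch}
    cal_dct = float(np.mean([dct[s.sample_id] for s in calibrators]))
    out = []
    for s in batch:
        ddct = dct[s.sample_id] - cal_dct
        out.append(
            RelativeCopyNumber(
                sample_id=s.sample_id,
                dct=dct[s.sample_id],
                ddct=ddct,
                rel_cn=2.0 * 2.0 ** (-ddct),
            )
        )
    return out


def cn_group_regression(
    rel_cn: Sequence[float],
    groups: Sequence[str],
    age: Sequence[float],
    sex: Sequence[str],
) -> dict[str, float]:
    """OLS of relative copy number on group, adjusted for age and sex.

    Group is coded case = 1 / control = 0 and sex M = 1 / F = 0; no
    interactions. Returns the group coefficient, its standard error and
    the two-sided t-test p-value. A constant outcome or a singular design
    (e.g. a constant covariate column) raises.
    """
    y = np.asarray(rel_cn, dtype=float)
    g = np.asarray([1.0 if v == "case" else 0.0 for v in groups])
    if len(set(groups)) < 2:
        raise ValueError("need at least two groups")
    x_age = np.asarray(age, dtype=float)
    x_sex = np.asarray([1.0 if v == "M" else 0.0 for v in sex])
    X = np.column_stack([np.ones_like(y), g, x_age, x_sex])
    if y.size <= X.shape[1]:
        raise ValueError("need more samples than coefficients")
    if np.ptp(y) == 0:
        raise ValueError("degenerate fit: constant outcome vector")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (constant covariate column?)")
    fit = sm.OLS(y, X).fit()
    return {
        "group_coef": float(fit.params[1]),
        "group_se": float(fit.bse[1]),
        "group_p": float(fit.pvalues[1]),
        "n": int(y.size),
    }


_CATEGORY_COLUMNS = {
    "sex": ("M", "F"),
    "microtia_degree": ("I", "II", "III"),
    "ear_side": ("L", "R", "B"),
}
_LESIONS = ("VSD", "ASD", "TOF", "PDA", "PFO", "TI", "PI", "PH")


def summarize_cohort(
    phenotypes: pd.DataFrame, sporadic_only: bool = True
) -> dict:
    """Counts and percentages of clinical categories over the cohort.

    With ``sporadic_only`` the familial child is excluded and percentages
    use the sporadic-patient denominator. Mutually exclusive families
    (sex, degree, laterality) sum to 100% up to rounding; cardiac lesions
    are counted once per lesion per patient, so their percentages need not
    sum to 100. The mean age is emitted unrounded.
    """
    df = phenotypes
    if sporadic_only and "familial_child" in df.columns:
        df = df[~df["familial_child"]]
    n = len(df)
    if n == 0:
        raise ValueError("empty cohort")
    summary: dict = {"n": n, "mean_age": float(df["age"].mean())}
    for col, levels in _CATEGORY_COLUMNS.items():
        counts = df[col].value_counts()
        summary[col] = {
            level: {
                "count": int(counts.get(level, 0)),
                "percent": round_half_up(100.0 * counts.get(level, 0) / n, 2),
            }
            for level in levels
        }
    lesion_counts = {lesion: 0 for lesion in _LESIONS}
    for entry in df["cardiac"]:
        for lesion in {x.strip() for x in str(entry).split(";") if x.strip()}:
            if lesion in lesion_counts:
                lesion_counts[lesion] += 1
    summary["cardiac"] = {
        lesion: {
            "count": c,
            "percent": round_half_up(100.0 * c / n, 2),
        }
        for lesion, c in lesion_counts.items()
    }
    return summary


def variant_spectrum(records, annotations, case_ids: Sequence[str]) -> dict:
    """Descriptive tallies: occurrence-across-cases histogram, coding-class
    counts and the indel length distribution."""
    from .variant_prioritization import DOSAGE, MISSING

    occurrence: dict[int, int] = {}
    class_counts: dict[str, int] = {}
    indel_lengths: dict[int, int] = {}
    for rec in records:
        carriers = sum(
            1
            for s in case_ids
            if DOSAGE[rec.genotypes.get(s, MISSING)] > 0
        )
        if carriers:
            occurrence[carriers] = occurrence.get(carriers, 0) + 1
        ann = annotations.get(rec.key)
        if ann is not None:
            class_counts[ann.functional_class] = (
                class_counts.get(ann.functional_class, 0) + 1
            )
        if rec.vtype == "indel":
            ln = abs(len(rec.ref) - len(rec.alt))
            indel_lengths[ln] = indel_lengths.get(ln, 0) + 1
    return {
        "occurrence_in_cases": {str(k): occurrence[k] for k in sorted(occurrence)},
        "n_in_all_cases": occurrence.get(len(case_ids), 0),
        "functional_class_counts": dict(sorted(class_counts.items())),
        "indel_length_counts": {str(k): indel_lengths[k] for k in sorted(indel_lengths)},
    }


def write_report(
    outdir: str | Path,
    *,
    funnel: Mapping[str, int],
    burden_table: pd.DataFrame,
    cnv_candidates: pd.DataFrame,
    deletion_calls: pd.DataFrame,
    cohort_summary: Mapping,
    qpcr_summary: Mapping,
    spectrum: Mapping,
) -> Path:
    """Write the report bundle (TSV/JSON) to ``outdir``; deterministic
    given identical inputs. Every stage output is required."""
    for name, value in (
        ("funnel", funnel),
        ("burden_table", burden_table),
        ("cnv_candidates", cnv_candidates),
        ("deletion_calls", deletion_calls),
        ("cohort_summary", cohort_summary),
        ("qpcr_summary", qpcr_summary),
        ("spectrum", spectrum),
    ):
        if value is None:
            raise ValueError(f"missing stage output: {name}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "funnel.json").write_text(json.dumps(dict(funnel), indent=2, sort_keys=True) + "\n")
    burden_table.to_csv(outdir / "burden.tsv", sep="\t", index=False)
    cnv_candidates.to_csv(outdir / "cnv_candidates.tsv", sep="\t", index=False)
    deletion_calls.to_csv(outdir / "deletion_calls.tsv", sep="\t", index=False)
    for name, payload in (
        ("cohort_summary", cohort_summary),
        ("qpcr_summary", qpcr_summary),
        ("variant_spectrum", spectrum),
    ):
        (outdir / f"{name}.json").write_text(
            json.dumps(dict(payload), indent=2, sort_keys=True) + "\n"
        )
    return outdir
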