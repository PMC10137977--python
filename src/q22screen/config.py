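"""Simulation configuration for the synthetic 22q11.2-style cohort.

The defaults describe the study design the pipeline targets: a contiguous
~8 Mb capture region screened in 19 sporadic cases plus one nuclear family
(father, mother, affected child), with 103 population controls (a CHB-style
panel) for the gene-burden comparison and a 64-case / 96-control validation
set for qPCR. The trio child carries a ~3 Mb heterozygous deletion
(0.5x depth); a recurrent duplication locus can be planted across cases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping


@dataclass
class CnvParams:
    """Recurrent-duplication planting and per-sample CNV call noise.

    ``boundary_jitter`` is the maximum absolute uniform shift (bp) applied
    independently to each bound of a carrier's call; with the default 40 kb
    locus this keeps all carrier calls mutually concordant (>50% reciprocal
    overlap). ``qc_fail_fraction`` of the noise calls deliberately violate
    one of the call-level QC rules (p-value, size, q0) so filters are
    exercised.
    """

    dup_interval: tuple[int, int] = (2_000_000, 2_040_000)
    carrier_prob: float = 0.65
    parent_carrier_prob: float = 0.0
    boundary_jitter: int = 2_000
    noise_calls_per_sample: float = 12.0
    qc_fail_fraction: float = 0.2
    include_child_deletion_call: bool = True


@dataclass
class DeletionParams:
    """Trio-child large heterozygous deletion (depth ratio 0.5)."""

    interval: tuple[int, int] = (650_000, 3_650_000)
    depth_ratio: float = 0.5


@dataclass
class QpcrParams:
    """qPCR simulation for the validation cohort.

    The target-probe Ct shifts by ``ct_shift_per_extra_copy`` cycles per
    extra copy relative to the diploid calibrator, so a carrier with one
    extra-copy unit has ddCt = -1 and relative copy number 2*2^1 = 4.
    Ages and sex ratios default to the validation-set demographics
    (cases mean 11.39 y, 57.81% male; controls mean 39.23 y, 40.63% male).
    """

    case_carrier_prob: float = 0.5
    control_carrier_prob: float = 0.02
    extra_copies: int = 1
    ct_shift_per_extra_copy: float = -1.0
    replicate_sd: float = 0.1
    base_dct: float = 2.0
    ref_ct_mean: float = 25.0
    case_age_mean: float = 11.39
    control_age_mean: float = 39.23
    age_sd: float = 8.0
    case_male_prob: float = 0.5781
    control_male_prob: float = 0.4063


def _default_gene_intervals(
    region_length: int, n_genes: int, gene_length: int
) -> dict[str, tuple[int, int]]:
    spacing = region_length // n_genes
    if gene_length >= spacing:
        raise ValueError("gene_length must be smaller than region_length / n_genes")
    offset = (spacing - gene_length) // 2
    return {
        f"GENE{i + 1:03d}": (i * spacing + offset, i * spacing + offset + gene_length)
        for i in range(n_genes)
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; identical config + seed gives
    byte-identical outputs.

    ``enriched_genes`` maps gene name -> case odds multiplier applied to the
    per-allele carrier odds in cases only (1.0 = null). Population allele
    frequencies follow a beta law concentrated below 1% with a configurable
    fraction of common (>1%) sites to exercise the rarity exclusion.
    """

    region_length: int = 8_000_000
    chrom: str = "22"
    n_genes: int = 40
    gene_length: int = 40_000
    gene_intervals: dict[str, tuple[int, int]] | None = None
    n_cases: int = 19
    n_controls: int = 103
    include_trio: bool = True
    enriched_genes: dict[str, float] = field(default_factory=dict)
    n_variants: int = 4_000
    af_beta: tuple[float, float] = (0.2, 20.0)
    common_fraction: float = 0.12
    common_af_range: tuple[float, float] = (0.011, 0.30)
    indel_fraction: float = 0.18
    qc_fail_fraction: float = 0.05
    metric_missing_prob: float = 0.10
    novel_fraction: float = 0.30
    af_missing_prob: float = 0.05
    deleterious_fraction: float = 0.35
    predictor_damaging_prob: float = 0.80
    predictor_false_prob: float = 0.05
    predictor_missing_prob: float = 0.05
    missing_gt_prob: float = 0.01
    de_novo_rate: float = 0.02
    mean_depth: float = 80.0
    depth_cv: float = 0.15
    bin_size: int = 100
    cnv: CnvParams = field(default_factory=CnvParams)
    deletion: DeletionParams = field(default_factory=DeletionParams)
    qpcr: QpcrParams = field(default_factory=QpcrParams)
    validation_n_cases: int = 64
    validation_n_controls: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_intervals is None:
            self.gene_intervals = _default_gene_intervals(
                self.region_length, self.n_genes, self.gene_length
            )
        else:
            self.gene_intervals = {
                g: (int(a), int(b)) for g, (a, b) in self.gene_intervals.items()
            }
            self.n_genes = len(self.gene_intervals)
        self._validate()

    def _validate(self) -> None:
        errs = []
        for name, count in (
            ("region_length", self.region_length),
            ("n_cases", self.n_cases),
            ("n_controls", self.n_controls),
            ("n_variants", self.n_variants),
            ("bin_size", self.bin_size),
        ):
            if count <= 0:
                errs.append(f"{name} must be positive (got {count})")
        prev_end = -1
        for gene, (start, end) in sorted(
            self.gene_intervals.items(), key=lambda kv: kv[1]
        ):
            if not (0 <= start < end <= self.region_length):
                errs.append(f"gene {gene} interval {start}-{end} outside region")
            if start < prev_end:
                errs.append(f"gene {gene} overlaps the previous gene interval")
            prev_end = end
        for name, p in (
            ("common_fraction", self.common_fraction),
            ("indel_fraction", self.indel_fraction),
            ("qc_fail_fraction", self.qc_fail_fraction),
            ("metric_missing_prob", self.metric_missing_prob),
            ("novel_fraction", self.novel_fraction),
            ("af_missing_prob", self.af_missing_prob),
            ("deleterious_fraction", self.deleterious_fraction),
            ("predictor_damaging_prob", self.predictor_damaging_prob),
            ("predictor_false_prob", self.predictor_false_prob),
            ("predictor_missing_prob", self.predictor_missing_prob),
            ("missing_gt_prob", self.missing_gt_prob),
            ("de_novo_rate", self.de_novo_rate),
            ("cnv.carrier_prob", self.cnv.carrier_prob),
            ("cnv.parent_carrier_prob", self.cnv.parent_carrier_prob),
            ("cnv.qc_fail_fraction", self.cnv.qc_fail_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                errs.append(f"{name} must be in [0,1] (got {p})")
        if self.mean_depth <= 0:
            errs.append(f"mean_depth must be positive (got {self.mean_depth})")
        if self.depth_cv < 0:
            errs.append("depth_cv must be >= 0")
        ds, de = self.deletion.interval
        if not (0 <= ds < de <= self.region_length):
            errs.append(f"deletion interval {ds}-{de} outside region")
        if errs:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errs))

    def stream_seed(self, purpose: str, extra: int = 0) -> list[int]:
        """Seed-sequence key for an independent, purpose-bound RNG stream."""
        streams = {"variants": 1, "cnv": 2, "depth": 3, "phenotypes": 4, "qpcr": 5, "track": 6}
        if purpose not in streams:
            raise ValueError(f"unknown stream {purpose!r}")
        return [int(self.seed), streams[purpose], int(extra)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if d.get("cnv") is not None and not isinstance(d["cnv"], CnvParams):
            c = dict(d["cnv"])
            c["dup_interval"] = tuple(c["dup_interval"])
            d["cnv"] = CnvParams(**c)
        if d.get("deletion") is not None and not isinstance(d["deletion"], DeletionParams):
            c = dict(d["deletion"])
            c["interval"] = tuple(c["interval"])
            d["deletion"] = DeletionParams(**c)
        if d.get("qpcr") is not None and not isinstance(d["qpcr"], QpcrParams):
            d["qpcr"] = QpcrParams(**dict(d["qpcr"]))
        for key in ("af_beta", "common_af_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("gene_intervals"):
            d["gene_intervals"] = {
                g: tuple(v) for g, v in d["gene_intervals"].items()
            }
        return cls(**d)
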