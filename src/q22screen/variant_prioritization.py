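"""Site-level hard filtering and the variant prioritization cascade.

The discovery-side SNV funnel for a targeted 22q11.2 screen: GATK-style
hard filters applied separately to SNPs and indels, novelty/rarity
classification against dbSNP membership and East-Asian population allele
frequencies, consequence classification into loss-of-function (LoF) and
consensus-damaging missense (damaging in at least two of eight in-silico
predictors), and an optional trio parent-absence filter for the nuclear
family.

All operations are per-site and order-independent; the cascade is a strict
funnel (each stage only removes variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "DOSAGE",
    "PREDICTORS",
    "LOF_CLASSES",
    "FUNCTIONAL_CLASSES",
    "VariantRecord",
    "FilterThresholds",
    "VariantAnnotation",
    "PrioritizedVariant",
    "apply_site_filters",
    "compute_maf",
    "classify_novelty",
    "classify_consequence",
    "flag_trio_absent",
    "prioritize_variants",
]

# genotype codes
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
GENOTYPE_CODES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})

#: alt-allele dosage per genotype code; missing contributes nothing
DOSAGE = {HOM_REF: 0, HET: 1, HOM_ALT: 2, MISSING: 0}

#: the eight in-silico damage predictors consulted for missense variants
PREDICTORS = (
    "SIFT",
    "Polyphen2",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "GERP++",
    "CADD",
)

FUNCTIONAL_CLASSES = (
    "synonymous",
    "nonsynonymous",
    "stop_gain",
    "splice",
    "frameshift",
    "unknown",
)

#: functional classes counted as loss-of-function
LOF_CLASSES = frozenset({"stop_gain", "frameshift", "splice"})

METRIC_KEYS = ("QD", "FS", "SOR", "MQ", "MQRankSum", "ReadPosRankSum", "InbreedingCoeff")


@dataclass
class VariantRecord:
    """One bi-allelic multi-sample variant site with QC metrics.

    Parameters
    ----------
    chrom, pos
        Contig name and 1-based position.
    ref, alt
        Reference and alternate allele strings (bi-allelic only; the VCF
        reader pre-splits multi-allelic sites).
    vtype
        ``"SNP"`` or ``"indel"``; must be consistent with allele lengths.
    metrics
        GATK-style site annotations (QD, FS, SOR, MQ, MQRankSum,
        ReadPosRankSum, InbreedingCoeff); any may be absent.
    genotypes
        Per-sample genotype code (``hom_ref``/``het``/``hom_alt``/``missing``).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str
    metrics: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        is_snp = len(self.ref) == 1 and len(self.alt) == 1
        if self.vtype not in ("SNP", "indel"):
            raise ValueError(f"unknown vtype {self.vtype!r}")
        if (self.vtype == "SNP") != is_snp:
            raise ValueError(
                f"vtype {self.vtype!r} inconsistent with alleles {self.ref}>{self.alt}"
            )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def _default_snp_thresholds() -> dict[str, float]:
    return {
        "QD_min": 2.0,
        "FS_max": 60.0,
        "SOR_max": 4.0,
        "MQ_min": 40.0,
        "MQRankSum_min": -12.5,
        "ReadPosRankSum_min": -8.0,
    }


def _default_indel_thresholds() -> dict[str, float]:
    return {
        "QD_min": 2.0,
        "FS_max": 200.0,
        "SOR_max": 10.0,
        "InbreedingCoeff_min": -0.8,
        "ReadPosRankSum_min": -20.0,
    }


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds, separate rule sets for SNPs and indels.

    ``*_min`` rules remove a record when the metric is strictly below the
    threshold; ``*_max`` rules when strictly above. A missing metric never
    violates a rule (hard filters only act on evidence present).
    """

    snp: Mapping[str, float] = field(default_factory=_default_snp_thresholds)
    indel: Mapping[str, float] = field(default_factory=_default_indel_thresholds)

    def rules_for(self, vtype: str) -> Mapping[str, float]:
        if vtype == "SNP":
            return self.snp
        if vtype == "indel":
            return self.indel
        raise ValueError(f"unknown vtype {vtype!r}")


@dataclass
class VariantAnnotation:
    """Population-frequency and predictor annotation for one variant.

    ``af_eas_1000g`` / ``af_exac_eas`` are East-Asian alternate-allele
    frequencies (``None`` when the panel has no record).
    ``predictor_calls`` maps each of the eight predictors to
    ``damaging``/``tolerated``/``missing``.
    """

    key: str
    gene: str
    functional_class: str
    in_dbsnp: bool
    in_1000g: bool
    af_eas_1000g: float | None = None
    af_exac_eas: float | None = None
    predictor_calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class {self.functional_class!r}")
        for f in (self.af_eas_1000g, self.af_exac_eas):
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency out of [0,1]: {f}")
        if not self.predictor_calls:
            self.predictor_calls = {p: "missing" for p in PREDICTORS}
        if set(self.predictor_calls) != set(PREDICTORS):
            raise ValueError("predictor_calls must carry exactly the 8 known predictors")

    @property
    def n_damaging(self) -> int:
        return sum(1 for v in self.predictor_calls.values() if v == "damaging")


@dataclass
class PrioritizedVariant:
    """A variant that survived the full prioritization cascade.

    ``absent_in_parents`` is ``None`` when no trio was supplied.
    ``af_assumed_zero`` marks dbSNP-known variants classed rare only
    because neither East-Asian panel reports a frequency.
    """

    key: str
    gene: str
    novelty: str  # "novel" | "rare"
    category: str  # "LoF" | "missense_damaging"
    absent_in_parents: bool | None = None
    af_assumed_zero: bool = False


def apply_site_filters(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], dict[str, list[str]]]:
    """Apply SNP/indel hard filters; return retained records and fail reasons.

    A record is removed iff at least one rule of its variant-type rule set
    is violated (strict inequalities; values exactly at a threshold pass).
    The second return value maps each removed record's key to the names of
    every violated metric.
    """
    thresholds = thresholds or FilterThresholds()
    retained: list[VariantRecord] = []
    failures: dict[str, list[str]] = {}
    for rec in records:
        rules = thresholds.rules_for(rec.vtype)
        reasons = []
        for rule, cutoff in rules.items():
            metric, kind = rule.rsplit("_", 1)
            value = rec.metrics.get(metric)
            if value is None:
                continue
            if (kind == "min" and value < cutoff) or (kind == "max" and value > cutoff):
                reasons.append(metric)
        if reasons:
            failures[rec.key] = reasons
        else:
            retained.append(rec)
    return retained, failures


def compute_maf(record: VariantRecord, samples: Sequence[str]) -> float:
    """Folded minor-allele frequency of ``record`` within a sample subset.

    Alt-allele count over ``2 x`` non-missing samples, folded to
    ``min(f, 1 - f)``. Raises if every genotype in the subset is missing.
    """
    if not samples:
        raise ValueError("sample subset is empty")
    alt = 0
    n = 0
    for sid in samples:
        g = record.genotypes[sid]
        if g == MISSING:
            continue
        alt += DOSAGE[g]
        n += 1
    if n == 0:
        raise ValueError(f"all genotypes missing for {record.key} in the given subset")
    f = alt / (2 * n)
    return min(f, 1.0 - f)


def classify_novelty(
    annotation: VariantAnnotation, maf_cutoff: float = 0.01
) -> str:
    """Classify a variant as ``novel``, ``rare`` or ``excluded``.

    Novel: absent from both dbSNP and the 1000 Genomes catalogue.
    Otherwise rare iff every *available* East-Asian frequency (1000G EAS,
    ExAC EAS) does not exceed ``maf_cutoff`` (inclusive). A catalogued
    variant with no frequency record in either panel is treated as
    frequency 0, hence rare.
    """
    if not annotation.in_dbsnp and not annotation.in_1000g:
        return "novel"
    freqs = [
        f for f in (annotation.af_eas_1000g, annotation.af_exac_eas) if f is not None
    ]
    if all(f <= maf_cutoff for f in freqs):  # vacuously rare when both missing
        return "rare"
    return "excluded"


def classify_consequence(annotation: VariantAnnotation) -> str:
    """Classify as ``LoF``, ``missense_damaging`` or ``other``.

    LoF covers stop-gain, frameshift and splice-site alterations. A
    missense (nonsynonymous) variant qualifies as damaging when at least
    two of the eight predictors call it damaging; a missing predictor
    verdict never counts as a damaging vote and the 2-vote threshold does
    not shrink with the number of predictors that reported.
    """
    if annotation.functional_class in LOF_CLASSES:
        return "LoF"
    if annotation.functional_class == "nonsynonymous" and annotation.n_damaging >= 2:
        return "missense_damaging"
    return "other"


def flag_trio_absent(
    record: VariantRecord, child: str, father: str, mother: str
) -> bool:
    """True iff the child carries >= 1 alt allele and both parents are hom-ref.

    A missing parent genotype yields ``False`` (conservative: no de-novo /
    parent-absence claim without observed parental genotypes).
    """
    for sid in (child, father, mother):
        if sid not in record.genotypes:
            raise ValueError(f"sample {sid!r} not present in record {record.key}")
    if record.genotypes[child] not in (HET, HOM_ALT):
        return False
    return (
        record.genotypes[father] == HOM_REF and record.genotypes[mother] == HOM_REF
    )


def prioritize_variants(
    records: Iterable[VariantRecord],
    annotations: Mapping[str, VariantAnnotation],
    thresholds: FilterThresholds | None = None,
    maf_cutoff: float = 0.01,
    trio: tuple[str, str, str] | None = None,
    require_parent_absent: bool = False,
) -> tuple[list[PrioritizedVariant], dict[str, int]]:
    """Run the full cascade and report a stage-by-stage funnel.

    Stages: site hard filters -> novelty in {novel, rare} -> consequence in
    {LoF, missense_damaging} -> (optional) parent absence in the trio.
    When ``trio=(child, father, mother)`` is given each emitted variant
    carries the parent-absence flag; with ``require_parent_absent=True``
    variants present in a parent are additionally dropped.

    Returns the prioritized variants (input order preserved) and the
    funnel counts.
    """
    records = list(records)
    retained, _ = apply_site_filters(records, thresholds)
    funnel = {"input": len(records), "site_pass": len(retained)}

    staged: list[PrioritizedVariant] = []
    n_novel_or_rare = 0
    for rec in retained:
        ann = annotations.get(rec.key)
        if ann is None:
            raise ValueError(f"no annotation for retained variant {rec.key}")
        novelty = classify_novelty(ann, maf_cutoff=maf_cutoff)
        if novelty == "excluded":
            continue
        n_novel_or_rare += 1
        category = classify_consequence(ann)
        if category == "other":
            continue
        assumed = (
            novelty == "rare"
            and ann.af_eas_1000g is None
            and ann.af_exac_eas is None
        )
        staged.append(
            PrioritizedVariant(
                key=rec.key,
                gene=ann.gene,
                novelty=novelty,
                category=category,
                af_assumed_zero=assumed,
            )
        )
    funnel["novel_or_rare"] = n_novel_or_rare
    funnel["lof_or_damaging"] = len(staged)

    if trio is not None:
        child, father, mother = trio
        by_key = {r.key: r for r in retained}
        for pv in staged:
            pv.absent_in_parents = flag_trio_absent(by_key[pv.key], child, father, mother)
        n_absent = sum(1 for pv in staged if pv.absent_in_parents)
        funnel["parent_absent"] = n_absent
        if require_parent_absent:
            staged = [pv for pv in staged if pv.absent_in_parents]
    return staged, funnel
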