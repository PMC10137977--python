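"""Readers and writers for every on-disk pipeline format.

VCF v4.2 (multi-sample, GT + the seven GATK-style INFO metrics) through
pysam; tab-separated tables through pandas; BED+frequency for the
population CNV track; a JSON manifest recording config and seed. Every
writer/reader pair round-trips losslessly: INFO floats are rounded to three
decimals on both sides (htslib prints 32-bit floats with six
significant digits), and the VCF
reader splits multi-allelic sites into bi-allelic records.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .cnv_recurrence import DepthProfile
from .variant_prioritization import (
    HET,
    HOM_ALT,
    HOM_REF,
    METRIC_KEYS,
    MISSING,
    PREDICTORS,
    PrioritizedVariant,
    VariantAnnotation,
    VariantRecord,
)

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_annotations",
    "read_annotations",
    "write_prioritized",
    "write_table",
    "read_table",
    "write_frequency_track",
    "read_frequency_track",
    "write_depth_profile",
    "read_depth_profile",
    "write_manifest",
    "read_manifest",
]

_GT = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def write_vcf(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    chrom: str = "22",
    chrom_length: int = 8_000_000,
) -> Path:
    """Write bi-allelic records as an uncompressed multi-sample VCF v4.2."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={chrom_length}>")
    for key in METRIC_KEYS:
        header.info.add(key, 1, "Float", f"{key} site annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in samples:
        header.add_sample(sid)
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in records:
            out = vcf.new_record(
                contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            for key in METRIC_KEYS:
                if key in rec.metrics:
                    out.info[key] = round(float(rec.metrics[key]), 3)
            for sid in samples:
                out.samples[sid]["GT"] = _GT[rec.genotypes.get(sid, MISSING)]
            vcf.write(out)
    return path


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a multi-sample VCF into variant records.

    Multi-allelic sites are split into one bi-allelic record per alternate
    allele (genotypes are re-expressed against that allele; other alternate
    alleles count as reference). INFO floats are rounded to three decimals.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for site in vcf:
            alts = site.alts or ()
            for ai, alt in enumerate(alts, start=1):
                metrics = {}
                for key in METRIC_KEYS:
                    value = site.info.get(key)
                    if value is not None:
                        metrics[key] = round(float(value), 3)
                genotypes = {}
                for sid in samples:
                    alleles = site.samples[sid]["GT"]
                    if alleles is None or any(a is None for a in alleles):
                        genotypes[sid] = MISSING
                    else:
                        dose = sum(1 for a in alleles if a == ai)
                        genotypes[sid] = (HOM_REF, HET, HOM_ALT)[dose]
                ref, alt_a = site.ref, alt
                vtype = "SNP" if len(ref) == 1 and len(alt_a) == 1 else "indel"
                records.append(
                    VariantRecord(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=ref,
                        alt=alt_a,
                        vtype=vtype,
                        metrics=metrics,
                        genotypes=genotypes,
                    )
                )
    return records, samples


# ---------------------------------------------------------------------
# annotation table


def write_annotations(
    annotations: Iterable[VariantAnnotation] | dict[str, VariantAnnotation],
    path: str | Path,
) -> Path:
    if isinstance(annotations, dict):
        annotations = annotations.values()
    rows = []
    for ann in annotations:
        row = {
            "key": ann.key,
            "gene": ann.gene,
            "functional_class": ann.functional_class,
            "in_dbsnp": ann.in_dbsnp,
            "in_1000g": ann.in_1000g,
            "af_eas_1000g": "" if ann.af_eas_1000g is None else repr(ann.af_eas_1000g),
            "af_exac_eas": "" if ann.af_exac_eas is None else repr(ann.af_exac_eas),
        }
        for p in PREDICTORS:
            row[p] = ann.predictor_calls[p]
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_annotations(path: str | Path) -> dict[str, VariantAnnotation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out: dict[str, VariantAnnotation] = {}
    for row in df.to_dict("records"):
        out[row["key"]] = VariantAnnotation(
            key=row["key"],
            gene=row["gene"],
            functional_class=row["functional_class"],
            in_dbsnp=row["in_dbsnp"] == "True",
            in_1000g=row["in_1000g"] == "True",
            af_eas_1000g=float(row["af_eas_1000g"]) if row["af_eas_1000g"] else None,
            af_exac_eas=float(row["af_exac_eas"]) if row["af_exac_eas"] else None,
            predictor_calls={p: row[p] for p in PREDICTORS},
        )
    return out


def write_prioritized(variants: Iterable[PrioritizedVariant], path: str | Path) -> Path:
    rows = [
        {
            "key": v.key,
            "gene": v.gene,
            "novelty": v.novelty,
            "category": v.category,
            "absent_in_parents": "" if v.absent_in_parents is None else v.absent_in_parents,
            "af_assumed_zero": v.af_assumed_zero,
        }
        for v in variants
    ]
    path = Path(path)
    pd.DataFrame(
        rows,
        columns=["key", "gene", "novelty", "category", "absent_in_parents", "af_assumed_zero"],
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------
# generic tables, BED track, depth, manifest


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    # repr keeps the shortest lossless decimal form so floats round-trip
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "chrom" in df.columns:  # contig names are labels, not numbers
        df["chrom"] = df["chrom"].astype(str)
    return df


def write_frequency_track(track: pd.DataFrame, path: str | Path) -> Path:
    """BED + frequency column (chrom, start, end, frequency), no header."""
    path = Path(path)
    track[["chrom", "start", "end", "frequency"]].to_csv(
        path, sep="\t", index=False, header=False,
        float_format=lambda x: repr(float(x)),
    )
    return path


def read_frequency_track(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "frequency"], header=None,
        float_precision="round_trip",
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_depth_profile(profile: DepthProfile, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#sample_id={profile.sample_id}\n")
        fh.write(f"#bin_size={profile.bin_size}\n")
        fh.write("bin_start\tdepth\n")
        for i, d in enumerate(profile.depths):
            fh.write(f"{i * profile.bin_size}\t{d:g}\n")
    return path


def read_depth_profile(path: str | Path) -> DepthProfile:
    sample_id, bin_size = "", 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key == "sample_id":
                sample_id = value
            elif key == "bin_size":
                bin_size = int(value)
    df = pd.read_csv(path, sep="\t", comment="#")
    return DepthProfile(
        sample_id=sample_id, bin_size=bin_size, depths=df["depth"].to_numpy(float)
    )


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
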