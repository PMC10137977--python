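"""Run the SNV prioritization cascade on the simulated cohort.

Applies the SNP/indel hard filters, classifies novelty/rarity against the
annotation table (novel = absent from dbSNP and 1000G; rare = every
available East-Asian frequency <= 1%), keeps LoF and consensus-damaging
missense variants (>= 2 of 8 predictors), and flags variants absent from
the healthy parents. Prints the funnel and writes
results/run/prioritized.tsv.
"""

import json
from pathlib import Path

from q22screen import io
from q22screen.variant_prioritization import FilterThresholds, prioritize_variants

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    records, _ = io.read_vcf(RUN / "inputs" / "cohort.vcf")
    annotations = io.read_annotations(RUN / "inputs" / "annotations.tsv")
    trio = io.read_manifest(RUN / "inputs" / "manifest.json")["samples"]["trio"]
    variants, funnel = prioritize_variants(
        records,
        annotations,
        FilterThresholds(),
        maf_cutoff=0.01,
        trio=(trio["child"], trio["father"], trio["mother"]),
    )
    io.write_prioritized(variants, RUN / "prioritized.tsv")
    (RUN / "funnel.json").write_text(json.dumps(funnel, indent=2) + "\n")
    print("prioritization funnel (variants surviving each stage):")
    for stage, n in funnel.items():
        print(f"  {stage:>15}: {n}")
    n_lof = sum(1 for v in variants if v.category == "LoF")
    print(f"candidates: {len(variants)} ({n_lof} LoF, "
          f"{len(variants) - n_lof} consensus-damaging missense) "
          f"-> {RUN / 'prioritized.tsv'}")


if __name__ == "__main__":
    main()
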