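"""Recurrent-CNV candidates and the trio-child deletion scan.

QC-filters the per-sample CNV calls (p < 0.01, size > 1 kb, q0 <= 50%),
merges concordant calls (>50% reciprocal overlap, same type) to their
outermost bounds, keeps candidates recurrent in >50% of the 19 cases and
absent from the parents, classifies rarity against the population CNV
track, and scans the trio child's binned depth profile for the planted
3 Mb heterozygous deletion. Writes results/run/cnv_candidates.tsv and
results/run/deletions.tsv.
"""

from pathlib import Path

import pandas as pd

from q22screen import io
from q22screen.cnv_recurrence import (
    calls_from_frame,
    classify_rare_cnv,
    cluster_and_merge,
    qc_filter_calls,
    recurrence_candidates,
    scan_depth_for_deletion,
)

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    df = io.read_table(RUN / "inputs" / "cnv_calls.tsv")
    track = io.read_frequency_track(RUN / "inputs" / "population_cnv.bed")
    n_cases = df.loc[df["role"] == "case", "sample_id"].nunique()
    case_calls = qc_filter_calls(calls_from_frame(df[df["role"] == "case"]))
    parent_calls = qc_filter_calls(
        calls_from_frame(df[df["role"].isin(["father", "mother"])])
    )
    candidates = recurrence_candidates(
        cluster_and_merge(case_calls), n_cases, parent_calls, threshold=0.5
    )
    rows = [
        dict(chrom=m.chrom, start=m.start, end=m.end, cnv_type=m.cnv_type,
             n_supporting=len(m.supporting_samples),
             recurrence_rate=round(m.recurrence_rate, 4),
             rare=classify_rare_cnv(m, track))
        for m in candidates
    ]
    out = pd.DataFrame(rows)
    io.write_table(out, RUN / "cnv_candidates.tsv")
    print(f"{len(case_calls)} case calls pass QC; "
          f"{len(candidates)} recurrent candidate(s):")
    if len(out):
        print(out.to_string(index=False))

    child = io.read_depth_profile(RUN / "inputs" / "depth_child.tsv")
    dels = scan_depth_for_deletion(child)
    del_df = pd.DataFrame(
        [dict(sample_id=d.sample_id, start=d.start, end=d.end,
              mean_normalized_depth=round(d.mean_normalized_depth, 4))
         for d in dels]
    )
    io.write_table(del_df, RUN / "deletions.tsv")
    print("depth-scan deletions in the trio child:")
    print(del_df.to_string(index=False) if len(del_df) else "  none")


if __name__ == "__main__":
    main()
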