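"""Recurrent-CNV post-processing and read-depth deletion scanning.

Turns per-sample CNV calls into merged, recurrence-filtered,
parent-subtracted, rarity-classified candidates:

* call-level QC (p-value, size, fraction of zero-mapping-quality reads);
* pairwise concordance at >50% reciprocal overlap, same type only;
* merging of concordant calls to the outermost bounds via connected
  components of the concordance graph (concordance is not transitive, so
  a component merge is needed for the covering property);
* recurrence filtering against the case count with parent subtraction
  tested against the merged interval;
* rarity classification against a DGV-style population frequency track
  (rare iff <=50% of the candidate's length is covered by the union of
  regions at >1% population frequency);
* a large-deletion scanner over binned read depth (median-normalized,
  rolling-median smoothed, thresholded runs).

All intervals are 0-based half-open internally; BED conventions on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CnvCall",
    "MergedCnv",
    "DepthProfile",
    "DeletionCall",
    "qc_filter_calls",
    "reciprocal_overlap",
    "is_concordant",
    "cluster_and_merge",
    "recurrence_candidates",
    "classify_rare_cnv",
    "presence_matrix",
    "scan_depth_for_deletion",
    "calls_from_frame",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class CnvCall:
    """One per-sample CNV call (0-based half-open interval)."""

    sample_id: str
    start: int
    end: int
    cnv_type: str  # "DUP" | "DEL"
    p_value: float
    q0_fraction: float
    normalized_rd: float | None = None
    chrom: str = "22"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.start}-{self.end}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")
        if not 0.0 <= self.q0_fraction <= 1.0:
            raise ValueError(f"q0_fraction out of [0,1]: {self.q0_fraction}")
        if self.cnv_type not in ("DUP", "DEL"):
            raise ValueError(f"unknown cnv_type {self.cnv_type!r}")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MergedCnv:
    """A cross-sample merged CNV candidate.

    The interval is the outermost span of all member calls, so every
    member is covered. ``recurrence_rate``, ``present_in_parents`` and
    ``rare`` are filled by the downstream filters.
    """

    start: int
    end: int
    cnv_type: str
    supporting_samples: frozenset[str]
    chrom: str = "22"
    members: tuple[CnvCall, ...] = ()
    recurrence_rate: float | None = None
    present_in_parents: bool | None = None
    rare: bool | None = None

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def calls_from_frame(df: pd.DataFrame) -> list[CnvCall]:
    """Build :class:`CnvCall` objects from a call table."""
    return [
        CnvCall(
            sample_id=str(r.sample_id),
            start=int(r.start),
            end=int(r.end),
            cnv_type=str(r.cnv_type),
            p_value=float(r.p_value),
            q0_fraction=float(r.q0_fraction),
            normalized_rd=float(r.normalized_rd) if "normalized_rd" in df.columns else None,
            chrom=str(r.chrom) if "chrom" in df.columns else "22",
        )
        for r in df.itertuples(index=False)
    ]


def qc_filter_calls(
    calls: Iterable[CnvCall],
    p_max: float = 0.01,
    min_size: int = 1_000,
    q0_max: float = 0.5,
) -> list[CnvCall]:
    """Retain calls with p-value < ``p_max``, size > ``min_size`` and
    q0 fraction <= ``q0_max`` (strict/inclusive comparisons as stated)."""
    return [
        c
        for c in calls
        if c.p_value < p_max and c.length > min_size and c.q0_fraction <= q0_max
    ]


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """min(overlap/len(a), overlap/len(b)); 1.0 iff identical intervals."""
    (a0, a1), (b0, b1) = a, b
    if a1 <= a0 or b1 <= b0:
        raise ValueError("intervals must be non-empty")
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return min(ov / (a1 - a0), ov / (b1 - b0))


def is_concordant(a: CnvCall | MergedCnv, b: CnvCall | MergedCnv,
                  min_ro: float = 0.5) -> bool:
    """Same-type calls with reciprocal overlap strictly above ``min_ro``."""
    if a.cnv_type != b.cnv_type:
        return False
    return reciprocal_overlap(a.interval, b.interval) > min_ro


def cluster_and_merge(calls: Sequence[CnvCall], min_ro: float = 0.5) -> list[MergedCnv]:
    """Merge concordant calls to the outermost bounds.

    Builds the pairwise concordance graph (edges between same-type calls
    with >``min_ro`` reciprocal overlap) and merges each connected
    component to ``[min start, max end)``, so every member call is covered
    by its merged CNV. Output is deterministic: sorted by start, then type,
    then end.
    """
    calls = list(calls)
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if is_concordant(calls[i], calls[j], min_ro):
                g.add_edge(i, j)
    merged = []
    for comp in nx.connected_components(g):
        members = tuple(sorted((calls[i] for i in comp),
                               key=lambda c: (c.start, c.end, c.sample_id)))
        merged.append(
            MergedCnv(
                start=min(c.start for c in members),
                end=max(c.end for c in members),
                cnv_type=members[0].cnv_type,
                supporting_samples=frozenset(c.sample_id for c in members),
                chrom=members[0].chrom,
                members=members,
            )
        )
    return sorted(merged, key=lambda m: (m.start, m.cnv_type, m.end))


def recurrence_candidates(
    merged: Iterable[MergedCnv],
    n_cases: int,
    parent_calls: Iterable[CnvCall] = (),
    threshold: float = 0.5,
) -> list[MergedCnv]:
    """Keep merged CNVs recurrent in > ``threshold`` of cases and absent
    from the parents.

    Recurrence is the supporting-sample count over ``n_cases`` (strictly
    greater than the threshold). Parent subtraction tests same-type
    concordance (>50% reciprocal overlap) of any parent call against the
    *merged* interval. The returned copies carry ``recurrence_rate`` and
    ``present_in_parents``.
    """
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    parent_calls = list(parent_calls)
    out = []
    for m in merged:
        rate = len(m.supporting_samples) / n_cases
        in_parents = any(
            pc.cnv_type == m.cnv_type
            and reciprocal_overlap(m.interval, pc.interval) > 0.5
            for pc in parent_calls
        )
        if rate > threshold and not in_parents:
            out.append(replace(m, recurrence_rate=rate, present_in_parents=in_parents))
    return out


def _union_intervals(intervals: list[Interval]) -> list[Interval]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def classify_rare_cnv(
    merged: MergedCnv | Interval,
    track: pd.DataFrame,
    freq_cutoff: float = 0.01,
    overlap_cutoff: float = 0.5,
) -> bool:
    """Rare iff <= ``overlap_cutoff`` of the CNV's length is covered by the
    union of track regions at population frequency > ``freq_cutoff``.

    The union (not the sum) of common-region coverage is used so
    overlapping track records are not double counted.
    """
    if isinstance(merged, MergedCnv):
        start, end = merged.interval
    else:
        start, end = merged
    common = track[track["frequency"] > freq_cutoff]
    union = _union_intervals(
        [(int(s), int(e)) for s, e in zip(common["start"], common["end"])]
    )
    covered = sum(
        max(0, min(end, e) - max(start, s)) for s, e in union
    )
    return covered / (end - start) <= overlap_cutoff


def presence_matrix(candidates: Sequence[MergedCnv], case_ids: Sequence[str]) -> pd.DataFrame:
    """Candidate x case presence matrix (per-candidate sample support)."""
    labels = [f"{m.cnv_type}_{m.start}_{m.end}" for m in candidates]
    data = {
        sid: [sid in m.supporting_samples for m in candidates] for sid in case_ids
    }
    return pd.DataFrame(data, index=labels)


# ---------------------------------------------------------------------
# read-depth deletion scan


@dataclass
class DepthProfile:
    """Per-sample binned coverage; bin ``i`` covers
    ``[i*bin_size, (i+1)*bin_size)``."""

    sample_id: str
    bin_size: int
    depths: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")


@dataclass(frozen=True)
class DeletionCall:
    """A depth-supported deletion interval with its mean normalized depth."""

    start: int
    end: int
    mean_normalized_depth: float
    sample_id: str = ""


def _low_runs(
    smoothed: np.ndarray, cutoff: float, min_bins: int
) -> list[tuple[int, int]]:
    below = smoothed < cutoff
    runs = []
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_bins:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def scan_depth_for_deletion(
    profile: DepthProfile,
    ratio_cutoff: float = 0.7,
    min_length: int = 500_000,
    smooth_window: int = 51,
) -> list[DeletionCall]:
    """Detect large low-depth runs in a binned coverage profile.

    Depths are normalized by the profile median, smoothed with a centered
    rolling median, and maximal runs of bins below ``ratio_cutoff``
    spanning at least ``min_length`` bases are reported with their mean
    normalized (unsmoothed) depth.

    A deletion spanning a sizeable fraction of the target drags the global
    median down, biasing the normalized depth inside it upward; the
    baseline is therefore re-estimated once excluding first-pass runs and
    the scan repeated against the refined baseline. A profile uniformly at
    a reduced level has no within-sample contrast and yields no calls
    (normalization makes it flat); a zero median is an error.
    """
    depths = profile.depths
    min_bins = -(-min_length // profile.bin_size)
    if depths.size < min_bins:
        raise ValueError("profile shorter than the minimum deletion length")
    baseline = float(np.median(depths))
    if baseline <= 0:
        raise ValueError("degenerate profile: median depth is zero")

    def runs_at(b: float) -> list[tuple[int, int]]:
        smoothed = (
            pd.Series(depths / b)
            .rolling(smooth_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        return _low_runs(smoothed, ratio_cutoff, min_bins)

    runs = runs_at(baseline)
    if runs:
        mask = np.zeros(depths.size, dtype=bool)
        for i, j in runs:
            mask[i:j] = True
        outside = depths[~mask]
        if outside.size:
            refined = float(np.median(outside))
            if refined > 0:
                baseline = refined
                runs = runs_at(baseline)
    return [
        DeletionCall(
            start=i * profile.bin_size,
            end=j * profile.bin_size,
            mean_normalized_depth=float(depths[i:j].mean() / baseline),
            sample_id=profile.sample_id,
        )
        for i, j in runs
    ]
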