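"""Loop candidate filtering, clustering, summit selection, and benchmarking.

Candidates are tested pairs that are both closer than their local background
(negative test direction) and significant after FDR control (FDR < 10% by
default).  Nearby candidates — within twice the bin resolution on both
anchors — are grouped by single linkage into clusters; each cluster is
represented by its most significant member (the summit).  Summits of
multi-candidate clusters are kept when their population-level contact
frequency is at least 1/3, singletons when it is at least 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance_core import DistanceSummary
from .trace_io import LocusAnnotation

LOOP_COLUMNS = [
    "region_id", "i", "j", "cluster_id", "cluster_size", "is_summit",
    "contact_freq", "t_stat", "p_value", "fdr", "n_case", "flag",
]


@dataclass(frozen=True)
class CallConfig:
    """Thresholds of the post-processing stage.

    ``fdr_max`` is strict ("less than 10%"); the contact-frequency floors
    are inclusive.  The clustering gap is ``gap_multiplier`` times the bin
    resolution on each anchor axis.
    """

    fdr_max: float = 0.10
    gap_multiplier: int = 2
    summit_cf_min: float = 1.0 / 3.0
    singleton_cf_min: float = 1.0 / 2.0
    overlap_tolerance: int | None = None  # bp; None = 1 bin at evaluation time


def filter_candidates(results: pd.DataFrame, cfg: CallConfig = CallConfig()) -> pd.DataFrame:
    """Tested pairs with negative direction and FDR strictly below the cap.

    The direction rule ``mean_case < mean_ctrl`` coincides with ``t < 0``
    for the t-test and supplies the sign for the rank-sum alternative.
    """
    keep = (
        results["tested"]
        & (results["mean_case"] < results["mean_ctrl"])
        & (results["fdr"] < cfg.fdr_max)
    )
    return results[keep.fillna(False)].reset_index(drop=True)


def cluster_candidates(
    cands: pd.DataFrame, ann: LocusAnnotation, cfg: CallConfig = CallConfig()
) -> pd.DataFrame:
    """Single-linkage clusters of candidates within the gap.

    Two candidates of the same region are adjacent when both anchor offsets
    satisfy ``|i-i'| * res <= gap`` and ``|j-j'| * res <= gap`` with
    ``gap = gap_multiplier * res``; clusters are the connected components of
    this graph (transitive closure).  Cluster ids are assigned in order of
    each cluster's smallest (region, i, j) member, so they are deterministic.

    Returns the candidate table with ``cluster_id`` and ``cluster_size``.
    """
    cands = cands.sort_values(["region_id", "i", "j"], kind="mergesort").reset_index(drop=True)
    n = len(cands)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    regions = cands["region_id"].to_numpy()
    ii = cands["i"].to_numpy()
    jj = cands["j"].to_numpy()
    for a in range(n):
        for b in range(a + 1, n):
            if regions[a] != regions[b]:
                continue
            if abs(ii[a] - ii[b]) <= cfg.gap_multiplier and abs(jj[a] - jj[b]) <= cfg.gap_multiplier:
                union(a, b)

    roots = [find(a) for a in range(n)]
    order = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    cands = cands.copy()
    cands["cluster_id"] = [order[r] for r in roots]
    cands["cluster_size"] = cands.groupby("cluster_id")["cluster_id"].transform("size")
    return cands


def select_summit(cluster: pd.DataFrame) -> pd.Series:
    """Cluster member with minimal FDR.

    Ties break by smaller p-value, then smaller mean case distance, then
    lexicographic (i, j).
    """
    if cluster.empty:
        raise ValueError("empty cluster")
    ordered = cluster.sort_values(
        ["fdr", "p_value", "mean_case", "i", "j"], kind="mergesort"
    )
    return ordered.iloc[0]


def finalize_loops(
    clustered: pd.DataFrame,
    summaries: DistanceSummary,
    cfg: CallConfig = CallConfig(),
) -> pd.DataFrame:
    """Final loop list: cluster summits and singletons passing the
    contact-frequency floors (inclusive >=).

    Returns a table with ``LOOP_COLUMNS``, one row per surviving cluster,
    sorted by (region, i, j).
    """
    merged = clustered.merge(
        summaries.df[["region_id", "i", "j", "contact_freq"]],
        on=["region_id", "i", "j"],
        how="left",
    )
    rows = []
    for _, cluster in merged.groupby("cluster_id", sort=True):
        summit = select_summit(cluster)
        size = int(summit["cluster_size"])
        cf = summit["contact_freq"]
        threshold = cfg.singleton_cf_min if size == 1 else cfg.summit_cf_min
        if pd.notna(cf) and cf >= threshold:
            rows.append(
                {
                    "region_id": summit["region_id"],
                    "i": int(summit["i"]),
                    "j": int(summit["j"]),
                    "cluster_id": int(summit["cluster_id"]),
                    "cluster_size": size,
                    "is_summit": True,
                    "contact_freq": float(cf),
                    "t_stat": float(summit["t_stat"]),
                    "p_value": float(summit["p_value"]),
                    "fdr": float(summit["fdr"]),
                    "n_case": int(summit["n_case"]),
                    "flag": "singleton" if size == 1 else "summit",
                }
            )
    out = pd.DataFrame(rows, columns=LOOP_COLUMNS)
    return out.sort_values(["region_id", "i", "j"], kind="mergesort").reset_index(drop=True)


def call_loops(
    results: pd.DataFrame,
    summaries: DistanceSummary,
    ann: LocusAnnotation,
    cfg: CallConfig = CallConfig(),
) -> pd.DataFrame:
    """filter -> cluster -> summit/contact-frequency filter, in one call."""
    cands = filter_candidates(results, cfg)
    if cands.empty:
        return pd.DataFrame(columns=LOOP_COLUMNS)
    return finalize_loops(cluster_candidates(cands, ann, cfg), summaries, cfg)


@dataclass(frozen=True)
class EvaluationResult:
    precision: float
    recall: float
    f1: float
    n_calls: int
    n_reference: int
    n_matched: int
    matches: tuple  # (call index, reference index) pairs


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate_against_reference(
    calls: pd.DataFrame, reference: pd.DataFrame, tolerance: int
) -> EvaluationResult:
    """Benchmark loop calls against a reference anchor list.

    Both tables need columns ``chrom, a_start, b_start`` (anchor bin starts,
    any shared coordinate convention, anchors ordered so a <= b); ``calls``
    may carry ``fdr`` to set the greedy matching order (most significant
    first).  A call matches a reference loop when both anchor starts are
    within ``tolerance`` bp of the corresponding reference anchors; each
    reference is consumed by at most one call.  Precision is matched calls
    over calls (0 when there are no calls), recall matched references over
    references.
    """
    n_calls, n_ref = len(calls), len(reference)
    if n_calls == 0:
        return EvaluationResult(0.0, 0.0, 0.0, 0, n_ref, 0, ())

    order = (
        calls.sort_values("fdr", kind="mergesort").index
        if "fdr" in calls.columns and calls["fdr"].notna().any()
        else calls.index
    )
    taken = np.zeros(n_ref, dtype=bool)
    ref_chrom = reference["chrom"].to_numpy()
    ref_a = reference["a_start"].to_numpy(np.int64)
    ref_b = reference["b_start"].to_numpy(np.int64)
    matches = []
    for idx in order:
        chrom = calls.at[idx, "chrom"]
        a = int(calls.at[idx, "a_start"])
        b = int(calls.at[idx, "b_start"])
        da = np.abs(ref_a - a)
        db = np.abs(ref_b - b)
        ok = (~taken) & (ref_chrom == chrom) & (da <= tolerance) & (db <= tolerance)
        if ok.any():
            cand = np.flatnonzero(ok)
            best = cand[np.argmin(np.maximum(da[cand], db[cand]))]
            taken[best] = True
            matches.append((idx, int(best)))

    n_matched = len(matches)
    precision = n_matched / n_calls
    recall = n_matched / n_ref if n_ref else 0.0
    return EvaluationResult(
        precision, recall, f1_score(precision, recall),
        n_calls, n_ref, n_matched, tuple(matches),
    )


def loops_to_anchor_frame(loops: pd.DataFrame, ann: LocusAnnotation) -> pd.DataFrame:
    """Convert a loop-call table to the (chrom, a_start, b_start[, fdr])
    layout used by :func:`evaluate_against_reference`, on 1-based bin
    starts."""
    rows = []
    for row in loops.itertuples(index=False):
        a = ann.bin_start(row.region_id, row.i)
        b = ann.bin_start(row.region_id, row.j)
        rows.append(
            {"chrom": ann.chrom(row.region_id), "a_start": min(a, b),
             "b_start": max(a, b), "fdr": getattr(row, "fdr", np.nan)}
        )
    return pd.DataFrame(rows, columns=["chrom", "a_start", "b_start", "fdr"])


def bedpe_to_anchor_frame(bedpe: pd.DataFrame) -> pd.DataFrame:
    """Anchor frame from a parsed BEDPE table (0-based starts kept as-is)."""
    out = pd.DataFrame(
        {
            "chrom": bedpe["chrom1"],
            "a_start": np.minimum(bedpe["start1"], bedpe["start2"]),
            "b_start": np.maximum(bedpe["start1"], bedpe["start2"]),
        }
    )
    if "fdr" in bedpe.columns:
        out["fdr"] = bedpe["fdr"].to_numpy()
    return out
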