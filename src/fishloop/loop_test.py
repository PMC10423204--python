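"""Candidate enumeration, local-neighborhood control sets, the two-sample
test, and Benjamini-Hochberg FDR.

A candidate is any within-region locus pair at 100 Kb - 1 Mb of 1D genomic
separation.  Its control is the "circle" of locus pairs whose Chebyshev
offset from the candidate (in the 2D bin grid, measured in bp) lies in
25-50 Kb, the same donut-style local background used by Hi-C loop callers.
The candidate's observed distances across alleles are compared with the
pooled observed distances of its neighborhood with a two-sample test:
a negative statistic means the pair sits closer in space than its local
background, which is the loop signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .distance_core import DistanceRecordSet
from .trace_io import LocusAnnotation

DEFAULT_MIN_SEP = 100_000
DEFAULT_MAX_SEP = 1_000_000

RESULT_COLUMNS = [
    "region_id", "i", "j", "tested", "n_case", "n_ctrl",
    "mean_case", "mean_ctrl", "t_stat", "p_value", "fdr",
]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """1D genomic distance band (bp) defining the local control region."""

    lower: int = 25_000
    upper: int = 50_000

    def __post_init__(self):
        if not 0 < self.lower <= self.upper:
            raise ValueError("need 0 < lower <= upper")


def candidate_pairs(
    ann: LocusAnnotation,
    min_sep: int = DEFAULT_MIN_SEP,
    max_sep: int = DEFAULT_MAX_SEP,
) -> list[tuple]:
    """All within-region pairs with ``min_sep <= separation <= max_sep``
    (inclusive bounds), sorted by (region, i, j)."""
    out = []
    for region in ann.regions:
        n = ann.n_loci(region)
        res = ann.resolution(region)
        for i in range(n):
            for j in range(i + 1, n):
                if min_sep <= (j - i) * res <= max_sep:
                    out.append((region, i, j))
    return out


def neighborhood(pair, ann: LocusAnnotation, spec: NeighborhoodSpec = NeighborhoodSpec()) -> list[tuple]:
    """Local control pairs of ``pair = (region, i, j)``.

    All valid pairs ``(i', j')`` with ``i' < j'`` in the same region whose
    Chebyshev offset ``max(|i-i'|, |j-j'|) * resolution`` lies inclusively
    in ``[spec.lower, spec.upper]``; offsets falling outside the annotation
    or on/past the diagonal are truncated, and the pair itself is excluded.
    """
    region, i, j = pair
    res = ann.resolution(region)
    n = ann.n_loci(region)
    reach = spec.upper // res
    out = []
    for di in range(-reach, reach + 1):
        for dj in range(-reach, reach + 1):
            cheb = max(abs(di), abs(dj)) * res
            if not spec.lower <= cheb <= spec.upper:
                continue
            ip, jp = i + di, j + dj
            if 0 <= ip < jp < n:
                out.append((region, ip, jp))
    return out


def welch_t(case, ctrl, variant: str = "welch") -> tuple[float, float]:
    """Two-sample t statistic and two-sided p-value.

    Welch (unequal variance) by default; ``variant='pooled'`` for the
    classical equal-variance form.  Negative t means the case sample sits
    below the control.  Two degenerate zero-variance samples with equal
    means give (0, 1).
    """
    case = np.asarray(case, float)
    ctrl = np.asarray(ctrl, float)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least two observations per sample")
    if case.var(ddof=1) == 0.0 and ctrl.var(ddof=1) == 0.0:
        if case.mean() == ctrl.mean():
            return 0.0, 1.0
        return (-np.inf if case.mean() < ctrl.mean() else np.inf), 0.0
    t, p = stats.ttest_ind(case, ctrl, equal_var=(variant == "pooled"))
    return float(t), float(p)


def rank_sum_test(case, ctrl) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact null distribution for small samples (n_case + n_ctrl <= 20, no
    ties), otherwise the normal approximation with tie and continuity
    correction.  Returns (U of the case sample, p).  The loop direction is
    judged from the sample means, as for the t-test.
    """
    case = np.asarray(case, float)
    ctrl = np.asarray(ctrl, float)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least two observations per sample")
    pooled = np.concatenate([case, ctrl])
    if np.all(pooled == pooled[0]):
        return float(len(case) * len(ctrl) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method)
    return float(u), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_region(
    drs: DistanceRecordSet,
    ann: LocusAnnotation | None = None,
    spec: NeighborhoodSpec = NeighborhoodSpec(),
    method: str = "t",
    min_n: int = 2,
    t_variant: str = "welch",
    fdr_scope: str = "per_region",
    min_sep: int = DEFAULT_MIN_SEP,
    max_sep: int = DEFAULT_MAX_SEP,
    ctrl_mode: str = "pooled",
) -> pd.DataFrame:
    """Run the local-background test for every candidate pair.

    The case sample is the pair's observed distances across alleles.  With
    ``ctrl_mode='pooled'`` (default) the control pools the observed
    distances of every neighborhood pair across alleles into one sample;
    ``ctrl_mode='cell_mean'`` instead uses one value per allele — that
    allele's average distance over its observed neighborhood pairs — which
    has less power but weights each cell equally.  Pairs with fewer than
    ``min_n`` observations on either side are reported with
    ``tested=False`` and NaN statistics.  BH adjustment is applied over
    tested pairs, per region by default (``fdr_scope='global'`` pools all
    regions).

    Returns one row per candidate pair (columns ``RESULT_COLUMNS``),
    sorted by (region, i, j); deterministic in its inputs.
    """
    ann = ann if ann is not None else drs.ann
    if method not in ("t", "wilcoxon"):
        raise ValueError(f"unknown method {method!r}")
    if ctrl_mode not in ("pooled", "cell_mean"):
        raise ValueError(f"unknown ctrl_mode {ctrl_mode!r}")

    dists = drs.df["dist"].to_numpy() if len(drs.df) else np.empty(0)
    if ctrl_mode == "cell_mean":
        if len(drs.df):
            _, allele_codes = np.unique(drs.df["allele_id"], return_inverse=True)
            n_alleles = int(allele_codes.max()) + 1
        else:
            allele_codes, n_alleles = np.empty(0, dtype=np.int64), 0
    grouped = drs.df.groupby(["region_id", "i", "j"], sort=False).indices
    by_pair: dict[tuple, np.ndarray] = {key: dists[idx] for key, idx in grouped.items()}
    empty = np.empty(0)
    rows = []
    for pair in candidate_pairs(ann, min_sep, max_sep):
        case = by_pair.get(pair, empty)
        neighbors = neighborhood(pair, ann, spec)
        if ctrl_mode == "pooled":
            ctrl_parts = [by_pair.get(q, empty) for q in neighbors]
            ctrl = np.concatenate(ctrl_parts) if ctrl_parts else empty
        else:
            sums = np.zeros(n_alleles)
            counts = np.zeros(n_alleles, dtype=np.int64)
            for q in neighbors:
                idx = grouped.get(q)
                if idx is not None:
                    np.add.at(sums, allele_codes[idx], dists[idx])
                    np.add.at(counts, allele_codes[idx], 1)
            seen = counts > 0
            ctrl = sums[seen] / counts[seen]
        region, i, j = pair
        row = {
            "region_id": region, "i": i, "j": j,
            "n_case": len(case), "n_ctrl": len(ctrl),
            "mean_case": case.mean() if len(case) else np.nan,
            "mean_ctrl": ctrl.mean() if len(ctrl) else np.nan,
            "t_stat": np.nan, "p_value": np.nan, "tested": False,
        }
        if len(case) >= min_n and len(ctrl) >= min_n:
            if method == "t":
                t, p = welch_t(case, ctrl, variant=t_variant)
            else:
                t, p = rank_sum_test(case, ctrl)
            row.update(t_stat=t, p_value=p, tested=True)
        rows.append(row)

    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    if out.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    if fdr_scope == "global":
        mask = out["tested"].to_numpy()
        if mask.any():
            out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p_value"])
    elif fdr_scope == "per_region":
        for region in out["region_id"].unique():
            mask = (out["region_id"] == region) & out["tested"]
            if mask.any():
                out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p_value"])
    else:
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    return out[RESULT_COLUMNS]
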