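"""Pairwise Euclidean distances, the 25 Kb reference cutoff, and
population-level contact frequencies.

Each allele's trace yields one observed distance per pair of loci both
localized in that allele.  The dataset-level scalar ``avg.dist.1D.25Kb`` —
the mean Euclidean distance over all pairs separated by 25 Kb of genomic
sequence — converts continuous distances into a binary "contact": a pair is
in contact in an allele when its distance is strictly smaller than the
cutoff, and the population-level contact frequency of a pair is the fraction
of observing alleles in contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .trace_io import LocusAnnotation, TraceSet

DEFAULT_D0 = 25_000  # bp of 1D separation defining the reference cutoff


@dataclass
class DistanceRecordSet:
    """Long-form observed pairwise distances.

    ``df`` columns: ``allele_id, region_id, i, j, dist`` with ``i < j`` and
    one record per (allele, pair) where both loci were observed.
    """

    df: pd.DataFrame
    ann: LocusAnnotation = field(repr=False)


@dataclass
class DistanceSummary:
    """Per-pair summary over alleles.

    ``df`` columns: ``region_id, i, j, genomic_dist, n_obs, mean_dist,
    contact_freq``; every within-region pair appears, with ``n_obs == 0``
    and NaN statistics for pairs never co-observed.  ``cutoff`` is the
    reference distance (nm) used for the contact calls.
    """

    df: pd.DataFrame
    cutoff: float
    ann: LocusAnnotation = field(repr=False)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# reference_cutoff_nm={self.cutoff!r}\n")
            self.df.to_csv(fh, sep="\t", index=False)


def euclidean_distances(ts: TraceSet) -> DistanceRecordSet:
    """All within-allele pairwise 3D Euclidean distances.

    Pairs with a missing locus produce no record; an allele with fewer than
    two localizations contributes nothing.
    """
    out_allele, out_region, out_i, out_j, out_d = [], [], [], [], []
    for (allele, region), sub in ts.df.groupby(["allele_id", "region_id"], sort=False):
        sub = sub.sort_values("locus_id")
        loci = sub["locus_id"].to_numpy()
        if len(loci) < 2:
            continue
        coords = sub[["x", "y", "z"]].to_numpy(float)
        d = pdist(coords)
        ii, jj = np.triu_indices(len(loci), k=1)
        out_allele.append(np.full(len(d), allele, dtype=object))
        out_region.append(np.full(len(d), region, dtype=object))
        out_i.append(loci[ii])
        out_j.append(loci[jj])
        out_d.append(d)
    if not out_d:
        df = pd.DataFrame(columns=["allele_id", "region_id", "i", "j", "dist"])
    else:
        df = pd.DataFrame(
            {
                "allele_id": np.concatenate(out_allele),
                "region_id": np.concatenate(out_region),
                "i": np.concatenate(out_i).astype(np.int64),
                "j": np.concatenate(out_j).astype(np.int64),
                "dist": np.concatenate(out_d),
            }
        )
    return DistanceRecordSet(df, ts.ann)


def genomic_distance(pair, ann: LocusAnnotation) -> int:
    """1D genomic separation of a pair ``(region_id, i, j)`` in bp.

    Equal to the difference of bin starts, i.e. ``(j - i) * resolution``.
    """
    region, i, j = pair
    if not i < j:
        raise ValueError("PairKey requires i < j")
    return ann.bin_start(region, j) - ann.bin_start(region, i)


def _separations(df: pd.DataFrame, ann: LocusAnnotation) -> np.ndarray:
    res_by_region = {r: ann.resolution(r) for r in ann.regions}
    res = df["region_id"].map(res_by_region).to_numpy(np.int64)
    return (df["j"].to_numpy() - df["i"].to_numpy()) * res


def reference_cutoff(
    drs: DistanceRecordSet, d0: int = DEFAULT_D0, scope: str = "pooled"
):
    """Mean Euclidean distance of all pairs separated by ``d0`` bp.

    Pooled over alleles and regions by default (one scalar per dataset);
    ``scope='per_region'`` returns a dict of per-region means instead.
    Raises if no pair realizes the separation ``d0`` — pick a ``d0`` the
    imaged region can realize, e.g. one bin for very short regions.
    """
    sep = _separations(drs.df, drs.ann)
    mask = sep == d0
    if scope == "pooled":
        if not mask.any():
            raise ValueError(
                f"no observed pair with 1D separation {d0} bp; "
                "set d0 explicitly to a separation the region supports"
            )
        return float(drs.df.loc[mask, "dist"].mean())
    if scope == "per_region":
        out = {}
        for region in drs.ann.regions:
            m = mask & (drs.df["region_id"] == region).to_numpy()
            if not m.any():
                raise ValueError(
                    f"region {region!r} has no observed pair at separation {d0} bp"
                )
            out[region] = float(drs.df.loc[m, "dist"].mean())
        return out
    raise ValueError(f"unknown scope {scope!r}")


def _all_pairs(ann: LocusAnnotation) -> pd.DataFrame:
    frames = []
    for region in ann.regions:
        n = ann.n_loci(region)
        ii, jj = np.triu_indices(n, k=1)
        frames.append(pd.DataFrame({"region_id": region, "i": ii, "j": jj}))
    return pd.concat(frames, ignore_index=True)


def contact_frequencies(drs: DistanceRecordSet, cutoff: float) -> DistanceSummary:
    """Per-pair contact frequency: fraction of observing alleles with
    distance strictly below ``cutoff``.

    A distance exactly equal to the cutoff counts as *not* in contact.
    Pairs with no co-observation are carried with ``n_obs = 0`` and NaN
    frequency so downstream stages can flag rather than silently drop them.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    base = _all_pairs(drs.ann)
    if drs.df.empty:
        obs = pd.DataFrame(columns=["region_id", "i", "j", "n_obs", "mean_dist", "n_contact"])
    else:
        grp = drs.df.groupby(["region_id", "i", "j"], sort=False)
        obs = grp["dist"].agg(
            n_obs="size", mean_dist="mean", n_contact=lambda d: int((d < cutoff).sum())
        ).reset_index()
    df = base.merge(obs, on=["region_id", "i", "j"], how="left")
    df["n_obs"] = df["n_obs"].fillna(0).astype(np.int64)
    df["contact_freq"] = np.where(df["n_obs"] > 0, df.pop("n_contact") / df["n_obs"], np.nan)
    df["genomic_dist"] = _separations(df, drs.ann)
    df = df[["region_id", "i", "j", "genomic_dist", "n_obs", "mean_dist", "contact_freq"]]
    return DistanceSummary(df, float(cutoff), drs.ann)
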