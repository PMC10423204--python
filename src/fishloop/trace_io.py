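"""Reading, validating and writing chromatin-trace tables.

The canonical on-disk representation is a tidy long-format delimited table
(comma for ``.csv``, tab otherwise):

* annotation — one row per targeted segment (genomic bin):
  ``region_id, locus_id, chrom, start, end`` with 1-based inclusive
  coordinates (UCSC style);
* traces — one row per observed 3D localization:
  ``allele_id, region_id, locus_id, x, y, z`` in nanometers.

Loci an imaging experiment failed to detect are simply absent: there are no
sentinel rows and nothing is imputed.  Loop calls are serialized to BEDPE
(0-based half-open) so they can be compared with loop lists from Hi-C
pipelines with standard tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("fishloop")

ANNOTATION_COLUMNS = ["region_id", "locus_id", "chrom", "start", "end"]
TRACE_COLUMNS = ["allele_id", "region_id", "locus_id", "x", "y", "z"]

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "t_stat", "p_value", "fdr", "contact_freq", "n_case", "flag",
]


class FormatError(ValueError):
    """Raised when an input table violates the expected layout or invariants."""


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sep_for(path), comment="#")


@dataclass(frozen=True)
class LocusAnnotation:
    """Genomic home of every targeted segment.

    ``df`` has columns ``region_id, locus_id, chrom, start, end, resolution``
    sorted by ``(region_id, locus_id)``; ``locus_id`` is the 0-based,
    consecutive bin index within its region and ``resolution`` the bin size
    in bp (identical for all bins of a region).
    """

    df: pd.DataFrame

    @property
    def regions(self) -> list:
        return list(dict.fromkeys(self.df["region_id"]))

    def region(self, region_id) -> pd.DataFrame:
        sub = self.df[self.df["region_id"] == region_id]
        if sub.empty:
            raise KeyError(f"unknown region {region_id!r}")
        return sub

    def n_loci(self, region_id) -> int:
        return len(self.region(region_id))

    def resolution(self, region_id) -> int:
        return int(self.region(region_id)["resolution"].iloc[0])

    def chrom(self, region_id) -> str:
        return str(self.region(region_id)["chrom"].iloc[0])

    def bin_start(self, region_id, locus_id) -> int:
        sub = self.region(region_id)
        row = sub[sub["locus_id"] == locus_id]
        if row.empty:
            raise KeyError(f"unknown locus {locus_id} in region {region_id!r}")
        return int(row["start"].iloc[0])


def annotation_from_frame(df: pd.DataFrame) -> LocusAnnotation:
    """Validate a raw annotation table and infer per-region bin resolution.

    Raises :class:`FormatError` on duplicate bins, inverted intervals,
    non-consecutive bin indices or non-uniform bin spacing (the offending
    region is named in the message).
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation is missing columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    for col in ("locus_id", "start", "end"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"annotation column {col!r} is not integer") from exc

    dup = df.duplicated(subset=["region_id", "locus_id"])
    if dup.any():
        r, l = df.loc[dup.idxmax(), ["region_id", "locus_id"]]
        raise FormatError(f"duplicate locus {l} in region {r!r}")
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise FormatError(
            f"locus {bad['locus_id']} of region {bad['region_id']!r} has end <= start"
        )

    df = df.sort_values(["region_id", "locus_id"], kind="mergesort").reset_index(drop=True)
    resolutions = np.empty(len(df), dtype=np.int64)
    for region_id, sub in df.groupby("region_id", sort=False):
        loci = sub["locus_id"].to_numpy()
        if loci[0] != 0 or not np.array_equal(loci, np.arange(len(loci))):
            raise FormatError(
                f"region {region_id!r}: locus ids must be 0-based and consecutive"
            )
        starts = sub["start"].to_numpy()
        if len(starts) >= 2:
            diffs = np.diff(starts)
            if len(set(diffs.tolist())) != 1:
                raise FormatError(f"region {region_id!r}: non-uniform bin spacing {sorted(set(diffs.tolist()))}")
            res = int(diffs[0])
            ends = sub["end"].to_numpy()
            if (ends[:-1] >= starts[1:]).any():
                raise FormatError(f"region {region_id!r}: overlapping bins")
        else:
            res = int(sub["end"].iloc[0] - sub["start"].iloc[0] + 1)
        resolutions[sub.index] = res
    df["resolution"] = resolutions
    return LocusAnnotation(df)


def read_annotation(path) -> LocusAnnotation:
    """Read and validate a locus annotation table (CSV/TSV by extension)."""
    return annotation_from_frame(_read_table(path))


@dataclass
class TraceSet:
    """Observed per-allele 3D localizations, linked to their annotation.

    ``df`` has columns ``allele_id, region_id, locus_id, x, y, z`` with at
    most one localization per (allele, region, locus).  Coordinates are in
    nanometers; missing loci are simply absent.
    """

    df: pd.DataFrame
    ann: LocusAnnotation = field(repr=False)

    @property
    def n_alleles(self) -> int:
        return self.df.groupby(["allele_id", "region_id"], sort=False).ngroups


def traceset_from_frame(
    df: pd.DataFrame, ann: LocusAnnotation, dedup_policy: str = "mean"
) -> TraceSet:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trace table is missing columns {missing}")
    df = df[TRACE_COLUMNS].copy()
    df["locus_id"] = pd.to_numeric(df["locus_id"], errors="raise").astype(np.int64)
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            raise FormatError(f"non-numeric or missing coordinate in column {col!r}")
        if not np.isfinite(coerced).all():
            raise FormatError(f"non-finite coordinate in column {col!r}")
        df[col] = coerced.astype(float)

    known = set(map(tuple, ann.df[["region_id", "locus_id"]].itertuples(index=False)))
    pairs = set(map(tuple, df[["region_id", "locus_id"]].drop_duplicates().itertuples(index=False)))
    unknown = pairs - known
    if unknown:
        raise FormatError(f"localizations for loci absent from annotation: {sorted(unknown)[:5]}")

    key = ["allele_id", "region_id", "locus_id"]
    if df.duplicated(subset=key).any():
        n_dup = int(df.duplicated(subset=key).sum())
        if dedup_policy == "error":
            raise FormatError(f"{n_dup} duplicate localizations")
        if dedup_policy == "first":
            df = df.drop_duplicates(subset=key, keep="first")
        elif dedup_policy == "mean":
            logger.warning("collapsing %d duplicate localizations to centroids", n_dup)
            df = df.groupby(key, as_index=False, sort=False).mean(numeric_only=True)
            df = df[TRACE_COLUMNS]
        else:
            raise ValueError(f"unknown dedup_policy {dedup_policy!r}")
    return TraceSet(df.reset_index(drop=True), ann)


def read_traces(path, ann: LocusAnnotation, dedup_policy: str = "mean") -> TraceSet:
    """Read a localization table and attach it to ``ann``.

    ``dedup_policy`` controls what happens when an allele carries more than
    one spot for the same locus: ``mean`` (default) collapses them to the
    centroid with a logged warning, ``first`` keeps the first row, ``error``
    raises.
    """
    return traceset_from_frame(_read_table(path), ann, dedup_policy)


def write_traces(ts: TraceSet, path) -> None:
    """Write a TraceSet back to its canonical delimited layout."""
    ts.df.to_csv(path, sep=_sep_for(path), index=False)


def write_annotation(ann: LocusAnnotation, path) -> None:
    ann.df[ANNOTATION_COLUMNS].to_csv(path, sep=_sep_for(path), index=False)


def detection_efficiency(ts: TraceSet) -> float:
    """Proportion of imaged targeted segments among all targeted segments.

    Computed per allele (observed loci over the number of annotated loci of
    that allele's region) and averaged over alleles; when every allele spans
    one common region this equals the pooled proportion.
    """
    if ts.df.empty:
        raise ValueError("detection efficiency is undefined for an empty TraceSet")
    counts = ts.df.groupby(["allele_id", "region_id"], sort=False)["locus_id"].nunique()
    totals = counts.index.get_level_values("region_id").map(ts.ann.n_loci)
    return float((counts / totals).mean())


def write_loops_bedpe(loops: pd.DataFrame, ann: LocusAnnotation, path) -> None:
    """Serialize loop calls to BEDPE.

    ``loops`` is a loop-call table with columns ``region_id, i, j`` and the
    statistics columns ``t_stat, p_value, fdr, contact_freq, n_case, flag``
    (see :mod:`fishloop.loop_call`).  1-based annotation starts become
    0-based half-open BEDPE intervals; anchor1 is the 5' anchor.
    """
    lines = ["#" + "\t".join(BEDPE_COLUMNS)]
    for row in loops.itertuples(index=False):
        region = row.region_id
        chrom = ann.chrom(region)
        res = ann.resolution(region)
        s1 = ann.bin_start(region, row.i) - 1
        s2 = ann.bin_start(region, row.j) - 1
        if s2 < s1:  # anchor1 must be 5'
            s1, s2 = s2, s1
        name = f"{region}:{row.i}-{row.j}"
        stats = "\t".join(
            f"{getattr(row, c):.6f}" for c in ("t_stat", "p_value", "fdr", "contact_freq")
        )
        lines.append(
            f"{chrom}\t{s1}\t{s1 + res}\t{chrom}\t{s2}\t{s2 + res}\t"
            f"{name}\t{stats}\t{int(row.n_case)}\t{row.flag}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_loops_bedpe(path) -> pd.DataFrame:
    """Parse a BEDPE loop list; extra columns beyond the first six are kept
    under this package's column names when the count matches, otherwise as
    ``extra_k``."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    if not rows:
        return pd.DataFrame(columns=BEDPE_COLUMNS)
    width = len(rows[0])
    if width == len(BEDPE_COLUMNS):
        cols = BEDPE_COLUMNS
    else:
        cols = BEDPE_COLUMNS[:6] + [f"extra_{k}" for k in range(width - 6)]
    df = pd.DataFrame(rows, columns=cols)
    for col in ("start1", "end1", "start2", "end2"):
        df[col] = df[col].astype(np.int64)
    for col in ("t_stat", "p_value", "fdr", "contact_freq"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    if "n_case" in df.columns:
        df["n_case"] = df["n_case"].astype(np.int64)
    return df
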