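"""End-to-end orchestration: traces in, loop BEDPE out.

``run_pipeline`` chains the stages — distances, reference cutoff, contact
frequencies, local-background testing, candidate filtering / clustering /
summit selection — writes every intermediate table plus a run log (config
echo, package version, input checksums, per-region funnel counts), and is
deterministic given inputs and config.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .distance_core import contact_frequencies, euclidean_distances, reference_cutoff
from .loop_call import call_loops, filter_candidates
from .loop_test import test_region
from .trace_io import read_annotation, read_traces, write_loops_bedpe

logger = logging.getLogger("fishloop")

ARTIFACTS = {
    "summary": "distance_summary.tsv",
    "results": "test_results.tsv",
    "candidates": "candidates.tsv",
    "loops": "loops.bedpe",
    "log": "run.log",
}


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    traces_path, annotation_path, config: PipelineConfig | None = None, outdir=None
) -> pd.DataFrame:
    """Run the full caller on a trace/annotation file pair.

    Returns the final loop table; when ``outdir`` is given, also writes the
    distance summary, test results, candidate table, final BEDPE and the
    run log there.
    """
    cfg = config or PipelineConfig()
    ann = read_annotation(annotation_path)
    ts = read_traces(traces_path, ann, dedup_policy=cfg.dedup_policy)
    if cfg.xy_nm_per_voxel != 1.0:
        ts.df[["x", "y"]] *= cfg.xy_nm_per_voxel
    if cfg.z_nm_per_voxel != 1.0:
        ts.df["z"] *= cfg.z_nm_per_voxel

    drs = euclidean_distances(ts)
    cutoff = reference_cutoff(drs, d0=cfg.d0, scope="pooled")
    summary = contact_frequencies(drs, cutoff)
    results = test_region(
        drs,
        ann,
        spec=cfg.neighborhood_spec,
        method=cfg.method,
        t_variant=cfg.t_variant,
        fdr_scope=cfg.fdr_scope,
        min_sep=cfg.min_sep,
        max_sep=cfg.max_sep,
        ctrl_mode=cfg.ctrl_mode,
    )
    cands = filter_candidates(results, cfg.call_config)
    loops = call_loops(results, summary, ann, cfg.call_config)

    n_tested = int(results["tested"].sum()) if not results.empty else 0
    if n_tested == 0:
        logger.warning("zero tested pairs; writing an empty loop list")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.write_tsv(outdir / ARTIFACTS["summary"])
        results.to_csv(outdir / ARTIFACTS["results"], sep="\t", index=False)
        cands.to_csv(outdir / ARTIFACTS["candidates"], sep="\t", index=False)
        write_loops_bedpe(loops, ann, outdir / ARTIFACTS["loops"])

        lines = [f"fishloop {__version__}", "config:"]
        lines += [f"  {k}: {v}" for k, v in cfg.to_dict().items()]
        lines += [
            "inputs:",
            f"  traces: {Path(traces_path).name} sha256={_sha256(traces_path)}",
            f"  annotation: {Path(annotation_path).name} sha256={_sha256(annotation_path)}",
            f"reference_cutoff_nm: {cutoff!r}",
            "funnel:",
        ]
        for region in ann.regions:
            r = results[results["region_id"] == region] if not results.empty else results
            c = cands[cands["region_id"] == region] if not cands.empty else cands
            l = loops[loops["region_id"] == region] if not loops.empty else loops
            n_alleles = ts.df.loc[ts.df["region_id"] == region, "allele_id"].nunique()
            lines.append(
                f"  {region}: alleles={n_alleles} loci={ann.n_loci(region)} "
                f"tested={int(r['tested'].sum()) if len(r) else 0} "
                f"candidates={len(c)} final_loops={len(l)}"
            )
        (outdir / ARTIFACTS["log"]).write_text("\n".join(lines) + "\n")
    return loops
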