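"""Synthetic chromatin traces with known loop structure.

The generative model is intentionally the simplest one consistent with the
operational definition of a loop used by the caller:

* each allele is a Gaussian chain — successive loci differ by independent
  per-axis Normal(0, ``step_sigma``^2) displacements;
* a planted loop ``(a, b, f, loop_sigma)`` makes a fraction ``f`` of
  alleles "looping": the anchor-to-anchor displacement is redrawn from the
  much tighter Normal(0, ``loop_sigma``^2) per axis and the loci strictly
  between the anchors are re-laid as a discrete Brownian bridge between the
  anchor positions (loci downstream of ``b`` ride along rigidly);
* every localization is then independently dropped with probability
  ``1 - detection_q`` (imaging detection efficiency) and jittered by
  per-axis Normal(0, ``loc_error_sigma``^2) localization error.

No excluded volume, territory structure or decoding errors are modeled.
Everything is reproducible from the seed; fixtures derive their streams
from a (base seed, fixture name) pair so adding a fixture never perturbs
an existing one.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .trace_io import (
    LocusAnnotation,
    TraceSet,
    annotation_from_frame,
    write_annotation,
    write_traces,
)

TRUTH_COLUMNS = ["chrom", "a_start", "b_start", "region_id", "a", "b", "f", "loop_sigma"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated imaging experiment (single region).

    ``loops`` is a list of ``(anchor_a, anchor_b, looping_fraction,
    loop_sigma)`` tuples with bin indices ``anchor_a < anchor_b``;
    ``loop_sigma`` must be smaller than the free-chain scale
    ``step_sigma * sqrt(anchor_b - anchor_a)`` or the "loop" would not
    contract anything.
    """

    n_alleles: int
    n_loci: int
    resolution: int = 25_000
    step_sigma: float = 150.0
    loops: tuple = ()
    detection_q: float = 1.0
    loc_error_sigma: float = 0.0
    seed: int = 0
    region_id: str = "sim"
    chrom: str = "chrSim"
    start0: int = 1  # 1-based start of bin 0

    def __post_init__(self):
        if self.n_alleles < 1 or self.n_loci < 2:
            raise ValueError("need n_alleles >= 1 and n_loci >= 2")
        if not 0 < self.detection_q <= 1:
            raise ValueError("detection_q must lie in (0, 1]")
        if self.step_sigma <= 0 or self.loc_error_sigma < 0:
            raise ValueError("bad noise scales")
        for a, b, f, ls in self.loops:
            if not 0 <= a < b < self.n_loci:
                raise ValueError(f"loop anchors ({a}, {b}) outside the chain")
            if not 0 <= f <= 1:
                raise ValueError("looping fraction must lie in [0, 1]")
            if not ls < self.step_sigma * np.sqrt(b - a):
                raise ValueError(
                    "loop_sigma must be below the free-chain anchor scale "
                    f"{self.step_sigma * np.sqrt(b - a):.1f}"
                )


def build_annotation(cfg: SimConfig) -> LocusAnnotation:
    starts = cfg.start0 + cfg.resolution * np.arange(cfg.n_loci)
    return annotation_from_frame(
        pd.DataFrame(
            {
                "region_id": cfg.region_id,
                "locus_id": np.arange(cfg.n_loci),
                "chrom": cfg.chrom,
                "start": starts,
                "end": starts + cfg.resolution - 1,
            }
        )
    )


def simulate_traces(cfg: SimConfig) -> tuple[TraceSet, pd.DataFrame]:
    """Draw a TraceSet from ``cfg``; returns it with the truth loop table.

    Truth rows carry both bin indices and 1-based anchor bin starts so they
    can be matched against calls without re-deriving coordinates.
    """
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_alleles, cfg.n_loci

    steps = rng.normal(0.0, cfg.step_sigma, size=(n, L - 1, 3))
    pos = np.concatenate([np.zeros((n, 1, 3)), np.cumsum(steps, axis=1)], axis=1)

    assignments = []
    for a, b, f, loop_sigma in cfg.loops:
        looping = rng.random(n) < f
        assignments.append(looping.copy())
        k = int(looping.sum())
        if k == 0:
            continue
        m = b - a
        disp = rng.normal(0.0, loop_sigma, size=(k, 3))
        old_b = pos[looping, b].copy()
        new_b = pos[looping, a] + disp
        # ride the downstream tail on the moved anchor
        pos[looping, b:] += (new_b - old_b)[:, None, :]
        if m > 1:
            walk = np.cumsum(rng.normal(0.0, cfg.step_sigma, size=(k, m, 3)), axis=1)
            frac = (np.arange(1, m) / m)[None, :, None]
            bridge = walk[:, :-1] - frac * walk[:, -1][:, None, :]
            pos[looping, a + 1 : b] = (
                pos[looping, a][:, None, :] + frac * disp[:, None, :] + bridge
            )

    if cfg.loc_error_sigma > 0:
        pos = pos + rng.normal(0.0, cfg.loc_error_sigma, size=pos.shape)
    observed = rng.random((n, L)) < cfg.detection_q

    alleles, loci = np.nonzero(observed)
    width = len(str(max(n - 1, 1)))
    allele_ids = np.array([f"a{k:0{width}d}" for k in range(n)])
    df = pd.DataFrame(
        {
            "allele_id": allele_ids[alleles],
            "region_id": cfg.region_id,
            "locus_id": loci.astype(np.int64),
            "x": pos[alleles, loci, 0],
            "y": pos[alleles, loci, 1],
            "z": pos[alleles, loci, 2],
        }
    )
    ann = build_annotation(cfg)
    truth = pd.DataFrame(
        [
            {
                "chrom": cfg.chrom,
                "a_start": cfg.start0 + cfg.resolution * a,
                "b_start": cfg.start0 + cfg.resolution * b,
                "region_id": cfg.region_id,
                "a": a,
                "b": b,
                "f": f,
                "loop_sigma": ls,
            }
            for a, b, f, ls in cfg.loops
        ],
        columns=TRUTH_COLUMNS,
    )
    # which alleles loop, per planted loop (row order of `truth`); handy for
    # validating the contraction without re-deriving it from coordinates
    truth.attrs["assignments"] = assignments
    return TraceSet(df, ann), truth


# ---------------------------------------------------------------------------
# Named fixtures

#: Canonical desk-scale scenarios.  step_sigma is set so that typical
#: adjacent-bin distances land in the few-hundred-nm range seen in
#: kilobase-scale chromatin tracing; detection_q spans the efficiency range
#: of published experiments (~0.4-0.9).
FIXTURES: dict[str, SimConfig] = {
    # no loops: the null background for calibration.  1.5 Mb of 25 Kb bins
    # and 65% detection efficiency match the published 25 Kb-resolution
    # imaging regime this scenario emulates.
    "null_25kb": SimConfig(
        n_alleles=500, n_loci=60, resolution=25_000, step_sigma=150.0,
        loops=(), detection_q=0.65, loc_error_sigma=30.0,
        region_id="null25", chrom="chrS1",
    ),
    # one strong loop at 200 Kb separation
    "one_loop_25kb": SimConfig(
        n_alleles=800, n_loci=40, resolution=25_000, step_sigma=150.0,
        loops=((16, 24, 0.6, 100.0),), detection_q=0.75, loc_error_sigma=30.0,
        region_id="loop25", chrom="chrS2",
    ),
    # 41 x 5 Kb bins emulating an enhancer-promoter locus: one loop at
    # 110 Kb separation between bins 9 and 31
    "sox2_like_5kb": SimConfig(
        n_alleles=700, n_loci=41, resolution=5_000, step_sigma=70.0,
        loops=((9, 31, 0.5, 90.0),), detection_q=0.7, loc_error_sigma=30.0,
        region_id="sox2like", chrom="chr3", start0=34_600_001,
    ),
}


def fixture_seed(name: str, base_seed: int = 0) -> int:
    """Stable per-fixture stream: hash the name into the base seed."""
    return int(np.random.SeedSequence(
        [int(base_seed), zlib.crc32(name.encode())]
    ).generate_state(1)[0] % (2**31))


def fixture_config(name: str, n_alleles: int | None = None, base_seed: int = 0) -> SimConfig:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(FIXTURES)}")
    cfg = FIXTURES[name]
    kwargs = {"seed": fixture_seed(name, base_seed)}
    if n_alleles is not None:
        kwargs["n_alleles"] = n_alleles
    return SimConfig(**{**cfg.__dict__, **kwargs})


def truth_to_bedpe(truth: pd.DataFrame, resolution: int, path) -> None:
    lines = ["#chrom1\tstart1\tend1\tchrom2\tstart2\tend2"]
    for row in truth.itertuples(index=False):
        s1, s2 = row.a_start - 1, row.b_start - 1
        lines.append(
            f"{row.chrom}\t{s1}\t{s1 + resolution}\t{row.chrom}\t{s2}\t{s2 + resolution}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def make_fixture(
    name: str, outdir, n_alleles: int | None = None, base_seed: int = 0
) -> tuple[dict, pd.DataFrame]:
    """Write the named fixture's trace, annotation and truth files.

    Returns ``(paths, truth)`` where ``paths`` maps ``traces``,
    ``annotation`` and ``truth`` to the written files.
    """
    cfg = fixture_config(name, n_alleles, base_seed)
    ts, truth = simulate_traces(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": outdir / f"{name}.traces.csv",
        "annotation": outdir / f"{name}.annotation.csv",
        "truth": outdir / f"{name}.truth.bedpe",
    }
    write_traces(ts, paths["traces"])
    write_annotation(ts.ann, paths["annotation"])
    truth_to_bedpe(truth, cfg.resolution, paths["truth"])
    return paths, truth
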