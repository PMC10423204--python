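# Methods

## The statistical model

The caller treats each imaged allele as an independent observation. For a
candidate bin pair, the *case* sample collects that pair's Euclidean
distances across all alleles in which both bins were localized; the
*control* sample collects the distances of the pair's local genomic
neighborhood. A loop is, operationally, a pair whose case distances are
systematically smaller than its control distances — significance is
assessed with an unpaired two-sample test, FDR-controlled, and the
surviving candidates are post-processed into summit-level calls.

The unpaired (rather than paired) comparison is deliberate: detection is
incomplete, so the set of alleles observing the pair and the set observing
any given neighborhood pair differ, and a paired statistic would discard
most of the data. The price is mild conservatism — case and control share
alleles, so their means are positively correlated and the two-sample
standard error slightly overestimates the variance of the difference (see
Calibration below).

### Neighborhood geometry

The control region of pair (i, j) contains every valid pair (i′, j′),
i′ < j′ in the same region, whose Chebyshev offset
max(|i−i′|, |j−j′|) × resolution lies in [25 Kb, 50 Kb], both bounds
inclusive — the square-annulus ("donut") background familiar from Hi-C
loop callers, expressed in 1D genomic distance. Offsets that leave the
annotation or cross the diagonal are truncated; the pair itself is always
excluded. A pair whose case or control sample has fewer than `min_n = 2`
observations is reported as untested, never silently dropped.

### Control pooling

Two control constructions are implemented:

* `ctrl_mode="pooled"` (default): all neighborhood distance records across
  pairs and alleles form one sample. This weights information by
  observation and preserves power.
* `ctrl_mode="cell_mean"`: one value per allele — the allele's mean
  distance over its observed neighborhood pairs — weighting each cell
  equally. Measured on loop-free simulations this variant is strictly more
  conservative (null p < 0.05 fraction 0.017 vs 0.027 for pooling), which
  is why pooling is the default.

### Tests

Welch's unequal-variance t-test is the default (`t_variant="pooled"`
selects the classical equal-variance form). Both degenerate zero-variance
branches are defined explicitly: equal means give (t = 0, p = 1). The
Wilcoxon/Mann–Whitney rank-sum alternative uses the exact null
distribution when n ≤ 20 without ties, otherwise the tie- and
continuity-corrected normal approximation; its loop direction is taken
from the sample means, as for the t-test. Benjamini–Hochberg adjustment is
applied over tested pairs per region by default (`fdr_scope="global"`
pools regions); per-region scope matches datasets that image one region
per chromosome.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `d0` | 25,000 bp | 1D separation defining the reference cutoff (mean distance of all pairs at this separation, pooled over the dataset) |
| candidate band | 100 Kb – 1 Mb, inclusive | separations eligible for testing |
| neighborhood | 25–50 Kb, inclusive | Chebyshev control annulus |
| `fdr_max` | 0.10, strict | candidate significance cap |
| gap | 2 × resolution | single-linkage clustering adjacency on both anchors |
| summit CF floor | 1/3, inclusive | contact-frequency filter for multi-candidate cluster summits |
| singleton CF floor | 1/2, inclusive | stricter filter for isolated candidates |

Contact is strict (`dist < cutoff`): a distance exactly at the cutoff is
not a contact. Summit ties on FDR break by smaller p, then smaller case
mean distance, then lexicographic (i, j), making the output fully
deterministic; reruns on identical inputs produce byte-identical BEDPE.

## The synthetic generator

`simulate_traces` draws each allele as a Gaussian chain: successive loci
differ by independent per-axis Normal(0, `step_sigma`²) steps. A planted
loop (a, b, f, `loop_sigma`) makes each allele "looping" with probability
f: the anchor displacement is redrawn from the tighter per-axis
Normal(0, `loop_sigma`²), interior loci are re-laid as a discrete Brownian
bridge between the anchors, and downstream loci ride along rigidly. Every
localization is then dropped independently with probability
1 − `detection_q` and jittered with per-axis Normal(0,
`loc_error_sigma`²) localization error.

Canonical fixtures (all nm-scale; `step_sigma` chosen so adjacent 25 Kb
bins average ≈ 240 nm apart, in the range reported for kilobase-scale
chromatin tracing; localization error 30 nm):

* `null_25kb` — 500 alleles × 60 bins of 25 Kb (a 1.5 Mb region, the
  short end of published 25 Kb-resolution imaging panels), no loops,
  detection 0.65 (the published mESC seqFISH+ efficiency). Used for
  calibration.
* `one_loop_25kb` — 800 alleles × 40 bins, one loop at 200 Kb separation,
  looping fraction 0.6, `loop_sigma` 100 nm, detection 0.75. Used for
  recovery.
* `sox2_like_5kb` — 700 alleles × 41 bins of 5 Kb from chr3:34,600,001,
  one loop at 110 Kb separation (bins 9–31, emulating an
  enhancer-promoter pair ~110 Kb apart), looping fraction 0.5, detection
  0.7.

What the generator does **not** model: excluded volume and polymer
confinement (real chromatin distances scale much more slowly than the
chain's √separation beyond ~100 Kb), chromosome territories, locus
decoding errors, and structured (non-independent) detection dropout.
Passing tests therefore demonstrate the pipeline's statistical behavior
under a clean polymer null, not performance on any particular instrument's
error model.

## Calibration

On loop-free simulations (20 × `null_25kb`), the final loop list is empty
in ≥ 90% of runs and the fraction of tested pairs with p < 0.05 is
≈ 0.027–0.030 (seed-dependent), slightly below the nominal 0.05. Two
opposing mechanisms, both verified by stratifying the null t statistics by
separation: at small separations the test is anticonservative because
expected distance grows like √separation and the control annulus spans
±100 Kb of separation (concavity makes the control mean smaller than the
case mean), compounded near region edges where the annulus is truncated
asymmetrically; at large separations it is conservative because case and
control share alleles and overlapping genomic intervals, so their means
are positively correlated and the unpaired standard error is an
overestimate. On short regions (≪ 1 Mb), where every candidate sits near
an edge, the anticonservative side dominates; on realistic ≥ 1.5 Mb
panels the net effect is mild conservatism. The t < 0 direction filter
means the anticonservative (positive-t) tail does not translate into
false loop calls.

## Numerical and design choices

* Bin resolution is inferred per region from annotation start spacing and
  must be uniform; single-bin regions use end − start + 1.
* Duplicate localizations of one locus in one allele collapse to their
  centroid by default (`dedup_policy` = `mean` | `first` | `error`), with
  a logged warning.
* Detection efficiency is the per-allele fraction of annotated loci
  observed, averaged over alleles; for complete single-region annotations
  this equals the pooled proportion.
* Voxel-unit inputs are scaled to nm at ingestion via
  `xy_nm_per_voxel` / `z_nm_per_voxel`; the core operates in nm.
* Reference matching in benchmarking is greedy by call FDR; each
  reference loop is consumed by at most one call, and a match requires
  both anchor starts within the tolerance (1 bin by default; 10 Kb is the
  convention for enhancer-promoter benchmarks at 5 Kb resolution).
* With no calls, precision (hence F1) is defined as 0.
* For datasets whose regions cannot realize 25 Kb of separation, the
  cutoff separation `d0` must be set explicitly; the error message says
  so rather than silently substituting a different separation.

## Problem sizes

Simulation-backed checks use 20 seeds × 500–800 alleles × 40–60 loci —
enough for the planted-loop effect (anchor contraction from ~680 nm to
~160 nm in looping alleles) to be unambiguous while the full suite and
the acceptance script each finish in about one to two minutes.

## Known limitations

* The caller tests pairs independently; it does not model multi-way
  contacts or impute missing localizations (both explicitly out of
  scope).
* Calibration of the two-sample test depends on the distance–separation
  scaling of the input polymer; the quoted numbers hold for the Gaussian
  chain null.
* BH adjustment treats tested pairs as independent, which overlapping
  neighborhoods violate; the per-region scope limits, but does not
  remove, this dependence.
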