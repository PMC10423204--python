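# fishloop

Chromatin loop calling from multiplexed DNA FISH / chromatin-tracing data.

Chromatin tracing experiments (multiplexed DNA FISH, DNA seqFISH+, ORCA,
…) localize consecutive genomic bins — "targeted segments" of 5–25 Kb —
as 3D points in single cells, one trace per allele. Loop callers built for
proximity-ligation counts do not apply to these continuous distance
measurements, and detection is incomplete: typically only 40–90% of
targeted segments are imaged per allele. `fishloop` identifies chromatin
loops directly from such per-allele 3D localizations.

## Method

For alleles *k* and bins *i*, *j* with observed coordinates, the caller:

1. computes all within-allele Euclidean distances
   *d<sub>k</sub>(i, j)* (pairs with a missing localization are simply
   absent — nothing is imputed);
2. sets the dataset-level reference cutoff *r* = mean of
   *d<sub>k</sub>(i, j)* over all pairs with 25 Kb of 1D genomic
   separation, and defines the population-level contact frequency of a
   pair as the fraction of observing alleles with
   *d<sub>k</sub>(i, j)* &lt; *r*;
3. for every candidate pair at 100 Kb – 1 Mb separation, compares its
   distances (case) against the pooled distances of its local
   neighborhood — all pairs (*i′*, *j′*) with Chebyshev offset
   max(|*i* − *i′*|, |*j* − *j′*|) of 25–50 Kb — with a two-sample Welch
   *t*-test (Wilcoxon rank-sum available). *t* &lt; 0 means the pair is
   closer in space than its local background;
4. converts p-values to FDRs (Benjamini–Hochberg, per region), keeps
   candidates with *t* &lt; 0 and FDR &lt; 10%, groups nearby candidates
   (both anchor offsets ≤ 2 bins) by single linkage, and selects each
   cluster's minimum-FDR member as its summit;
5. reports summits with contact frequency ≥ 1/3 and singleton candidates
   with contact frequency ≥ 1/2 as the final loop list, serialized to
   BEDPE.

Calls can be benchmarked against a reference loop list (e.g. from bulk
Hi-C) with anchor-tolerance matching: precision = matched calls / calls,
recall = matched references / references, F1 = their harmonic mean.

A synthetic trace generator (`fishloop.synthetic_traces`) produces
Gaussian-chain alleles with planted loops (Brownian-bridge contraction in
a configurable fraction of alleles), per-locus dropout and localization
error, so every stage is testable without external data.

## Worked example

```sh
python examples/01_call_loops_end_to_end.py
```

builds a synthetic experiment (800 alleles, 40 bins of 25 Kb, one loop
planted between bins 16 and 24 in 60% of alleles, 75% detection
efficiency), runs the caller, and prints:

```
planted loop: bins 16-24 (400,001-600,001 bp)
  region_id   i   j  cluster_size  contact_freq    t_stat           fdr    flag
0    loop25  16  24            11      0.530067 -9.066347  2.106424e-15  summit
```

Exactly one loop is called — the planted anchor pair, recovered as the
summit of an 11-candidate cluster. Its anchor distances are strongly
contracted relative to the local neighborhood (*t* = −9.1,
FDR ≈ 2 × 10⁻¹⁵) and the pair is in contact in 53% of alleles.
`examples/02_stagewise_statistics.py` prints the intermediate quantities
of each stage and `examples/03_benchmark_against_reference.py` scores
calls against a reference list.

The same pipeline is available from the shell:

```sh
fishloop simulate --fixture one_loop_25kb --outdir work
fishloop run --traces work/one_loop_25kb.traces.csv \
             --annotation work/one_loop_25kb.annotation.csv --outdir work/out
fishloop evaluate --calls work/out/loops.bedpe \
                  --reference work/one_loop_25kb.truth.bedpe --tolerance 25000
```

Input formats: a locus annotation table (`region_id, locus_id, chrom,
start, end`; 1-based inclusive) and a localization table (`allele_id,
region_id, locus_id, x, y, z` in nm), comma- or tab-delimited by
extension. Outputs: distance/contact-frequency summary TSV, per-pair test
TSV, candidate TSV, final BEDPE (0-based half-open), and a run log with
the full configuration echo and input checksums.

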