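# refstab

Discovery and validation of **stable reference (housekeeping) genes** for
quantitative real-time PCR, aimed at tissues undergoing drastic
compositional change — the motivating case being the peripheral nerve
after injury, where Wallerian degeneration, axon regrowth and
remyelination remodel the cellular makeup so thoroughly that commonly
used housekeeping genes (GAPDH, ACTB, 18S, ...) are themselves regulated
and unfit for normalization.

The package implements the complete computational pipeline:

1. **Microarray mining cascade** (`refstab.screen`) — nominate candidate
   stable genes from public normalized expression time courses.  Per
   probe, fold changes fc₁/₀, fc₅/₀ and fc₅/₁ (ratio of replicate-mean
   fluorescence between time points) must all lie in [0.99, 1.01]
   (boundaries inclusive), every condition mean must reach a fluorescence
   of 100, and a gene needs ≥ 2 surviving probes.  Candidates are then
   confirmed in an independent study: over *all* probes of the gene, each
   gated contrast (including fc₇/₀) must have mean ∈ [0.98, 1.02] and
   sample SD ≤ 0.05, and genes with pseudogenes are dropped.
2. **geNorm** (`refstab.genorm`) — from a CT table, relative quantities
   rq = 2^(−ΔCT) (ΔCT anchored at each gene's highest-CT sample); the
   stability measure of gene *j* is

   M_j = mean over partners k ≠ j of SD over samples of log₂(rq_j / rq_k),

   with stepwise exclusion of the highest-M gene down to a final pair.
   Normalization factors NF_n (per-sample geometric mean of the *n* most
   stable genes) give the pairwise variation
   V_{n/n+1} = SD(log₂(NF_n / NF_{n+1})); the smallest n with V < 0.15
   is the number of reference genes you need.
3. **NormFinder-style stability** (`refstab.normfinder`) — fit
   x_gi = μ + α_g + β_i + ε_gi on log₂ relative quantities and estimate
   each gene's residual SD with a moment bias correction; the stability
   value ρ is lower for more stable genes.
4. **Synthetic data** (`refstab.synthetic`) — seeded generators for CT
   tables and probe-level expression matrices with planted stable /
   regulated genes, used throughout the test suite and in the examples.

`refstab.io` reads/writes the plain-text formats involved: wide CT TSVs
(samples in rows, genes in columns), plain or GEO-Series-Matrix
expression tables, probe→gene and per-gene (pseudogene flag) annotation
TSVs.

## Worked example

`python examples/genorm_worked_example.py` — genes A and B move in
perfect proportion across three samples while C stays flat:

```
stability measure M (lower = more stable):
A    0.5
B    0.5
C    1.0

stepwise exclusion order (least stable first): ['C']
final, most stable pair: ('A', 'B')

pairwise variation V_2/3 = 0.3333 (exactly 1/3)
optimal number of reference genes at cutoff 0.15: 3 (no V fell below the cutoff)
```

A and B never disagree with each other (log-ratio SD 0), so each carries
M = 0.5 purely from its disagreement with C; C disagrees with both
(M = 1.0) and is excluded first.  Adding C to the normalization factor
changes it appreciably (V_2/3 = 1/3 ≥ 0.15), so on this toy matrix no
two-gene NF is declared sufficient.

The other examples simulate an injury time course (days 0/1/7/28,
biological triplicates) and show both algorithms ranking the planted
stable pair on top (`rank_simulated_timecourse.py`), run the full
screening cascade against planted stage-by-stage violations
(`screen_planted_cascade.py`), and print box-plot CT summaries
(`ct_boxplot_summary.py`).

A thin CLI wraps the same functions:

```bash
refstab simulate ct --seed 7 --out sim/
refstab genorm --ct sim/ct_table.tsv --out report/
refstab rank --ct sim/ct_table.tsv
```

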