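# barcodeval

Evaluation of short DNA barcode regions (ITS2-style nuclear markers) for
species discrimination in taxonomically structured datasets — for
molecular ecologists and taxonomists who want to know, before trusting a
marker, whether its intraspecific and interspecific variation actually
separate.

Given a multi-FASTA alignment and a taxonomy table (sequence →
species → genus → subfamily, with optional species-complex membership),
the package computes, at four nested taxonomic levels (species complex,
genus, subfamily, family):

* **alignment variability** — conserved (CS), variable (VS),
  parsimony-informative (PIS) and singleton (SS) site counts plus the
  overall mean distance (OMD) of each group;
* **K2P divergence indices** — pairwise Kimura two-parameter distances
  under pairwise deletion,

  d = −½ · ln[(1 − 2P − Q) · √(1 − 2Q)],

  with P and Q the transition and transversion proportions over the L
  comparable sites of a pair; per group: all/minimum interspecific
  distance, all intraspecific distance, θ (per-species mean intraspecific
  distance, averaged over species) and coalescent depth (per-species
  maximum, averaged);
* **barcode-gap analysis** — frequency distributions of intra- vs
  interspecific distances in 1-percentage-point bins, arbitrary range
  shares, and the gap/overlap summary;
* **identification success** — leave-one-out Best Match (BM), Best Close
  Match (BCM, 95th-percentile intraspecific threshold) and a best-hit
  (BLAST1-style) criterion, each scoring queries correct / incorrect /
  ambiguous / no-match by the species composition of the tied best set.

A built-in simulator (`barcodeval.simulate`) generates
species/genus/subfamily-structured alignments under a K2P substitution
process with controllable divergence regimes — including a
zero-variation species complex and cross-species haplotype sharing — so
the entire pipeline is testable without any sequence download.

## Worked example

Simulate a family-scale survey and run the full analysis:

```
barcodeval simulate --seed 2022 --zero-variation-complex --outdir demo
barcodeval all --fasta demo/sequences.fasta --taxonomy demo/taxonomy.tsv --outdir demo/out
```

or run the numbered drivers (`analysis/01_simulate.py` …
`analysis/05_identification.py`), which print and write the same tables
under `results/`. With the default conditions (7 genera, 40 species,
~170 sequences of 250 bp; δ_w = 0.01, δ_b = 0.10, δ_g = 0.30
substitutions/site, κ = 2) the variability table begins:

```
  level        group   n  AL           CS          VS         PIS         SS   OMD
complex          CPX  24 250 250 (100.00)    0 (0.00)    0 (0.00)   0 (0.00) 0.000
  genus       GenusA  21 250  174 (69.60)  76 (30.40)  60 (24.00)  16 (6.40) 0.093
...
 family       family 164 250    16 (6.40) 234 (93.60) 220 (88.00)  14 (5.60) 0.208
```

The zero-variation complex (CPX) is 100% conserved — and, exactly
because every sequence is identical across its five species, the
identification stage classifies 100% of its queries as *ambiguous* under
BM, BCM and the best-hit rule: the tied nearest-reference set always
spans several species. At family level, where the barcode gap is wider,
BM identifies 76.83% of 164 queries correctly. The gap driver prints the
distance-distribution shares behind this, e.g. 88.74% of intraspecific
pairs below 2% distance while only 3.97% of interspecific pairs fall
below 6%.

Everything the summary tables contain can be re-derived from the
per-query verdict TSVs and per-group histogram CSVs written next to
them.

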