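# Methods

## Scope and data model

The package evaluates a short aligned nuclear barcode region over a
taxonomically nested dataset. The unit of analysis is one sequence with
a species label; species map to genus and subfamily, and optionally to a
named species complex. All analyses run per *group view*: the subset of
the master alignment belonging to one group at one level (species
complex, genus, subfamily, family), with columns that became all-gap
after subsetting removed, so each group's alignment length (AL) is
group-specific. Under pairwise deletion this column stripping provably
never changes a pairwise distance (the stripped sites are excluded from
every affected pair anyway); a test asserts this on gapped synthetic
data. An optional `realign` hook lets callers substitute a true
per-group realignment (e.g. an external aligner) when strict
re-alignment semantics are wanted; the built-in path is deterministic
and dependency-free.

## Validation

Two filters mirror standard barcode-study practice: (1) any sequence
containing a character outside `{A,C,G,T,-}` (case-insensitive; `U`
normalized to `T` on read) is discarded as ambiguous — the conservative
reading of "ambiguous bases", since partial-information handling of
IUPAC codes would silently change P/Q counts; (2) species left with a
single sequence are removed, because a leave-one-out query from such a
species can never find a conspecific match. The filter is idempotent and
logs every removal with its reason.

## Site classification

Columns are classified using only unambiguous residues; gaps and
ambiguity codes do not count as base types. A column with fewer than two
usable residues is *indeterminate*: it is counted in AL but in neither
the conserved nor the variable tally — this is the third category that
makes CS + VS < AL possible on gappy alignments. Among columns with ≥2
usable residues: one base type → conserved; ≥2 types each occurring ≥2
times → parsimony-informative; otherwise (at most one repeated type) →
singleton. Under this rule every variable column is either
parsimony-informative or singleton; a defensive `variable-other`
category exists in the API but is unreachable. Alignment programs differ
in how they count partially-ambiguous columns, so these tallies should
be compared across tools only qualitatively.

## Distances

K2P distances are computed per pair under pairwise deletion: sites where
either sequence carries a gap or ambiguity are excluded, leaving L
comparable sites; transitions are A↔G and C↔T, everything else is a
transversion. The distance is d = −½·ln[(1 − 2P − Q)·√(1 − 2Q)]. When
L = 0 or the log argument is non-positive (saturation) the pair is
*undefined*: it propagates as missing, is excluded from every mean, and
every summary carries a dropped-pair count. No gamma correction or
variance weighting is applied. The overall mean distance (OMD) of a
group is the arithmetic mean of its defined pairwise distances; the same
K2P/pairwise-deletion framework is used for OMD as for the divergence
indices, keeping all distance-derived quantities on one scale.

## Divergence indices

Per group: *all interspecific* = pooled mean over heterospecific pairs;
*minimum interspecific* = per species, the smallest defined distance to
any non-conspecific, averaged over species (a per-species average rather
than a group-wide minimum, so a group where only some species share
haplotypes still shows a non-zero mean); *all intraspecific* = pooled
mean over conspecific pairs; *θ* and *coalescent depth* = per species
with ≥2 sequences, the mean and the maximum conspecific distance,
averaged over species. Species with one sequence are skipped — not
zero-filled — for θ and depth, avoiding a downward bias. A
single-species group reports 0 for all five indices (there is nothing to
diverge from within the group). The ± term is the sample standard
deviation over the constituents (pairwise distances for pooled indices,
per-species values otherwise); the standard error is also emitted in the
long-form table, since conventions differ across published tables.

## Barcode gap

Defined pair distances are expressed in percent and binned into
half-open `[lo, hi)` bins of 1 percentage point by default; a value
landing exactly on the top edge is still counted (closed terminal bin).
Relative abundance is per class (intra/inter). Range shares are computed
from the raw distances, not the bins, so arbitrary ranges are exact. The
gap summary reports max intraspecific, min interspecific, their
difference (negative = overlap) and the share of interspecific pairs
below the 95th percentile of intraspecific distances. The CSV is always
written; figures are optional.

## Identification

All three criteria are leave-one-out: the query is removed from the
reference pool, every other sequence (including conspecifics) remains.
Ties are kept at exact floating-point equality — the distances derive
from identical arithmetic, so no epsilon is warranted, and ties are
precisely what produces the *ambiguous* verdict. Best Match classifies
the tied nearest set: all conspecific → correct, none → incorrect, mixed
→ ambiguous. Best Close Match first discards references farther than a
threshold — by default the 95th percentile (linear interpolation) of all
pooled intraspecific distances, configurable — and returns *no match*
when nothing survives; it can therefore only convert verdicts toward
no-match, never incorrect→correct. The best-hit criterion ranks
references by similarity; the built-in scorer is the fraction of
matching comparable sites on the aligned sequences, which is
rank-equivalent to p-distance and, on gap-free data, produces the same
verdicts as Best Match (asserted in tests). An external tab-separated
hit table (query, subject, …, bit score) can be supplied instead, so a
real BLAST run against a live database can be scored with the same
three-way rule; the built-in scorer makes no claim to reproduce
database-dependent BLAST rates. Only queries whose species has ≥2
sequences are eligible; percentages are rounded half-up to 2 decimals at
the report boundary only.

## Synthetic data

The generator emulates the structure such surveys actually face: nested
genus/species grouping across subfamilies, uneven sampling (1–10
sequences per species by default), a zero-variation species complex and
shared haplotypes between sibling species. Sequences evolve along a
star-within-star topology under the K2P process (closed-form transition
matrix; rates normalized so a branch of length t accrues t expected
substitutions/site; κ = α/β). Branch lengths are set from three target
divergences δ_w ≤ δ_b ≤ δ_g (conspecific, congeneric, cross-genus);
defaults δ_w = 0.01, δ_b = 0.10, δ_g = 0.30 at 250 bp with κ = 2 sit
inside the empirically observed spans for conifer ITS2 surveys
(intraspecific group means up to ~0.20, interspecific up to ~0.36). The
star topology makes expected pairwise divergence exactly controllable —
the K2P estimator is consistent for its own model, so E[d̂] equals the
branch-length separation, which the parameter-recovery tests verify at
30 species × 4 sequences with tolerances derived from the binomial
sampling error of a 250-site estimate. What the generator does *not*
model: birth–death tree shape, rate heterogeneity across sites or
lineages, indel evolution (an optional gap-column injector only
exercises pairwise deletion), and concerted-evolution/paralogy dynamics
of rDNA arrays. Passing tests on synthetic data therefore demonstrate
the correctness of the statistics and decision rules, not that any real
marker has a barcode gap.

## Numerical and design choices

* Distances of identical pairs are exactly 0.0 (the −0.0 from
  −½·ln(1) is normalized).
* Undefined pairs are never clamped or set to infinity; missingness is
  explicit and counted everywhere.
* All randomness in the simulator flows through one seeded NumPy
  generator; a fixed seed gives byte-identical FASTA/TSV/JSON output.
* Internal values keep full precision; rounding (half-up, mirroring how
  printed tables are typeset) happens only in report writers.
* The taxonomy file is a per-sequence TSV (`id`, `species`, `genus`,
  `subfamily`, optional `complex`); conflicting species→genus rows are
  rejected rather than resolved silently.
* The pipeline recomputes the distance matrix per group view rather than
  slicing the family matrix — equivalent under pairwise deletion (see
  above) but keeps each group self-contained, and is what a per-group
  realignment hook requires anyway.

## Limitations

Identification rates computed with the internal similarity scorer are
not comparable to rates obtained against a live reference database with
heuristic local alignment; use the external hit-table import for that.
The minimum-interspecific and ± conventions vary across published
tables; both choices here are documented above and the long-form output
carries enough raw columns (means, SD, SE, counts) to re-aggregate under
other conventions.
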