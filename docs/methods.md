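# Methods

This note records the models, rules, parameters and numerical choices
behind `crypticlade`, and what its synthetic validation does and does not
demonstrate.

## The delineation problem

Given a table of codominant multi-locus genotypes (two alleles per
individual per locus, missing values allowed), the task is to discover,
from first principles and without reference to sampling locality, whether
the individuals fall into discrete genetic lineages; to flag individuals
of putatively mixed ancestry; and to quantify how diagnosable the lineages
are from one another. The approach is the classical allozyme-era one:
ordination of individuals, applied stepwise, followed by fixed-difference
counting and genetic-distance estimation on the discovered groups. It
assumes codominant inheritance, approximately independent loci, and that
lineage divergence manifests as allele-frequency differences large enough
to produce (near-)fixed differences at some loci.

## Genotype encoding and ordination

Each (locus, allele) pair becomes one column of allele dosage: 1 for a
homozygote carrying the allele, 0.5 for a heterozygote, 0 otherwise, so
the dosages at a locus sum to 1 for a scored individual. Missing
genotypes are imputed with the column mean **within the current analysis
subset** — imputation is recomputed at every recursion step so that group
structure from a wider analysis never leaks into a nested one. The
inter-individual metric is Euclidean distance on this encoding, under
which PCoA (classical scaling: double-centring of the squared-distance
matrix, `B = -½ J D² J`, eigendecomposition, coordinates `v√λ`) is
equivalent to a PCA of the dosage matrix; this makes an independent
brute-force oracle trivial to write and is the package's default and only
built-in metric (the distance function is an extension point). Axes with
eigenvalues at or below a relative tolerance of 1e-12 of the largest are
dropped; for fully degenerate input (all individuals identical) the
result simply has zero axes. Eigenvector sign is canonicalised by making
the largest-magnitude coordinate on each axis positive, so repeated runs
are bit-identical.

## The split rule

The original protocol delimited clusters by eye on scatterplots. The
automation here must make that judgement explicit. On the first two axes,
single-linkage clustering supplies candidate partitions (cut at k = 2, 3,
… clusters); clusters below a size floor *m* are set aside as
"unassigned" points. A candidate is accepted when:

1. at least two clusters reach the size floor (*m* = 4 by default — the
   smallest group the quantification stage should ever see);
2. the smallest between-cluster single-link distance (the gap) exceeds
   *g* × the median within-cluster nearest-neighbour distance (*g* = 3);
3. the gap exceeds `jump_factor` × the largest single-link merge height
   inside any retained cluster (default 1.7). This coherence test is the
   formal analogue of "the scatterplot shows separate blobs": each
   retained cluster must be internally connected at distances well below
   the separation. Without it, a single panmictic sample is occasionally
   shaved into spurious edge clumps, because the dosage encoding is
   discrete and PCoA axes amplify chance lumpiness. In simulations the
   two regimes are well separated (true splits score ≥ 2.1, panmictic
   artefacts ≤ 1.4), and 1.7 sits between them.

Among accepted candidates, the one with the largest gap-to-coherence
ratio wins. Unassigned points are folded into the nearest retained
cluster but remembered: they are the candidate pool for admixture
flagging. Ties in single linkage are made deterministic by processing
individuals in sorted-id order.

A geometric split is then **corroborated by the markers**: for every pair
of child cluster cores, fixed differences at the configured tolerance are
counted, and pairs sharing fewer than `min_diagnostic_loci` (default 1)
diagnostic loci are merged back. Ordination clusters are only recognised
as lineages when the genotypes can actually diagnose them — the same
logic by which the original workflow reported every recognised cluster
pair as fully diagnosable. The recursion (re-encode, re-ordinate,
re-test) continues inside every surviving child until no split is
accepted.

## Admixture flagging

After an accepted split, a candidate (an individual that cohered with no
cluster core) is flagged as putatively admixed when, for some pair of
children it was folded into, (a) its position on the axis best separating
the two cores lies strictly between the cores' convex ranges, and (b) it
carries private alleles of *both* cores at ≥ 50% of its scoreable
diagnostic loci. Diagnostics for this gate are computed between the cores
(candidates excluded), because a single F1 genotype inside a group makes
the other group's alleles "shared" at full frequency and would otherwise
erase the very loci that betray the hybrid. Individuals with all
diagnostic loci missing are never flagged (a warning is logged). Flagged
individuals receive an admixed flag, not a lineage label, and are
excluded from child membership before recursion. The model detected is
F1-like admixture; backcrosses are outside scope.

## Diagnosability statistics

*Fixed differences with tolerance.* For groups A and B at one locus,
shared alleles are those with positive frequency in both; with
`S_A = Σ_{shared} x_{A,i}` and `S_B` likewise, the locus is diagnostic
when `max(S_A, S_B) ≤ τ`, default τ = 0.10. The reading of the tolerance
as a per-group budget is a deliberate choice; the alternative
`S_A + S_B ≤ τ` is available as `tolerance_mode="sum"`. τ = 0 reduces to
strict fixed differences (disjoint allele sets). A locus with no scored
copies in either group is never diagnostic.

*Δp screening.* Per locus, `Δp = max_i |x_{A,i} − x_{B,i}|` over the
union of alleles; loci with Δp above a threshold (default 0.40) are
reported as near-diagnostic.

*Nei's unbiased D.* Per locus `Ĵ_x = (2n_A Σ x_i² − 1)/(2n_A − 1)` (and
`Ĵ_y`), `J_xy = Σ x_i y_i`; arithmetic means over loci scoreable (2n ≥ 2)
in both groups, `I = mean(J_xy)/√(mean(Ĵ_x)·mean(Ĵ_y))`, `D = −ln I`.
Loci failing the 2n ≥ 2 floor in either group are dropped pairwise with a
logged count. `Ĵ` is clamped to [0, 1] before averaging; `I > 1` — which
the unbiased correction genuinely produces at small n (two groups both at
0.5/0.5 with n = 10 give `Ĵ = 9/19 < J_xy = ½`) — is clamped to 1 with a
note, so D is never negative; `I ≤ 0` yields `D = +∞`. With
`corrected=False` the uncorrected `J_x = Σx_i²` is used, under which a
group's self-distance is exactly zero. Rare alleles are used as
estimated, never pooled: the tolerance rule already absorbs rare sharing.

## Neighbour-joining

Standard Saitou–Nei agglomeration on the Q-criterion, exact on additive
matrices. Ties in Q are broken by the lexicographically smallest label
pair, identifying an internal node by the smallest leaf label beneath it,
so output is deterministic and invariant to input label order. A negative
branch length at a join is clamped to zero with the deficit transferred
to its sibling (the joined pair's path length is preserved); raw
unclamped lengths are kept as node annotations. Trees are unrooted
(trifurcating seed node); outgroup rooting is display-only via the CLI's
`--root`. Infinite or NaN distances are rejected with the offending pair
named — a Nei's D of +∞ (fully fixed groups) cannot be placed on a tree
and should be handled upstream.

## Sequence divergence

p-distance = differing sites / compared sites, case-insensitive, with
sites containing `N` or `-` in either sequence excluded (pairwise
deletion, matching mainstream defaults); complete deletion is available
for sensitivity. Gaps are treated like missing data because in the
intended inputs (protein-coding mtDNA alignments of partial amplicons)
they denote absent flanks, not indels. A pair with zero comparable sites
is an explicit error for a single comparison and a flagged NaN inside a
matrix. Clade summaries report min–max ranges among and within clades
(proportions to 3 decimals, percentages on demand); single-member clades
have undefined within-ranges, flagged rather than zeroed. Clade
membership is always supplied by the caller — the statistic is decoupled
from any tree inference. Windowed re-analysis (`prune_alignment`, 1-based
inclusive coordinates) supports comparisons restricted to a short
amplicon region; the window is configuration, not a constant, because
amplicon coordinates vary between primer systems.

## Synthetic data generator

Genotypes are drawn per individual per locus as two independent draws
from the lineage's allele frequencies (Hardy–Weinberg), then masked to
missing at a configured rate; all randomness flows from one integer seed
through `numpy`'s Generator, so outputs are bit-identical per seed.
Admixed individuals draw one allele from each parent lineage at every
locus (F1 model). Sequences evolve down a user-supplied tree under
Jukes–Cantor with exact per-branch transition probabilities
(`P(same) = ¼ + ¾e^{−4t/3}`), the root uniform over the four bases;
terminal runs can be masked to `N` to emulate partial amplicons of
varying length.

The reference scenario used throughout testing has three lineages of 25
individuals, 40 loci, 5% missing data, and strict diagnostic loci planted
in counts 4/6/8 for the three lineage pairs (at a pair's diagnostic
locus the third lineage segregates both alleles at 0.5/0.5, so the locus
diagnoses exactly that pair); the remaining 22 loci are shared two-allele
polymorphisms with major-allele frequencies cycling through
0.9/0.8/0.7/0.6, typical of allozyme polymorphism. These sizes keep the
full 100-replicate validation under a minute while leaving the
within-lineage scatter large enough that the split rule is genuinely
exercised.

What passing these simulations shows: the pipeline recovers planted
structure of the stated strength (several strict diagnostic loci per
pair) essentially always, does not invent structure in panmictic samples,
and recognises F1 hybrids between diagnosable lineages. What it does not
show: behaviour under linkage, inbreeding, isolation-by-distance clines,
backcrossed or later-generation hybrids, or lineages separated only by
frequency shifts without near-fixed differences — real data can present
all of these, and the marker-corroboration gate deliberately refuses to
name lineages that no locus diagnoses.

## Numerical and interface choices

- Genotype tables: CSV/TSV with header `individual,site[,region],locus…`;
  tokens `ab`, `a/b` on read, canonical `a/b` (homozygotes explicit,
  missing empty) on write, so round-trips are byte-identical. Allele
  labels are opaque case-normalised tokens. Genepop export assigns
  two-digit codes in sorted label order.
- Distance matrices: labelled TSV and PHYLIP square; symmetry enforced at
  1e-12, diagonal exactly zero.
- Newick output quotes labels containing metacharacters and formats
  lengths with trailing-zero trimming at a configurable precision;
  parsing is delegated to dendropy.
- The pipeline writes machine outputs (TSV/JSON) deterministically —
  reruns with the same config and inputs are byte-identical — plus a
  plain-text combined matrix (fixed differences lower triangle, Nei's D
  to 2 decimals upper triangle) for human reading. Exit codes: 0 success,
  1 input error, 2 internal error.

## Known limitations

- The split rule sees only the first two PCoA axes per step (the
  recursion compensates across steps, as in the original stepwise
  protocol); structure expressed purely on axis 3+ of a given step is
  found only after an earlier split isolates it.
- Admixture detection requires diagnostic loci between the flanking
  clusters at the configured tolerance; shallow splits without them
  cannot yield flags (by design).
- Nei's D between groups with disjoint alleles at all shared loci is +∞,
  which NJ cannot consume; site-level trees therefore require some shared
  variation.
- The generator's Hardy–Weinberg, linkage-free model understates the
  correlation structure of real multi-locus data.
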