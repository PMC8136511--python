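# Methods

This note documents the models, algorithms, defaults and design
choices behind `lbagrid`, and what its synthetic benchmarks do and do
not demonstrate.

## The problem

Long-branch attraction (LBA) is the systematic error by which
phylogenetic methods group fast-evolving lineages together regardless
of their true relationships. It is most damaging at short, deep
internodes flanked by lineages with heterogeneous rates — the regime
of the chelicerate backbone, where the placement of pseudoscorpions
(a fast-evolving order whose basal superfamilies are short-branched)
flips between its true sister group and unrelated fast-evolving
orders depending on which taxa are sampled. The package implements
the two complementary attacks on this problem: (1) a *sensitivity
grid* that systematically varies matrix completeness (gene-occupancy
families) against taxon sampling (a sequential-pruning series) and
reads off the focal clade's inferred sister group in every cell, and
(2) *rare genomic changes* — shared gene and miRNA duplications from
an ancient whole-genome duplication, and parsimony reconstructions of
behavioral characters — as external arbiters that do not depend on
sequence-rate assumptions.

## Design accounting

The bundled registry reproduces the ordinal composition of the
motivating data set: 117 chelicerate terminals (40 pseudoscorpions
covering all superfamilies) plus 15 outgroups. The pruning series
removes basally branching pseudoscorpion superfamilies in order —
Chthonioidea (6), Feaelloidea (2), Neobisioidea (10), Garypoidea (5),
Garypinoidea (3), Cheridoidea + Sternophoroidea (2, one combined
step) — leaving the 12 Cheliferoidea exemplars, i.e. focal counts
40, 34, 32, 22, 17, 14, 12 across T0 … T-6. Occupancy families are
labelled G1 … G6 by decreasing threshold (80, 75, 70, 65, 60, 55%),
so G1 is the densest and shortest matrix. The full plan — partitioned
ML and summary-coalescent runs on the 6 × 7 grid, site-heterogeneous
mixture reruns of G1 and G6 (and a richer mixture of G1), and
rate-tertile runs of G2 and G3 — enumerates to 189 analyses; the
arithmetic is checked against a brute-force flat enumeration.
Subgroup labels match case-sensitively after whitespace trimming;
fuzzy matching would hide registry errors.

## Supermatrix construction

A taxon is *present* in a locus only with at least one unambiguous
residue; all-gap or all-X rows never count, so concatenation padding
cannot inflate occupancy. Occupancy filtering happens once, on the
full taxon set, and pruning is applied afterwards to each family
without re-filtering; loci left with fewer than four taxa are flagged
untreeable but retained. Partition spans are 1-based inclusive and
tile the concatenated length exactly (a tested invariant).

Evolutionary rate is proxied by mean percent pairwise sequence
identity (MPSI): the mean over unordered row pairs of the fraction of
identical, mutually unambiguous columns, times 100. Pairs with no
comparable columns are dropped; a locus with no comparable pair has
undefined MPSI. Tertile binning sorts by MPSI descending (high
identity = slow), splits into three bins with sizes differing by at
most one, assigns the remainder slow-first, and breaks ties
lexicographically by locus id — the remainder and tie rules are
arbitrary but deterministic, and documented here because no standard
fixes them.

## Likelihood engine

Substitution models are general time-reversible 20-state chains
Q_ij = S_ij π_j (i ≠ j), normalized to one expected substitution per
unit branch length. LG, WAG and JTT exchangeabilities and
frequencies are bundled as PAML-layout text files of the published
tables (Le & Gascuel 2008; Whelan & Goldman 2001; Jones, Taylor &
Thornton 1992); Poisson (equal rates, equal frequencies) is computed.
Rate heterogeneity uses the standard discrete-gamma approximation:
k equal-weight categories whose rates are interval means of the
quantile partition (default k = 4), computed from the regularized
incomplete gamma function; the category mean is 1 to 1e-10.

P(t) = exp(Qt) is computed by symmetric eigendecomposition of
D^{1/2} Q D^{-1/2} (D = diag(π)); entries are clipped to [0, 1]
against numerical noise, and t = 0 returns the exact identity so that
zero-length branches behave exactly.

Felsenstein pruning treats `-`, `X`, `?` and the other ambiguity
codes as fully ambiguous (partial likelihood 1 for every state).
Underflow is handled by per-node rescaling with accumulated log
scalers. Per-site likelihoods are averaged over gamma categories with
equal weights before the log; a site of zero likelihood is floored at
log-likelihood −745 with a warning, keeping sums finite while
surfacing the pathology.

Branch lengths are optimized coordinate-wise. For each edge the
likelihood is a one-dimensional function of that edge's length once
the subtree ("down") conditionals and rest-of-tree ("up",
root prior folded in) conditionals are available; each such problem
is solved by bounded Brent search on [1e-8, 20]. A sweep computes one
down/up pass pair and optimizes every edge against that shared
context; because contexts go stale within the sweep, the sweep's
result is verified against the full likelihood and, in the rare case
of a decrease, reverted and redone with exact per-edge recomputation.
Sweeps stop when the improvement falls below the tolerance
(default 1e-4, at most 50 sweeps; non-convergence returns best-so-far
with a warning). The two-taxon case matches the closed-form 20-state
Poisson distance −(19/20)·ln(1 − 20p/19) to 1e-4 (a tested
invariant).

Model choice is by BIC = −2 lnL + p·ln(sites), with p counting free
branch lengths plus one for a gamma shape; gamma candidates alternate
bounded shape optimization (α ∈ [0.02, 100]) with branch-length
sweeps. Ties break by candidate order. The engine fits one model per
matrix; per-partition fitting of concatenated matrices is out of
scope (per-locus models arise only in ΔGLS, where each gene is fitted
separately).

Tree search is deliberately modest — neighbor joining on
Poisson-corrected distances (negative branch lengths clamped to zero
with a warning) followed by nearest-neighbor-interchange hill
climbing, re-optimizing branch lengths per candidate and stopping
when no interchange gains more than 1e-3 lnL. Support comes from a
plain nonparametric site bootstrap (resample columns, rerun the
search, count bipartitions of the point estimate), reproducible under
a fixed seed. Fitch parsimony encodes residues as 20-bit masks and is
the package's model-free foil: precisely the inference that is
inconsistent in the Felsenstein zone.

## Gene-wise signal (ΔGLS)

ΔGLS for a locus is lnL(locus | T₁) − lnL(locus | T₂). Each
constraint topology is pruned to the taxa present in the locus
(degree-2 nodes suppressed, lengths summed), a model is chosen per
gene by BIC, and branch lengths are re-optimized on each constraint —
the statistic's standard construction, stated here because it is
easy to get silently wrong. Loci with fewer than four taxa after
restriction on either side are skipped and flagged rather than
guessed. Summaries report proportions over defined, non-zero values
(exact zeros — e.g. loci for which both constraints collapse to the
same restricted topology — are neutral and reported separately) plus
magnitude quantiles.

## Placement classification

A tree is rooted on the edge separating its outgroup when the
outgroup is monophyletic; otherwise on the first outgroup leaf, with
a loud flag. If the focal leaves are not monophyletic the category is
"non-monophyletic"; otherwise the sister is the remainder of the
focal clade's parent, and the category is the single group covering
it, a composite "A+B" label when it is exactly a union of whole
groups, or "other" (with the sister leaf set recorded) when it is
not. Because placement hypotheses can be nested (a sister group that
is one member of a larger named clade), `category_matches` counts a
category toward every hypothesis set containing all its groups.
Support read-off returns the label of the node whose descendant set
equals the hypothesis clade, or "not recovered" (plotted as 0 by
convention) when absent.

## Ancestral states: ACCTRAN and DELTRAN

Characters are binary (or small-alphabet) with "?" as a free state.
Fitch's downpass gives the minimum change count. Among the
minimum-length reconstructions, ACCTRAN is formalized as the one that
additionally *minimizes* the sum of root-depths of change edges
(changes as rootward as possible — an early gain with later
reversals), and DELTRAN as the one that *maximizes* it (changes
delayed tipward — parallel gains). Both are computed exactly by a
Sankoff dynamic program over lexicographic costs, so the equal-length
guarantee is structural, and both are validated against exhaustive
enumeration of all minimum-length reconstructions on random trees.
Root-state ties resolve to the state observed in the outgroup.

On the bundled order-level chelicerate fixture, the *promenade à
deux* courtship dance (present in Pseudoscorpiones — retained in
Cheliferoidea, coded present at the tip granularity of the fixture —
Scorpiones, Amblypygi, Uropygi, Schizomida) has Fitch length 2 with
exactly two reconstructions: ACCTRAN = gain on the Arachnopulmonata
stem + loss in spiders; DELTRAN = parallel gains on the Panscorpiones
and Pedipalpi stems. Book lungs reconstruct under ACCTRAN as an
arachnopulmonate gain secondarily lost in pseudoscorpions. The
sub-ordinal loss/regain story within pseudoscorpions is below the
fixture's tip granularity and is documentation, not coding.

## Reconciliation and duplication evidence

LCA reconciliation maps each gene-tree node to the most recent common
ancestor of its descendant species; a node is a duplication iff its
mapping equals a child's mapping. A duplication is *shared by a
clade* iff it maps at or above the clade's MRCA with clade members on
both sides; it is *lineage-specific* when confined within one member
or strictly inside the clade. Event labels are validated against an
independent leaf-set-based oracle on random gene trees. Gene trees
must arrive rooted; reconciliation is rooting-sensitive and silent
auto-rooting would hide errors.

Paralog screening works on aligned candidate fragments: a pair is
called paralogous only with an overlap exceeding 100 residues and at
least two substitutions; pairs differing at most once are alleles
and merged; non-overlapping fragments merge into one putative copy;
short-but-divergent overlaps merge conservatively. Copy number is the
number of connected components of the merge graph, hence invariant to
input order. "Multiple substitutions" is read as ≥2 and "exceeding
100 amino acids" as >100 — literal, documented readings. The motif
filter retains peptides containing every required motif (defaults
ELEKEF and KIWFQN, the homeodomain anchors used for screening
candidate homeobox translations). miRNA/homeobox *discovery*
(BLAST, secondary structure, CDD classification) is out of scope;
the package consumes copy tables and applies the tally logic: a row
is flagged as a shared duplication iff some focal-clade species and
some reference-clade species both have ≥2 copies.

## The synthetic LBA scenario

`lba_scenario` builds a 24-taxon tree structured like the empirical
problem: a focal clade of 8 (three basal subgroups of two
short-branch tips plus two fast-evolving derived tips), a
short-branch true sister clade of 4, an unrelated fast-evolving
attractor clade of 4, 4 other ingroup tips and 4 outgroup tips.
Long lineages are created by multiplying branch lengths (6× on
derived-focal tips and on the attractor stem and tips), never by
switching the substitution process — isolating rate as the only
confounding mechanism. Loci (default 300, 150–400 sites) draw
across-locus rate multipliers from a gamma with shape 1 and mean 1;
each taxon independently drops out of each locus with probability
0.25, producing occupancy centered near 75%; gaps arise only from
dropout (no indel process). Identical seeds give byte-identical locus
sets.

Three base lengths set the regime and were calibrated by simulation
under the generator's full conditions (rate multipliers and dropout
included), then frozen: short tips 0.02, within-clade internals 0.12,
deep backbone internodes 0.03 substitutions/site. Two structural
choices matter and are the package's own:

- The 6× multiplier applies to the derived subgroup's *tips* but not
  its *stem*. With the stem also inflated, the long unbroken pendant
  edge exists at every taxon subset and no parameter region separates
  the pruned from the unpruned regime — the unpruned analysis then
  loses focal monophyly about as often as the pruned one is
  attracted. With a short stem, the long pendant is *assembled by
  pruning*: removing the basal subgroups concatenates the ladder
  internals onto the stem, which is exactly the branch-breaking
  mechanism taxon sampling is supposed to provide.
- Backbone internodes are distinct from (and much shorter than)
  within-clade internals: the deep radiation is the hard part of the
  problem, while the ladder internals are what pruning converts into
  pendant length.

Under these conditions, model-free inference (Fitch parsimony over
NJ+NNI) on concatenated locus sets recovers the true sister at T0 and
is attracted to the attractor clade at T-3, with T-1/T-2 as the
transition zone — the block pattern the sensitivity grid is built to
expose. Maximum likelihood under the generating model recovers the
true topology in the same Felsenstein-zone constructions where
parsimony fails (a tested contrast on quartets).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run everything at desk
scale, chosen as the smallest sizes at which the qualitative claims
are stable: 200 randomized trees of ≤5 leaves against exhaustive
enumeration (tolerance 1e-8); a 200-locus ΔGLS scenario (equal-rates
model per gene); 50 replicate 60-locus scenarios for the
pruned-vs-unpruned contrast plus replicate occupancy × pruning grids
for the block pattern; 500 random 12-leaf reconciliations against the
oracle; 300-locus supermatrix bookkeeping. All randomness flows from
explicit seeds.

## What the synthetic benchmarks do and do not show

They show that the pipeline's statistics and classifications behave
as designed on data generated under the package's own models: rate
inflation alone, at realistic topologies and occupancy, suffices to
produce the taxon-sampling-dependent placement flip, and the engine's
numerics are correct against closed forms and enumeration. They do
not show anything about compositional bias, heterotachy within loci,
alignment or orthology error, or model misspecification beyond
rate — none of which the generator emulates. Real-data conclusions
require the external arbiters (duplication evidence) precisely
because simulated rescue of a simulated artifact cannot license a
claim about empirical chelicerates.

## Known limitations

- One substitution model per matrix; no per-partition concatenated
  fitting, no site-heterogeneous mixtures (site-heterogeneous trees
  are consumed as Newick input, not recomputed).
- NNI-only topology search; no SPR/TBR, so searches on large trees
  can stall in local optima (bootstrap replicates inherit this).
- Plain site bootstrap, not ultrafast bootstrap; support values are
  comparable in convention (percentages on bipartitions) but not in
  distribution.
- The summary-coalescent step of the original design (quartet-based
  species trees from gene trees) is consumed as external input; the
  package classifies and grids those trees but does not estimate
  them.
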