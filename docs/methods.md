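# Methods

This note records the models, parameter choices and known limitations behind
the package, in the order the pipeline runs them.

## Gene-family simulator

**Birth–death process.** Each stem lineage enters the species-tree root as a
single gene copy. Along every branch of length t (expected substitutions per
site), each copy draws Poisson(dup_rate·t) duplications and
Poisson(loss_rate·t) losses, placed at uniform positions and applied in
order; a loss kills the copy (remaining drawn events are void), a
duplication spawns a second copy that explores the rest of the branch with
fresh draws. This per-branch Poisson formulation is distributionally a
standard linear birth–death process but keeps closed-form checks trivial:
under pure loss, survival across a branch is exactly e^(−μt), which the test
suite verifies against 10,000 replicates.

**Default regime.** `dup_rate = loss_rate = 0.01` per unit branch length on
a 12-species tree of total length ≈ 3.8. The regime is deliberately easy in
a precise sense: the clade-calling estimand is the number of ancestral genes
*at the radiation*, which equals the planted `n_stem_lineages = 5` only when
no event hits the deep branches — a duplication on the pre-bilaterian path
creates two genuinely distinct broadly-sampled paralog clades, and a loss on
a superphylum stem can truly remove a lineage from two of the three
bilaterian superphyla, after which no composition-based caller should call
it. With the distorting channel ≈ 1.05 units per lineage, the default rate
keeps the probability of a distorted run near 5%, so the planted count is
the correct answer in the overwhelming majority of runs while typical runs
still contain occasional duplications and losses. Higher rates are fully
supported; they simply change what the truth is.

**Sequences.** A fixed 150-residue helical-biased template with five anchor
positions (indices 17, 46, 69, 104, 137; all clear of the first eight
residues so planted N-terminal motifs never touch them) that are never
substituted — the synthetic analogue of the invariant residues that anchor
real globin alignments. Per branch, each non-anchor site is replaced with
probability 1 − e^(−t·subst_rate_scale) by a uniform draw from the other 19
residues; this "at most one effective substitution per branch" scheme makes
the expected changed-site count on a branch exactly (L−A)(1 − e^(−t)),
which the tests verify. There are no indels, so simulated sequences are
aligned by construction and the core alignment is simply the trailing 150
residues of each protein.

**Stem divergence.** Each lineage first evolves along a private stem branch
of length `stem_divergence = 0.6` before the radiation. The value comes from
a saturation bound, not from tuning: the deepest leaf-to-leaf path is
2·(stem + 0.5), and uncorrected p-distances approach 0.95·(1 − e^(−T));
keeping T ≤ 2.2 holds p below the Poisson-correction cap (0.95) so
between-lineage distances remain estimable while staying much larger than
within-lineage ones.

**Planted features.** The secretion lineage gets a 19-residue signal peptide
prepended (n-region MKF, 10-residue hydrophobic h-region, AS-A-type
c-region); the membrane lineage has its first eight residues overwritten
with a Gly-2/Cys-3 dual-acylation motif. Features are applied after sequence
evolution, so predictor tables derived from truth are exact. Decoys are
per-species shuffles of the template — composition-matched nulls, which is
the hardest realistic case for a composition-blind screen.

**qPCR plate.** Stages 48 hpf → 6 weeks → 50 segments → metamorphosis I →
metamorphosis II → swarming, with planted relative levels
(0.001, 0.02, 0.40, 1.20, 0.30, 0.005): negligible early, rising to a peak
at the onset of metamorphosis, collapsing in the swarming adult. Reference
genes rps9/sams sit near Ct 18/20; biological noise is 0.3 cycles (shared by
the technical duplicates of a sample) and technical noise a tenth of that.
Note the 50-segment and metamorphosis-II levels differ by only ~0.4 cycles —
within biological noise — so recovery is judged on the profile shape and
rank agreement, not on a total order of all six stages.

**What the simulator does not emulate.** Indels and alignment uncertainty;
rate heterogeneity across sites and lineages (no LG-style matrix);
gene conversion; incomplete proteome annotation; compositional drift.
Passing tests therefore demonstrate the pipeline's logic is correct on data
satisfying its assumptions, not that real proteomes behave this cleanly.

## Homology screen

`smith_waterman` is Biopython's C local aligner (affine gaps, default
BLOSUM62 with its X row, gap open 11 / extend 1); the test suite holds it to
an independently written three-matrix Gotoh DP on hundreds of random pairs.
E-values use the ungapped-form Karlin–Altschul statistic with
published-style gapped BLOSUM62 constants (λ = 0.267, K = 0.041),
configurable. The screen E-value is computed in the actual probe×proteome
search space. Reciprocal validation, by contrast, emulates a search against
a comprehensive protein database: the packaged labelled reference set stands
in for that database, and its E-values are computed in an effective search
space of 10⁷ residues (overridable) so that the customary cutoff
(reciprocal E ≤ 10⁻³) keeps its ~40-bit meaning instead of degrading to the
~27 bits a 2-kb toy database would imply — with composition-matched decoys,
that difference is exactly what separates chance matches from homology.
The primary-screen cutoff defaults to E ≤ 10 (a deliberately permissive
cutoff so even the most divergent members enter the ranked list; the
stopping rule, not the cutoff, ends the scan). Ranking ties break by score
then id, so scans are deterministic. A hit whose best reciprocal match is
ambiguous counts as a validation failure.

## Localization, clusters, introns

Localization is a total three-way function with extracellular (signal
peptide) taking precedence over membrane (dual acylation). "Closely located"
dual acylation is quantified as both sites within the N-terminal 25 residues
and ≤ 10 residues apart (configurable); dual-acylation biology is
N-terminal, and the defaults comfortably cover the planted Gly-2/Cys-3
motif. When no predictor table is supplied, sequence-only fallbacks run: the
signal heuristic (≥ 8 consecutive hydrophobic residues starting 1–5 residues
into the sequence, within the first 30) and an acylation heuristic (Met-Gly
start plus a Cys in the first 10 residues). The acylation fallback is a
package addition so that the fallback path can classify all three classes;
both heuristics are documented stand-ins and are never used when external
predictions exist. When several external predictors disagree about a signal
peptide, combine them by logical OR before building the table (one flag per
gene, its source recorded): for a screen whose point is not to miss
divergent members, a single confident predictor suffices to flag a
candidate.

Clusters are single-linkage groups per scaffold with inter-gene gap ≤ 50 kb
(compact cluster scale; configurable); intervals are converted to half-open
coordinates at parse time and overlap flags are set on intersection.
Intron labels use the globin helix track (helices A–H over the template,
inter-helix segments named by the flanking pair, NA before A and HC after
H): column, helix residue index and phase compose to labels such as B12.2
or G7.0.

## Tree analysis

Supports are read from internal node labels; values on a 0–100 scale are
rescaled with a warning. All operations are functions of the bipartition
set, so they are invariant to leaf order and to the arbitrary rooting of the
Newick text; the two rooted-representation edges at the seed node collapse
to one unrooted edge, keeping the stronger label.

"Broad sampling" is quantified as ≥ 2 of the three bilaterian superphyla and
≥ 4 species (configurable; reported in output). The single-ancestral-gene
criterion fails a side iff it contains two *disjoint* well-supported sides
that are each broadly sampled — breadth is judged on bilaterian sampling
regardless of non-bilaterian presence, otherwise the complement of every
true clade would pass whenever non-bilaterians exist. Delineation keeps
maximal qualifying sides: nested candidates (a clade minus one species, or a
clade plus a small non-bilaterian radiation attached under its defining
edge) collapse onto the largest, which is also why a clade that absorbs
attached non-bilaterian genes is reported pan-metazoan rather than leaving
those genes unplaced. Mono-species radiations need ≥ 3 genes. Root exclusion
removes edges strictly inside accepted clades (the defining edge stays
admissible) and raises a diagnostic when nothing remains.

Parsimony-informative columns require ≥ 2 states each in ≥ 2 sequences;
gaps are missing data by default, not a fifth state.

The stand-in tree builder is neighbour-joining (scikit-bio) on
Poisson-corrected distances d = −ln(1 − p), with p capped at 0.95 under a
warning; supports are bootstrap proportions over column resamples
(default 100 replicates, seeded). It exists so synthetic tests can run
without an external ML engine; for real data, import any Newick tree with
supports instead.

## Dollo reconstruction

Single gain above the MRCA of carriers (so clades present on both sides of
the root annotate the root branch), losses = maximal absent subtrees below
it; polytomies are handled per child. Replay verification runs on every
call. For simulations, where every lineage originates at the root, the
package also derives the *presence-level truth history* (gain at the root,
one loss per branch where presence switches off). When presence spans both
root children the Dollo reconstruction provably coincides with that history;
when an entire root-side is lost, Dollo's gain migrates down to the MRCA and
its loss count is a lower bound — the validation experiments check exact
equality on the former cases and the bound on the rest. Independent regain
is not modelled, matching the single-ancestral-gene reading of clade
membership.

## qPCR

Efficiency E = 10^(−1/slope); slope from least squares of Ct on log10
dilution. Relative levels are 2^(−ΔCt) against the arithmetic mean of
reference Cts (equivalently the geometric mean of linear quantities);
efficiency is reported but never folded into the expression formula.
Technical replicates are averaged as Ct *before* ΔCt — the order matters
because 2^x is convex, and a regression test pins it. Stage values are
medians across biological replicates, with min/max spread reported. No
outlier removal is performed.

## Problem sizes

Default analyses run at 12 species × 5 lineages (~60 genes plus 480
decoys), 150-residue sequences, 100 bootstrap replicates, and 50 replicate
simulations for the recovery experiment; oracle-equivalence checks use 200
random pairs (aligner), and 100 random instances each for root exclusion
and Dollo reconstruction. These sizes keep a full validation run around a
minute on one CPU while leaving every statistical check with comfortable
resolving power.
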