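# Methods

This note documents the models and procedures implemented in `sirphylo`,
the parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Repeat detection

**Dot matrix.** Two protein sequences are compared with a sliding window of
odd length *w* (default 11) scored by a substitution matrix (default
PAM250). A mark is placed at window-center pair (i, j) when the ungapped
window score reaches `min_score_fraction` × the maximum attainable window
self-score. We define the attainable maximum as the query window's
self-score capped by the reference window's: with either window's
self-score alone, a self-comparison would not be exactly symmetric, while
the capped rule preserves symmetry, the fully marked main diagonal at
fraction 1.0, and monotonicity (lowering the fraction can only add marks).

**Boundary calling.** For each maximal run of consecutive marks along a
diagonal (minimum run length 3, automatically reduced when the window
leaves fewer than 3 valid centers on a 50-residue reference), a frame of
exactly `domain_length` residues (default 50) is anchored at the start
maximizing the summed ungapped score against the reference domain, searched
within ± one window of the run's implied start. A unit is kept when that
score reaches `min_score_fraction` of the reference's self-score. Hits are
merged across reference domains; overlaps are resolved by higher score,
ties by earlier start; ordinals are assigned N→C. This makes an otherwise
manual boundary-designation step deterministic and reproducible; a curated
boundary table can always be substituted upstream.

**Stringency tiers and degeneracy.** Detection runs at a high and a low
stringency (default fractions 0.5 and 0.3, both config-exposed; the
windowed-dot-plot literature fixes neither). Units found only at low
stringency are flagged *degenerate* and excluded from species profiles by
default. Calibration on planted repeats: 85%-identity copies of a 50-mer
are recovered within ±3 residues in ≥95% of seeded replicates at the high
tier; copies below ~45% identity are generally invisible even at the low
tier, which matches the intended meaning of "degenerate" (recognizable as a
repeat, little residual homology).

**Linker extraction.** The repeat-bearing linker is the region strictly
between the local-alignment footprints of a C-terminal ERS anchor and an
N-terminal PRS anchor (BLOSUM62, open 11 / extend 1, via Biopython's
PairwiseAligner). Each anchor must score ≥ 40% of its self-alignment score
(configurable); failures name the missing anchor. Stop codons from
mistranslated frames are never stripped; boundary calling rejects linkers
containing `*` so frame-choice errors surface.

## Alignment

Pairwise global alignment is Gotoh's affine-gap algorithm; a gap of length
L costs `gap_open + gap_extend·(L−1)` (defaults 10 and 0.5, BLOSUM62). The
traceback is deterministic (diagonal > up > left on ties), so identical
inputs always give byte-identical alignments. Gap-state switches (a gap in
one sequence immediately following a gap in the other) are permitted, so
the score is the true optimum over all alignments; tests verify this
against both exhaustive enumeration and an independent implementation.

Percent identity counts identical-residue columns over countable columns;
gap/gap columns never count. Two denominators are exposed: `all_columns`
and `exclude_terminal_gaps` (default), which drops leading/trailing gap
overhangs — the two conventions that alignment viewers commonly print.

The progressive aligner builds an NJ guide tree from pairwise score
distances `1 − s/min(self-scores)` and merges profiles in postorder;
profile–profile column scores are count-weighted mean substitution scores.
No iterative refinement is attempted; an aligned-FASTA import hook lets any
external MSA tool stand in.

## Substitution models and trees

Dayhoff (1978) and WAG (Whelan & Goldman 2001) are shipped as plain-text
exchangeability/frequency tables and assembled as reversible generators
Q_ij = s_ij·π_j, normalized to one expected substitution per site per unit
time; transition matrices come from the symmetrized eigendecomposition.
Among-site rate variation uses k equal-probability discrete gamma
categories (default 4), each assigned its slice's exact mean via the
regularized incomplete gamma function, so the category rates average to 1
exactly. The deviation of the categories from 1 at large shape α scales as
1/√α (≈1.27×10⁻³ at α = 10⁶, k = 4).

**Distances and NJ.** Pairwise distances maximize the likelihood of the
shared (pairwise-deleted) columns under uniform rates, bounded on
[10⁻⁸, 10]; entries at the cap are flagged saturated. Neighbor joining
follows Saitou–Nei with two determinism rules: Q-criterion ties break by
the lexicographically smallest pair of cluster tags, and negative branch
lengths are clamped to zero with the deficit moved to the sister branch.

**Maximum likelihood.** Felsenstein pruning with gaps/X as missing data and
per-pattern scaling. Branch lengths are optimized coordinate-wise by
bounded Brent (tolerance 10⁻⁶); each 1-D optimization caches the edge's
"up" and "outer" partials so an evaluation costs one 20×20 product (valid
for reversible models, where the downward message reuses the same
`U @ P.T` form by detailed balance). The search starts from NJ on ML
distances (a deterministic stand-in for a tool-specific "default initial
tree") and hill-climbs over the full SPR neighborhood, accepting the best
neighbor until no move improves lnL by more than 10⁻⁴. Model selection
ranks {Dayhoff, WAG} × {uniform, Γ₄} by BIC (−2lnL + p·ln columns, p =
branches + 1 for α, ties to fewer parameters) on each candidate's NJ
topology, with α estimated by Brent on [0.05, 50].

**Bayesian sampler.** A deliberately minimal Metropolis–Hastings sampler:
uniform choice among NNI, branch-length multiplier (log-uniform window,
Hastings m), and α sliding window; priors are iid Exponential(10) branch
lengths, uniform topology, uniform α. Samples taken every `sample_every`
generations; the first `burnin_fraction` (default 0.25) of samples is
discarded; the majority-rule consensus carries bipartition posteriors. It
is seed-reproducible bit-for-bit. It makes no convergence claims and is not
intended to reproduce any particular Bayesian package's posteriors — only
the consensus/burn-in contract and qualitative concentration on clean data
are promised (tests check consensus = ML topology and posterior-mean tree
length against the ML estimate on easy data).

**Cross-algorithm support.** For each internal bipartition of a primary
tree, the number of the three trees (NJ, ML, consensus) containing it is
attached; counts of 2 and 3 serialize as `*` and `**` internal labels.
This is the support notion used throughout instead of bootstrap resampling,
which is deliberately out of scope.

## Species-tree collapse

Repeat classes come either from manual clade anchors (class = smallest
clade containing the anchors; clades must be disjoint and covering) or from
k-medoids (PAM, deterministic given seed) on patristic distances. Species
become count vectors over classes; degenerate units are excluded by
default.

The collapse finds the minimum-total-cost tree connecting the observed
profiles in the integer lattice where one step is a single-domain event:
tandem duplication (+1 to a present class), loss (−1), or innovation (+1 to
an absent class — duplication with divergence founding a new class). All
three events cost 1 by default; the edit distance between profiles is then
the L1 distance, verified against a breadth-first-search oracle and
property-tested as a metric. Candidate Steiner points are restricted to the
Hanan grid (cartesian product of observed per-class counts). Instances with
at most `max_exact_terminals` (default 6) distinct profiles are solved
exactly by the Dreyfus–Wagner dynamic program (the L1 metric lets each
subset's "walk" relaxation be a single closure step); larger instances use
a greedy nearest-terminal insertion and are flagged heuristic.

Among equally parsimonious trees the solver prefers ancestors that retain
more domain classes: edges touching class-poor profiles carry an ε penalty
(10⁻⁶-scale, never affecting the integer optimum). The rationale is
Dollo-flavored — re-founding a lost class requires an independent
innovation, the rarest event — and it resolves ties the way a manual
collapse of repeat profiles resolves them, e.g. choosing a b+c-bearing
ancestor over an empty-linker ancestor at equal cost. Multi-step edges are
expanded into chains of unit-step nodes (losses before gains, classes in
sorted order); every node whose profile matches no observed species is
flagged *predicted* and reported with its nearest observed species by edit
distance. Within-class subtree topology is not used as a constraint.

## Synthetic data generator

The generator emulates: an ultrametric species tree (supplied Newick, or a
crown-conditioned birth–death process accepted by rejection on the extant
leaf count); per-branch Gillespie domain events at per-domain rates
λ_dup, λ_loss, λ_innov (duplicates insert in tandem next to their parent
with a freshly drawn spacer; innovations found a new class); and sequence
evolution under WAG with three relative-rate tiers — flank 0.1, domain 1.0,
spacer 5.0 by default, the slow/informative/fast structure that motivates
repeat-based phylogenetics. The tier ordering flank < domain < spacer is
enforced unless explicitly overridden. A class-founding copy receives
0.1 × `burst_factor` extra expected substitutions per site at birth
(default burst_factor 3). Root domains are built from one ancestral
sequence: one founder per root class diverged by `root_class_divergence`
(default 0.75 substitutions/site), same-class copies nearly identical
(0.05), so root classes are separable by clustering. No quantitative rate
estimates exist for the real domains and spacers; the defaults are declared
values chosen to make recovery experiments non-trivial, not inferred ones.

Default study conditions: 8 species, speciation 1.0 / extinction 0 / crown
age 1.0, λ_dup 0.5, λ_loss 0.2, λ_innov 0.1, 50-residue domains, spacers
uniform on 10–40 residues, 60-residue flanks, one root class. The
generator does **not** emulate: indels inside domains (boundary calling is
exercised under substitution divergence only), gene conversion or concerted
evolution between repeats, horizontal transfer, codon-level effects, or
alignment errors from real low-complexity sequence. Passing tests therefore
demonstrate correctness of the algorithms under tree-like repeat evolution
with substitution-only divergence, not robustness to every artifact of real
linker sequences.

Everything is deterministic given the seed: the event log replays to the
exact leaf architectures, and emitted truth coordinates are verified
against the FASTA slices before writing.

## End-to-end recovery and its limits

The full pipeline (detect → align → NJ tree → k-medoids classes → collapse)
is exercised on an "easy" preset: a balanced 8-leaf species tree with all
branches 0.1 time units, root architecture of three classes × three copies,
λ_dup = λ_loss = 2.5 (fast domain turnover relative to sequence
divergence), λ_innov = 0, root class divergence 0.75. Under these
conditions detection recovers ≥90% of planted units and the inferred
class-count profiles equal the truth up to class-label permutation in most
species. The measured problem sizes: ~40–90 repeat units per dataset,
50-residue units, 8 species, 3 classes.

Recovering the full species *topology* from the collapse is a different
matter. Three integer class counts are a highly homoplastic character
system: sister species frequently end a replicate with identical profiles
(and merge into one terminal), parallel gains/losses shortcut the L1
geometry, and minimum Steiner trees over such profiles admit many
co-optima. A positive control with a clean character system (one unique
class gained per branch) is recovered exactly (RF = 0 at cost = number of
events), and feeding the collapse the *true* simulated profiles still
essentially never yields RF = 0 at 8 species / 3 classes. The honest
summary, which `scripts/acceptance.py` measures and reports, is that
profile *content* is recovered nearly perfectly while exact 8-taxon
topology recovery from 3-class counts alone is information-theoretically
out of reach; on real data the method's value lies in the coarse structure
and in the predicted intermediate profiles, with the repeat-sequence tree
supplying the finer signal.

## Degenerate inputs and edge cases

Empty linkers yield empty unit lists (not errors); linkers shorter than the
domain length warn and return nothing. Species with no (or only degenerate)
units keep explicit zero profiles — repeat-less linked proteins are a real
observed state. A collapse over species that all share one profile returns
a single-node tree. Saturated distances are capped and flagged rather than
propagated as infinities. Alignment rows that are entirely gaps are
rejected before likelihood computation; label mismatches between trees and
alignments report the asymmetric difference.
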