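# Methods

`synphylo` audits gene-tree reconstruction for duplicated genes produced by
polyploidy, using the three-genome cotton system (grape outgroup *Vv*,
cacao ortholog *Tc*, 3–5 collinear cotton paralogs *Gr*) as its model. This
note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what passing tests demonstrate.

## The expected tree and conformance

A collinear homolog group has a known history: the grape lineage split
first, then cacao, then a single polyploidy multiplied the cotton gene.
The *expected tree* is therefore `(Vv,(Tc,(Gr1,...,Grk)));` with the cotton
paralogs left as a polytomy — the duplication event is treated as
simultaneous, and nothing constrains the paralogs' internal order. A
reconstructed tree *conforms* when, after rooting on the grape leaf's
pendant edge (midpoint of that edge), every constraint clade of the
expected tree is present; with the default template this is exactly cotton
monophyly. Conformance is judged on the point-estimate topology: branch
lengths, child rotations and bootstrap supports are ignored (supports are
carried in the record for sensitivity analyses). A polytomy containing
only cotton genes counts as conforming. When a tree fails, the
`escape_pattern` is the set of cottons outside the maximal cotton-only
clade (plurality rule; ties resolved toward the lexicographically smaller
label set).

Multi-subgenome groups (e.g. AA/Dt/At/DD tetraploid material) require an
explicit user template, since nothing in the three-species data determines
how resolved their expected tree should be; the constraint set is then all
non-trivial clades of the expanded template.

## Tree inference

The five reconstruction methods are implemented from scratch and made
bit-deterministic by one tie-break rule: the lexicographically smallest
label (pair) wins, everywhere.

- **Distances** — p-distance with pairwise deletion of gap/ambiguous
  columns; Poisson `−ln(1−p)`; Jukes–Cantor `−(3/4)ln(1−4p/3)`. Entries
  outside the model domain (p ≥ 3/4 for JC) are flagged *saturated* and
  stored as NaN; `DistanceMatrix.capped()` replaces them with 1.5× the
  largest finite entry when a complete matrix is required.
- **NJ** — Saitou–Nei Q-criterion; negative branch lengths clamped to 0
  with a counter (`n_clamped_branches`), following the common convention.
- **UPGMA** — size-weighted average linkage, node height = distance/2.
- **ME** — NJ start, non-negative OLS branch lengths (NNLS on the
  path-indicator system), steepest-descent NNI on total tree length.
- **MP** — Fitch counting over bitmasks with gaps as missing data;
  exhaustive search over all unrooted topologies up to 7 taxa (co-optimal
  count reported, first tree in enumeration order returned), NJ+NNI above
  that.
- **ML** — nucleotide JC/HKY (equal frequencies), Felsenstein pruning with
  per-column rescaling; NJ start, bounded scalar search per branch (xatol
  1e-6), NNI accepted when lnL improves by > 1e-8.
- **Bootstrap** — columns resampled with replacement, codon alignments in
  codon-triplet blocks to preserve frame; support = % of replicates
  containing each point-estimate bipartition.

Protein-model ML (JTT) is not provided; nucleotide/codon ML stands in for
it, which matches how the main (CDS-based) audit is run.

## Codon models and selection inference

The selection module implements a Goldman–Yang rate matrix over the 61
sense codons with equal codon frequencies (1/61): single-nucleotide changes
have rate ∝ κ for transitions and ∝ ω for nonsynonymous changes, scaled so
branch lengths are expected substitutions per codon. Models: M0 (one ω),
M1 (nearly-neutral, ω₀ < 1 free and ω₁ = 1), M7 (beta-distributed ω,
K = 10 equal-probability classes, class ω at the bin median), M8 (beta plus
one class with ωₛ ≥ 1), and branch models (two-ratio with labelled
foreground edges; free ratio with one ω per branch).

Numerical choices:

- Likelihoods by pruning over codon states with per-pattern rescaling and
  site-pattern compression; mixtures combined by logsumexp.
- Optimisation with L-BFGS-B on log/logit-transformed parameters
  (ω ∈ [1e-4, 99], κ ∈ [0.1, 50], branch lengths ∈ [1e-6, 15]); branch
  lengths are re-estimated under each model unless explicitly fixed.
  Non-convergence flags the fit rather than raising.
- Trees are derooted before fitting: under a reversible model the two
  root-adjacent branches are confounded (in length and in ω), so a
  bifurcating root would be unidentifiable. Branch identities are
  normalised as unrooted splits so fits on different topologies of the
  same leaves are comparable.
- M8 is prone to a boundary local optimum when the truth is M7; in
  calibration work it is warm-started from the M7 optimum (`init_beta`,
  `init_p0≈1`, `init_omega_s≈1`).
- Positive-site identification is naive empirical Bayes (NEB): posterior of
  class k at site s ∝ p_k L_s(ω_k); BEB (integration over parameter
  priors) is out of scope, and all reports state the method used. The
  "M1" naming is ambiguous in parts of the literature; here it is the
  nearly-neutral two-class model, and the M0-vs-M1 test (df = 1) is
  reported with the caveat that the pair is not strictly nested.

## The synthetic-data generator

The generator emulates the statistical structure of the real collinear
dataset so every pipeline stage is testable without genome downloads. Per
group: cotton paralog count drawn from the mixture P(3,4,5) =
(0.814, 0.165, 0.021); the true tree is the expected topology with branch
roles (defaults, substitutions/codon): grape stem 0.20, shared Malvales
stem 0.15, cacao stem 0.30, cotton stem 0.10, cotton tips 0.20. The
defaults satisfy `cacao_stem = cotton_stem + cotton_tip`, i.e. a strict
molecular clock holds when no rate elevation is applied, so rate effects
are attributable to the multipliers alone. At these depths the cacao–grape
synonymous distance is ≈1.3–1.5, matching deep eudicot divergences while
staying below Nei–Gojobori saturation.

Each cotton tip receives an independent lognormal rate multiplier
(defaults: mean 1.5, sd 0.5; lognormal for positivity and the right skew
implied by the asymmetric observed R_Max/R_Min). The closed form
`multiplier_mean_for_elevation(target)` inverts the tree geometry to give
the mean multiplier producing a chosen mean R_A — a 15% target needs mean
≈1.49, and the default 1.5 sits inside the observed 9–18% band. Sequences
evolve by sampling the Goldman–Yang process (root uniform over sense
codons), so simulated CDS never contain in-frame stops and, with the
default indel rate of 0, are already exactly aligned — alignment-stage
error can be toggled off. A per-site-ω variant
(`evolve_heterogeneous_sequences`) generates beta site-model data for LRT
calibration.

What the generator does **not** emulate: indel/domain turnover and
alignment ambiguity (unless the optional deletion rate is enabled), codon
usage bias (frequencies are uniform), gene conversion between paralogs,
tandem duplication, and saturation-level divergence. Passing tests
therefore show the machinery is correct and the mechanisms are
directionally reproducible — not that real-genome non-conformance rates
are recovered quantitatively.

## Relative-rate statistics

Pairwise Ka/Ks uses the original Nei–Gojobori (1986) counting: per-codon
synonymous site fractions averaged over the two sequences,
multi-difference codons averaged over all minimal substitution pathways
with equal weights (stop-containing pathways excluded), Jukes–Cantor
correction, saturation flagged at p ≥ 3/4, gapped/ambiguous codons dropped
pairwise. Known estimator limits, visible in the tests: with transition
bias (κ > 1) or at high divergence the estimated dN/dS sits a few percent
below truth even when ω = 1 (NG counts changes-to-stop as possible
nonsynonymous events that the process never realises, and the JC
correction error differs between the dN and dS scales). The ω = 1 oracle
check is therefore run at κ = 1 and total divergence 0.1, where the bias
is negligible.

Per group, against the grape outgroup, with `TcVv = Ks(cacao, grape)` and
`GrᵢVv = Ks(cottonᵢ, grape)`:

    R_A   = [mean(GrᵢVv) − TcVv] / TcVv
    R_Max = [max(GrᵢVv)  − TcVv] / TcVv
    R_Min = [min(GrᵢVv)  − TcVv] / TcVv

The Ks-elevation test is Welch's unequal-variance t-test, one-sided
(cotton > cacao) with the two-sided p reported alongside, since the
sidedness convention varies between studies. Saturated pairs are excluded
from ratios and tests but counted.

## Experiment scenarios

Two experiments run in dedicated branch-length scenarios rather than the
generator defaults, because topology distortion by rate heterogeneity is
a short-internal-branch phenomenon — with the default cotton stem of 0.10
every method recovers the topology at any plausible rate variance, and
there is no mechanism to observe:

- **Variance trend** (stem 0.05, tips 0.25): the multiplier distribution is
  widened on the log scale (σ ∈ {0, 0.3, 0.6, 0.9, 1.2}) while its
  *median* is held at 1. Holding the median rather than the mean matters:
  a mean-fixed lognormal has a median that falls as the spread grows, so
  typical tips shorten and the two effects cancel. With the median fixed,
  non-conformance of NJ trees rises monotonically with σ (Spearman ρ > 0
  across seeds).
- **Misplacement / selection over-assessment** (stem 0.02, five paralogs,
  tip multipliers 8/3/1/1/1, 500 codons): replicates are kept only when
  the NJ tree actually misplaces a paralog (non-conforming), then the
  free-ratio model is fitted on both topologies. The distorted topology
  must absorb the misplaced paralog's history in artifactual short
  branches whose ω estimates are unstable upward, so it flags at least as
  many ω > 1 branches as the expected topology in nearly all replicates
  and strictly more in a clear plurality — the over-assessment direction.
  Replicates where both topologies flag zero branches tie, which is why
  the assertion is "≥ in a majority, and strictly more often more" rather
  than a strict increase everywhere.

The Ks-test type-I calibration draws the cotton and cacao samples from
*disjoint* group sets: within one group both distances share the grape
lineage, and that positive correlation would make a two-sample test
conservative; with independent samples the empirical rejection rate at
α = 0.05 sits in the nominal band.

## Pipeline and reporting conventions

Per-group isolation: one group's failure (missing sequence, alignment or
inference error) is recorded in the manifest and the group is dropped from
aggregates; the run never aborts. All percentage formatting goes through
one rounding function (half-up; tables at 1 decimal, group-agreement
classes printed adaptively: 2 decimals below 1%, 1 decimal below 10%,
integers above). Method-subset averages are taken over the *rounded*
per-method percentages, matching how such tables are usually summarised.
In simulate mode with no indels the generator's output is already an exact
alignment and the aligner is skipped by default (`skip_alignment=None`
auto-detects this); file-mode input is always aligned.

Problem sizes used by the test suite and acceptance script (20 replicates
for recovery checks, 100 groups per variance level, 60–100 LRT calibration
replicates, 200–500 codons) were chosen as the smallest sizes at which the
statistical assertions are stable across seeds.

## Known limitations

- Progressive alignment is a single pass (guide tree + profile NW); no
  iterative refinement or trimming. The two presets emulate common
  aligner defaults but are not the external tools.
- ML tree search is NNI-only from an NJ start; no SPR/TBR, no GTR+Γ, no
  protein matrices.
- NG86 Ka/Ks carries the biases described above; the codon-model route
  (M0) is the likelihood-based alternative within the package.
- BEB, M2a/M3, clade and branch-site models are not implemented.
- The free-ratio model on short branches produces boundary ω estimates
  (ω → 99 when a branch shows nonsynonymous but no synonymous changes);
  reports count them as ω > 1 flags, as the corresponding field tools do.
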