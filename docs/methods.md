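# Methods

This note documents the models and procedures phylodiscord implements, the
defaults it ships with and why, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter when reading its
output.

## Likelihood engine

**Model.** Time-reversible substitution models: a symmetric exchangeability
matrix S and equilibrium frequencies π give Q = S·diag(π), diagonal set so
rows sum to zero, rescaled so Σ_i π_i(−Q_ii) = 1 (branch lengths in
expected substitutions per site). Amino-acid options are Poisson (equal
rates), WAG and LG with their published frequencies; the nucleotide model
is an equal-exchangeability (F81-style) matrix with free frequencies.
Transition matrices come from the symmetric eigendecomposition of
diag(√π)·Q·diag(1/√π), which is numerically stable and makes every P(t)
exactly detailed-balanced; P(0) is special-cased to the exact identity so
that conflicting states across a zero-length path produce likelihood 0
(reported as −inf with a warning) rather than a rounding artifact.

**Rate heterogeneity.** Discrete gamma with equal-probability categories
represented by category *means* (the dominant convention in ML
phylogenetics), 4 categories by default, mean rate normalized to exactly 1.
The shape α is configuration (default 0.5, a typical protein-alignment
value); `estimate_gamma_shape` offers a bounded 1-D search on [0.05, 50]
when it must be fitted.

**Pruning.** Felsenstein pruning with per-node, per-category rescaling of
partial likelihoods (log-space scalers), so alignments of arbitrary length
cannot underflow. Gaps and ambiguity codes contribute a partial vector of
ones over their compatible state sets — fully missing data. Trees with a
bifurcating root are internally derooted (the two root edges merged), which
leaves the likelihood unchanged under reversibility and makes every branch
parameter identifiable.

**Branch-length optimization.** Round-robin bounded scalar optimization
(Brent on [1e-8, 10]) edge by edge. Each pass refreshes downward partials
and upward complement partials once, then optimizes the edges against them;
because the complements are refreshed per pass rather than per edge, the
one-dimensional objectives are exact at the first edge and slightly stale
afterwards — the pass-level safeguard (revert and stop if a pass ever
lowers the true total log-likelihood) makes the procedure monotone
regardless. Function defaults iterate to an improvement below 1e-6 nats
(50-pass cap); the pipeline uses 0.1 nats, the convergence scale common in
ML tree software, because downstream contrasts are insensitive to
branch-length error at that scale and it is several-fold faster.

## Topology contrast

ΔSLS is fixed as mt − nuc: positive values favor the mt-topology. The
strong-site threshold is a parameter defaulting to 0.5 with *strict*
inequalities at the boundary. ΔCLS is the plain sum of ΔSLS over a group's
sites and average ΔCLS the per-site mean, so marker-level values are
exactly additive to the matrix level. The SH test is the RELL form:
site-level log-likelihood vectors are resampled with replacement, each
tree's resampled totals are centered on their own mean, and the one-sided
p-value is the fraction of resamples whose centered deficit to the best
tree reaches the observed deficit; the best tree gets p = 1 by
construction, and adding any per-site constant to all trees cancels.

## Concordance factors

An internal branch defines four subtrees. A quartet (one leaf per subtree)
finds a site decisive when all four states are unambiguous and form a 2+2
pattern; the pairing picks one of the three resolutions, so defined sCF
values close to 100 exactly. Quartets default to 100 per branch, drawn
uniformly with replacement; the generator is seeded from the sorted leaf
labels around the branch, so results are independent of taxon order and of
which other branches are evaluated, and an exhaustive mode enumerates all
quartets for small problems. Sites with gaps/ambiguities in the quartet are
indecisive; a marker with no decisive site in any quartet is *missing*, not
zero. For gCF, a gene tree is decisive for a branch when it carries at
least one taxon from each subtree and concordant when one of its
bipartitions, restricted to its taxa, separates the two near groups from
the two far ones; unresolved (star) trees are decisive but never
concordant, which is conservative and flagged by the decisive-tree count.
The 1/3 line (33.3%) is exposed as the plurality threshold: above it a
resolution beats both alternatives.

## Composition statistics

AT skew (A−T)/(A+T), GC skew (G−C)/(G+C), G+T content, the frequency of
codons with G or T at *both* first and second positions ("GT-rich codons";
the disjunctive either-position reading is available behind a flag — the
conjunctive reading was chosen because it is distinct from plain positional
G+T content), and G+T at third positions of four-fold degenerate codons.
Four-fold families are derived from the genetic-code tables themselves
(Biopython's tables 1 and 5), never hard-coded, so code-specific
reassignments propagate automatically. Ambiguous bases and gaps are
excluded from every numerator and denominator; empty denominators yield
missing values. Annotation coordinates are 1-based inclusive at file
boundaries (0-based half-open internally); unassigned regions are the
complement of the union of all features regardless of strand, and their
G+T content is scored on the plus strand as given.

## Group tests

Kruskal–Wallis uses the tie-corrected rank form with the chi-square
approximation at k−1 df regardless of sample size (the standard choice at
these group sizes). Dunn's post-hoc z uses pooled mean ranks with the
tie-corrected variance and two-sided normal p-values, Bonferroni-adjusted
over all k(k−1)/2 pairs; singleton groups are computed but flagged
low-power. The contact comparison is Student's pooled-variance t by
default — Welch is available — two-sided, with group summaries and missing
markers dropped (and counted) rather than zero-filled.

## Synthetic studies

The generator is the package's study design, not a convenience fixture.
Defaults: four clades of two taxa each (eight taxa — enough for two leaves
per subtree around the focal branch while keeping likelihood work small);
the 13 organellar OXPHOS markers at typical bivalve protein lengths with
the NADH genes split into minus-strand (nadh1,2,6) and plus-strand
(nadh3,4,4l,5) groups; 25 contact and 30 non-contact nuclear markers of
200 aa (matching the scale of the real contact/non-contact comparison);
Poisson+Γ(α=0.5) amino-acid model; branch lengths exponential with mean
0.1 and a 0.05 focal branch so the topology question is nontrivial.
Everything simulates on the mt-topology; non-contact markers get a tenfold
weaker focal branch (signal 0.1), which plants the contact > non-contact
sCF effect, and their gene trees show the alternative resolution, which
makes gCF informative. The compositional shift moves 0.1 of equilibrium
mass onto G+T (nucleotides) or onto the GT-rich-codon residue set FLVGCW
(amino acids) on the shifted clade's subtree only — a nonstationary,
mechanism-like change, not post-hoc data editing; the effect size is a
design choice (the source observations are boxplot-scale only). CDS are
independent stop-free codons from position-specific base frequencies
(AT-skewed, G+T ≈ 0.58) — composition, not selection, is the target — and
mock genomes are i.i.d. sequence with a fixed six-feature annotation
leaving ~15% unassigned.

What the generator does **not** emulate: alignment error and masking,
paralogy, heteroplasmy, rate variation across lineages, codon-level
selection, and real mitogenome architecture. Passing tests therefore show
the *analysis chain* recovers planted effects of realistic size and shape;
they do not certify behavior under assembly artifacts or model violation.

## Problem sizes and determinism

The shipped checks run the power analyses at 50 partitions × 200 aa sites
with 20 seeded replicates (topology contrast, SH power) and 20 seeds of the
default study (composition shift, contact effect) — sizes at which the
planted effects are comfortably detectable while a full run stays in the
minutes range. All randomness flows from explicit integer seeds through
`numpy.random.Generator`; per-marker and per-branch streams are derived by
hashing the seed with a role tag, so adding or removing one marker never
shifts another's data. Reports format floats at 10 significant digits and
missing values as `NA`; reruns with one config are byte-identical.

## Known limitations

- No topology search: trees are inputs; only branch lengths are fitted.
- The round-robin optimizer can stop at the pass-level tolerance slightly
  short of the joint optimum on near-flat likelihood surfaces.
- The nucleotide model family is frequency-only (no GTR exchangeability
  fitting); amino-acid models are the empirical matrices as published.
- Dunn's test has no second independent implementation in the dependency
  set; it is verified through the k = 2 identity z² = H against an
  external Kruskal–Wallis implementation plus first-principles rank
  checks.
- The SH test implements the classic RELL form only (no AU or KH test).
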