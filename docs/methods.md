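# Methods

## Efficiency model

Each accession is scored by the output-oriented radial measure Θ ≥ 1: the
largest uniform expansion of all its output traits achievable by a convex
combination of peer accessions that uses no more of any input trait. The
BCC (variable returns to scale) form imposes the convexity constraint
Σλ = 1 on the peer weights; the CCR (constant returns) form drops it, so
the frontier becomes the cone of observed input–output rays and every
CCR-efficient accession is automatically BCC-efficient. The package reports
Θ and the convenience value 1/Θ ∈ (0, 1].

Note on naming: some of the literature calls this radial-output-expansion
program "output-oriented" and some "input-oriented"; we follow the
equations, not the label — Θ = 1 is efficient, Θ > 1 dominated.

### Two-phase solution and Pareto-Koopmans classification

A radial optimum can hide residual input excess or output shortfall:
Θ = 1 does not by itself mean nothing can be improved, and the slacks
returned at an arbitrary optimal vertex are not unique. We therefore solve
a second LP with Θ fixed at its optimum that maximizes the total slack
Σs_i + Σs_j, and classify an accession as fully (Pareto-Koopmans)
efficient only if Θ = 1 *and* all phase-2 slacks vanish, each within a
configurable tolerance (default 1e-6, matched to LP solver precision).
Θ = 1 with positive maximal slack is weak efficiency.

### Multiplier form and the sign convention

The weight-space (multiplier) dual is solved for every accession and
cross-checked against the envelopment Θ. Deriving the exact LP dual of the
envelopment problem gives, for the VRS case,

    min  Σ ν_i x_ia − u
    s.t. Σ μ_j y_ja = 1
         Σ ν_i x_ia' − Σ μ_j y_ja' − u ≥ 0   for every accession a'
         ν, μ ≥ 0, u free.

The accession constraints must bound the free intercept u from above;
written with the opposite sense the program is unbounded (u → ∞ drives the
objective to −∞). Printed formulations of this model sometimes flip that
sign; the implementation keeps the duality-consistent form, which is forced
by the requirement that the multiplier objective equal the envelopment Θ
(verified to 1e-6 on every solve by default).

All LPs are solved with HiGHS through `scipy.optimize.linprog`. If the
phase-2 LP is reported infeasible at the tolerance edge, the phase-1 slacks
are kept and the status recorded; this fallback has not been observed in
practice.

## PCA reduction

When m + n approaches or exceeds s, the multiplier LP has enough free
weights to declare almost every accession efficient. Each trait block
(inputs and outputs separately, per condition) is therefore reduced by PCA:
eigendecomposition of the covariance matrix (default) or correlation
matrix (option, for incommensurate units), components ordered by
eigenvalue, and k selected as the smallest number of components whose
cumulative explained variance ζ reaches the threshold (0.85/0.90/0.95 in
the standard protocol).

Numerical conventions: eigenvector signs are fixed by making the
largest-magnitude coefficient positive; ties between eigenvalues are broken
by a stable sort preserving trait order; both choices are purely for
cross-platform determinism.

### Scores fed to the transformed LPs are uncentered

The transformed envelopment problem acts on score matrices X_k = L_X X,
Y_k = L_Y Y (loadings as rows), with slacks kept in the original trait
space (premultiplied by the loadings) and the implied original-trait
weights V·L_X, U·L_Y constrained nonnegative in the multiplier form. The
eigenvectors come from the *centered* covariance, but the projections are
applied without subtracting the mean: centering the outputs would change
the radial expansion target (Θ(y − ȳ) + ȳ ≠ Θy) and destroy the defining
property that retaining all components is a pure change of coordinates
reproducing the raw-data scores. The general-purpose `transform` function
defaults to the conventional centered scores; the DEA path passes
`center=False`.

Reduced-dimension score matrices are sign-mixed, and for weakly structured
(near-uncorrelated) data the transformed program can be unbounded: the
solver reports this per accession with a recommendation to raise the
variance threshold rather than silently shifting the data, since any
translation changes the VRS frontier. In the intended regime — correlated
trait blocks — this does not arise. PCA is fit per condition (trait
covariance structure is itself condition-dependent).

## Rank statistics

Kendall τ uses the tau-a convention throughout: (concordant − discordant) /
s(s−1)/2, tied pairs counted in the denominator only. This matters because
efficiency vectors are tie-rich (every fully efficient accession shares
Θ = 1): with t tied pairs the attainable maximum of τ is
1 − t/(s(s−1)/2) < 1 even for identical vectors. Derived statistics are
differences of τ values over the same accession set, so the ceiling
cancels; absolute τ values printed in reports should be read with it in
mind. tau-b (tie-rescaled) is available as an option but is used nowhere by
default. Efficiency vectors are compared as raw Θ values (τ is invariant to
monotone transforms, so no tie-breaking pre-ranking is applied), snapped to
10 decimals so that ~1e-12 LP jitter cannot split exact ties.

Significance is assessed by a seeded Monte-Carlo permutation test
(two-sided, add-one estimator, default 10,000 permutations; the protocol
runner uses 2,000) with a normal-approximation option for speed. No
multiple-testing correction is applied across traits by default;
Benjamini–Hochberg can be applied downstream by the user.

Trait influence refits the *input* PCA on the reduced trait set and leaves
the output side untouched; only input traits are removed (removing output
traits answers a different question and is out of scope). Valency is
symmetric in the two conditions by construction, Φ ∈ [0, 2], and exactly
zero when the two conditions are identical.

## Synthetic data

The generator emulates a natural-variation phenotyping design (defaults:
23 accessions, 10 input and 8 output traits, 3 conditions, matching the
scale of the motivating study design) with known ground truth:

- a latent resource axis u per accession; frontier accessions sit on the
  strictly concave, strictly increasing curve g(u) = 3·u^0.6 (diminishing
  returns), u drawn in [1, 10] with a minimum spacing of 0.2;
- every trait is a positive per-trait multiple of u (inputs) or g(u)
  (outputs), in blocks of one base trait plus `trait_redundancy` noisy
  duplicates (duplicates share the base trait's noise plus a half-strength
  independent component, giving tight within-block correlation);
- dominated accessions are frontier points with all inputs multiplied and
  all outputs divided by an inefficiency factor f > 1, which forces
  Θ ≥ f by construction;
- noise is multiplicative lognormal (relative sd, default 0.05),
  preserving positivity;
- further conditions apply seeded lognormal perturbations of stated
  relative strength (defaults 0, 0.15, 0.30) to every trait value.

By units invariance of DEA, the zero-noise instance is equivalent to the
1-D curve, so the planted accessions are *exactly* the fully efficient set
— this is the ground truth used by the recovery checks (factors ≥ 1.5,
noise 0). With noise the frontier blurs and recovery is no longer claimed.

For valency ground truth the generator can designate one input trait: its
values are reassigned in reverse rank order in every non-base condition
(a random permutation can by chance leave the ranking nearly intact), and
the trait is rescaled by `scramble_boost` (default 5) in *all* conditions
so it carries the dominant input variance — a pure unit change that leaves
raw DEA untouched but makes the planted discordance attributable to the
designated trait after reduction. In the targeted family (zero noise, the
other traits exact duplicates of each other, threshold 1.0) every
non-designated trait has Φ = 0 exactly, because removing a trait that is an
exact positive multiple of another is removing a redundant LP constraint.

### What the generator does not emulate

Real metabolic panels are not one latent dimension plus noise: they contain
several partially independent biochemical axes, condition-specific trait
covariance rewiring, and measurement error that is neither lognormal nor
independent across traits. Passing the planted-recovery and valency checks
therefore demonstrates correctness of the algorithms under controlled
ground truth, not statistical power on real phenotyping data.

## Problem sizes and determinism

Verification runs use instances of up to 15 accessions and 4 + 4 traits
(hundreds of random instances), 50 planted scenarios, 1,000 random vector
pairs for the rank statistics, and one study-scale protocol run
(23 × (10 + 8) × 3 conditions, threshold 0.85, 500 permutations) — sizes at
which the geometric oracles are exact and the whole suite completes in a
few minutes on one core. All randomness flows from explicit seeds;
re-running the protocol with an identical configuration byte-reproduces
every report file.

## Known limitations

- Reference sets (λ supports) are reported as the solver's vertex solution;
  no uniqueness or maximal-reference-set analysis is attempted, since no
  downstream statistic consumes them.
- No efficiency bootstrap / confidence intervals, super-efficiency,
  cross-efficiency or Malmquist extensions.
- Raw trait values must be strictly positive; exact zeros are replaced only
  on explicit request (`replace_zeros`), never silently.
- Printed efficiency values of 1.000 can mask weak efficiency; the
  `fully_efficient` flag (phase-2 slack test) is the authoritative
  classification.
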