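# Methods

## Data model and conventions

One screen row is an siRNA oligo: identifier, guide-strand sequence
(5′→3′), intended target gene (empty = non-targeting), library and screen
labels, and a cell-count phenotype expressed as a z-score against the
screening background. Sequences are canonicalized to the DNA alphabet
(U→T, uppercased) so seeds hash identically across vendors; positions are
1-based from the guide 5′ end; the seed is positions 2–8 inclusive. More
negative z means fewer cells (more growth-restricting). Oligo lengths of
19–21 nt are accepted side by side; any per-position statistic uses only
the oligos long enough to cover that position. Input sequences are treated
as guide strands — vendors do not always state which strand they report,
and this assumption is the user's responsibility to check.

Position 1 is excluded from profiles and from the default model: library
design rules constrain it so strongly that not all nucleotides are
adequately observed there. A flag (`include_position_1`, or passing
explicit `positions`) overrides this.

## Positional profiles and shifts

`build_positional_profile` computes, per (nucleotide, position) cell, the
mean z over all oligos with that residue, its support count, and a CI
half-width (nonparametric bootstrap with 1000 seeded resamples by default;
normal-theory 1.96·SE or none as cheaper options). Cells with support
below `min_count` are NaN, never zero. By construction the count-weighted
cell mean at a position equals the global mean of oligos covering it; this
conservation identity is exact and is asserted in tests.

`conditional_shift` contrasts the subset with a given residue against its
complement (two-sided Welch t-test; the shift itself is the difference of
means). Seed groups are summarized per screen; with two screens each group
also carries its additive contribution to the Pearson correlation of
per-seed means, so reproducible seed effects can be ranked.

Profiles are compared as flattened vectors, mean-centered per profile
(removing per-screen offsets and putting z-valued phenotype profiles and
frequency-valued design-bias profiles on a comparable shape scale), under
Euclidean distance; no canonical metric exists for this comparison, so the
simplest one is used and documented. The PCoA embedding is classical
metric scaling — eigendecomposition of the double-centered squared-distance
matrix — delegated to scikit-bio; an independent double-centering oracle in
the test suite cross-checks coordinates and eigenvalues.

## The cell-count predictor

**Positional linear model.** OLS of z on per-position nucleotide
indicators under sum-to-zero contrasts: each position contributes weights
for its present nucleotides constrained to sum to zero, estimated via a
reference-nucleotide contrast encoding and solved with `numpy.linalg.lstsq`.
The sum-to-zero parameterization makes weights directly comparable to the
positional profile and makes predictions invariant to the choice of
reference (asserted to 1e-8). A nucleotide never observed at a position is
unidentifiable; its weight is fixed at 0 and reported in
`model.degenerate`. Prediction is intercept + sum of the weights matching
the query sequence; positions beyond a shorter oligo contribute nothing.

**Seed model.** The mean training z per 7-mer seed, kept for groups with
at least `min_count = 2` members (no threshold is canonical; two is the
smallest count for which a group mean differs from memorizing one oligo).
Unseen seeds predict 0 — the screen-background mean on the z scale — with
an explicit `seen` flag, i.e. the model abstains rather than extrapolates.

**Combination.** ẑ = α·ẑ_lin + (1−α)·ẑ_seed with α scanned over a 0–100%
grid in 5% steps against held-out data, maximizing Pearson r. Exact ties
break toward the smaller α. If one submodel emits constant predictions,
every interior α is a rescaling of the other model and correlation is flat
across the grid up to float jitter; the scan then short-circuits to the
informative model's endpoint (α = 1 for a degenerate seed model, α = 0 for
a degenerate linear model). Degenerate validation sets (constant observed
values, or both submodels constant) are errors.

Accuracy is defined as 100·(Pearson r between observed and predicted z).
The 90/10 train/test split is uniform over oligos (not stratified by gene)
and seed-reproducible.

## Oligo design

Sampling is position-independent with per-position probabilities
∝ background·exp(−w/T) (growth-restricting), ∝ background·exp(+w/T)
(non-growth-restricting) or ∝ background (random-background). The
exponential tilt is the minimal kernel with the right limits: T→∞
recovers pure background sampling in every class, T→0 concentrates on the
per-position argmin/argmax weight. The default temperature 0.05 is on the
scale of a large fitted weight, giving strong but not deterministic
enrichment. A `neutral` option tilts by exp(−|w|/T) for designs meant to
leave cell counts unchanged rather than to increase them; the default
non-growth-restricting class tilts toward cell-count-increasing residues,
matching how such validation oligos behave (high observed cell counts).
Sequences whose full sequence or seed is in the exclusion set — or that
were already emitted in the same call — are rejected and resampled, up to
1000 attempts per oligo before a hard error. On-target screening of
designed oligos against a transcriptome is out of scope; exclusion sets
are the supported mechanism for novelty constraints.

## Dose-response analysis

The 4PL curve f(x) = c + (d−c)/(1+(x/e)^b) is fitted by nonlinear least
squares over (b, c, d, log e): the log parameterization keeps e positive
and makes the fit exactly equivariant under unit rescaling (concentrations
scaled by k scale e by k and leave b, c, d unchanged). Self-starting
values: c₀/d₀ from the response range, log e₀ the median log
concentration, b₀ from the mid-range slope of y against log x via
df/dlog x|ₓ₌ₑ = −b(d−c)/4. Up to five perturbed restarts (fixed internal
seed) run when the first attempt fails; a fit that never converges is
returned flagged with diagnostics rather than raised. Fits with b < 0 are
canonicalized by (b, c, d) → (−b, d, c), an exact identity of the curve,
so c is always the lower asymptote when the response falls with dose.
f(e) = (c+d)/2 holds by construction and is asserted on every converged
fit. The standard error of e comes from the Jacobian at the optimum
(delta method on log e). Zero-concentration control wells are excluded
from the fit — the log-logistic curve is undefined at x = 0 — and serve
only as a plausibility check on d. At least 5 distinct positive
concentrations and non-constant responses are required.

Competition shifts are summarized as fold changes e(condition)/e(reference)
and, across replicated fits, compared on log e (fold change is the natural
effect scale) by one-way ANOVA followed by Tukey HSD (statsmodels,
studentized-range distribution) at α = 0.05. Curves are fitted per
replicate, and the per-replicate e estimates are the ANOVA observations;
each condition needs at least two replicates.

## Synthetic data: what it emulates, and what it does not

`generate_screen` draws z_i = Σ_p w[p, nt_i(p)] + s[seed_i] + g[gene_i] + ε_i
with ε ~ N(0, noise_sd²), returning the planted truth alongside. Draw
order is fixed (background, sequences, positional weights, seed effects,
gene effects, noise), so output is bit-reproducible per seed.

Key defaults, chosen once as the package's study conditions:

- `n_oligos = 40 000`, `oligo_length = 19`, `noise_sd = 1` (a z-scored
  readout).
- **Library background**: per-position permutations of
  (0.50, 0.30, 0.12, 0.08). Commercial libraries are strongly non-uniform,
  and — critically for seed modeling — their 7-mer seed usage is
  concentrated, with seed families of roughly ten oligos in genome-wide
  libraries. A uniform i.i.d. library would spread 40 000 oligos over all
  16 384 seeds (≈2.4 per seed), leaving seed-group means dominated by
  estimation noise, unlike any real screen. The biased background yields a
  mean seed-group size of ≈9.
- **Positional weights**: N(0, 0.25²) at positions 2..L, centered to
  sum-to-zero per position (the identifiable parameterization); position 1
  carries no planted effect, mirroring its exclusion from analysis.
- **Seed effects**: by default every seed realized in the library is
  active, with effects scaled so their variance over oligos equals the
  realized positional variance ("match_positional") — the balanced regime
  in which neither predictor dominates. A numeric `seed_effect_sd` and a
  restricted `n_active_seeds` are available instead.
- **Gene structure**: consecutive blocks of 4 oligos per gene with
  N(0, 0.2²) on-target effects — reproducible but deliberately weak,
  reflecting the poor gene-level phenotype agreement of distinct siRNAs
  in real screens. Neither predictor uses gene labels, so this acts as a
  small extra noise floor.

Under these conditions the held-out combined-model accuracy lands near
65% with single models near 50%, and the combination optimum at 50–55% —
the regime reported for real genome-wide screens — and these values are
measured by the acceptance script, not assumed.

What the generator does **not** emulate: correlated oligo design within a
vendor library (sequences are i.i.d. given the background), hybridization
biology (seed effects are arbitrary labels, not binding predictions),
plate/batch structure, non-Gaussian phenotype tails, and any infection-type
phenotype. Passing tests on this generator therefore demonstrate correct
and well-calibrated inference under the stated additive model, not that
real screens follow that model.

`generate_dose_response` produces replicate titrations
y = f(x)·(1 + N(0, noise_cv²)) clipped at zero — multiplicative noise,
appropriate for cell-count readouts spanning orders of magnitude.

## Problem sizes and numerical tolerances

Simulation-based checks use 40 000 oligos for the combination scan,
20 000 for noisy weight recovery (5 seeds), 5000 for exact noiseless
recovery, and 200 repeats for ANOVA type-I calibration (3 conditions × 5
replicate 4PL fits each) — sizes at which every expected property holds
with wide margins while a full run stays within a coffee break. Exact
identities (conservation, sum-to-zero, PCoA round-trip, OLS vs normal
equations, noiseless recovery) are asserted at 1e-8 or tighter;
statistical quantities at tolerances implied by their sampling variance.

## Known limitations

- The positional model is strictly additive in single positions; no
  dinucleotide or interaction terms.
- The seed model memorizes group means; it cannot generalize to unseen
  seeds (by design it abstains with prediction 0).
- Tukey HSD assumes approximately normal, homoskedastic log-ED50
  estimates across conditions; heavily unbalanced or tiny replicate sets
  will be miscalibrated.
- The designer does not verify absence of genomic targets; exclusion sets
  only enforce novelty against supplied sequence collections.
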