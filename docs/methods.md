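# Methods

This note documents the models behind each analysis stage, the defaults
that matter, what the synthetic-data generators do and do not emulate, and
the numerical conventions adopted where the underlying methods left a
choice open.

## Peak tables, CSP and the significance filter

Input is one assignment table per ligation state: (residue, atom ∈ {H, N,
C}, shift in ppm, optional linewidth in ppm). Two plain-text dialects are
read: a delimited table (`[state,]residue,atom,shift_ppm[,linewidth_ppm]`)
and a peak-list export shape (`F100N-H  119.8  8.21`, one amide per line
expanding to an N and an H entry). Residue matching is by integer residue
number, 1-based; insertion codes are out of scope. Alignment keeps only
residues carrying both H and N in *every* state — the treatment of
resonances broadened out of individual states.

Combined perturbations use Δδ = sqrt(ΔδH² + (α·ΔδN)²) with α = 0.154, the
conventional compensation for the larger ¹⁵N ppm range. Signed per-nucleus
differences are retained everywhere; the combined value is only a
magnitude.

The significance filter retains a residue when its shift change between
two states strictly exceeds ½Δν(A) + ½Δν(B) in the relevant dimension
(linewidths in ppm; a dialect option converts Hz via the spectrometer
frequency). Strictness at the boundary is deliberate: a change equal to
the pooled half-linewidths is not distinguishable from line overlap.
Defaults when linewidths are missing: 0.01 ppm (H), 0.05 ppm (N),
logged on use. Because the source experiments do not pin down which state
pair defines the filter, the caller chooses a pair, with a
max-over-all-pairs convenience mode (the default inside
`concise_analysis`); likewise both a per-nucleus ("any-dimension",
default) and a stricter "both-dimensions" mode exist rather than guessing
a single intent.

## CONCISE

For each retained residue the per-state vectors (ΔδH, α·ΔδN), centered
across states, are decomposed by PCA. *Linearity* is λ₁/(λ₁+λ₂), the PC1
variance fraction; residues with linearity ≥ 0.85 (default; the threshold
is not standardized in the literature, so it is a flag) and, optionally,
endpoint CSP ≥ `csp_min` are pooled. Per-residue PC1 scores are
standardized (mean 0, variance 1 across states) before pooling so that
response amplitude does not weight the pool; each state's density is then
the moment-fit normal (mean, sd) over residues. With fewer than three
retained residues the density is refused rather than fitted.

PC1 sign is arbitrary and the orientation convention is consequential.
The default makes the largest-magnitude loading positive ("loading"
convention): a residue whose response runs *against* the consensus keeps
inverted scores, so uncoordinated responses show up as broader densities —
which is precisely the diagnostic the width carries. The alternative
("endpoint") convention forces the last declared state non-negative; it
normalises every residue onto the declared equilibrium direction, which
stabilises the mean positions but silently hides anti-correlated
responders, so it is not the default. Under a global sign flip of all
input data the endpoint convention is pointwise invariant and the loading
convention flips every score coherently (a mirrored axis); widths and
ordering structure are unaffected either way.

## CHESCA

The response matrix holds, per residue, the signed per-state deviations
from the across-state mean for both nuclei (N scaled by α), concatenated
into a length-2S vector (default mode; H-only and N-only modes exist for
sensitivity checks). Correlations are Pearson; |R_ij| is compared to the
cutoff so that anti-correlated linear responders — two ends of the same
two-state equilibrium — count as networked. Ties at the cutoff are
excluded (strict inequality).

Clustering is complete-linkage agglomeration on distance 1 − |R_ij| cut at
1 − R_cutoff (display cutoff 0.98 by default): a reported cluster is a set
in which *every* pair exceeds the cutoff, the strict reading of a drawn
correlation network. Note this makes recovery demanding — with within-
cluster correlations centred at ρ, a cluster of n members survives only if
all n(n−1)/2 sample correlations exceed the cutoff, so ρ must sit well
above it. The SVD of the response matrix (singular values and variance
fractions) is attached as a coherence diagnostic; a single coordinated
network is ~rank-1.

Correlation scores are pair-counting fractions. Community scores use the
n_A·n_B normalisation off-diagonal and n_A(n_A−1) with self-pairs excluded
on the diagonal, cutoff 0.8 by default. Community membership ships as an
editable `label,start,end` text map — the functional community definitions
belong to the structural-biology literature of the particular kinase and
are not hardcoded.

## ITC

The finite-injection forward model is the default and the fit model. Total
concentrations after each injection follow the displaced-volume convention
(injection of dV into a full cell of volume V₀ dilutes existing contents
by 1 − dV/V₀; an "overfill" moles-in-growing-volume convention is also
implemented). Bound complex comes from the exact 1:1 quadratic with the
site concentration n·[M]; the per-injection heat is the telescoping form

    q_i = ΔH · V₀ · ([MX]_i − [MX]_{i−1})

chosen so that heats sum exactly to ΔH·V₀·[MX]_final (heat conservation to
machine precision). A consequence worth knowing: past saturation q_i does
not go to zero but to the small dilution signal of the saturated complex,
so the "mean of last 3 injections" dilution-subtraction heuristic
over-subtracts slightly; the blank-table mode and the fitted baseline
offset are exact and preferred when available.

The continuum model evaluates the analytic single-site isotherm derivative
d[MX]/dX_tot = ½ + (1 − (1+r)/2 − R_m/2)/√(R_m² − 2R_m(1−r) + (1+r)²)
(r = K_d/[M]_tot, R_m = X_tot/[M]_tot, site-normalised) at midpoint
compositions, *plus* its symmetric partner term in d[M]_tot that accounts
for macromolecule dilution. Without the partner term the continuum and
discrete models disagree by several percent under displaced-volume
dilution no matter how small the injections; with it they agree to
< 0.02% at 1-µL injections into 300 µL (the continuum-limit cross-check in
the test suite).

Fitting is least squares via lmfit with K_d parameterised on a log scale
(positivity plus better conditioning across the µM–mM range), ΔH free, n
optionally fitted, optional baseline offset; parameter uncertainties come
from the Jacobian. A c-value (= n[M]₀/K_d) outside [0.1, 10⁴] triggers a
weak-identifiability warning. Thermodynamics: ΔG = RT ln K_d with K_d in
molar (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹; ΔG < 0 for sub-molar K_d),
TΔS = ΔH − ΔG. Cooperativity σ = K_d(apo)/K_d(nucleotide-saturated), with
the relative errors of the two K_d estimates propagated in quadrature.

## Markov-state toolkit

tICA solves the symmetrized generalized eigenproblem C_τ v = λ C₀ v with
mean-free data, a small ridge (10⁻¹⁰ by default) on C₀, eigenvalues sorted
descending and components sign-fixed on their largest loading. Eigenvalues
are lagged autocorrelations of the tICs and lie in [−1, 1] after
symmetrization.

Transition counts use a sliding window at the chosen lag and never cross
trajectory boundaries. Reversible estimation symmetrizes counts,
(C + Cᵀ)/2, before row-normalisation — detailed balance then holds exactly
and the stationary law is the row-sum distribution. The model is
restricted to the largest connected set, dropped states listed. The
estimation lag is a required argument: the analysis lag is a scientific
choice (the tICA lag is its natural default) and silently defaulting it
invites inconsistent models.

Populations map to free energies in two conventions, recorded in the
output: "complement", ΔG = −RT ln(p/(1−p)), the exchange free energy of a
state against everything else (the NMR detection-limit convention: p =
0.005 at 300 K gives 3.16 ≈ 3.2 kcal/mol), and "ground-state",
ΔG_i = −RT ln(p_i/p_ref). Kinetic Monte Carlo draws per-step categorical
jumps from the transition-matrix rows with a seeded generator; occupancy
converges to π as 1/√n for ergodic chains, and a point-mass row triggers
an absorbing-state warning.

## Ensemble Δω and the replica-averaged restraint

Δω per site is the difference of ensemble-mean predicted shifts, excited
minus ground state (sign kept; magnitude used for regression against
experimental values, matching how exchange experiments report |Δω|), with
a nonparametric bootstrap over conformers for the standard error.
The predicted-vs-experimental comparison is unweighted OLS with intercept
(an errors-in-variables treatment is a documented extension point, since
both axes carry error); R² is symmetric under axis exchange, the slope is
not. Per-site sign agreement is reported separately from the fit.

The restraint penalty is E_cs = α Σ_k Σ_l (δ_exp,kl − M⁻¹ Σ_m δ_calc,klm)²
— the squared deviation of the *replica-averaged* calculated shift from
experiment, the standard replica-averaged harmonic restraint: the ensemble
mean, not any individual replica, is pushed onto the measurement. E_cs ≥ 0,
vanishes iff every replica-averaged shift matches, scales linearly in α
and quadratically in a uniform offset.

## Synthetic-data generators

`gen_shift_tables` emulates a four-state ligation series (default
activation coordinates x = 0, 0.5, 0.8, 1.0 for apo/ADP/ATPγN/ternary —
monotone open→intermediate→closed, values chosen once as plausible rather
than asserted). Each planted network is a set of residues responding along
a common (H, N) ppm direction with per-residue scalar magnitudes, driven
by a per-cluster activation coordinate: shift(state) = baseline ±
magnitude·direction·x_state + noise. Two modelling choices are deliberate
and load-bearing:

- **Proportional rows.** A cluster shares one response direction; members
  differ only by magnitude (and optional sign flip). This is what makes
  concatenated-HN response rows proportional and within-cluster |R| → 1 —
  the structure a covariance analysis detects. If every member instead had
  an independent H:N amplitude ratio, within-cluster correlations would be
  the cosine between amplitude directions (arbitrarily far from 1) and no
  cutoff-based recovery could succeed, noiseless or not.
- **Orthogonal coordinates.** The second default cluster follows a state
  pattern orthogonalised against the primary coordinate: two networks
  responding to the *same* scalar equilibrium are mutually correlated by
  construction, so statistically separable networks must ride on distinct
  underlying processes.

Noise is Gaussian per nucleus with sd = `noise_fraction` × the residue's
across-state RMS response deviation (default 0.05, i.e. scatter about the
linear trajectory at 5% of the trajectory's spread — the regime in which
within-cluster correlations concentrate near 1 and recovery at the 0.98
display cutoff is meaningful). Background residues perturb independently
with sd 0.002 ppm (H) / 0.01 ppm (N), well inside the default linewidths
of 0.01 / 0.05 ppm: experimentally "unresponsive" means within the line.
Baselines are uniform over typical amide ranges (7–9.5 ppm H, 105–130 ppm
N). The generator emulates peak-table statistics only — no spectra,
overlap, missing assignments (beyond deliberate deletion), or non-Gaussian
tails — so passing recovery tests demonstrates the estimators, not
robustness to pathological spectra.

`gen_itc_experiment` wraps the finite-injection model for a pair of
experiments (apo-like and nucleotide-saturated-like, the second with
K_d/σ), default 25 × 2 µL injections of 1 mM titrant into 100 µM protein
in 300 µL at 300 K — ordinary bench conditions with c ≈ 6 — and
multiplicative Gaussian heat noise (default 2%) plus a small additive
floor. `gen_markov_features` samples a hidden chain from a given
transition matrix and emits per-state Gaussians. `gen_ensemble_shifts`
draws Gaussian conformer shifts per state. All generators are
deterministic given their seed and return the planted truth.

## Problem sizes and numerical conventions

The shipped analyses and the reproduction script run at desk scale:
150-residue series, 200 ITC replicate fits, 10⁵–10⁶-step chains and
2×10⁵-frame tICA inputs — sizes at which every planted quantity is
recovered within tight sampling error while a full run stays around half
a minute. Degenerate inputs are flagged rather than silently handled:
zero-variance residues are excluded from correlation with a report,
all-zero isotherms return an explicit unidentifiability flag, reducible
chains are restricted to their largest connected set with the dropped
states listed, and densities over fewer than three residues are refused.
Ties: significance and correlation cutoffs are strict (boundary cases
excluded); the PC1 orientation tie (exactly zero score or loading) resolves
to +.

## Known limitations

- CHESCA recovery under complete linkage requires within-cluster
  correlations concentrated well above the cutoff; at noise levels ≈ 10%
  of the response spread, clusters begin to split at the 0.98 cutoff (an
  intrinsic property of the all-pairs criterion, not an implementation
  limit).
- The ITC model covers a single 1:1 site; multi-site/sequential schemes
  and raw thermogram processing are out of scope.
- Macrostate assignment in the MSM toolkit is by user mapping (or a
  spectral-gap heuristic flagged as such); no PCCA+ style coarse-graining.
- Shift prediction from structures is consumed as input tables, never
  computed here.
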