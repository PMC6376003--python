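# Methods

This note records the model, the defaults and the numerical choices behind
`physiomatrix`, and what the synthetic benchmark does and does not show.

## Signal model and phase binning

The analysis assumes a flow signal of the form

    flow(t) = Q + R(φ_r(t)) + E(φ_c(t)) + I(φ_r(t), φ_c(t)) + ε(t)

where φ_r, φ_c ∈ [0, 1) are the fractions of the current respiratory and
cardiac cycle elapsed at time t, R and E are periodic zero-mean components,
I is a doubly-centered periodic interaction and Q the constant net-flow
level (ml/s). Phases are defined per *individual* cycle, not against the
mean cycle length, so rate variability stretches each cycle onto the same
unit interval instead of smearing the phase axes.

Respiratory cycle onsets are the belt-curve maxima (the
inspiration-to-expiration transition); a sample is a maximum when it is the
largest value in the centered sliding window (`belt_window_s`, default
0.8 s — long enough to span plateaus at the peak, shorter than any
plausible respiratory cycle at rest). Runs of equal window-maxima are
reduced to the run midpoint. Cardiac onsets are the R-wave event times
recorded by the monitoring unit; no ECG waveform processing is done.

Samples before the first or after the last complete cycle of either kind
are dropped rather than extrapolated; with 6–7 minute acquisitions this
discards well under 5% of samples and introduces no boundary bias. The
physio-matrix bins (default `n_resp_phases=40`, `n_cardiac_phases=10`,
matching the temporal resolution achievable at typical heart and breathing
rates with 48 ms dynamics) hold arithmetic means of their samples; empty
bins are masked and, under the default `empty_bin_policy="error"`, block
volume integration (the alternative `"gam-impute"` fills them from the
fitted smooth surface before integration).

## Volumes and gating

V_net = Σ_ij P_ij Δt_j / n_i uses one constant phase interval per axis
(Δt = mean cycle period / phase count); per-cycle durations are not
propagated. Marginals are computed as plain sums (Σ_i P_ij, Σ_j P_ij); all
gated volumes carry the same Δt_j / n_i factor, so summing *all* entries
instead of the negative ones reproduces V_net identically in every mode,
and retrograde fractions are unaffected by the sums-vs-means convention.
Retrograde fractions are printed as positive magnitudes and serialized
signed (both conventions circulate in the clinical literature). BSA
indexing is optional; without it volumes are ml per cardiac cycle.

## The functional-ANOVA fit

Smooths use cyclic cubic B-spline bases on the unit phase circle with
cyclic second-order difference penalties (periodic P-splines). Basis
dimensions default to 20 (respiratory), 8 (cardiac) and 8×5 (interaction):
the respiratory axis must resolve flow features a few bins wide (the
Fontan-type expiratory dip spans ~0.2 cycle; a basis with knot spacing 0.1
demonstrably cannot follow it), while staying below the 40/10 bin
resolution so the penalized fit, not the basis, controls smoothness.
Sum-to-zero (main effects) and marginal-centering (interaction) constraints
over the native phase grid are absorbed by null-space reparameterization,
after which the fit is an ordinary penalized least-squares problem solved
by Cholesky factorization.

One smoothing parameter per term is chosen by minimizing the GCV score
n·RSS/(n − tr(A))² over a 5³ log₁₀ grid (−4…4) refined by Nelder-Mead and
clipped to 10^±8. REML is not offered; GCV is the package's single
automatic criterion, with `smoothing="fixed:<λ>"` as the manual escape.
The default fit uses one observation per occupied matrix bin (≥80%
occupancy required), unweighted; `weight_by_counts=True` and
`fit_level="samples"` (fit the raw samples at their exact phase fractions)
are available variants.

Degenerate inputs: a perfectly fitted (zero-residual) surface yields
σ² = 0; component tests then reduce to whether the coefficients are
literally zero. Rank deficiency of the penalized normal equations raises a
fitting error rather than silently pseudo-inverting.

### Component significance

Each component is tested with a Wald-type statistic: the quadratic form of
its coefficients in the pseudo-inverse of their *frequentist* (sandwich)
covariance σ²·A⁻¹XᵀWX·A⁻¹, referred to chi-square at the retained rank.
With the full numerical rank retained, the statistic is — for a fixed
smoothing parameter — exactly a projection of the noise onto a
fixed-dimension subspace, hence exactly chi-square under the component's
null. This matters in practice: the Bayesian posterior covariance
(A⁻¹σ²) overstates the sampling variability of heavily penalized
coefficients and drove the realized test size to ≈0%, while truncating at
the rounded effective degrees of freedom interacted with GCV selection and
inflated it to ≈10%. The shipped default measures ≈5.5% at nominal 5% over
200 null simulations; the EDF-rank variant remains available through
`wald_test(..., rank_policy="edf")`.

### Amplitudes

Component amplitudes (max − min) are read off the fitted continuous
splines on a grid oversampled 10× relative to the native bins. Evaluating
only at the 40/10 native points can miss a narrow extremum falling between
bin midpoints (up to ~12% of the respiratory amplitude for a dip centered
on a bin boundary); the continuous spline carries the information, so the
package uses it. Pulsatility indices divide amplitudes by Q and are
flagged undefined when Q = 0; the respiratory-to-cardiac ratio A_r/A_c
equals the ratio of the pulsatility indices identically.

## Resting-state plateau

The plateau search runs on the cardiac-averaged fitted waveform Q + R_i
(not the raw marginal, which still carries cardiac leakage and noise).
For every cyclic window of `plateau_fit_points` (8) consecutive phases the
least-squares slope is compared against `plateau_slope_fraction` (5%) of a
reference slope — by default the mean over adjacent local-extremum pairs
of |Δflow|/|Δtime| (`plateau_reference="global"` uses amplitude over mean
extremum spacing instead). Windows are cyclic so a plateau spanning the
phase wrap is found. A plateau must comprise at least `plateau_min_run`
(2) consecutive qualifying window positions: the slope of the single
window centered on a smooth extremum also vanishes, and such an isolated
zero-slope point is a turning point, not a resting state. Constant
waveforms have no extrema, leaving the reference undefined; the full range
is then returned with a degenerate-reference flag. The cardiac net
contribution is the mean of Q + R_i over the plateau; the respiratory
contribution is Q minus that, so the two sum to Q exactly by construction.

## What the synthetic generator emulates

Subjects are built from raised-cosine bumps and low-order harmonics,
centered analytically so the truth satisfies the same identifiability
constraints the fit enforces. Preset rates, amplitudes, net-flow levels
and BSA are the cohort means of the clinical study this pipeline mirrors
(Fontan: HR 80.1 min⁻¹, RR 21.8 min⁻¹, A_c 20.7, A_r 52.1, A_I 11.8 ml/s,
Q 21.6 ml/s = A_c over the reported cardiac pulsatility index; normal:
HR 78.9, RR 17.9, A_c 79.3, A_r 26.4, A_I 36.1, Q 35.1). Cycle periods are
lognormal with CV 5% (a realistic resting short-term variability; the
study conditions fix only the rate means), noise is Gaussian with
σ = 5 ml/s, and acquisitions default to 8000 samples at 48 ms with a 2 ms
belt record.

The waveform shapes are deliberately stylized so the gating signatures are
unambiguous: in the Fontan preset every negative flow value sits in an
early-expiration respiratory band across the whole cardiac cycle (so
exclusive ECG gating measures exactly zero retrograde volume), in the
normal preset every negative value sits in the atrial-contraction cardiac
dip across the whole respiratory cycle (so exclusive respiratory gating
does). Real subjects will not separate this cleanly; passing these checks
demonstrates that the gating arithmetic is right, not that real Fontan
retrograde flow is purely respiratory. Two further consequences of the
stylization are worth knowing. First, zero-mean centering of a
dip-dominated respiratory waveform pushes the Fontan resting plateau
slightly *above* Q, so the respiratory net contribution of the preset is
small and negative (≈ −17% of Q); the partition arithmetic (contributions
summing to Q) is what the tests verify, the sign is a property of the
preset shape. Second, the normal preset's atrial-contraction dip must
out-weigh Q plus the respiratory and interaction excursions to stay
retrograde at every respiratory phase, which makes its cardiac waveform
dip-dominated rather than classically triphasic-peaked.

Cohorts draw heart rate, breathing rate, cardiac amplitude, interaction
amplitude, Q and BSA from truncated normals around the preset means with
the reported between-subject SDs; the amplitude *ratio* is drawn directly
within each group's reported range (Fontan 1.01–6.72, normal 0.16–0.71)
and A_r set to ratio × A_c, because independent amplitude draws would
overlap the groups, contrary to the separation the study observed.

## Known limitations

- Fitting the bin-averaged matrix attenuates component extrema by the
  bin-integration factor (≈1.6% for a sinusoid at 10 cardiac bins, ≈1–3%
  for the narrow respiratory features at 40 bins — the same effect the
  phase-resolution error curve quantifies). Recovered amplitudes are
  therefore accurate to a few percent, not arbitrarily exact, even with
  zero noise; Q is unaffected (bin means average to the true level).
- The Wald p-values are conditional on the GCV-selected smoothing
  parameters; full-rank testing keeps the size near nominal but the test
  is still approximate for small matrices.
- The plateau rule inherits the ambiguity of "flat": its output depends on
  the window length, slope threshold and minimum run, all exposed in the
  configuration.
- Only a single vessel's flow series is analyzed; nothing here addresses
  vessel segmentation, multi-site flow, or clinical covariates.
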