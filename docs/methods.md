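# Methods

This note documents the models and estimators implemented in `motilikit`,
the defaults they ship with, and the design choices made where the
procedure was genuinely open.

## Data model and units

A trajectory is a uniformly sampled 2D path in micrometres with sampling
interval `dt` (default 0.5 s, i.e. 2 Hz). The reference recording
protocol is 4,100 frames over 34 min 10 s; a full-length move-step series
therefore has 4,099 entries. Micrometres are the single internal unit;
the intensity of response is reported in millimetres and speeds in µm/s
at the reporting boundary only. Frames are 0-based and must be
consecutive within a track: a missing frame is a validation error, never
interpolated, so the sampled dynamics are never silently altered. The
stimulus frame fixes +x toward the cathode; the chemoattractant source
lies toward −x.

## Estimators

### rmsf and the finite-size (bridge) correction

The move-step series `x` is mean-subtracted and integrated into the
profile `y(k) = Σ (x_i − x̄)`; the fluctuation function is the RMS of the
profile increments `y(k+l) − y(k)` over all overlapping windows, and the
fluctuation exponent α is the OLS slope of `log10 F` vs `log10 l` over
log-spaced scales in `[8, N/8]` frames.

Subtracting the sample mean pins `y(N) = 0`: the profile is exactly a
(fractional-)Brownian *bridge*, whose increment second moment at lag `l`
is analytically smaller than that of the free profile by a factor that
depends only on the exponent and `l/N`. For persistent series this
deflation is large — left uncorrected it biases α̂ down by ≈ 0.1 at
α = 0.9 for N ≈ 4,000 — so `rmsf_curve` divides the analytic bridge
factor out, iterating the exponent estimate to self-consistency (4
iterations; the factor was verified against a 300-replicate fGn
ensemble). With the correction the mean recovery error on exact fGn with
H ∈ {0.6, 0.75, 0.9} is ≤ 0.02. `finite_size_correction=False` gives the
uncorrected estimator.

### Correlation time

Local log–log slopes of the rmsf curve are measured in sliding
half-decade windows (linear interpolation of `log F` vs `log l`) at
scales on a 50-frame grid (25 s at 2 Hz). The correlation time is the
largest grid scale below which every local slope stays above
`0.5 + margin` (default margin 0.05, configurable); it is therefore
always a multiple of 25 s. If the first grid scale already fails, the
minimum grid value is returned with a no-correlated-regime flag. Because
curve scales are capped at `N/4` (1,025 frames at the full protocol), the
estimator saturates at ≈ 8.5 min; longer memory reads as the cap.

### MSD

Time-averaged over all overlapping origins,
`MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩_t`, fitted over lags `[1, N/10]` by default.
A noise-free ballistic path yields β = 2 to machine precision; position
shuffling drives β to ≈ 0 (the time-averaged MSD of exchangeable samples
is flat).

### DFA

Canonical DFA-1: integrate the mean-subtracted series, partition into
non-overlapping boxes (forward and reversed partitions averaged), remove
the per-box least-squares polynomial trend (order 1 by default, order
configurable), and take `F(n)` as the RMS residual, fitted over log-spaced
boxes in `[8, N/8]`. Note the detrending order bounds what a ramp does:
a linear ramp integrates to a parabola, which order-1 detrending does
*not* annihilate (order 2 does); a constant series yields `F ≡ 0`.
In the pipeline DFA runs on each Cartesian coordinate series separately
and the two exponents are averaged: coordinate series of a migrating cell
are Brownian-class, so the neutral value is γ = 1.5 and persistent
migration shows 1.5 < γ < 2, collapsing to ≈ 0.5 after position
shuffling (the shuffled coordinates are white noise). Regime
classification uses the 0.5/1.5 neutral points per input class with a
±0.05 "uncorrelated" band; exponents outside (0, 2) are not classified.

### ApEn

Classic Pincus approximate entropy (self-matches included, natural
logarithm): `ApEn = Φ^m(r) − Φ^(m+1)(r)` with `Φ^m(r)` the mean log
fraction of templates within Chebyshev distance `r`. Defaults `m = 2`
and `r = 0.2 × SD` of the analyzed window (the field convention; the
tolerance was not otherwise fixed), with an absolute-`r` override for
zero-variance series. Values are exact — the vectorized implementation
matches a naive O(n²) template count to 1e-12 — and invariant under
affine rescaling when `r` is SD-fractional. The growing-window profile
evaluates ApEn on nested prefixes 50, 100, …, N (82 windows at the full
protocol); windows shorter than 300 points are computed but flagged
invalid, since ApEn needs ≥ 10^m points and ≤ 200-point series are
unreliable. Strict calls on series shorter than 10^m raise.

### Kinematics

Displacement cosine = cosine between the net displacement and the
stimulus axis; sectors are half-open 45° bins `[k·45°, (k+1)·45°)`
measured from the axis (the bin-edge convention is not externally fixed;
45.0° belongs to sector 1). Average speed is total path length over
duration — identical to the mean instantaneous speed under uniform
sampling. Zero-net-displacement trajectories have undefined direction:
they yield NaN cosine/angle, are excluded from sector histograms and
cohort cosine statistics, and are counted in the run log.

### Cohort statistics

Median/IQR with type-7 (linear-interpolation) quartiles — IQR values are
convention-sensitive, so the convention is fixed and documented. The
Wilcoxon rank-sum test reports a Z from the tie- and continuity-corrected
normal approximation (appropriate at the cohort sizes of 50–400) and a
two-sided p that switches to the exact small-sample distribution for
tie-free samples with min(n) ≤ 8. Kruskal–Wallis uses the tie-corrected
H against χ²(k−1). The KS normality gate estimates mean/SD from the
sample, which makes its nominal p conservative (the Lilliefors caveat);
it is a routing decision, not an inferential endpoint. No
multiple-testing correction is applied.

## Surrogates

One uniform random permutation per surrogate, applied to the position
order for trajectory-level metrics (MSD, DFA, kinematics) and to the
move-step order for rmsf/ApEn. A uniform permutation is the
distributional fixed point of any long elementary-transposition shuffle;
the nominal operation count (2 × 10⁵) is retained as a configuration
echo. Permutation preserves the value multiset exactly, so surrogate
mean/SD equal the original's up to summation order.

## Synthetic motion

The generators exist to give every estimator inputs with known truth:

* **ballistic** — constant velocity; the β = 2 / DR = 1 calibration limit.
* **brownian** — iid Gaussian frame displacements with per-axis SD
  `speed_mean·dt/√2`; the β = 1 / α = 0.5 / γ(path) = 1.5 null.
* **fgn_steps** — exact Davies–Harte (circulant embedding) fractional
  Gaussian noise, scaled to per-frame step units, shifted by
  `max(0, −min)` and clipped at 0. The constant shift leaves every
  fluctuation statistic unchanged; clipping only bites at very low H.
  The raw `fgn()` sampler is exposed for exponent-recovery studies and is
  validated against the analytic fGn autocovariance.
* **persistent** — the emulator of observed migration. The heading
  diffuses on the circle with diffusion `2/τ` so the direction
  decorrelates as `exp(−t/τ)` (τ = persistence time, default ≈ 9–10 min
  to match the observed correlation-time scale), with an optional
  restoring drift `−(κ/τ)sin(θ − θ_bias)` giving a von Mises stationary
  heading of concentration κ. The speed follows a discretized
  Ornstein–Uhlenbeck process with the same relaxation time, mean ≈ 1.3–1.7
  µm/s and SD 0.45 µm/s, clipped at zero (truncated-normal marginal).
  Making the speed *correlated* rather than iid is deliberate: observed
  move-step series are long-range correlated with very low ApEn, and only
  a persistent speed process reproduces the experimental-vs-shuffled
  contrasts (α and ApEn) that the toolkit is designed to detect. An iid
  speed would make the step series white and the shuffle test vacuous.

Scenario presets fix the directional structure of the four experimental
conditions: Sc1 unbiased (κ = 0), Sc2 strongly cathode-directed
(κ = 3.0, cohort median cosine ≈ +0.97), Sc3 peptide-directed (κ = 0.7,
median ≈ −0.7), Sc4 a 58/42 peptide/cathode mixture of two κ = 0.6
subpopulations (broadly bimodal cosines). The κ values were calibrated
once against these target medians at the full 4,100-frame protocol.
Per-cell-type envelopes set speed/persistence to 1.70 µm/s / 10.42 min
(nucleated) and 1.34 µm/s / 8.33 min (cytoplast-like).

What the generators do **not** emulate: pseudopod-scale shape dynamics,
cell–cell interactions, boundary effects of the chamber, tracking noise,
and the exact marginal speed distribution of real amoebae (the
truncated-normal choice is an emulation convenience). Passing tests
therefore validate the *estimators* under known statistical structure,
not any biological claim about real trajectories.

## Pipeline and reproducibility

One master seed fans out through `numpy` `SeedSequence` to per-trajectory
child seeds (stable under cohort reordering); all generators and
surrogates are bit-reproducible given their config and seed, and
re-running the pipeline with the same seed reproduces every output table
byte for byte. Per-trajectory estimator failures are logged and reported
as NaN without aborting the run. Derived seeds are reduced mod 2³¹.

Problem sizes used in the shipped validation suite: deterministic limits
at the full 4,100-frame protocol; null calibrations and exponent recovery
with 100 and 50 replicates at n ≈ 4,100; surrogate contrasts on 50
persistent walks; pipeline round-trips on small cohorts (≈ 10 cells,
600 frames) — sizes chosen so the statistical tolerances quoted in the
tests are comfortably resolved.

## Known limitations

* The correlation-time estimator saturates at `N/4` frames (≈ 8.5 min at
  the full protocol) because rmsf scales are capped there.
* The rmsf bridge correction assumes a single power-law regime across
  the fitted scales; curves with strong crossovers are corrected with an
  effective exponent.
* DFA-1 cannot measure γ above ≈ 2 (order-limit saturation); strongly
  ballistic coordinate series read as γ ≈ 2.
* ApEn is O(n²); the 82-window profile of a full-length track costs a
  few seconds, so profile computation is optional in the pipeline.
* The Wilcoxon exact route is limited to tie-free small samples; all
  cohort-scale p-values use the normal approximation.
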