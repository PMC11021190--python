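# Methods

## Physical model

A particle at position **r** relative to the focus contributes an expected
photon rate proportional to a 3D Gaussian point-spread function

    W(r) = exp(−4 ln2 (x² + y²)/ω² − 4 ln2 z²/(AR·ω)²),

parameterized by the lateral full-width at half-maximum ω (µm) and the
axial/lateral aspect ratio AR. The same (ω, AR) convention is used by the
simulator and the correlation fitter; the single conversion to 1/e² radii,
w = ω/√(2 ln 2), lives in `simulate.fwhm_to_e2` so the two sides cannot
drift apart by a hidden factor of 2. The effective observation volume is
V_eff = π^{3/2} w_xy² w_z, and the mean focal occupancy N of a species at
concentration c is N = c·V_eff.

The simulator propagates particles by free Brownian motion — per bin a
Gaussian step of per-axis variance 2·D·Δt — inside a periodic box, and
draws Poisson counts around `background + Σ brightness·W`. Particle numbers
are Poisson draws around c·V_box (grand-canonical occupancy), so focal
number fluctuations carry the correct statistics for FCS amplitudes.
One step per bin is exact for the positions themselves (Gaussian increments
compose), but photon binning samples the intensity once per bin, so the
scheme is stated valid only for √(2·D·Δt) ≪ ω; analyses of fast diffusers
(D ≳ 50 µm²/s) shorten the bin time accordingly (tests use
Δt ≤ (0.08 ω)²/2D). Periodic rather than reflective boundaries preserve a
uniform concentration without depletion layers; the box must be at least 3×
the PSF half-widths per axis.

Ground truth records a transit wherever a particle's PSF weight exceeds 1%
of maximum (configurable constant `TRANSIT_WEIGHT_THRESHOLD`), with the
maximum weight reached, from which the expected peak height in any channel
is brightness × weight.

## Peak calling

The baseline of a channel is the median of its counts and the noise scale
σ = 1.4826·MAD, both insensitive to dilute peaks (tested to 1% contamination
at 100× the baseline). Peaks are maximal runs of bins above
baseline + k·σ (default k = 4; when σ = 0 an absolute baseline + 1 threshold
applies). Runs separated by at most `merge_gap_bins` are merged; merged runs
containing fewer than `min_width_bins` above-threshold bins are discarded.
Counting *above-threshold* bins rather than merged extent matters: with a
wide merge gap, two isolated shot-noise spikes would otherwise merge into a
"run" that passes a length filter by extent alone.

Defaults (merge gap 1 bin, minimum width 2 bins) suppress single-bin spikes
and suit traces whose bin time is comparable to the transit time. At 10 µs
bins with ~2 ms transits, the analyses in the examples, tests and acceptance
script use merge gap 100 bins (~τ_D/2) and minimum width 10 bins: within one
transit the signal stochastically dips below threshold on millisecond-scale
shoulders, and the merge gap must bridge those dropouts while staying well
below the inter-transit spacing. These are analysis parameters exposed in
every interface, not constants.

Per peak: brightness = maximum baseline-subtracted count (matching
per-particle intensity axes of density maps); integrated area as a secondary
field; width = FWHM of the baseline-subtracted profile with linear sub-bin
interpolation; center = bin of the maximum (plateau ties resolve to the
middle), kept on the bin grid because matching operates on bin extents.
Outlier flagging partitions peaks by brightness > 10× median or width > 5×
median (both configurable) — the aggregate/impurity screen.

## Matching and per-particle indices

Peaks from two channels co-occur iff their inclusive bin extents overlap by
≥ 1 bin; candidate pairs are accepted greedily by decreasing overlap, each
peak used once; leftovers become single-channel events. The co-occurrence
fraction is taken over events with a reference-channel peak — the reference
channel defines the particle; cargo-only events are excluded and logged.

Content index: (I_cargo − I_ref)/(I_cargo + I_ref), the only simple form
bounded in [−1, 1] with −1 anchored at zero cargo. GP:
(I_short − I_long)/(I_short + I_long), short = ordered-phase window. Both
are antisymmetric under channel swap and invariant under common intensity
scaling (property-tested).

Per-event GP is best computed by `gp_from_trace`, which integrates
baseline-subtracted counts of both channels over the union extent of the
matched peaks. Using every photon of the transit removes the extreme-value
bias of a per-channel maximum (the dimmer channel's max is inflated more,
biasing GP toward 0 by ~0.04–0.1) and shrinks per-event noise to
σ ≈ 0.02 at the default brightness; simulations recover population GP
within |bias| ≤ 0.005 at SNR ≥ 10.

## GP statistics

`fit_gp_histogram` bins values with Freedman–Diaconis bins clipped to
[−1, 1] and fits a single Gaussian by least squares; σ is the heterogeneity
measure. Degenerate samples short-circuit to (value, 0); when the fit fails
or explains under half the histogram variance (strongly bimodal samples,
where a single Gaussian is ill-posed) sample moments are reported with a
warning. `fit_gp_mixture` fits Gaussian mixtures with 1..max components to
the raw event values and selects by BIC, components sorted by mean.

A caveat established by simulation: end-to-end per-event GP values are a
*scale mixture* of normals — per-event photon budgets vary with transit
geometry — plus a small (~3–5%) class of chance coincidences of two
particles. BIC therefore genuinely prefers a third, broad component on
trace-level data however well separated the populations are; the two
dominant components still recover the population means within 0.05. On
homogeneous-noise GP values (the histogram's generating model), BIC selects
the true component count.

## Correlation analysis

The multi-tau correlator uses 16 linear lags in the first octave and 8 new
lags per octave after rebinning counts by 2 — the standard logarithmic
schedule. Normalization is symmetric (means over the valid overlap at each
lag) and cross-correlations average both lag directions, making
G_AB ≡ G_BA exact and reducing identically to the autocorrelation when the
channels coincide. The estimator is verified against an independent
naive-loop implementation to 1e-6 relative.

Fits of G(τ) = (1/N)(1 + τ/τ_D)⁻¹(1 + τ/(AR²τ_D))^(−1/2) use weighted
least squares (lmfit), weights 1/Δτ by default to rebalance the log-spaced
grid (uniform optional), initial guesses N₀ = 1/G(first lag) and τ₀ at the
half-decay lag, and a default lag window starting at the second lag (the
first is shot-noise dominated). AR is fixed at 5 unless freed: axial
calibration is rarely available and the model is weakly sensitive to AR.
ω is a required calibration input; D = ω²/(8 ln 2 τ_D) is a derived field
and is only as accurate as ω². Recovery on simulated traces: median fitted
D within 20% of truth across D ∈ {1, 5, 20, 100} µm²/s and fitted N within
20% of c·V_eff for N ∈ [0.5, 5] (20 and 12 traces per condition of 1–2.5 s
each — sizes chosen to keep the suite fast on one CPU while averaging the
single-trace scatter).

## What the simulator does and does not emulate

Emulated: free 3D diffusion, 3D Gaussian detection, per-channel brightness
and background, Poisson shot noise, multiple populations, ground-truth
transits. Not emulated: photophysics (triplet blinking, bleaching), flow,
anomalous diffusion, detector afterpulsing/dead time, spectral crosstalk,
intrinsic within-population compositional spread (each population has a
single brightness vector, so per-event GP spread is purely shot noise —
narrower than real samples, whose heterogeneity the σ statistic is designed
to measure). Passing tests therefore validate the estimators' correctness
and calibration under ideal optics, not robustness to those instrument
effects.

## Defaults and degenerate inputs

| parameter | default | meaning |
|---|---|---|
| ω | 0.25 µm | lateral PSF FWHM (a typical confocal value; not a calibrated constant) |
| AR | 5 | axial elongation of the PSF |
| bin time | 10 µs | simulator binning |
| box | (3, 3, 3·AR) µm half-widths | periodic volume; ≥ 3× PSF half-widths enforced |
| k | 4 | detection threshold multiplier |
| T, η | 298.15 K, 8.9×10⁻⁴ Pa·s | Stokes–Einstein (water, 25 °C) |

Degenerate inputs have defined behaviour rather than crashes: all-zero
traces yield no peaks; constant traces yield zero correlation but a
zero-mean trace is rejected; fewer than 10 peaks disable outlier flagging
with a warning; identical GP values short-circuit the histogram fit; a
non-convergent diffusion fit reports `converged=False` with parameters.

Batch runs are pure functions of (inputs, config, seed): identical configs
reproduce outputs bit-exactly apart from manifest timestamps, and one
corrupt sample is recorded as failed without aborting the batch.
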