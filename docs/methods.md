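# Methods

This note documents the models implemented in `rodnoise`, the synthetic
data the package uses to validate them, the numerical choices that were
genuinely open, and what the tests do and do not establish about real
recordings.

## Response models

**Hill intensity–response.** Sensitivity is the half-maximal flash
strength `I_0.5` of the Hill relation

    R / R_max = I^n / (I^n + I_0.5^n)

fitted by nonlinear least squares to (flash strength, peak amplitude)
pairs. The algebraically identical form `1/(1 + (I_0.5/I)^n)` is used
for evaluation to avoid overflow at large `I`. Initial values are
`R_max` = largest amplitude, `I_0.5` = first strength crossing half of
it, `n = 1.5`; bounds keep all parameters positive and `n ≤ 20`. A fit
whose `I_0.5` lands outside the sampled strengths is flagged
unreliable (the data do not span half-maximum); constant amplitudes
yield a flagged degenerate result rather than an arbitrary fit.

**Lamb–Pugh ensemble fit.** The activation phase of the flash response
follows

    R(t) = R_max · (1 − exp(−½ · Φ · A · (t − t_delay)²)),

with `Φ` photoisomerizations per rod per flash and `A` (s⁻²) the
amplification constant. One `(A, t_delay)` pair is fitted jointly
across all flashes of a family. "Leading edge" is operationalised as
the window from stimulus onset until the response first reaches 50% of
its own peak, capped at 80 ms post-flash — this confines the fit to the
activation-dominated phase on both dim and saturating flashes; the
fraction and cap are parameters. Responses are baseline-subtracted,
polarity-corrected and normalised by `R_max` taken from the family's
own Hill fit (falling back to the largest peak when the Hill fit is
unreliable). Peaks and window crossings are located on a 5 ms
moving-average copy of each trace so that noise maxima do not inflate
`R_max` or shift the windows, while the raw samples are what gets
fitted; this keeps the seed-averaged bias of `A` under 5% at the
default noise level. `t_delay` is fitted jointly (bounded to 0–20 ms)
because the source analysis does not state whether it was fixed; a
`fix_t_delay` argument holds it constant instead. The fit is restarted
from three amplification guesses (1, 5, 25 s⁻²) and the lowest-cost
solution kept. Only the product `A·Φ` is identified — rescaling all `Φ`
by `k` rescales the fitted `A` by `1/k` — so the stimulus calibration
is part of the result's meaning (a test asserts this confound
explicitly).

**Recovery time constant.** For a dim flash (peak at most 20% of
`R_max`, keeping the response quasi-linear — the threshold is a
parameter), a single exponential `a·e^(−t/τ)` is least-squares fitted
to the response from the time the recovery first falls to 35% of peak
until it returns to baseline (2% of peak) or the trace ends. "Final
35%" is read as the portion of recovery at or below 35% of peak
amplitude; the alternative reading (last 35% of the time axis) depends
on arbitrary trace length and was rejected. Crossings and the peak are
located on a 25 ms moving-average envelope for the same noise-robustness
reason as above; the raw samples are fitted. On a noise-free
exponential tail, the recovered τ is exact to numerical precision.

**ERG waves.** The a-wave is measured baseline-to-trough (minimum
within 5–80 ms post-flash) and the b-wave trough-to-peak (maximum
within 20–300 ms minus the trough value) — the standard convention; the
search windows are parameters and a baseline-to-peak b-wave variant is
a one-line change in the caller. Per-wave sensitivity reuses the Hill
machinery on (strength, amplitude) pairs. Traces whose a-trough follows
the b-peak are rejected as inverted polarity.

**Dark-noise band power.** Each epoch is detrended (mean and linear
drift), the saturated epoch is trimmed 0.5 s after flash onset to drop
the response transient, both power spectral densities are estimated
with identical Welch settings — Hann window, 5 s segments (Δf =
0.2 Hz, resolving the 0.6 Hz band edge), 50% overlap, per-segment
linear detrend — the instrumental density is subtracted pointwise from
the total, and the difference is integrated over 0.6–10 Hz by
trapezoid with interpolated partial bins at the band edges. Two
interpretive choices are deliberate: subtraction happens in the
spectral domain (subtracting stochastic time series sample-wise is
ill-defined), and negative post-subtraction densities are retained so
the band integral stays unbiased (a clamped copy exists for plotting).
The cumulative power curve uses the identical quadrature, so its
endpoint equals the band power bit-for-bit. Spectra are subtracted per
cell and only then averaged across cells. Changing segment length
(4–6 s), overlap or window within documented ranges moves the
recovered band power by under 10% on the default presets.

**ROS morphometry.** Lengths are binned in 2 µm increments aligned at
zero and normalised to frequency of occurrence (heights are fractions,
not percent — the ~0.2 peak heights of the source fits imply fraction
units). One or two Gaussians are least-squares fitted to the
bin-centre/frequency pairs, empty bins included at zero. The
two-component problem on a dozen bins has a well-populated local
optimum (a broad second component absorbing the tail), so the fit is
restarted from several inits — k-means centres on the raw lengths with
within-cluster SDs, and weighted-quantile centres at two width guesses
— and the lowest-SSE fit wins; fits whose centres land within one bin
are flagged as collapsed. No constraint ties the two FWHMs. Component
area uses the closed form `height·FWHM·√(π/(4 ln 2))` (agrees with
numerical integration to 10⁻⁶ relative), and `fraction_long` is the
longer-mean component's share of the total fitted area.

**Group statistics.** Two-way ANOVA uses type-II sums of squares with
genotype × age interaction (robust to the mildly unbalanced group sizes
of this design), via ordinary least squares; pairwise genotype
contrasts within each age are Welch t tests with Bonferroni correction
by the number of ages. The Kruskal–Wallis H is tie-corrected with a
chi-square p-value, returning (0, 1) on all-identical data. The
summary-statistics t test supports pooled and Welch variants (Welch
default); the Z outlier filter is single-pass with a default threshold
of 2 (none was stated in the source; note |z| ≤ (n−1)/√n bounds what a
small sample can ever exceed). Both omnibus tests hold their nominal
5% type-I error within the binomial 3σ interval over 1000 null
simulations in the test suite.

## The synthetic generator

The generator inverts the analysis models, with presets per genotype ×
age carrying the published WT/GARP2-KO response properties (rod
`I_0.5`, `n`, `R_max`, noise band power per age; amplification and
recovery constants, which were characterised at PM6, are reused across
ages; ERG Naka–Rushton parameters per age; ROS mixtures — monophasic
27.5 µm for WT, biphasic 26.8/34.0 µm with weights 0.77/0.23 for KO,
applied at all KO ages although the biphasy was observed at PM9).

*Flash families* rise along the Lamb–Pugh curve until reaching the
Hill-predicted peak amplitude for that flash, then decay exponentially
with `τ_rec`; the two regimes are joined by a raised-cosine cross-fade
of 10 ms centred on the peak time. The source analyses fit activation
and recovery separately and never state a full waveform; the cross-fade
is this package's construction, chosen because it leaves both fitted
regimes intact. It perturbs peak amplitudes by up to ~0.5%, so
noise-free peaks satisfy the Hill relation within 5% (tested); with the
cross-fade width set to zero the peaks are exactly Hill and a refit
recovers the generating parameters to three significant figures.
Acquisition mirrors the recording conditions: 10 kHz sampling, 300 Hz
low-pass, responses stored with native negative-going sign, additive
Gaussian noise (default sd 0.3 pA) low-pass filtered like the signal.
Flash ladders double flash-to-flash (default 2–256 R*/rod); ladders
whose top flash stays below 95% of `R_max` draw a warning rather than
an error so that the published KO PM9 parameters (top flash ≈ 92%)
remain usable.

*Dark recordings* are shaped-Gaussian cellular noise — white noise
through a 2-pole low-pass with 3 dB corner at 3 Hz, the band-limited
character of rod continuous noise — rescaled so its *expected* 0.6–10 Hz
band power equals the preset value. The calibration is analytic
(Parseval): unit white noise has one-sided density `2/fs`, the shaped
density is `(2/fs)|H(f)|²`, and the scale factor is the square root of
target over the integral of that density across the band. White
instrumental noise (sd 1 pA) is added to the dark epoch; the saturated
epoch carries instrumental noise plus a decaying flash transient
(`R_max·e^(−t/0.1 s)`) that the analysis trims. Default epochs are 60 s
dark / 15 s saturated. Discrete (thermal isomerization) noise events
are not modelled — the analyses here address continuous noise only.

*ROS lengths* are i.i.d. Gaussian-mixture draws (FWHM → σ via
`FWHM/(2√(2 ln 2))`). *ERG traces* are compact-support raised-cosine
templates — a-trough supported 5–35 ms, b-peak 35–255 ms — whose
noise-free amplitudes follow Naka–Rushton relations (Hill with `n = 1`,
the standard ERG form; the source tables give no exponent). Compact
support makes the zero-noise round trip through the wave measurement
exact, which anchors the ERG recovery suite.

All generators are deterministic given (preset, config, seed); per-cell
streams derive from the master seed by fixed stream offsets, so
identical configurations are byte-identical.

## What the simulations do and do not show

Passing recovery suites show that the estimators are consistent and
approximately unbiased *under the generator's assumptions*: exact
Lamb–Pugh rise, single-exponential recovery, Gaussian band-limited
noise, stationary epochs, i.i.d. mixture draws. Real recordings add
drift, seal instabilities, discrete noise events, light-adaptation
history and cell-to-cell parameter spread, none of which are emulated;
recovery within tolerance here is therefore necessary, not sufficient,
evidence about real data. Conversely the group means and SDs of the
animal cohorts are inputs (generator calibration values), not outputs —
no simulation can re-derive them.

## Problem sizes and tolerances

Monte-Carlo suites use 10–100 seeds depending on estimator variance
(10–12 families for amplification, 20 seeds for recovery and band
power, 100 for the unbiasedness check at 20 s epochs), and 1000
replicates for type-I calibration; these sizes put the Monte-Carlo
standard error comfortably below each check's tolerance while keeping
the default suite quick. Curve fits use scipy's trust-region reflective
least squares with analytic-free Jacobians; tolerances are library
defaults. Degenerate inputs (flat traces, empty histograms, zero-area
components, zero-variance groups) raise or flag rather than returning
silent numbers.
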