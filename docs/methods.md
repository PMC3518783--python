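# Methods

## Model and estimation

The continuous time–frequency power matrix `Y` (t × f) is modelled as
`Y = Xβ + ε` with `ε ~ N(0, C)`. Each event type contributes a block of
regressors formed by convolving its input function — by default a delta
train placed at the nearest power bin to each onset — with a peristimulus
basis set `B` (p bins × m functions). A parametric-modulator block scales
the delta train by mean-centred trial-wise covariate values, so the
unmodulated block keeps its average-response interpretation and the
modulator image reads as response change per unit covariate (a flag
disables centring). A discrete-cosine drift block (constant plus
`K = ⌊2 t f_c / fs_power⌋` cosines up to the cutoff `f_c`, default 0.1 Hz)
absorbs slow power drifts and replaces baseline correction; alternatively,
`highpass_design_and_data` residualises both `Y` and `X` against the same
DCT set (the projection is idempotent), matching a filtered-analysis
configuration with a 0.25 Hz cutoff.

`β` is estimated per frequency column by OLS (`lstsq`; rank-deficient
designs are solved by pseudoinverse and flagged together with the
design-efficiency diagnostic, the maximum absolute correlation between
columns of different event blocks). WLS multiplies rows of `Y` and `X` by
√weight — diagonal-covariance pre-whitening. Artefact weights are derived
by amplitude-thresholding the raw trace; every power bin whose analysis
window (centre ± win/2) overlaps a flagged sample receives weight 2⁻²⁵⁶,
which is numerically identical to row deletion (verified against a
row-deletion oracle) while keeping shapes fixed. Residual degrees of
freedom count only bins with weight above 2⁻¹²⁸. Serial correlation of the
power noise biases only the standard errors, not `β` itself (verified by a
property test with AR(1) residuals); first-level standard errors are not
produced, in keeping with the summary-statistic approach where inference
happens at the second level across repetitions or subjects.

The reconstruction `R_i = B β_i` consumes column provenance, never column
positions. No ReML estimation of the t × t temporal covariance is
attempted at the first level; its cost grows quadratically in the number of
power bins (thousands to tens of thousands) and OLS/WLS with pre-specified
weights is the deliberate trade-off.

## Spectral estimation

Sliding-window multitaper estimation: window 0.4 s, step 0.05 s (so the
power series is sampled at 20 Hz and starts at win/2; interior windows
only, no padding), frequencies 2.5–90 Hz in 2.5 Hz steps. The frequency
smoothing (half-bandwidth) is 2.5 Hz up to 25 Hz, 0.1·f between 25 and
50 Hz, and 5 Hz above — continuous in f, so images have no
discontinuities across frequency. The taper count is
`K = max(1, round(2·win·Δf) − 1)` (half rounded away from zero), which
reproduces the printed schedule — one taper for 2.5–30 Hz, two for
32.5–42.5 Hz, three from 45 Hz — as a unit test verifies at every analysis
frequency; no default setting lands on an exact .5 under this rounding.
DPSS tapers are L2-normalised and power is **averaged** (not summed) over
tapers, so the taper count does not change the expected power level;
whether the original analyses averaged or summed is not documented, and
averaging is the choice here. Power is scaled as a one-sided density
(2/fs). Transforms: identity, √, or log(x + ε) with
ε = 1e−12 × median power by default (configurable), keeping exact zeros
finite without distorting in-range values.

Event onsets are quantised to the nearest power bin (≤ 25 ms at the
default 20 Hz power sampling), far below the 0.4 s spectral smoothing; no
fractional-bin splitting is attempted.

## Basis sets

Fourier set of order q: sines and cosines of 1..q cycles of the
normalised window position, 2q columns and **no constant** (the drift
block's constant carries the mean — this matches the order-11 set having
exactly 22 functions). Hanning-windowed variant for responses concentrated
mid-window; FIR as contiguous unit boxes tiling the window (a partition of
unity). Default window ±2 s for the simulation configuration; an
empirical-style ±1.5 s window is a config choice. A Gamma basis is
deliberately not offered: no parameterisation is established for induced
responses, and inventing one here would be arbitrary.

Order selection: step-up extra-sum-of-squares F-tests (order k vs k−1,
design rebuilt each step; α = 0.05 default). The critical value rises with
model size as residual dof shrink. The decision rule is "largest order
whose F exceeds its threshold"; under the null each extra step still has an
α-sized chance of exceeding its threshold, so occasional overshoot is
expected behaviour of the rule itself. Non-nested families are ranked by
−BIC/2 computed from RSS and design rank — a deliberately simple evidence
approximation (a full hierarchical free-energy treatment is out of scope);
the interface accepts arbitrary design candidates so a richer criterion can
be swapped in. Only score differences on the same data are meaningful.

## Synthetic data

The generator emulates a single-channel recording with beta-band induced
responses: a carrier of band-pass-filtered Gaussian white noise (4th-order
Butterworth applied forward–backward, rescaled to sd 1 — "amplitude 1 a.u."
is read as unit standard deviation), duration 450 s at 200 Hz (the raw
rate is not pinned by the scenario; 200 Hz comfortably covers the 90 Hz
top analysis frequency). ERS: Gaussian amplitude bumps, gain +1.0
(a 100% amplitude increase at the peak), σ = 125 ms, onsets every 5 s
starting at 4 s so the first ±2 s epoch fits. ERD: gain −0.9, σ = 250 ms,
present in a random half of trials at latency `N(μ, σ_lat)` after the ERS;
latency draws may fall outside the recording and simply spill their tails.
Source mixing multiplies one carrier by `1 + ERS − ERD` (all bumps summed
before applying; clipped at zero with a logged warning if heavy overlap
drives the modulation negative); sensor mixing modulates two independent
carriers separately and sums them. Optional white Gaussian noise (sd 1 for
the SNR-1 scenario); a 1/f profile is not emulated since each narrow
frequency band is analysed independently. Noise-free single-component
traces on the same carriers provide ground truth; truth waveforms are the
epoch-average (with −2..−1.5 s baseline) of the truth trace under the same
transform, band-averaged over 15–35 Hz.

What passing these simulations does *not* show: performance under
multi-channel mixing with realistic head geometry, non-Gaussian artefacts,
or nonlinear interactions between overlapping responses — the model is
linear in the (transformed) power.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so identical configurations are bit-reproducible.

## Experiment harness and problem sizes

`experiments.latency_sweep` runs the full 450 s simulation per latency
condition (sd 2⁻ⁿ s, n = 0..6) with the complete 36-frequency spectral
analysis — the reference problem size, not a reduction. The
latency-confound experiment uses 10 repetitions × 2 conditions
(μ = 0.3 vs 0.6 s, σ = 0.125 s) and pixelwise pooled-variance two-sample
t-tests; false-positive summaries are evaluated over the 15–30 Hz rows,
the range actually examined in band-limited simulations — outside it a
noise-free simulation leaves near-zero pixel variance and t-statistics are
numerically meaningless. The amplitude-equalised variant raises the
condition-1 ERS gain by the closed-form difference in expected averaged
ERD pull at time 0 (the ERD bump convolved with the Gaussian latency
density), `equalize_average_peak_gain`, ≈ 1.186 under the default
parameters. Order-recovery and F-calibration experiments generate power
columns directly as `X b + noise`, since the statistics under test see
only a single column; type-I calibration uses 2000 null draws against a
fixed random nested design pair (rank gap 2).

Artifact suppression: 100 spikes of amplitude 100 are added to the sd-1
trace and detected by thresholding at 2 a.u. Because the carrier is
Gaussian with unit sd, ~4.6% of uncontaminated samples also exceed the
threshold, and window-overlap weighting therefore removes a large share of
power bins — disproportionately those at ERS peaks, where the doubled
amplitude guarantees excursions. WLS still recovers the response far
better than unweighted OLS on contaminated data, but a residual gap to the
clean-data fit remains that is attributable to this deletion (refitting
clean data under the same weights reproduces the gap); this is a known
limitation of plain amplitude thresholding on signals whose natural
excursions cross the threshold.

## Numerical choices

- Delta inputs: nearest-bin placement; events outside the power axis are
  dropped with a warning.
- Weight boundary: a sample exactly at the window edge counts as inside
  (a 1 ns guard absorbs float accumulation on the time axis).
- F-test: designs are declared nested when the reduced columns project
  onto the full design's span to 1e−6 relative tolerance; zero rank gain
  returns F = 0 (flagged); a perfect fit returns F = ∞, p = 0.
- Epoching: nearest-bin alignment; epochs exceeding the recording are
  dropped with a log entry; the comparator applies transform → epoch →
  average → baseline-subtract, in that order.
- Smoothing kernels are FWHM-parameterised (the neuroimaging convention),
  separable Gaussian, reflective boundaries.
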