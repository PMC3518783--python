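# tfdeconv

GLM deconvolution of induced time–frequency responses in continuous
M/EEG power series.

## The problem

Induced responses — stimulus-related changes in oscillatory power that are
not phase-locked to the event — are conventionally estimated by epoching
the time–frequency power around each event, averaging over trials and
baseline-correcting. This *post-hoc* averaging fails when responses to
different events overlap in time, or when response components have variable
relative timing within a trial (e.g. stimulus- and reaction-time-locked
components): the average mixes the components, and systematic latency
differences between conditions masquerade as amplitude differences (the
*latency confound*).

`tfdeconv` instead models the continuous power series with a linear
convolution model, the approach standard in fMRI time-series analysis.
Target users are electrophysiologists analysing single-channel (or
virtual-channel) M/EEG power with overlapping or variably timed trial
components.

## The model

The continuous power matrix `Y ∈ R^{t×f}` (t time bins × f frequencies,
from a sliding-window multitaper estimate, optionally √- or log-
transformed) is modelled as

    Y = X β + ε

where the design matrix `X` contains, for each event type *i*, the
regressors `X_{(i-1)m+j} = U_i ∗ B_j` — the convolution of that event's
input (stimulus) function `U_i` (a delta train at the onsets, a boxcar, or
a continuous covariate) with each of *m* peristimulus basis functions
`B ∈ R^{p×m}` (Fourier, Hanning-windowed Fourier, or FIR) — plus a
discrete-cosine drift block that replaces baseline correction. `β` is
estimated per frequency by ordinary least squares, or by weighted least
squares with near-zero weights (2⁻²⁵⁶) on power bins whose analysis window
overlaps detected artefacts. The deconvolved response image for event type
*i* is

    R_i = B β_i ∈ R^{p×f},

the time–frequency response that the event would evoke in isolation, and is
a drop-in replacement for a conventional trial average in second-level
(summary-statistic) analyses. Basis order is chosen by step-up
extra-sum-of-squares F-tests; non-nested basis families are ranked by an
approximate (BIC) log evidence.

The package ships a synthetic-data generator emulating the classic
validation scenario — a 15–35 Hz band-limited-noise carrier with Gaussian
amplitude bumps for event-related synchronisation (ERS, +100%, σ = 125 ms,
every 5 s) and desynchronisation (ERD, −90%, σ = 250 ms, in a random half
of trials at variable latency) — and an `experiments` module that runs the
full simulation study (latency sweeps, artifact suppression, the
latency-confound two-sample design, basis-order recovery).

## Worked example

```python
from tfdeconv import SimConfig, SpectralConfig, simulate
from tfdeconv.model import InducedResponseModel
from tfdeconv.experiments import events_frame, ground_truth_waveform, r_squared

cfg = SimConfig(latency_sd_s=0.125, seed=42)   # 450 s, ERS every 5 s, ERD in half of trials
sim = simulate(cfg)
model = InducedResponseModel.from_signal(sim.signal, events_frame(sim), transform="sqrt")
res = model.fit()
print(res.summary())
for which in ("ers", "erd"):
    truth = ground_truth_waveform(sim, which, SpectralConfig())
    print(f"r2({which}) = {r_squared(res.band_waveform(which, (15, 35)), truth):.3f}")
```

prints

```
Induced-response convolution model
==================================
time bins:            8993
frequencies:          36 (2.5-90 Hz)
power transform:      sqrt
basis:                fourier order 11 (22 functions over [-2, 2] s)
design columns:       134 (rank 134)
residual dof:         8859
estimator:            OLS
max inter-event corr: 0.680

event type        peak |R|   at time (s)   at freq (Hz)
erd                -0.1665        -0.05         22.5
ers                +0.1699        +0.00         30.0
r2(ers) = 0.992
r2(erd) = 0.992
```

The ERS image peaks at peristimulus time 0 in the beta band and the ERD
trough sits just before it; both band-averaged (15–35 Hz) reconstructions
correlate with the noise-free single-component ground truth at r² ≈ 0.99 —
even though the ERS–ERD latency spread here (sd 0.125 s) makes the two
components inseparable by epoch averaging. `res.response("ers").plot()`
displays the image; `res.comparator_average("ers")` gives the conventional
epoch average for comparison.

A command-line interface mirrors the pipeline:

```sh
tfdeconv simulate --seed 0 --out sim/
tfdeconv spectrogram --signal sim/signal.h5 --out power.h5
tfdeconv fit --power power.h5 --events sim/events.tsv --out fit/
tfdeconv select-basis --power power.h5 --events sim/events.tsv --out sel/
```

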