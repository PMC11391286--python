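# Methods

This note documents the models and procedures implemented in
`roostcall`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the package's numerical
conventions.

## Acoustic chain

Each roost-night is summarized once per second as band-integrated
power. Non-overlapping 1-s frames aligned to the recording start are
estimated by Welch's method (Hann windows, segment length 1024 at
8 kHz), the PSD is integrated over the analysis band by the trapezoid
rule, and the result expressed as 10·log₁₀(power) with a floor of
−120 dB for zero-power frames (determinism on silent input). A partial
trailing frame is dropped. The call band is 1000–3000 Hz, wide enough
to capture corvid calls while limiting overlap with low-frequency
anthropogenic noise; background noise is quantified over 0–4000 Hz.

**Noise reduction** is deterministic STFT spectral gating (FFT 1024,
hop 512, Hann, one-sided): a per-bin gate is set at 3.0 × the mean
magnitude of a reference noise profile, bins at or below the gate are
attenuated by the requested depth (default 6 dB), bins above pass
unchanged, and overlap-add inversion reconstructs the waveform at the
exact input length. The sensitivity of 3.0 was chosen so that the
*realized* broadband attenuation of stationary noise matches the
requested depth: bin magnitudes of Gaussian noise are Rayleigh
distributed, and a gate at 3× the mean magnitude leaves under 1% of
noise *energy* ungated (measured reduction ≈ 5.9 dB of a requested
6 dB), whereas a gate at 2× leaves ≈ 18% ungated and only ≈ 4 dB
realized. Calls even a few dB above the gate pass with < 0.1 dB loss.
The nightly profile defaults to a 5-min call-free stretch starting
62.5% into the recording (02:00 on a 16:00 start); the
background-noise measurement instead profiles the calling-dense
arrival period, so that residual calls — not the noise being
measured — are what the gate attenuates.

**Trimming and normalization.** The series is cut to the occupied
period: from the argmax over the first 2 h (roost arrival peak)
through the argmax over the last 2.5 h (departure peak), inclusive;
ties break to the earliest index. nPSD is per-night min–max scaling to
[0, 1]; a constant series maps to zeros. Min–max was chosen over
z-scoring because the fixed calling thresholds (0.2 / 0.4) are only
meaningful on a unit scale, and because it exactly absorbs the
constant dB offset produced by recorder placement — `normalize_night`
is invariant to any flat gain on the waveform, which is the stated
purpose of normalization.

## Per-night statistics

Settling and pre-departure slopes are plain OLS slopes of nPSD against
time in seconds over the first 3600 s and last 5400 s of the trimmed
series, reported per hour (×3600), in normalized dB h⁻¹. Positive
settling slopes (birds failing to quieten) are retained, not
discarded. The night-calling proportion is the fraction of seconds at
or above the threshold between 1 h after the trimmed start (the
settling window, taken as the operational end of settling) and 1.5 h
before the trimmed end. The onset of continuous departure calling —
identified by eye in field practice — gets a deterministic surrogate:
the first second of the final 1.5 h whose nPSD stays ≥ 0.2 for 60
consecutive seconds (run length scaled with the window under time
compression), falling back to the window start.

## Departure grouping

Events are clustered greedily, left to right, within each 8-sector
compass direction: a cluster opens at the first unassigned event and
absorbs subsequent same-direction events while each inter-event gap is
< 2 s *and* the absorbed event lies ≤ 10 s after the cluster's first
event. Clusters totalling ≥ 2 birds are group departures; single-bird
clusters are singletons that still count toward emptying time. The
10-s window is anchored at the cluster's first event (not rolling),
which implements both stated clauses of the rule and is deterministic;
events in different compass sectors never merge. The rule is verified
against an independent longest-feasible-prefix brute force. Cohesion
is the largest group's share of the roost; emptying time spans the
first to the last event.

## Mixed models

Each response is a Gaussian LMM with crossed random intercepts for
site and month, fitted by maximum likelihood (ML — required for valid
likelihood-ratio comparisons across fixed-effect specifications;
crossed intercepts are expressed as variance components over a single
all-data group). Predictors are centred and scaled to sample SD 1
within the complete-case subset — binary rain included — so
coefficients are per-SD effect sizes; proportions are
logit-transformed with clamping at ε = 1e-3 to keep exact 0/1 finite.
Single-term deletion refits the model without each fixed effect and
reports χ² = 2(ℓ_full − ℓ_reduced) on 1 df, its p-value and
ΔAIC = AIC_reduced − AIC_full; VIFs come from the fixed-effect design
matrix. Non-convergence is flagged on the report, not raised; the
L-BFGS fit falls back to Powell. The five prediction models take
background noise in the response-relevant window plus roost size,
mean temperature, mean windspeed and rain; the two departure models
(cohesion, emptying time) additionally take the overnight-calling
proportion. Three "four-site" variants refit the acoustic models with
mean light as an extra predictor while excluding a named (most urban)
site. No multiple-testing correction is applied across the five
models; this matches the reporting convention the suite emulates and
is a known limitation.

## Synthetic generators

`simulate_night` superimposes call transients on coloured background
noise. Calls are 0.2–0.5 s linear chirps sweeping the inner 80% of the
call band under a Hann envelope (≥ 90% of their energy in-band), with
per-call amplitude jitter of ±6 dB emulating caller distance and
orientation — it is this jitter that makes the 0.4 threshold genuinely
more conservative than 0.2. Call times follow an inhomogeneous Poisson
process discretized to 1-s bins: a linear rate decay from the arrival
peak (default 7200 → 30 calls/h at 7200 calls/h per hour), homogeneous
night calling (30 calls/h), and a linear crescendo (2000 calls/h per
hour over the final 1.5 h) that ceases at the departure anchor. Noise
is white noise low-passed to the noise band (a no-op at the default
8 kHz rate, whose Nyquist equals the 4 kHz band edge), with an
optional piecewise-constant level schedule and an optional < 1 kHz
"anthropogenic" component for masking experiments. All randomness
flows from the scenario's single integer seed.

Full-scale nights (16 h at 8 kHz) are impractically large for routine
testing, so `NightScenario.compressed(factor)` divides all times and
multiplies all rates by the factor, preserving expected per-phase call
counts; `PipelineConfig.scaled(factor)` shrinks every analysis window
consistently. The tests and the acceptance runs use factor 240 (4-min
nights). One regime change under compression is worth knowing: at high
compression the quiet phase holds ≥ 1 call/s, so the per-second dB
series saturates at the call level and its slope responds only weakly
to the planted crescendo steepness; monotonicity of the pre-departure
slope in the planted ramp is therefore checked in the sparse-calling
regime (per-second call probability sweeping ~0.05 → 1), which is also
the regime of full-scale recordings.

What the generator does *not* emulate: realistic corvid call spectra
or syntax, spatial acoustics and reverberation, multi-recorder
geometry, wind/rain transients, or diurnal drift of the noise floor.
Passing tests therefore demonstrate that the pipeline measures what it
claims on signals with the stated structure — not that the fixed
thresholds are optimal for any particular field deployment.

`simulate_events` plants groups as single-bird events whose
consecutive gaps stay below the segmentation gap and whose span stays
within the window, with distinct same-direction clusters separated by
at least the planted gap; it raises on layouts that violate
separability ("overlapping groups") and returns the planted partition
for round-trip checks. `simulate_season` draws night-level covariates
uniformly from configurable ranges (roost size 90–1500 with ±10%
nightly jitter, temperature −2–12 °C, wind 0–12, rain p = 0.4, light
0.1–50 lux, noise means 0.05–0.6), adds crossed Gaussian site/month
intercepts (SD 0.3 / 0.2) and residual noise (SD 0.5), and plants two
pathways: scaled overnight noise → logit night-calling proportion
(default β = 0.4) and scaled night calling → pre-departure slope
(default β = −0.3). Cohesion and emptying time share the latter
pathway's structure. Defaults (5 sites × 24 nights = 120) give the
planted-β estimator an SE near 0.05, so sign recovery is essentially
certain and the mean estimate sits well within 25% of truth.

## Numerical conventions and degenerate inputs

- dB floor −120 (power floor 1e-12) for silent frames; argmax ties
  earliest; constant series normalize to zeros.
- Logit clamping ε = 1e-3; inverse logit via `scipy.special.expit`.
- Zero-variance predictors raise with the offending column named.
- Scaling uses sample SD (ddof = 1).
- Audio: stereo is downmixed by channel average; 8/16/32-bit integer
  PCM rescaled to [−1, 1]; 16-bit written, with peak normalization
  only when the waveform exceeds full scale.
- Time-compressed configs round windows to ≥ 1 s and keep noise
  profiles ≥ 10 s.

## Problem sizes

The test suite and acceptance script run on: 4-min compressed nights
(factor 240; 50-night batches for threshold monotonicity), 900 random
event sets plus 100 planted scenarios for segmentation agreement, 100
simulated seasons for effect recovery and Wald coverage, and 200
seasons for drop1 null calibration. These sizes give the binomial and
KS checks comfortable resolution while keeping a full run to a few
minutes on one CPU.

## Known limitations

- The nPSD normalization and the 0.2/0.4 thresholds are conventions;
  alternative normalizations (e.g. robust quantile scaling) would
  shift threshold semantics.
- The departure-calling-onset heuristic is a surrogate for expert
  spectrogram inspection and will differ from human coding on noisy
  mornings.
- LRT p-values on 1 df are asymptotic; at ~120 nights they are mildly
  anti-conservative (the null-calibration check quantifies this).
- Real deployments involve recorder failure, wind/rain masking and
  inter-site hardware differences that the generator only gestures at
  via noise levels and schedules.
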