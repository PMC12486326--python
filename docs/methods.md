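# Methods

## Model

The analysis treats a passively stretched muscle–tendon unit (MTU) as two
force-bearing elements in parallel:

- **Non-contractile (extramysial) tissue.** An exponential force–length
  element, `F_NC(L) = a·(exp(b·(L−L0)) − 1)` for `L > L0`, zero below.
  `a` (N) sets the scale, `b` (1/mm) the stiffening rate, and `L0` (mm) the
  rest-length offset measured from baseline MTU length. This is the
  simplest form that gives zero force at rest and exponential growth with
  stretch.
- **Contractile tissue.** A linear spring–dashpot,
  `F_C = max(k·L + c·v, 0)` with stiffness `k` (N/mm) and viscosity `c`
  (N·s/mm). Passive contractile mechanics are not otherwise constrained by
  the data this package emulates; linear viscoelasticity is the minimal
  model that produces the force/yank velocity scaling the de-mixing
  analysis relies on. Saturation or nonlinearity of the real tissue is a
  known unknown; linearity here is a modelling choice.

Total force is `F_MTU = F_C + F_NC`, enforced pointwise in every simulated
trial. Yank is `Ẏ = dF_C/dt`, computed by second-order central differences
on the trial grid.

Afferent firing is linear in contractile force and rectified yank:

    rate = force_gain·F_C + yank_gain·max(Ẏ, 0) + offset + background

half-wave rectified at zero. Yank is rectified because the encoding gains
are all non-negative and release phases would otherwise drive rates
negative; rates, being firing rates, cannot be negative either. Group Ib
(tendon organ) encoders use the force term only. An optional Ia
initial-burst term adds extra yank drive during a 20 ms window after force
onset; its magnitude and shape are not constrained by the data this package
emulates, so it defaults to off.

### Default parameters

| parameter | value | units | rationale |
|---|---|---|---|
| stretch amplitude | 3 | mm | standard protocol |
| hold duration | 1 | s | standard protocol |
| ramp velocities | 15, 17.1, 20, 24, 30 | mm/s | standard protocol |
| repetitions | 3 per velocity (15 trials) | — | standard protocol |
| trial sample rate | 1780 | Hz | processed-recording rate |
| corner smoothing | 10 | ms | finite servo acceleration; keeps yank finite |
| `a`, `b`, `L0` | 0.05, 1.0, 0.0 | N, 1/mm, mm | ~1 N non-contractile force at 3 mm, plausible for rat triceps surae |
| `k`, `c` | 0.2, 0.005 | N/mm, N·s/mm | ~0.6 N elastic contractile force at full stretch; viscous transient keeps peak Ia rates below ~1100 spikes/s |
| Ia gains | 337.8, 33.6 | spikes/(N·s), spikes·s⁻¹/(N/s) | published spindle gain-matrix row 1 |
| II gains | 182.8, 4.9 | same | published row 2 |
| Ib force gain | 128.8 | spikes/(N·s) | published tendon-organ gain |

With these defaults peak contractile force is ~0.66–0.72 N across the five
velocities and peak rates are ~530–1060 (Ia), ~380 (II) and ~95 (Ib)
spikes/s — physiologically plausible magnitudes.

## Signal processing

Raw traces recorded at 17.8 kHz are decimated by 10 to 1.78 kHz behind a
zero-phase 8th-order Butterworth anti-alias filter at 0.45 of the output
rate (DC preserved exactly), then low-passed with a 4th-order Butterworth
at 100 Hz applied forward–backward. Zero-phase filtering is used throughout
because phase lag would misalign mechanics against firing rates; the
magnitude response is consequently that of an 8th-order filter.
Derivatives use a 2nd-order Savitzky–Golay filter with a 51-sample window
(~29 ms at 1.78 kHz): exact for quadratics at interior samples, polynomial
extrapolation at the edges.

Instantaneous firing rates are 1/ISI, stamped at the later spike of each
interval (the instant the rate becomes known), then linearly interpolated
onto a 1 kHz grid. The grid origin is the first recorded spike after
stretch onset (typically the Ia initial burst, earliest across the three
afferents of a trial); stretch onset itself is the first sample where the
length change exceeds 1% of the protocol amplitude — made explicit because
onset detection on arbitrary data is otherwise underdetermined. Traces
initialize at zero, or at the last pre-stretch rate when tonic background
firing is configured; after the final sample the last value is held
constant, which avoids spurious decays during the hold.

Spike emission in the generator is deterministic integrate-to-threshold
(one spike per unit area under the rate curve, crossing times found by
linear interpolation of the cumulative integral). Determinism makes
round-trip tests exact; Gaussian spike-time jitter is available behind a
parameter. The full chain encode → spikes → 1/ISI → interpolate recovers
encoder rates within 5% RMS wherever the rate exceeds 10 spikes/s; the
residual error is rate discretization (each ISI reports the average, not
instantaneous, rate).

## Fitting

Spindle (force, yank) gain pairs are fitted per trial by non-negative least
squares of the rate on `[F_C, max(Ẏ,0)]` with no intercept: the encoding
model has no offset term and its gains are non-negative. An intercept and
an onset-window mask (default 20 ms, for excluding initial-burst samples)
are available for real recordings. NNLS clamps anti-correlated components
to zero rather than returning negative gains. The K matrix is the
arithmetic mean of the per-trial pairs at one ramp velocity (default
15 mm/s), Ia row first; its determinant and condition number are checked
(|det| ≥ 1e-6 in gain units) before any inversion. The default published
matrix has det ≈ −4486.9 — comfortably invertible, but user-supplied
near-singular matrices fail loudly.

The non-contractile parameters and the Ib gain are fitted jointly by
bounded nonlinear least squares on
`k_F,Ib · max(F_MTU − F_NC(L; a,b,L0), 0) − R_Ib` with three seeded starts
to reduce local-minimum risk. The gain is profiled out analytically (for
fixed mechanics the optimal gain is `⟨F_C,R⟩/⟨F_C,F_C⟩`, clipped at zero),
which removes a scale ambiguity from the search. A fit whose best
contractile force is identically zero is flagged degenerate rather than
reported as a gain of zero. For spindle afferents only the rest length is
re-fitted (`refit_rest_length`, bounded 1-D search with an inner NNLS);
scale and rate constants stay shared from the tendon-organ fit.

## De-mixing

`demix_spindle` solves the 2x2 system per sample (direct solve, no explicit
inverse) and attaches det K and the condition number so consumers can judge
noise amplification. Negative force/yank estimates are reported, not
clipped — the de-mixer is a linear estimator and clipping would hide
miscalibration; a `rectified()` view exists for display. `estimate_forces`
is exactly linear in each rate input, so superposition holds and a constant
Ib offset δ (the eccentric-contraction scenario) maps to a constant
self-generated force δ/k_F,Ib. The offset magnitude is a configuration
parameter with no default: the scenario is hypothetical and "very small" is
the only guidance, so no magic number is baked in. Interneuron weights for
the three-afferent response are likewise exposed, not asserted: the
yank-activated, Ib-inhibited "startle" configuration used in tests sets the
Ib weight to cancel the Ia force component, leaving a pure onset response.

Decoded traces can be read as length/velocity surrogates (the static and
dynamic components scale similarly), but the package deliberately does not
rescale force/yank estimates into millimetres; that exploratory mapping is
left to the user.

## What the generator does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
trapezoidal kinematics with finite corner acceleration, a passive force
split satisfying `F_MTU = F_C + F_NC`, afferent rates exactly linear in
force and rectified yank, and optional multiplicative Gaussian rate noise
(seeded, rectified). It does not model history-dependent/thixotropic
intrafusal mechanics, fusimotor (γ) drive, true eccentric contractions,
receptor nonlinearities, or spike-generation stochasticity. Passing tests
therefore demonstrate correctness of the processing/fitting/de-mixing
chain under the linear encoding assumptions — not that real afferents obey
those assumptions; on real recordings the fits quantify, rather than
presume, the quality of the linear model.

## Problem sizes and numerics

Tests and the acceptance script run single trials of the default protocol
(~4300 samples at 1.78 kHz) or the full 15-trial protocol; the de-mix/remix
identity property uses 1000 random gain matrices on 50-sample traces.
Tolerances: machine-precision checks use 1e-9 relative (scaled by the
condition number where a solve is involved); noiseless gain recovery is
asserted at 0.1% or tighter; stochastic recovery with 5% rate noise at 5%.
Ties and degenerate inputs: zero-amplitude protocols, negative gains,
singular matrices and out-of-span epochs raise `ValueError` with the
offending quantity named; sub-2-spike trains and empty rate windows return
empty/constant results with a warning rather than raising.
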