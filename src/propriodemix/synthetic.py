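"""Synthetic ramp–hold–release stretch trials and afferent firing.

This module generates the study conditions the downstream analysis assumes:
trapezoidal muscle–tendon-unit (MTU) length trajectories, a passive force
model split into contractile and non-contractile components, and group
Ia / II / Ib afferent firing rates driven linearly by contractile force and
yank (the time derivative of force).

The default protocol is a 3 mm ramp–hold–release with a 1 s hold at ramp
velocities 15, 17.1, 20, 24 and 30 mm/s, three repetitions each (15 trials),
sampled at 1.78 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_VELOCITIES",
    "StretchProtocol",
    "StretchTrial",
    "MuscleParams",
    "ForceTrace",
    "AfferentParams",
    "SpikeTrain",
    "RateTrace",
    "IA_DEFAULT",
    "II_DEFAULT",
    "IB_DEFAULT",
    "generate_protocol",
    "simulate_forces",
    "encode_afferent",
    "rate_to_spikes",
    "add_noise",
]

#: Ramp velocities of the standard stretch protocol (mm/s).
DEFAULT_VELOCITIES = (15.0, 17.1, 20.0, 24.0, 30.0)


@dataclass(frozen=True)
class StretchProtocol:
    """Parameters of a ramp–hold–release stretch series.

    Attributes
    ----------
    amplitude : float
        Stretch amplitude in mm (peak MTU length change).
    hold_duration : float
        Duration of the plateau at full amplitude, in seconds.
    velocities : tuple of float
        Nominal ramp speeds in mm/s; one block of trials per speed.
    reps_per_velocity : int
        Number of repetitions at each speed.
    baseline_pre, baseline_post : float
        Quiescent time at baseline length before and after the stretch (s).
    sample_rate : float
        Sampling frequency of the generated trial grid (Hz).
    corner_smoothing : float
        Width (s) of the smoothing kernel applied to the trapezoid corners,
        emulating the finite acceleration of a servo motor.  Zero gives the
        ideal trapezoid with stepwise velocity (and impulsive yank).
    """

    amplitude: float = 3.0
    hold_duration: float = 1.0
    velocities: tuple[float, ...] = DEFAULT_VELOCITIES
    reps_per_velocity: int = 3
    baseline_pre: float = 0.5
    baseline_post: float = 0.5
    sample_rate: float = 1780.0
    corner_smoothing: float = 0.01

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0 mm, got {self.amplitude}")
        if any(v <= 0 for v in self.velocities):
            raise ValueError(f"all ramp velocities must be > 0 mm/s, got {self.velocities}")
        if self.reps_per_velocity < 1:
            raise ValueError("reps_per_velocity must be >= 1")
        if self.hold_duration < 0 or self.baseline_pre < 0 or self.baseline_post < 0:
            raise ValueError("durations must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0 Hz")
        if self.corner_smoothing < 0:
            raise ValueError("corner_smoothing must be >= 0 s")
        if self.corner_smoothing > 0 and (
                self.corner_smoothing / 2 > self.baseline_pre
                or self.corner_smoothing / 2 > self.baseline_post):
            raise ValueError("corner_smoothing wider than the baseline epochs")

    @property
    def n_trials(self) -> int:
        return len(self.velocities) * self.reps_per_velocity


@dataclass
class StretchTrial:
    """One ramp–hold–release trial: MTU kinematics on a uniform grid."""

    t: np.ndarray          # s
    L_MTU: np.ndarray      # mm, length change from baseline
    v: np.ndarray          # mm/s, d(L_MTU)/dt
    velocity_label: float  # nominal ramp speed, mm/s
    rep_index: int
    L_fasc: np.ndarray | None = None  # mm, optional fascicle length change

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class MuscleParams:
    """Passive MTU mechanics: exponential non-contractile element in
    parallel with a linear spring–dashpot contractile element.

    Non-contractile force: ``F_NC = nc_scale * (exp(nc_rate*(L-L0)) - 1)``
    for ``L > nc_rest_length``, zero below.  Contractile force:
    ``F_C = max(ce_stiffness*L + ce_viscosity*v, 0)``.
    """

    nc_scale: float = 0.05        # a, N
    nc_rate: float = 1.0          # b, 1/mm
    nc_rest_length: float = 0.0   # L0, mm (relative to baseline length)
    ce_stiffness: float = 0.2     # N/mm
    ce_viscosity: float = 0.005   # N*s/mm

    def __post_init__(self) -> None:
        if self.nc_scale < 0:
            raise ValueError("nc_scale must be >= 0")
        if self.nc_rate <= 0:
            raise ValueError("nc_rate must be > 0")
        if self.ce_stiffness < 0 or self.ce_viscosity < 0:
            raise ValueError("contractile stiffness/viscosity must be >= 0")

    def noncontractile_force(self, L: np.ndarray) -> np.ndarray:
        dL = np.asarray(L, dtype=float) - self.nc_rest_length
        return np.where(dL > 0, self.nc_scale * np.expm1(self.nc_rate * np.clip(dL, 0, None)), 0.0)


@dataclass
class ForceTrace:
    """Total, non-contractile and contractile MTU force plus yank."""

    t: np.ndarray      # s
    F_MTU: np.ndarray  # N
    F_NC: np.ndarray   # N
    F_C: np.ndarray    # N
    Y: np.ndarray      # N/s, dF_C/dt

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class AfferentParams:
    """Linear force/yank encoding gains for one afferent.

    rate = force_gain*F_C + yank_gain*max(Y, 0) + rate_offset
           + background_rate, half-wave rectified if rectify_output.

    Group Ib afferents use the force term only by default.  The optional
    ``initial_burst_gain`` adds an extra yank-driven component restricted to
    ``burst_window`` seconds after force onset, emulating the transient Ia
    initial burst; it is off (0) by default.
    """

    afferent_class: str
    force_gain: float            # spikes/(N*s)
    yank_gain: float = 0.0       # spikes/s per (N/s)
    rate_offset: float = 0.0     # spikes/s
    background_rate: float = 0.0  # spikes/s
    rectify_output: bool = True
    initial_burst_gain: float = 0.0  # spikes/s per (N/s), Ia only
    burst_window: float = 0.02       # s after force onset

    def __post_init__(self) -> None:
        if self.afferent_class not in ("Ia", "II", "Ib"):
            raise ValueError(f"unknown afferent class {self.afferent_class!r}")
        for name in ("force_gain", "yank_gain", "rate_offset",
                     "background_rate", "initial_burst_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.initial_burst_gain > 0 and self.afferent_class != "Ia":
            raise ValueError("initial_burst_gain is only defined for group Ia afferents")


# Published default gains: spindle K-matrix rows (Ia, II) and the Ib force gain.
IA_DEFAULT = AfferentParams("Ia", force_gain=337.8, yank_gain=33.6)
II_DEFAULT = AfferentParams("II", force_gain=182.8, yank_gain=4.9)
IB_DEFAULT = AfferentParams("Ib", force_gain=128.8, yank_gain=0.0)


@dataclass
class RateTrace:
    """An instantaneous firing rate on a uniform time grid."""

    t: np.ndarray
    rate: np.ndarray
    afferent_class: str | None = None
    velocity_label: float | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def copy(self) -> "RateTrace":
        return RateTrace(self.t.copy(), self.rate.copy(),
                         self.afferent_class, self.velocity_label)


@dataclass
class SpikeTrain:
    """Sorted spike times for one afferent on one trial."""

    spike_times: np.ndarray  # s, strictly increasing
    afferent_class: str | None = None
    velocity_label: float | None = None

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.size > 1 and not np.all(np.diff(st) > 0):
            raise ValueError("spike times must be strictly increasing")
        self.spike_times = st

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def _trapezoid(t: np.ndarray, onset: float, amplitude: float,
               velocity: float, hold: float) -> tuple[np.ndarray, np.ndarray]:
    """Length and velocity of a ramp–hold–release starting at `onset`."""
    ramp = amplitude / velocity
    t1, t2, t3 = onset + ramp, onset + ramp + hold, onset + 2 * ramp + hold
    L = np.piecewise(
        t,
        [t < onset, (t >= onset) & (t < t1), (t >= t1) & (t < t2), (t >= t2) & (t < t3)],
        [0.0,
         lambda x: velocity * (x - onset),
         amplitude,
         lambda x: amplitude - velocity * (x - t2),
         0.0],
    )
    v = np.piecewise(
        t,
        [t < onset, (t >= onset) & (t < t1), (t >= t1) & (t < t2), (t >= t2) & (t < t3)],
        [0.0, velocity, 0.0, -velocity, 0.0],
    )
    return L, v


def generate_protocol(config: StretchProtocol) -> list[StretchTrial]:
    """Generate one trapezoidal stretch trial per (velocity, repetition).

    Each trial is baseline -> ramp up at v -> hold at `amplitude` ->
    ramp down at v -> baseline.  All trials of one velocity are identical
    apart from their ``rep_index``; variability enters later through the
    noise model.

    Returns
    -------
    list of StretchTrial, ordered by velocity block then repetition.
    """
    trials: list[StretchTrial] = []
    dt = 1.0 / config.sample_rate
    kernel = None
    if config.corner_smoothing > 0:
        m = int(round(config.corner_smoothing * config.sample_rate))
        if m >= 2:
            kernel = np.hanning(m + 2)[1:-1]
            kernel /= kernel.sum()
    for vel in config.velocities:
        ramp = config.amplitude / vel
        total = config.baseline_pre + 2 * ramp + config.hold_duration + config.baseline_post
        n = int(round(total / dt)) + 1
        t = np.arange(n) * dt
        L, v = _trapezoid(t, config.baseline_pre, config.amplitude, vel,
                          config.hold_duration)
        if kernel is not None:
            # same kernel on L and v keeps v the derivative of L
            L = np.convolve(L, kernel, mode="same")
            v = np.convolve(v, kernel, mode="same")
        for rep in range(config.reps_per_velocity):
            trials.append(StretchTrial(t=t.copy(), L_MTU=L.copy(), v=v.copy(),
                                       velocity_label=vel, rep_index=rep,
                                       L_fasc=L.copy()))
    return trials


def simulate_forces(trial: StretchTrial, params: MuscleParams | None = None) -> ForceTrace:
    """Compute the passive force decomposition for one stretch trial.

    The total MTU force is the sum of a non-contractile exponential
    force–length element and a contractile linear spring–dashpot, both
    floored at zero (passive tissue cannot push).  Yank is the numerical
    time derivative of the contractile force.
    """
    params = params or MuscleParams()
    F_NC = params.noncontractile_force(trial.L_MTU)
    F_C = np.clip(params.ce_stiffness * trial.L_MTU + params.ce_viscosity * trial.v, 0.0, None)
    F_MTU = F_C + F_NC
    Y = np.gradient(F_C, trial.t)
    return ForceTrace(t=trial.t.copy(), F_MTU=F_MTU, F_NC=F_NC, F_C=F_C, Y=Y)


def encode_afferent(force: ForceTrace, params: AfferentParams,
                    velocity_label: float | None = None) -> RateTrace:
    """Drive an afferent firing rate from contractile force and yank.

    The rate is ``force_gain*F_C + yank_gain*max(Y,0)`` plus any offset and
    background, half-wave rectified at zero when ``rectify_output`` is set.
    Yank is rectified because the encoding gains are non-negative and release
    phases would otherwise drive the rate negative.
    """
    rate = (params.force_gain * force.F_C
            + params.yank_gain * np.clip(force.Y, 0.0, None)
            + params.rate_offset + params.background_rate)
    if params.initial_burst_gain > 0:
        onset_idx = np.argmax(force.F_C > 0)
        if force.F_C[onset_idx] > 0:
            t_on = force.t[onset_idx]
            in_burst = (force.t >= t_on) & (force.t < t_on + params.burst_window)
            rate = rate + np.where(in_burst,
                                   params.initial_burst_gain * np.clip(force.Y, 0.0, None),
                                   0.0)
    if params.rectify_output:
        rate = np.clip(rate, 0.0, None)
    return RateTrace(t=force.t.copy(), rate=rate,
                     afferent_class=params.afferent_class,
                     velocity_label=velocity_label)


def rate_to_spikes(rate: RateTrace, seed: int | None = None,
                   jitter_sd: float = 0.0) -> SpikeTrain:
    """Emit spikes by deterministic integrate-to-threshold.

    A spike is emitted each time the running integral of the rate crosses
    the next whole unit, so 1/ISI reconstructs the rate up to discretization
    error.  ``seed`` only matters when ``jitter_sd`` > 0, which adds
    Gaussian timing jitter (s) to each spike while preserving ordering.
    """
    r = np.asarray(rate.rate, dtype=float)
    if np.any(r < 0):
        raise ValueError("rate_to_spikes requires a non-negative rate")
    t = rate.t
    # cumulative spike count; linear interpolation of the crossing time
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (r[1:] + r[:-1]) * np.diff(t))])
    n_spikes = int(np.floor(cum[-1] + 1e-9))
    if n_spikes < 1:
        return SpikeTrain(np.empty(0), rate.afferent_class, rate.velocity_label)
    thresholds = np.arange(1, n_spikes + 1, dtype=float)
    spike_times = np.interp(thresholds, cum, t)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        spike_times = np.sort(spike_times + rng.normal(0.0, jitter_sd, n_spikes))
    return SpikeTrain(spike_times, rate.afferent_class, rate.velocity_label)


def add_noise(rate: RateTrace, cv: float, seed: int) -> RateTrace:
    """Multiplicative Gaussian perturbation of a rate trace.

    Each sample is scaled by ``1 + cv*z`` with iid standard-normal ``z``,
    then rectified at zero.  ``cv=0`` returns an identical copy; identical
    seeds give bit-identical output.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    out = rate.copy()
    if cv == 0:
        return out
    rng = np.random.default_rng(seed)
    out.rate = np.clip(out.rate * (1.0 + cv * rng.standard_normal(out.rate.size)), 0.0, None)
    return out
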