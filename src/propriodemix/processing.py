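"""Signal conditioning: decimation, zero-phase low-pass filtering,
Savitzky–Golay derivatives, and instantaneous-firing-rate (IFR) traces.

The standard chain for mechanical traces is: decimate 17.8 kHz recordings by
a factor of 10 to 1.78 kHz, low-pass with a fourth-order Butterworth at
100 Hz (applied forward–backward, so zero phase), and differentiate with a
second-order Savitzky–Golay filter over a 51-sample window (~29 ms at
1.78 kHz).  Spike trains are converted to per-spike 1/ISI samples and
linearly interpolated onto a 1 kHz grid whose origin is the first spike
after stretch onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import RateTrace, SpikeTrain

__all__ = [
    "FilterSpec",
    "IfrSamples",
    "AlignedGroup",
    "downsample",
    "lowpass",
    "sg_derivative",
    "spikes_to_ifr",
    "interpolate_ifr",
    "align_by_velocity",
]

IFR_GRID_RATE = 1000.0  # Hz, grid for interpolated firing rates


@dataclass(frozen=True)
class FilterSpec:
    """Filtering/differentiation settings for mechanical traces."""

    butterworth_order: int = 4
    cutoff: float = 100.0       # Hz
    sg_polyorder: int = 2
    sg_window: int = 51         # samples
    decimation_factor: int = 10

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.butterworth_order < 1 or self.decimation_factor < 1:
            raise ValueError("filter order and decimation factor must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0 Hz")


def downsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Decimate a uniformly sampled trace by an integer factor.

    Anti-alias filtering (zero-phase 8th-order Butterworth at 0.45 of the
    post-decimation sample rate) precedes subsampling, so DC is preserved
    exactly and no phase lag is introduced.  Output length is
    ``ceil(n/factor)``.
    """
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    x = np.asarray(x, dtype=float)
    if factor == 1:
        return x.copy()
    sos = sps.butter(8, 0.9 / factor, btype="low", output="sos")
    return sps.sosfiltfilt(sos, x)[::factor]


def lowpass(x: np.ndarray, sample_rate: float,
            spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Forward–backward application doubles the magnitude roll-off (effective
    8th order for the default 4th-order design) and cancels phase lag, which
    keeps mechanical traces time-aligned with firing rates.  DC gain is 1.
    """
    spec = spec or FilterSpec()
    nyq = sample_rate / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(spec.butterworth_order, spec.cutoff, btype="low",
                     fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def sg_derivative(x: np.ndarray, sample_rate: float,
                  spec: FilterSpec | None = None) -> np.ndarray:
    """Savitzky–Golay first derivative, in signal units per second.

    Exact (to round-off) for polynomials up to ``sg_polyorder`` at interior
    samples; edges are handled by polynomial fit extrapolation.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if spec.sg_window > x.size:
        raise ValueError(f"sg_window {spec.sg_window} longer than signal ({x.size} samples)")
    return sps.savgol_filter(x, spec.sg_window, spec.sg_polyorder,
                             deriv=1, delta=1.0 / sample_rate, mode="interp")


@dataclass
class IfrSamples:
    """Event-indexed instantaneous rates: one sample per ISI, stamped at the
    later spike of the interval (when the rate becomes known)."""

    t: np.ndarray     # s
    rate: np.ndarray  # spikes/s
    afferent_class: str | None = None
    velocity_label: float | None = None


def spikes_to_ifr(spikes: SpikeTrain) -> IfrSamples:
    """Convert spike times to per-spike 1/ISI rate samples."""
    st = spikes.spike_times
    if st.size < 2:
        warnings.warn("fewer than 2 spikes: no instantaneous rate defined",
                      stacklevel=2)
        return IfrSamples(np.empty(0), np.empty(0),
                          spikes.afferent_class, spikes.velocity_label)
    isi = np.diff(st)
    return IfrSamples(st[1:].copy(), 1.0 / isi,
                      spikes.afferent_class, spikes.velocity_label)


def interpolate_ifr(samples: IfrSamples, window: tuple[float, float],
                    background_rate: float | None = None,
                    grid_rate: float = IFR_GRID_RATE) -> RateTrace:
    """Linearly interpolate event-indexed rates onto a uniform grid.

    The grid spans ``window`` (start at the first recorded spike after
    stretch onset — typically the group Ia initial burst — through the end
    of the analysis epoch).  The trace is initialized at zero, or at
    ``background_rate`` (the last instantaneous rate recorded before the
    stretch) when the afferent fires tonically at rest.  After the final
    sample the last value is held constant.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    grid = t0 + np.arange(int(np.floor((t1 - t0) * grid_rate)) + 1) / grid_rate
    init = 0.0 if background_rate is None else float(background_rate)
    if samples.t.size == 0:
        warnings.warn("no rate samples in window: returning constant trace",
                      stacklevel=2)
        return RateTrace(grid, np.full(grid.size, init),
                         samples.afferent_class, samples.velocity_label)
    # anchor at window start unless a sample already sits there
    if samples.t[0] > t0:
        tk = np.concatenate([[t0], samples.t])
        rk = np.concatenate([[init], samples.rate])
    else:
        tk, rk = samples.t, samples.rate
    rate = np.interp(grid, tk, rk)  # np.interp holds the edge values
    return RateTrace(grid, rate, samples.afferent_class, samples.velocity_label)


@dataclass
class AlignedGroup:
    """Rate traces of each afferent class aligned on one grid, per velocity."""

    velocity_label: float
    t: np.ndarray
    rates: dict[str, np.ndarray]  # class -> rate, all of len(t)
    complete: bool                # True when Ia, II and Ib are all present


def align_by_velocity(traces: list[RateTrace],
                      required_classes: tuple[str, ...] = ("Ia", "II", "Ib"),
                      ) -> dict[float, AlignedGroup]:
    """Group rate traces by nominal ramp velocity on a shared grid.

    Within a velocity group all traces are truncated to the shortest member
    and re-referenced to a common time origin (each trace's own first
    sample).  A group missing any required afferent class is flagged
    incomplete rather than dropped.
    """
    by_vel: dict[float, list[RateTrace]] = {}
    for tr in traces:
        if tr.velocity_label is None:
            raise ValueError("every trace needs a velocity_label for alignment")
        by_vel.setdefault(float(tr.velocity_label), []).append(tr)

    groups: dict[float, AlignedGroup] = {}
    for vel, members in sorted(by_vel.items()):
        n = min(m.t.size for m in members)
        dt = members[0].dt
        grid = np.arange(n) * dt
        stacks: dict[str, list[np.ndarray]] = {}
        for m in members:
            stacks.setdefault(m.afferent_class or "unknown", []).append(m.rate[:n])
        # repeats of one class at one velocity are averaged
        rates = {cls: np.mean(reps, axis=0) for cls, reps in stacks.items()}
        complete = all(c in rates for c in required_classes)
        groups[vel] = AlignedGroup(velocity_label=vel, t=grid, rates=rates,
                                   complete=complete)
    return groups
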