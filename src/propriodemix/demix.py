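"""Linear de-mixing of afferent firing rates into mechanical state variables.

Two computations:

* Spindle de-mixing — invert the 2x2 gain matrix K to map group Ia and II
  firing rates back onto estimates of contractile force and yank:
  ``[F_est; Y_est] = K^-1 [R_Ia; R_II]``, sample by sample.
* Spindle/tendon-organ decomposition — divide the group II rate by its
  force gain to estimate externally imposed force (F_EI), divide the group
  Ib rate by its force gain to estimate total contractile force (F_C), and
  subtract to expose the self-generated force F_SG = F_C - F_EI.  During a
  purely passive stretch the two estimates cancel; an eccentric contraction
  (modelled as a small constant offset on the Ib rate) leaves a nonzero
  F_SG.

Negative estimates are reported, not clipped: the de-mixers are linear
estimators and clipping would hide miscalibration.  A rectified view is
available for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import DET_FLOOR, ForceGains, GainMatrix
from .synthetic import RateTrace

__all__ = [
    "DemixResult",
    "ForceDecomposition",
    "EccentricScenario",
    "InterneuronWeights",
    "demix_spindle",
    "estimate_forces",
    "apply_eccentric",
    "interneuron_response",
]


@dataclass
class DemixResult:
    """Force/yank estimates decoded from spindle rates, with conditioning."""

    t: np.ndarray
    F_est: np.ndarray   # N
    Y_est: np.ndarray   # N/s
    det_K: float
    condition_number: float
    velocity_label: float | None = None

    def rectified(self) -> "DemixResult":
        """Clipped-at-zero copy, for display parity with rate plots."""
        return DemixResult(self.t, np.clip(self.F_est, 0, None),
                           np.clip(self.Y_est, 0, None),
                           self.det_K, self.condition_number,
                           self.velocity_label)


@dataclass
class ForceDecomposition:
    """Externally imposed, contractile and self-generated force estimates."""

    t: np.ndarray
    F_EI_est: np.ndarray  # N, from group II
    F_C_est: np.ndarray   # N, from group Ib
    F_SG_est: np.ndarray  # N, F_C_est - F_EI_est


@dataclass(frozen=True)
class EccentricScenario:
    """Hypothetical eccentric contraction: a constant Ib rate offset.

    ``epoch`` bounds the interval (s) over which the offset applies; None
    means the full trace.
    """

    delta_R_Ib: float                       # spikes/s
    epoch: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.delta_R_Ib < 0:
            raise ValueError("Ib rate offset must be >= 0")


@dataclass(frozen=True)
class InterneuronWeights:
    """Signed weights of a hypothetical interneuron summing Ia/II/Ib input."""

    w_Ia: float
    w_II: float
    w_Ib: float
    rectify: bool = True

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.w_Ia, self.w_II, self.w_Ib])):
            raise ValueError("interneuron weights must be finite")


def _check_aligned(*traces: RateTrace) -> None:
    t0 = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0):
            raise ValueError("rate traces must share one time grid; "
                             "align them first")


def demix_spindle(R_Ia: RateTrace, R_II: RateTrace, K: GainMatrix,
                  det_floor: float = DET_FLOOR) -> DemixResult:
    """Estimate force and yank by inverting the spindle gain matrix.

    Solves ``K [F; Y] = [R_Ia; R_II]`` per sample (a direct 2x2 solve, not
    an explicit inverse).  Fails if the rates are on different grids or K is
    numerically singular; determinant and condition number are attached to
    the result so downstream consumers can judge amplification of rate
    noise.
    """
    _check_aligned(R_Ia, R_II)
    K.require_invertible(det_floor)
    est = np.linalg.solve(K.matrix, np.vstack([R_Ia.rate, R_II.rate]))
    return DemixResult(t=R_Ia.t.copy(), F_est=est[0], Y_est=est[1],
                       det_K=K.det, condition_number=K.condition_number,
                       velocity_label=R_Ia.velocity_label)


def estimate_forces(R_II: RateTrace, R_Ib: RateTrace,
                    gains: ForceGains) -> ForceDecomposition:
    """Decompose contractile force into external and self-generated parts.

    ``F_EI = R_II / kF_II`` (spindles signal the stretch-imposed force),
    ``F_C = R_Ib / kF_Ib`` (tendon organs signal total contractile force),
    and ``F_SG = F_C - F_EI``.  Linear in each rate input.
    """
    _check_aligned(R_II, R_Ib)
    f_ei = R_II.rate / gains.kF_II
    f_c = R_Ib.rate / gains.kF_Ib
    return ForceDecomposition(t=R_II.t.copy(), F_EI_est=f_ei, F_C_est=f_c,
                              F_SG_est=f_c - f_ei)


def apply_eccentric(R_Ib: RateTrace, scenario: EccentricScenario) -> RateTrace:
    """Add the eccentric-contraction rate offset to a group Ib trace."""
    out = R_Ib.copy()
    if scenario.epoch is None:
        out.rate = out.rate + scenario.delta_R_Ib
        return out
    start, stop = scenario.epoch
    if start >= stop:
        raise ValueError("epoch start must precede epoch end")
    if start > R_Ib.t[-1] or stop < R_Ib.t[0]:
        raise ValueError(
            f"epoch ({start}, {stop}) s lies outside the trace span "
            f"({R_Ib.t[0]:.3f}, {R_Ib.t[-1]:.3f}) s")
    mask = (out.t >= start) & (out.t <= stop)
    out.rate = out.rate + np.where(mask, scenario.delta_R_Ib, 0.0)
    return out


def interneuron_response(R_Ia: RateTrace, R_II: RateTrace, R_Ib: RateTrace,
                         w: InterneuronWeights) -> RateTrace:
    """Weighted sum of the three afferent rates, optionally rectified.

    With a positive Ia weight and a negative Ib weight the response is
    driven by stretch yank and inhibited by muscle force — a 'startle'
    unit that fires at sudden external stretch onset and is quenched during
    the hold.
    """
    _check_aligned(R_Ia, R_II, R_Ib)
    r = w.w_Ia * R_Ia.rate + w.w_II * R_II.rate + w.w_Ib * R_Ib.rate
    if w.rectify:
        r = np.clip(r, 0.0, None)
    return RateTrace(R_Ia.t.copy(), r, afferent_class=None,
                     velocity_label=R_Ia.velocity_label)
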