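"""Fitting afferent encoding models to firing rates.

Three estimators live here:

* :func:`fit_force_yank_gains` — non-negative least squares of a firing
  rate on contractile force and rectified yank, giving a (force, yank)
  gain pair for a spindle afferent (Ia or II).
* :func:`fit_noncontractile` — joint bounded optimization of the
  exponential non-contractile force–length parameters and the Golgi tendon
  organ (Ib) force gain against an Ib firing rate.
* :func:`assemble_K` — averages per-trial spindle gain pairs at one ramp
  velocity into the 2x2 gain matrix K whose inverse de-mixes force and yank
  from Ia/II rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .synthetic import MuscleParams, RateTrace

__all__ = [
    "GainMatrix",
    "ForceGains",
    "FitResult",
    "TrialGains",
    "fit_force_yank_gains",
    "fit_noncontractile",
    "refit_rest_length",
    "assemble_K",
]

#: determinant magnitude below which a gain matrix is treated as singular
DET_FLOOR = 1e-6


@dataclass(frozen=True)
class GainMatrix:
    """The 2x2 spindle gain matrix K.

    Row 1 is the group Ia (force, yank) gain pair; row 2 the group II pair.
    Units: force gains spikes/(N*s); yank gains spikes/s per (N/s).
    """

    k11: float
    k12: float
    k21: float
    k22: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if min(self.k11, self.k12, self.k21, self.k22) < 0:
            raise ValueError("gain matrix entries must be >= 0")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.k11, self.k12], [self.k21, self.k22]])

    @property
    def det(self) -> float:
        return self.k11 * self.k22 - self.k12 * self.k21

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def require_invertible(self, det_floor: float = DET_FLOOR) -> None:
        if abs(self.det) < det_floor:
            raise ValueError(
                f"gain matrix is numerically singular: |det| = {abs(self.det):.3g} "
                f"< floor {det_floor:.3g} (condition number {self.condition_number:.3g})")


@dataclass(frozen=True)
class ForceGains:
    """Scalar force gains used for the spindle/tendon-organ decomposition."""

    kF_II: float  # spikes/(N*s)
    kF_Ib: float  # spikes/(N*s)

    def __post_init__(self) -> None:
        if self.kF_II <= 0 or self.kF_Ib <= 0:
            raise ValueError("force gains must be > 0")


@dataclass
class FitResult:
    params: dict
    residual_rms: float          # spikes/s
    variance_explained: float    # fraction of rate variance (about 0)
    degenerate: bool = False
    message: str = ""


@dataclass
class TrialGains:
    """One fitted (force, yank) gain pair with its provenance."""

    afferent_class: str
    velocity_label: float
    force_gain: float
    yank_gain: float
    rep_index: int = 0


def _fit_quality(pred: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    resid = r - pred
    rms = float(np.sqrt(np.mean(resid**2)))
    total = float(np.sum(r**2))
    ve = 1.0 - float(np.sum(resid**2)) / total if total > 0 else 0.0
    return rms, ve


def fit_force_yank_gains(F_C: np.ndarray, Y: np.ndarray,
                         R: RateTrace | np.ndarray,
                         intercept: bool = False,
                         onset_mask: np.ndarray | None = None,
                         ) -> tuple[tuple[float, float], FitResult]:
    """Fit rate = force_gain*F_C + yank_gain*max(Y,0) by non-negative LS.

    The design has no intercept by default — the encoding model has no
    offset term and all gains are non-negative; a background-rate intercept
    is available behind ``intercept`` for real recordings.  ``onset_mask``
    (True = exclude) can drop initial-burst samples from the fit.

    Returns the (force_gain, yank_gain) pair and a :class:`FitResult`.
    """
    r = np.asarray(R.rate if isinstance(R, RateTrace) else R, dtype=float)
    fc = np.asarray(F_C, dtype=float)
    y_rect = np.clip(np.asarray(Y, dtype=float), 0.0, None)
    if onset_mask is not None:
        keep = ~np.asarray(onset_mask, dtype=bool)
        fc, y_rect, r = fc[keep], y_rect[keep], r[keep]
    cols = [fc, y_rect] + ([np.ones_like(fc)] if intercept else [])
    A = np.column_stack(cols)
    # collinearity check on the force/yank columns
    norms = np.linalg.norm(A[:, :2], axis=0)
    if np.all(norms > 0):
        cos = float(A[:, 0] @ A[:, 1] / (norms[0] * norms[1]))
        if cos > 1 - 1e-8:
            warnings.warn("force and rectified yank regressors are collinear; "
                          "gains are not separately identifiable", stacklevel=2)
    coef, _ = optimize.nnls(A, r)
    fg, yg = float(coef[0]), float(coef[1])
    rms, ve = _fit_quality(A @ coef, r)
    params = {"force_gain": fg, "yank_gain": yg}
    if intercept:
        params["offset"] = float(coef[2])
    return (fg, yg), FitResult(params=params, residual_rms=rms,
                               variance_explained=ve)


def _nc_force(L: np.ndarray, a: float, b: float, L0: float) -> np.ndarray:
    dL = L - L0
    return np.where(dL > 0, a * np.expm1(b * np.clip(dL, 0, None)), 0.0)


def fit_noncontractile(L: np.ndarray, F_MTU: np.ndarray,
                       R_Ib: RateTrace | np.ndarray,
                       init: MuscleParams | None = None,
                       n_starts: int = 3, seed: int = 0,
                       ) -> tuple[MuscleParams, float, FitResult]:
    """Fit the exponential non-contractile model plus the Ib force gain.

    Minimizes ``|| kF_Ib * max(F_MTU - F_NC(L; a, b, L0), 0) - R_Ib ||``
    over (a, b, L0) with bounds a >= 0, b > 0, via seeded multi-start
    bounded nonlinear least squares.  The gain kF_Ib is profiled out: for
    any candidate (a, b, L0) the optimal gain has the closed form
    ``<F_C, R>/<F_C, F_C>`` clipped at zero, which removes one dimension
    and a scale ambiguity from the search.

    Returns fitted mechanics (contractile terms carried over from ``init``),
    the Ib gain, and a :class:`FitResult`.  If the best-fit contractile
    force is identically zero the result is flagged degenerate.
    """
    L = np.asarray(L, dtype=float)
    F = np.asarray(F_MTU, dtype=float)
    r = np.asarray(R_Ib.rate if isinstance(R_Ib, RateTrace) else R_Ib, dtype=float)
    init = init or MuscleParams()

    def gain_for(fc: np.ndarray) -> float:
        denom = float(fc @ fc)
        return max(float(fc @ r) / denom, 0.0) if denom > 0 else 0.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, L0 = theta
        fc = np.clip(F - _nc_force(L, a, b, L0), 0.0, None)
        return gain_for(fc) * fc - r

    lo = np.array([0.0, 1e-6, np.min(L) - np.ptp(L)])
    hi = np.array([np.inf, np.inf, np.max(L)])
    x0 = np.clip(np.array([init.nc_scale, init.nc_rate, init.nc_rest_length]),
                 lo, hi)
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        jitter = np.array([x0[0] * rng.uniform(0.3, 3.0) + 0.01,
                           x0[1] * rng.uniform(0.3, 3.0),
                           x0[2] + rng.uniform(-0.5, 0.5) * max(np.ptp(L), 1.0)])
        starts.append(np.clip(jitter, lo, hi))

    best = None
    for s in starts:
        try:
            sol = optimize.least_squares(residuals, s, bounds=(lo, hi),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # pragma: no cover - optimizer failure path
            warnings.warn(f"non-contractile fit start failed: {exc}", stacklevel=2)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("non-contractile fit failed from every start")

    a, b, L0 = best.x
    fc = np.clip(F - _nc_force(L, a, b, L0), 0.0, None)
    k = gain_for(fc)
    rms, ve = _fit_quality(k * fc, r)
    degenerate = bool(np.max(fc) <= 0 or k == 0)
    params = MuscleParams(nc_scale=float(a), nc_rate=float(b),
                          nc_rest_length=float(L0),
                          ce_stiffness=init.ce_stiffness,
                          ce_viscosity=init.ce_viscosity)
    msg = "" if best.success else f"optimizer stopped early: {best.message}"
    if degenerate:
        msg = (msg + "; " if msg else "") + \
            "contractile force identically zero: Ib gain not identifiable"
    result = FitResult(params={"nc_scale": float(a), "nc_rate": float(b),
                               "nc_rest_length": float(L0), "kF_Ib": float(k)},
                       residual_rms=rms, variance_explained=ve,
                       degenerate=degenerate, message=msg)
    return params, float(k), result


def refit_rest_length(L: np.ndarray, F_MTU: np.ndarray,
                      R: RateTrace | np.ndarray,
                      base: MuscleParams, sample_rate: float,
                      ) -> tuple[MuscleParams, tuple[float, float], FitResult]:
    """Re-fit only the non-contractile resting length for a spindle afferent.

    The exponential scale and rate constants are shared from the tendon-organ
    fit; only the rest-length offset is re-optimized (bounded 1-D search)
    so the force–length curve seen by the spindle is shifted, jointly with a
    fresh non-negative (force, yank) gain pair at each candidate offset.
    Useful when spindle and tendon organ sit at different operating points
    on the passive force–length curve.
    """
    L = np.asarray(L, dtype=float)
    F = np.asarray(F_MTU, dtype=float)
    r = np.asarray(R.rate if isinstance(R, RateTrace) else R, dtype=float)

    def design(L0: float) -> np.ndarray:
        fc = np.clip(F - _nc_force(L, base.nc_scale, base.nc_rate, L0), 0.0, None)
        yank = np.gradient(fc, 1.0 / sample_rate)
        return np.column_stack([fc, np.clip(yank, 0.0, None)])

    def cost(L0: float) -> float:
        _, rnorm = optimize.nnls(design(L0), r)
        return rnorm

    lo = float(np.min(L) - np.ptp(L))
    hi = float(np.max(L))
    sol = optimize.minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    L0 = float(sol.x)
    A = design(L0)
    coef, _ = optimize.nnls(A, r)
    rms, ve = _fit_quality(A @ coef, r)
    fitted = replace(base, nc_rest_length=L0)
    result = FitResult(params={"nc_rest_length": L0,
                               "force_gain": float(coef[0]),
                               "yank_gain": float(coef[1])},
                       residual_rms=rms, variance_explained=ve)
    return fitted, (float(coef[0]), float(coef[1])), result


def assemble_K(per_trial_gains: list[TrialGains],
               velocity_filter: float = 15.0,
               det_floor: float = DET_FLOOR) -> GainMatrix:
    """Average per-trial spindle gain pairs into the K matrix.

    Only trials at ``velocity_filter`` (mm/s) enter the average; the Ia
    pair forms row 1 and the II pair row 2.  Invertibility is checked so
    that a near-singular mean matrix fails loudly before de-mixing.
    """
    rows: dict[str, list[tuple[float, float]]] = {"Ia": [], "II": []}
    for g in per_trial_gains:
        if g.afferent_class in rows and np.isclose(g.velocity_label, velocity_filter):
            rows[g.afferent_class].append((g.force_gain, g.yank_gain))
    for cls, pairs in rows.items():
        if not pairs:
            raise ValueError(f"no {cls} gain pairs at {velocity_filter} mm/s")
    (k11, k12) = np.mean(rows["Ia"], axis=0)
    (k21, k22) = np.mean(rows["II"], axis=0)
    K = GainMatrix(float(k11), float(k12), float(k21), float(k22),
                   provenance=f"mean over {len(rows['Ia'])} Ia / "
                              f"{len(rows['II'])} II trials at "
                              f"{velocity_filter} mm/s")
    K.require_invertible(det_floor)
    return K
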