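"""End-to-end orchestration: simulate -> process -> fit -> de-mix -> report.

Each stage reads/writes plain CSV (plus one resolved YAML config per run) so
results are regenerable bit-identically from config + seed, and consumable
outside Python.  The fitting stage operates on the encoder rate traces on
the native trial grid; the spike pathway (spike emission, 1/ISI, 1 kHz
interpolation) is exercised by the processing stage and its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import io as pio
from .demix import (DemixResult, EccentricScenario, ForceDecomposition,
                    apply_eccentric, demix_spindle, estimate_forces)
from .fitting import ForceGains, GainMatrix, TrialGains, assemble_K, \
    fit_force_yank_gains, fit_noncontractile
from .processing import align_by_velocity, interpolate_ifr, spikes_to_ifr
from .synthetic import (IA_DEFAULT, IB_DEFAULT, II_DEFAULT, AfferentParams,
                        MuscleParams, RateTrace, StretchProtocol,
                        add_noise, encode_afferent, generate_protocol,
                        rate_to_spikes, simulate_forces)

__all__ = ["default_config", "run_simulate", "run_process", "run_fit",
           "run_demix", "run_full"]

log = logging.getLogger("propriodemix")

DEFAULT_AFFERENTS = {"Ia": IA_DEFAULT, "II": II_DEFAULT, "Ib": IB_DEFAULT}


def default_config(seed: int = 0, noise_cv: float = 0.0,
                   velocity_filter: float = 15.0,
                   output_dir: str | Path = "results") -> dict:
    return {"protocol": StretchProtocol(), "muscle": MuscleParams(),
            "afferents": dict(DEFAULT_AFFERENTS), "seed": seed,
            "noise_cv": noise_cv, "velocity_filter": velocity_filter,
            "output_dir": str(output_dir)}


def _afferents(cfg: dict) -> dict[str, AfferentParams]:
    affs = dict(DEFAULT_AFFERENTS)
    affs.update(cfg.get("afferents") or {})
    return affs


def _trial_seed(base: int, velocity: float, rep: int, cls: str) -> int:
    # stable per-trial stream, independent of trial ordering
    idx = {"Ia": 0, "II": 1, "Ib": 2}[cls]
    return (int(base) * 1_000_003 + int(round(velocity * 10)) * 101
            + rep * 7 + idx) % (2**31 - 1)


def _encode_trial(trial, force, cfg: dict) -> dict[str, RateTrace]:
    """Ia/II/Ib rates for one trial, with the configured noise level."""
    rates = {}
    for cls, params in _afferents(cfg).items():
        r = encode_afferent(force, params, velocity_label=trial.velocity_label)
        if cfg.get("noise_cv", 0.0) > 0:
            r = add_noise(r, cfg["noise_cv"],
                          _trial_seed(cfg.get("seed", 0), trial.velocity_label,
                                      trial.rep_index, cls))
        rates[cls] = r
    return rates


def run_simulate(cfg: dict, output_dir: str | Path | None = None) -> Path:
    """Write trial CSVs and spike-time files for the configured protocol."""
    outdir = Path(output_dir or cfg["output_dir"]) / "trials"
    outdir.mkdir(parents=True, exist_ok=True)
    trials = generate_protocol(cfg["protocol"])
    log.info("simulate: %d trials at %s mm/s", len(trials),
             list(cfg["protocol"].velocities))
    for trial in trials:
        force = simulate_forces(trial, cfg["muscle"])
        pio.write_trial_csv(
            outdir / pio.trial_filename(trial.velocity_label, trial.rep_index),
            trial, force)
        for cls, rate in _encode_trial(trial, force, cfg).items():
            spikes = rate_to_spikes(rate)
            pio.write_spike_times(
                outdir / f"spikes_{cls}_v{trial.velocity_label:g}_rep{trial.rep_index}.txt",
                spikes)
    pio.dump_config(outdir.parent / "resolved_config.yaml", cfg)
    return outdir


def run_process(cfg: dict, output_dir: str | Path | None = None) -> dict:
    """Spike pathway: 1/ISI rates interpolated to 1 kHz, aligned by velocity.

    The grid origin for each (velocity, repetition) is the first recorded
    spike after stretch onset across the three afferents (typically the
    group Ia).  Stretch onset is taken as the first sample where the length
    change exceeds 1% of the protocol amplitude.
    """
    outdir = Path(output_dir or cfg["output_dir"]) / "aligned"
    outdir.mkdir(parents=True, exist_ok=True)
    proto: StretchProtocol = cfg["protocol"]
    traces: list[RateTrace] = []
    for trial in generate_protocol(proto):
        force = simulate_forces(trial, cfg["muscle"])
        onset_idx = np.argmax(trial.L_MTU > 0.01 * proto.amplitude)
        t_onset = trial.t[onset_idx]
        rates = _encode_trial(trial, force, cfg)
        spike_trains = {cls: rate_to_spikes(r) for cls, r in rates.items()}
        first_spikes = [st.spike_times[st.spike_times >= t_onset][0]
                        for st in spike_trains.values()
                        if np.any(st.spike_times >= t_onset)]
        if not first_spikes:
            log.warning("process: no spikes after onset at v=%g rep=%d",
                        trial.velocity_label, trial.rep_index)
            continue
        t0 = min(first_spikes)
        for cls, st in spike_trains.items():
            samples = spikes_to_ifr(st)
            bg = cfg["afferents"].get(cls, DEFAULT_AFFERENTS[cls]).background_rate \
                if cfg.get("afferents") else DEFAULT_AFFERENTS[cls].background_rate
            tr = interpolate_ifr(samples, (t0, trial.t[-1]),
                                 background_rate=bg if bg > 0 else None)
            tr.afferent_class = cls
            tr.velocity_label = trial.velocity_label
            traces.append(tr)
    groups = align_by_velocity(traces)
    for vel, group in groups.items():
        pio.write_aligned_group(outdir / f"aligned_v{vel:g}.csv", group)
    log.info("process: %d velocity groups (%d complete)", len(groups),
             sum(g.complete for g in groups.values()))
    return groups


@dataclass
class FitBundle:
    K: GainMatrix
    force_gains: ForceGains
    muscle_fit: MuscleParams
    per_trial: list[TrialGains]
    recovery: dict  # relative errors vs generating gains


def run_fit(cfg: dict, output_dir: str | Path | None = None) -> FitBundle:
    """Fit spindle gain pairs, the non-contractile model and the Ib gain.

    Spindle (Ia, II) force/yank pairs are fitted per trial by non-negative
    least squares and averaged at the filter velocity into K.  The Ib gain
    comes from the joint non-contractile fit, initialized away from the
    generating parameters.
    """
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    vfilt = cfg.get("velocity_filter", 15.0)
    affs = _afferents(cfg)
    per_trial: list[TrialGains] = []
    kf_ib_fits: list[float] = []
    muscle_fit = cfg["muscle"]
    for trial in generate_protocol(cfg["protocol"]):
        force = simulate_forces(trial, cfg["muscle"])
        rates = _encode_trial(trial, force, cfg)
        for cls in ("Ia", "II"):
            (fg, yg), _ = fit_force_yank_gains(force.F_C, force.Y, rates[cls])
            per_trial.append(TrialGains(cls, trial.velocity_label, fg, yg,
                                        trial.rep_index))
        if np.isclose(trial.velocity_label, vfilt):
            init = replace(cfg["muscle"],
                           nc_scale=cfg["muscle"].nc_scale * 2 + 0.01,
                           nc_rate=cfg["muscle"].nc_rate * 0.5)
            muscle_fit, k_ib, _ = fit_noncontractile(
                trial.L_MTU, force.F_MTU, rates["Ib"], init=init,
                seed=cfg.get("seed", 0))
            kf_ib_fits.append(k_ib)
    K = assemble_K(per_trial, velocity_filter=vfilt)
    k21 = K.k21  # II force gain at the filter velocity
    gains = ForceGains(kF_II=k21, kF_Ib=float(np.mean(kf_ib_fits)))
    recovery = {
        "k11": _rel_err(K.k11, affs["Ia"].force_gain),
        "k12": _rel_err(K.k12, affs["Ia"].yank_gain),
        "k21": _rel_err(K.k21, affs["II"].force_gain),
        "k22": _rel_err(K.k22, affs["II"].yank_gain),
        "kF_Ib": _rel_err(gains.kF_Ib, affs["Ib"].force_gain),
    }
    with open(outdir / "fitted_gains.json", "w") as fh:
        json.dump({"K": {"k11": K.k11, "k12": K.k12, "k21": K.k21,
                         "k22": K.k22, "det": K.det,
                         "condition_number": K.condition_number},
                   "kF_II": gains.kF_II, "kF_Ib": gains.kF_Ib,
                   "recovery_relative_error": recovery}, fh, indent=2)
    with open(outdir / "per_trial_gains.csv", "w") as fh:
        fh.write("afferent_class,velocity,rep,force_gain,yank_gain\n")
        for g in per_trial:
            fh.write(f"{g.afferent_class},{g.velocity_label:g},{g.rep_index},"
                     f"{g.force_gain:.10g},{g.yank_gain:.10g}\n")
    log.info("fit: K det=%.4g cond=%.4g; kF_II=%.4g kF_Ib=%.4g",
             K.det, K.condition_number, gains.kF_II, gains.kF_Ib)
    return FitBundle(K=K, force_gains=gains, muscle_fit=muscle_fit,
                     per_trial=per_trial, recovery=recovery)


def _rel_err(fitted: float, true: float) -> float:
    return abs(fitted - true) / abs(true) if true != 0 else abs(fitted)


@dataclass
class DemixBundle:
    demixed: dict[float, DemixResult]
    decompositions: dict[float, ForceDecomposition]
    eccentric: dict[float, ForceDecomposition]
    cancellation: dict


def run_demix(cfg: dict, fit: FitBundle,
              output_dir: str | Path | None = None,
              eccentric_offset: float = 0.0) -> DemixBundle:
    """De-mix rates at every velocity with the fitted gains."""
    outdir = Path(output_dir or cfg["output_dir"]) / "demixed"
    outdir.mkdir(parents=True, exist_ok=True)
    demixed: dict[float, DemixResult] = {}
    decomps: dict[float, ForceDecomposition] = {}
    eccentric: dict[float, ForceDecomposition] = {}
    cancel: dict[float, dict] = {}
    for trial in generate_protocol(cfg["protocol"]):
        if trial.rep_index != 0:
            continue
        force = simulate_forces(trial, cfg["muscle"])
        rates = _encode_trial(trial, force, cfg)
        vel = trial.velocity_label
        demixed[vel] = demix_spindle(rates["Ia"], rates["II"], fit.K)
        decomps[vel] = estimate_forces(rates["II"], rates["Ib"],
                                       fit.force_gains)
        cancel[vel] = {
            "max_abs_F_SG": float(np.max(np.abs(decomps[vel].F_SG_est))),
            "rms_F_SG": float(np.sqrt(np.mean(decomps[vel].F_SG_est**2))),
            "peak_F_C": float(np.max(force.F_C)),
        }
        if eccentric_offset > 0:
            r_ib = apply_eccentric(rates["Ib"],
                                   EccentricScenario(eccentric_offset))
            eccentric[vel] = estimate_forces(rates["II"], r_ib,
                                             fit.force_gains)
        d = demixed[vel]
        with open(outdir / f"demixed_v{vel:g}.csv", "w") as fh:
            fh.write("t,F_est,Y_est,F_EI_est,F_C_est,F_SG_est\n")
            dc = decomps[vel]
            for i in range(d.t.size):
                fh.write(f"{d.t[i]:.10g},{d.F_est[i]:.10g},{d.Y_est[i]:.10g},"
                         f"{dc.F_EI_est[i]:.10g},{dc.F_C_est[i]:.10g},"
                         f"{dc.F_SG_est[i]:.10g}\n")
    log.info("demix: %d velocities, worst cancellation RMS %.3g N",
             len(demixed), max(c["rms_F_SG"] for c in cancel.values()))
    return DemixBundle(demixed=demixed, decompositions=decomps,
                       eccentric=eccentric, cancellation=cancel)


def run_report(cfg: dict, fit: FitBundle, dm: DemixBundle,
               output_dir: str | Path | None = None,
               plots: bool = True) -> dict:
    """Summary report: recovery table, cancellation metrics, peak scaling."""
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    peaks = {vel: {"peak_F_est": float(np.max(d.F_est)),
                   "peak_Y_est": float(np.max(d.Y_est))}
             for vel, d in dm.demixed.items()}
    report = {
        "recovery_relative_error": fit.recovery,
        "K": {"det": fit.K.det, "condition_number": fit.K.condition_number},
        "cancellation": dm.cancellation,
        "decoded_peaks_by_velocity": peaks,
        "n_trials": cfg["protocol"].n_trials,
        "samples_per_trial": {f"{v:g}": int(d.t.size)
                              for v, d in dm.demixed.items()},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    if plots:
        _plot_summary(dm, outdir)
    return report


def _plot_summary(dm: DemixBundle, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for vel in sorted(dm.demixed):
        d = dm.demixed[vel]
        axes[0].plot(d.t, d.F_est, label=f"{vel:g} mm/s", lw=0.8)
        axes[1].plot(d.t, d.Y_est, lw=0.8)
        axes[2].plot(dm.decompositions[vel].t,
                     dm.decompositions[vel].F_SG_est, lw=0.8)
    axes[0].set(title="decoded force", xlabel="t (s)", ylabel="N")
    axes[1].set(title="decoded yank", xlabel="t (s)", ylabel="N/s")
    axes[2].set(title="self-generated force estimate", xlabel="t (s)",
                ylabel="N")
    axes[0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(outdir / "summary.png", dpi=120)
    plt.close(fig)


def run_full(cfg: dict, output_dir: str | Path | None = None,
             eccentric_offset: float = 0.0, plots: bool = True) -> dict:
    """Run the whole pipeline and return the summary report."""
    outdir = Path(output_dir or cfg["output_dir"])
    state: dict = {}
    stages = [
        ("simulate", lambda: run_simulate(cfg, outdir)),
        ("process", lambda: run_process(cfg, outdir)),
        ("fit", lambda: state.__setitem__("fit", run_fit(cfg, outdir))),
        ("demix", lambda: state.__setitem__(
            "dm", run_demix(cfg, state["fit"], outdir,
                            eccentric_offset=eccentric_offset))),
        ("report", lambda: state.__setitem__(
            "report", run_report(cfg, state["fit"], state["dm"], outdir,
                                 plots=plots))),
    ]
    for stage, fn in stages:
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return state["report"]
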