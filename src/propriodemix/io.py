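"""Plain-text I/O: trial CSVs, spike-time files, aligned-rate CSVs, YAML config.

Trial files carry columns ``t, L_MTU, L_fasc, v, F_MTU, F_NC, F_C, Y`` with
one file per trial; filenames encode the nominal velocity and repetition
(``trial_v15.0_rep0.csv``).  Spike trains are one-column text files of spike
times in seconds.  Aligned rate groups are CSVs with columns
``t, rate_Ia, rate_II, rate_Ib, velocity``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .processing import AlignedGroup
from .synthetic import (AfferentParams, ForceTrace, MuscleParams, SpikeTrain,
                        StretchProtocol, StretchTrial)

__all__ = [
    "trial_filename",
    "write_trial_csv",
    "read_trial_csv",
    "write_spike_times",
    "read_spike_times",
    "write_aligned_group",
    "read_aligned_group",
    "load_config",
    "dump_config",
]

TRIAL_COLUMNS = ["t", "L_MTU", "L_fasc", "v", "F_MTU", "F_NC", "F_C", "Y"]


def trial_filename(velocity: float, rep: int) -> str:
    return f"trial_v{velocity:g}_rep{rep}.csv"


def write_trial_csv(path: str | Path, trial: StretchTrial,
                    force: ForceTrace) -> Path:
    path = Path(path)
    l_fasc = trial.L_fasc if trial.L_fasc is not None else trial.L_MTU
    df = pd.DataFrame({"t": trial.t, "L_MTU": trial.L_MTU, "L_fasc": l_fasc,
                       "v": trial.v, "F_MTU": force.F_MTU, "F_NC": force.F_NC,
                       "F_C": force.F_C, "Y": force.Y})
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_trial_csv(path: str | Path,
                   velocity_label: float | None = None,
                   rep_index: int = 0) -> tuple[StretchTrial, ForceTrace]:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trial columns {missing}")
    if velocity_label is None:
        # recover from filename written by trial_filename()
        stem = Path(path).stem
        try:
            velocity_label = float(stem.split("_v")[1].split("_rep")[0])
            rep_index = int(stem.rsplit("_rep", 1)[1])
        except (IndexError, ValueError):
            velocity_label = float("nan")
    t = df["t"].to_numpy()
    trial = StretchTrial(t=t, L_MTU=df["L_MTU"].to_numpy(),
                         v=df["v"].to_numpy(), velocity_label=velocity_label,
                         rep_index=rep_index, L_fasc=df["L_fasc"].to_numpy())
    force = ForceTrace(t=t.copy(), F_MTU=df["F_MTU"].to_numpy(),
                       F_NC=df["F_NC"].to_numpy(), F_C=df["F_C"].to_numpy(),
                       Y=df["Y"].to_numpy())
    return trial, force


def write_spike_times(path: str | Path, spikes: SpikeTrain) -> Path:
    path = Path(path)
    np.savetxt(path, spikes.spike_times, fmt="%.9f")
    return path


def read_spike_times(path: str | Path, afferent_class: str | None = None,
                     velocity_label: float | None = None) -> SpikeTrain:
    times = np.atleast_1d(np.loadtxt(path, dtype=float, ndmin=1))
    return SpikeTrain(times, afferent_class, velocity_label)


def write_aligned_group(path: str | Path, group: AlignedGroup) -> Path:
    path = Path(path)
    data = {"t": group.t}
    for cls in ("Ia", "II", "Ib"):
        if cls in group.rates:
            data[f"rate_{cls}"] = group.rates[cls]
    data["velocity"] = np.full(group.t.size, group.velocity_label)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    return path


def read_aligned_group(path: str | Path) -> AlignedGroup:
    df = pd.read_csv(path)
    rates = {c.removeprefix("rate_"): df[c].to_numpy()
             for c in df.columns if c.startswith("rate_")}
    vel = float(df["velocity"].iloc[0])
    complete = all(c in rates for c in ("Ia", "II", "Ib"))
    return AlignedGroup(velocity_label=vel, t=df["t"].to_numpy(),
                        rates=rates, complete=complete)


def _protocol_from_dict(d: dict) -> StretchProtocol:
    if "velocities" in d:
        d = {**d, "velocities": tuple(float(v) for v in d["velocities"])}
    return StretchProtocol(**d)


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into typed parameter objects.

    Sections: ``protocol``, ``muscle``, ``afferents`` (mapping class ->
    encoder parameters), ``seed``, ``noise_cv``, ``velocity_filter``,
    ``output_dir``.  Absent sections fall back to package defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = {
        "protocol": _protocol_from_dict(raw.get("protocol", {})),
        "muscle": MuscleParams(**raw.get("muscle", {})),
        "seed": int(raw.get("seed", 0)),
        "noise_cv": float(raw.get("noise_cv", 0.0)),
        "velocity_filter": float(raw.get("velocity_filter", 15.0)),
        "output_dir": raw.get("output_dir", "results"),
    }
    affs = {}
    for cls, params in (raw.get("afferents") or {}).items():
        affs[cls] = AfferentParams(afferent_class=cls, **params)
    cfg["afferents"] = affs
    return cfg


def dump_config(path: str | Path, cfg: dict) -> Path:
    """Write the resolved configuration next to the run outputs."""
    out: dict = {}
    proto = cfg["protocol"]
    out["protocol"] = {"amplitude": proto.amplitude,
                       "hold_duration": proto.hold_duration,
                       "velocities": list(proto.velocities),
                       "reps_per_velocity": proto.reps_per_velocity,
                       "baseline_pre": proto.baseline_pre,
                       "baseline_post": proto.baseline_post,
                       "sample_rate": proto.sample_rate,
                       "corner_smoothing": proto.corner_smoothing}
    m = cfg["muscle"]
    out["muscle"] = {"nc_scale": m.nc_scale, "nc_rate": m.nc_rate,
                     "nc_rest_length": m.nc_rest_length,
                     "ce_stiffness": m.ce_stiffness,
                     "ce_viscosity": m.ce_viscosity}
    out["afferents"] = {
        cls: {"force_gain": a.force_gain, "yank_gain": a.yank_gain,
              "rate_offset": a.rate_offset,
              "background_rate": a.background_rate,
              "rectify_output": a.rectify_output,
              "initial_burst_gain": a.initial_burst_gain}
        for cls, a in cfg.get("afferents", {}).items()}
    for key in ("seed", "noise_cv", "velocity_filter", "output_dir"):
        if key in cfg:
            out[key] = cfg[key]
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
    return path
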