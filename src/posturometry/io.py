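"""Plain-text interchange for recordings, panels and configs.

Formats:

* marker trajectories — long CSV with columns
  ``subject, trial, task, occasion, device, frame, marker, x, y, z`` (cm);
* CoP traces — CSV with ``subject, trial, task, occasion, device, frame,
  ap, ml`` (cm);
* endpoint panels — tidy CSV with ``subject, occasion, device, variable,
  value, source_trial, units``;
* simulation/study configs — YAML (or JSON; both are read back).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .kinematics import CoPTrace, MarkerTrajectorySet, VariablePanel
from .synthetic import SimulationConfig, TrialRecording
from .variables import variable

__all__ = [
    "write_trials_csv",
    "read_trials_csv",
    "write_panels_csv",
    "read_panels_csv",
    "panels_to_frame",
    "write_config",
    "read_config",
]

_MARKER_COLS = ["subject", "trial", "task", "occasion", "device",
                "frame", "marker", "x", "y", "z"]
_COP_COLS = ["subject", "trial", "task", "occasion", "device",
             "frame", "ap", "ml"]


def write_trials_csv(trials: Iterable[TrialRecording], markers_path, cop_path
                     ) -> None:
    """Write trial recordings as long-format marker and CoP CSV files."""
    m_rows, c_rows = [], []
    for t in trials:
        key = (t.subject, t.trial, t.task, t.occasion, t.device)
        for name, arr in sorted(t.markers.data.items()):
            n = arr.shape[0]
            m_rows.append(pd.DataFrame({
                "subject": key[0], "trial": key[1], "task": key[2],
                "occasion": key[3], "device": key[4],
                "frame": np.arange(n), "marker": name,
                "x": arr[:, 0], "y": arr[:, 1], "z": arr[:, 2],
                "rate": t.markers.rate,
            }))
        if t.cop is not None:
            c_rows.append(pd.DataFrame({
                "subject": key[0], "trial": key[1], "task": key[2],
                "occasion": key[3], "device": key[4],
                "frame": np.arange(t.cop.n_frames),
                "ap": t.cop.ap, "ml": t.cop.ml, "rate": t.cop.rate,
            }))
    pd.concat(m_rows, ignore_index=True).to_csv(markers_path, index=False)
    if c_rows:
        pd.concat(c_rows, ignore_index=True).to_csv(cop_path, index=False)


def read_trials_csv(markers_path, cop_path=None,
                    alias: dict[str, str] | None = None
                    ) -> list[TrialRecording]:
    """Read trial recordings back from long-format CSV.

    ``alias`` maps foreign marker labels onto the canonical names
    (e.g. ``{"LHEAD": "head_top"}``).
    """
    mdf = pd.read_csv(markers_path)
    missing = set(_MARKER_COLS) - set(mdf.columns)
    if missing:
        raise ValueError(f"marker CSV lacks columns: {sorted(missing)}")
    if alias:
        mdf["marker"] = mdf["marker"].map(lambda m: alias.get(m, m))
    cdf = pd.read_csv(cop_path) if cop_path is not None else None
    key_cols = ["subject", "trial", "task", "occasion", "device"]
    trials = []
    for key, grp in mdf.groupby(key_cols, sort=True):
        rate = float(grp["rate"].iloc[0]) if "rate" in grp else 30.0
        data = {}
        for marker, sub in grp.groupby("marker"):
            sub = sub.sort_values("frame")
            data[str(marker)] = sub[["x", "y", "z"]].to_numpy(dtype=float)
        cop = None
        if cdf is not None:
            mask = np.logical_and.reduce(
                [cdf[c] == v for c, v in zip(key_cols, key)])
            sub = cdf[mask].sort_values("frame")
            if len(sub):
                crate = float(sub["rate"].iloc[0]) if "rate" in sub else rate
                cop = CoPTrace(sub["ap"].to_numpy(float),
                               sub["ml"].to_numpy(float), crate)
        trials.append(TrialRecording(
            markers=MarkerTrajectorySet(data, rate), cop=cop,
            task=str(key[2]), occasion=int(key[3]), device=str(key[4]),
            trial=int(key[1]), subject=str(key[0])))
    return trials


def panels_to_frame(panels: Iterable[VariablePanel]) -> pd.DataFrame:
    """Tidy DataFrame of panels: one row per (subject, occasion, device, variable)."""
    rows = []
    for p in panels:
        for name, value in p.values.items():
            rows.append({
                "subject": p.subject, "occasion": p.occasion, "device": p.device,
                "variable": name, "value": value,
                "source_trial": p.source_trial.get(name),
                "units": variable(name).unit,
                "missing_reason": p.missing.get(name, ""),
            })
    return pd.DataFrame(rows)


def write_panels_csv(panels: Iterable[VariablePanel], path) -> None:
    panels_to_frame(panels).to_csv(path, index=False)


def read_panels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"subject", "variable", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"panel CSV lacks columns: {sorted(need - set(df.columns))}")
    return df


def _config_dict(config) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def write_config(config, path) -> None:
    """Serialise a config dataclass to YAML (or JSON by extension)."""
    path = Path(path)
    d = _config_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def read_config(path, cls=SimulationConfig):
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in d and isinstance(d[f.name], list):
            d[f.name] = tuple(d[f.name])
    return cls(**d)
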