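"""Readers and writers for the pipeline's file formats.

Tracks, steps and state assignments travel as UTF-8 CSV with mandatory
header rows (coordinates in um, times in minutes); models and fit results
as JSON with a ``schema_version`` field; model/run configuration as YAML;
images and masks as single- or multi-page TIFF.  Every writer's output is
readable by the corresponding reader with lossless field values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fit import FitResult, ProfileResult
from .model import CellTrack, MixtureModel, StateParams
from .predict import StatePosterior
from .steps import StepDataset

SCHEMA_VERSION = 1

TRACK_COLUMNS = ["cell_id", "frame", "time_min", "x_um", "y_um"]
STEP_COLUMNS = ["cell_id", "step_index", "dx_par_um", "dy_perp_um", "turn_angle_rad"]

__all__ = [
    "read_tracks_csv",
    "write_tracks_csv",
    "write_steps_csv",
    "read_steps_csv",
    "model_to_dict",
    "model_from_dict",
    "read_model_yaml",
    "write_model_yaml",
    "write_fit_json",
    "read_fit_json",
    "write_profile_json",
    "write_states_csv",
    "read_tiff_stack",
]


def write_tracks_csv(tracks: list[CellTrack], path) -> None:
    rows = []
    for t in tracks:
        for i in range(len(t)):
            row = {
                "cell_id": t.cell_id,
                "frame": i,
                "time_min": t.times[i],
                "x_um": t.xs[i],
                "y_um": t.ys[i],
            }
            if t.true_states is not None:
                # state of the displacement *arriving* at this point; blank on frame 0
                row["true_state"] = t.true_states[i - 1] if i > 0 else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(path) -> list[CellTrack]:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed track CSV {path}: missing columns {sorted(missing)}")
    tracks = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("frame")
        true_states = None
        if "true_state" in g.columns and g["true_state"].iloc[1:].notna().all():
            true_states = g["true_state"].iloc[1:].astype(int).to_numpy()
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                times=g["time_min"].to_numpy(),
                xs=g["x_um"].to_numpy(),
                ys=g["y_um"].to_numpy(),
                true_states=true_states,
            )
        )
    return tracks


def write_steps_csv(steps: StepDataset, path) -> None:
    pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in steps.samples],
            "step_index": [s.step_index for s in steps.samples],
            "dx_par_um": [s.dx_par for s in steps.samples],
            "dy_perp_um": [s.dy_perp for s in steps.samples],
            "turn_angle_rad": [s.turn_angle for s in steps.samples],
        }
    ).to_csv(path, index=False)


def read_steps_csv(path, dt: float = 1.0) -> StepDataset:
    from .steps import StepSample

    df = pd.read_csv(path)
    missing = set(STEP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed steps CSV {path}: missing columns {sorted(missing)}")
    samples = [
        StepSample(
            dx_par=r.dx_par_um,
            dy_perp=r.dy_perp_um,
            turn_angle=r.turn_angle_rad,
            cell_id=str(r.cell_id),
            step_index=int(r.step_index),
        )
        for r in df.itertuples()
    ]
    return StepDataset(samples=samples, dt=dt)


def model_to_dict(model: MixtureModel) -> dict:
    return {
        "states": [
            {
                "mu_r": s.mu_r,
                "sigma_r": s.sigma_r,
                "sigma_theta": s.sigma_theta,
                "label": s.label,
            }
            for s in model.states
        ],
        "alphas": list(model.alphas),
        "dt": model.dt,
    }


def model_from_dict(d: dict) -> MixtureModel:
    states = [
        StateParams(
            mu_r=float(s["mu_r"]),
            sigma_r=float(s["sigma_r"]),
            sigma_theta=float(s["sigma_theta"]),
            label=str(s.get("label", "")),
        )
        for s in d["states"]
    ]
    return MixtureModel(states, d.get("alphas"), dt=float(d.get("dt", 1.0)))


def read_model_yaml(path) -> MixtureModel:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict) or "states" not in d:
        raise ValueError(f"malformed model YAML {path}: need a mapping with 'states'")
    return model_from_dict(d)


def write_model_yaml(model: MixtureModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def write_fit_json(
    fit: FitResult,
    path,
    seed: int | None = None,
    config_echo: dict | None = None,
    threshold: float | None = None,
    intervals: dict | None = None,
) -> None:
    out = {
        "schema_version": SCHEMA_VERSION,
        "model": model_to_dict(fit.model),
        "sse": fit.sse,
        "n_states": fit.n_states,
        "restart_id": fit.restart_id,
        "refined": fit.refined,
        "trace": np.asarray(fit.trace).tolist(),
        "seed": seed,
        "config": config_echo or {},
        "bootstrap_sse_threshold": threshold,
        "confidence_intervals": intervals or {},
    }
    Path(path).write_text(json.dumps(out, indent=2))


def read_fit_json(path) -> tuple[MixtureModel, dict]:
    d = json.loads(Path(path).read_text())
    return model_from_dict(d["model"]), d


def write_profile_json(profile: ProfileResult, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "param_name": profile.param_name,
                "grid": profile.grid.tolist(),
                "profiled_sse": profile.profiled_sse.tolist(),
                "estimate": profile.estimate,
                "threshold": profile.threshold,
                "ci_low": profile.ci_low,
                "ci_high": profile.ci_high,
            },
            indent=2,
        )
    )


def write_states_csv(posteriors: dict[str, list[StatePosterior]], path) -> None:
    """``posteriors`` maps cell_id -> per-step StatePosterior list."""
    rows = []
    for cell_id, sps in posteriors.items():
        for sp in sps:
            row = {"cell_id": cell_id, "step_index": sp.step_index}
            for i, p in enumerate(sp.posteriors, start=1):
                row[f"p_state{i}"] = p
            row["assigned_state"] = sp.assigned_state
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tiff_stack(path) -> np.ndarray:
    """Read a TIFF as an (n_frames, h, w) array; single frames gain an axis."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"malformed TIFF {path}: expected 2-D frames, got shape {arr.shape}")
    return arr
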