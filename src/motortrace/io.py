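"""Configuration, file formats and report serialization.

Formats: movies are multi-page 16-bit grayscale TIFF with a YAML sidecar
recording pixel size and frame interval; ground truth and event tables are
plain CSV; analysis reports are JSON. Units are fixed package-wide (nm, s,
µm, events·µm⁻¹·min⁻¹); files always carry values in those units.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .models import (
    Landing,
    MicrotubuleField,
    MotorModel,
    Movie,
    MTSegment,
    OpticsModel,
    TrajectoryTruth,
    as_motor_model,
    as_optics_model,
)

__all__ = [
    "ConfigError",
    "load_config",
    "packaged_config",
    "packaged_config_names",
    "write_movie",
    "read_movie",
    "write_truth",
    "read_truth",
    "write_field",
    "read_field",
    "events_to_frame",
    "write_events",
    "read_events",
    "report_to_json",
]

PACKAGED_CONFIGS = ("cenpe483", "cenpe483lz", "cenpe754", "cenpefl", "k560")


class ConfigError(ValueError):
    """Configuration did not validate; message lists every offending key."""


_MOTOR_KEYS = {
    "landing_rate_total", "processive_fraction", "velocity_components",
    "run_length_mean", "residency_mean", "pause_entry_rate", "pause_exit_rate",
    "static_dwell_mean", "detach_mode", "n_fluorophores", "bleach_rate",
}
_OPTICS_KEYS = {
    "pixel_size", "frame_interval", "exposure", "psf_sigma",
    "photons_per_fluorophore_per_frame", "background_mean", "read_noise_sd",
    "duration", "image_shape",
}


def _validate_raw(raw: dict) -> list[str]:
    problems = []
    for block in ("motor", "optics", "field"):
        if block not in raw:
            problems.append(f"missing block '{block}'")
    motor = raw.get("motor", {})
    for key in motor:
        if key not in _MOTOR_KEYS:
            problems.append(f"unknown motor key '{key}'")
    for key in raw.get("optics", {}):
        if key not in _OPTICS_KEYS:
            problems.append(f"unknown optics key '{key}'")
    for key in raw.get("field", {}):
        if key not in {"n_mts", "length_mean", "length_sd", "duration_min"}:
            problems.append(f"unknown field key '{key}'")
    return problems


@dataclasses.dataclass
class Config:
    """Validated simulation/analysis configuration."""

    name: str
    motor: MotorModel
    optics: OpticsModel
    field: dict
    seed: int
    n_events: int | None = None
    gliding: dict | None = None

    def replace_motor(self, **kwargs) -> "Config":
        return dataclasses.replace(self, motor=dataclasses.replace(self.motor, **kwargs))


def load_config(path: "str | Path | dict") -> Config:
    """Load and validate a YAML config with motor/optics/field/seed blocks."""
    if isinstance(path, dict):
        raw = path
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    problems = _validate_raw(raw)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    try:
        motor = as_motor_model({"name": raw.get("name", "motor"), **raw["motor"]})
        optics = as_optics_model(raw["optics"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config: {exc}") from exc
    return Config(
        name=raw.get("name", "motor"),
        motor=motor,
        optics=optics,
        field=dict(raw["field"]),
        seed=int(raw.get("seed", 0)),
        n_events=raw.get("n_events"),
        gliding=raw.get("gliding"),
    )


def packaged_config(name: str) -> Config:
    """Load one of the packaged construct configs by name (e.g. 'cenpe754')."""
    if name not in PACKAGED_CONFIGS:
        raise KeyError(f"unknown packaged config {name!r}; have {PACKAGED_CONFIGS}")
    ref = resources.files("motortrace") / "configs" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return load_config(path)


def packaged_config_names() -> tuple[str, ...]:
    return PACKAGED_CONFIGS


# ---------------------------------------------------------------------------
# movies


def write_movie(path: "str | Path", movie: Movie) -> None:
    """Write a movie as multi-page 16-bit TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    data = movie.data
    if data.dtype != np.uint16:
        data = np.clip(np.rint(data), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "pixel_size_nm": movie.optics.pixel_size,
        "frame_interval_s": movie.optics.frame_interval,
        "n_frames": int(movie.n_frames),
        "image_shape": list(movie.data.shape[1:]),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_movie(path: "str | Path", optics: OpticsModel | None = None) -> Movie:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if optics is None:
        sidecar_path = path.with_suffix(".yaml")
        kwargs = {}
        if sidecar_path.exists():
            meta = yaml.safe_load(sidecar_path.read_text())
            kwargs = {
                "pixel_size": meta["pixel_size_nm"],
                "frame_interval": meta["frame_interval_s"],
            }
        optics = OpticsModel(
            image_shape=data.shape[1:],
            duration=data.shape[0] * kwargs.get("frame_interval", 0.12),
            **kwargs,
        )
    return Movie(data, optics)


# ---------------------------------------------------------------------------
# ground truth and fields


def write_truth(
    prefix: "str | Path", trajectories: list[TrajectoryTruth], frame_interval: float = 0.12
) -> tuple[Path, Path]:
    """Write per-frame and per-motor truth CSVs; returns both paths."""
    prefix = Path(prefix)
    frame_rows, motor_rows = [], []
    for traj in trajectories:
        counts = traj.n_unbleached(traj.frames_t) if traj.frames_t.size else []
        for t, pos, state, n_fl in zip(
            traj.frames_t, traj.positions_nm, traj.states, counts
        ):
            frame_rows.append({
                "motor_id": traj.motor_id,
                "mt_id": traj.mt_id,
                "frame": int(round(t / frame_interval)),
                "t": t,
                "position_nm": pos,
                "state": state,
                "n_unbleached": int(n_fl),
            })
        motor_rows.append({
            "motor_id": traj.motor_id,
            "mt_id": traj.mt_id,
            "class": traj.cls,
            "t_land": traj.t_land,
            "t_detach": traj.t_detach,
            "velocity_draw": traj.velocity_draw,
            "run_length_true": traj.run_length_true,
            "residency_true": traj.residency_true,
            "n_frames": int(traj.frames_t.size),
        })
    frames_path = prefix.with_name(prefix.name + "_frames.csv")
    motors_path = prefix.with_name(prefix.name + "_motors.csv")
    pd.DataFrame(
        frame_rows,
        columns=["motor_id", "mt_id", "frame", "t", "position_nm", "state", "n_unbleached"],
    ).to_csv(frames_path, index=False)
    pd.DataFrame(
        motor_rows,
        columns=["motor_id", "mt_id", "class", "t_land", "t_detach", "velocity_draw",
                 "run_length_true", "residency_true", "n_frames"],
    ).to_csv(motors_path, index=False)
    return frames_path, motors_path


def read_truth(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path)


def write_field(path: "str | Path", field: MicrotubuleField) -> None:
    rows = [
        {
            "mt_id": i,
            "a_row": s.endpoint_a[0], "a_col": s.endpoint_a[1],
            "b_row": s.endpoint_b[0], "b_col": s.endpoint_b[1],
            "length_um": s.length_um, "polarity": s.polarity,
        }
        for i, s in enumerate(field.segments)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_field(path: "str | Path") -> MicrotubuleField:
    df = pd.read_csv(path)
    segs = tuple(
        MTSegment(
            (row.a_row, row.a_col), (row.b_row, row.b_col),
            row.length_um, int(row.polarity),
        )
        for row in df.itertuples()
    )
    return MicrotubuleField(segs)


# ---------------------------------------------------------------------------
# events


def events_to_frame(events: list) -> pd.DataFrame:
    rows = [
        {
            "motor_id": ev.motor_id,
            "mt_id": ev.mt_id,
            "t_start": ev.t_start,
            "t_end": ev.t_end,
            "n_frames": ev.n_frames,
            "x_start": ev.x_start,
            "x_end": ev.x_end,
            "net_displacement": ev.net_displacement,
            "velocity": ev.velocity,
            "run_length": ev.run_length,
            "residency": ev.residency,
            "motile": ev.motile,
            "censored": ev.censored,
        }
        for ev in events
    ]
    cols = ["motor_id", "mt_id", "t_start", "t_end", "n_frames", "x_start", "x_end",
            "net_displacement", "velocity", "run_length", "residency", "motile", "censored"]
    return pd.DataFrame(rows, columns=cols)


def write_events(path: "str | Path", events: list) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def report_to_json(report: dict, path: "str | Path | None" = None) -> str:
    """Serialize an analysis report losslessly to JSON (and optionally a file)."""
    text = json.dumps(_jsonable(report), indent=2, sort_keys=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
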