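"""File formats and run configuration.

CSV dialects (UTF-8, ``.`` decimal, mandatory header row):

* angle series     ``time_s,value_deg``
* IMU stream       ``time_s,ax_g,ay_g,az_g``
* landmark frames  ``frame,point_id,u_px,v_px``

Camera intrinsics and 3D landmark models travel as JSON, as do run
configurations and ground-truth sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .courses import COURSE_NAMES
from .pose import CameraModel, LandmarkFrame, LandmarkModel
from .imu import ImuStream
from .series import CHANNELS, AngleSeries

ANGLE_HEADER = ["time_s", "value_deg"]
IMU_HEADER = ["time_s", "ax_g", "ay_g", "az_g"]
LANDMARK_HEADER = ["frame", "point_id", "u_px", "v_px"]


def _infer_rate(t: np.ndarray, path: Path) -> float:
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer the rate")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValueError(f"{path}: time column is not increasing")
    return 1.0 / dt


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parse-error types
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"expected header {','.join(columns)}")
    bad = df[columns].apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: non-numeric value at line {line}")
    return df[columns].astype(float)


def write_angle_series(path, series: AngleSeries) -> None:
    pd.DataFrame({"time_s": series.t, "value_deg": series.value}).to_csv(
        path, index=False)


def read_angle_series(path, channel: str = "steering") -> AngleSeries:
    df = _read_csv(path, ANGLE_HEADER)
    t = df["time_s"].to_numpy()
    return AngleSeries(t, df["value_deg"].to_numpy(),
                       _infer_rate(t, Path(path)), channel)


def write_imu_stream(path, stream: ImuStream) -> None:
    pd.DataFrame({"time_s": stream.t, "ax_g": stream.a[:, 0],
                  "ay_g": stream.a[:, 1], "az_g": stream.a[:, 2]}).to_csv(
        path, index=False)


def read_imu_stream(path) -> ImuStream:
    df = _read_csv(path, IMU_HEADER)
    t = df["time_s"].to_numpy()
    a = df[["ax_g", "ay_g", "az_g"]].to_numpy()
    return ImuStream(t, a, _infer_rate(t, Path(path)))


def write_landmark_frames(path, frames: list[LandmarkFrame]) -> None:
    rows = []
    for f in frames:
        for pid, (u, v) in zip(f.point_ids, f.uv):
            rows.append((f.frame, pid, u, v))
    pd.DataFrame(rows, columns=LANDMARK_HEADER).to_csv(path, index=False)


def read_landmark_frames(path) -> list[LandmarkFrame]:
    df = _read_csv(path, LANDMARK_HEADER)
    frames = []
    for idx, grp in df.groupby("frame", sort=True):
        frames.append(LandmarkFrame(int(idx),
                                    tuple(int(p) for p in grp["point_id"]),
                                    grp[["u_px", "v_px"]].to_numpy()))
    return frames


def write_camera(path, camera: CameraModel) -> None:
    Path(path).write_text(json.dumps(
        {"fx": camera.fx, "fy": camera.fy, "cx": camera.cx, "cy": camera.cy},
        indent=2))


def read_camera(path) -> CameraModel:
    d = json.loads(Path(path).read_text())
    return CameraModel(fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"])


def write_landmark_model(path, model: LandmarkModel) -> None:
    Path(path).write_text(json.dumps(
        {"points": {str(pid): list(map(float, xyz))
                    for pid, xyz in zip(model.point_ids, model.points)}},
        indent=2))


def read_landmark_model(path) -> LandmarkModel:
    d = json.loads(Path(path).read_text())["points"]
    ids = tuple(int(k) for k in d)
    return LandmarkModel(ids, np.array([d[str(i)] for i in ids]))


class CouplingConfig(BaseModel):
    lead_time_s: float = Field(0.6, ge=0.0)
    gain: float = 1.5
    noise_sd_deg: float = Field(2.0, ge=0.0)
    drift_sd_deg: float = Field(0.0, ge=0.0)


class WindowConfig(BaseModel):
    window_s: float = Field(20.0, gt=0.0)
    step_s: float = Field(1.0, gt=0.0)
    max_lag_s: float = Field(5.0, gt=0.0)


class RunConfig(BaseModel):
    """Fully resolved pipeline configuration; written next to every output."""

    course: str = "slalom"
    rate_hz: float = Field(10.0, ge=2.0)
    speed_ms: float = Field(1.0, gt=0.0, le=4.0 / 3.6)
    seed: int = Field(0, ge=0)
    coupling: CouplingConfig = CouplingConfig()
    window: WindowConfig = WindowConfig()
    steering_axis: str = "pitch"  # which lever tilt axis carries steering
    vibration_sd_ms2: float = Field(0.0, ge=0.0)
    sensor_noise_sd_ms2: float = Field(0.0, ge=0.0)
    pixel_noise_sd_px: float = Field(0.0, ge=0.0)
    head_distance_mm: float = Field(600.0, gt=0.0)
    refine_peak: bool = True

    @field_validator("course")
    @classmethod
    def _valid_course(cls, v: str) -> str:
        if v not in COURSE_NAMES:
            raise ValueError(f"unknown course {v!r}; valid: {', '.join(COURSE_NAMES)}")
        return v

    @field_validator("steering_axis")
    @classmethod
    def _valid_axis(cls, v: str) -> str:
        if v not in ("pitch", "roll"):
            raise ValueError("steering_axis must be 'pitch' or 'roll'")
        return v


def load_config(path) -> RunConfig:
    """Read a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data or {})


def dump_config(path, config: RunConfig) -> None:
    Path(path).write_text(config.model_dump_json(indent=2))
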