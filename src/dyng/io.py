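"""File ingestion and writing, ROI extraction from thermal stacks, and
time alignment of temperature and environment streams.

All delimited formats are comma-separated UTF-8 with a mandatory header and
'.' decimal. Temperatures on disk are °C (camera convention); everything in
memory is kelvin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .physics import EnvironmentState
from .ebalance import TemperatureSeries

logger = logging.getLogger("dyng")

__all__ = [
    "RoiMask",
    "read_temperature_csv",
    "write_temperature_csv",
    "read_environment_csv",
    "write_environment_csv",
    "read_al_spec_csv",
    "extract_roi_series",
    "align_streams",
]


@dataclass(frozen=True)
class RoiMask:
    """Pixel set of one object in the camera frame."""

    object_id: str
    pixels: tuple          # ((row, col), ...)
    frame_shape: tuple     # (rows, cols)

    def __post_init__(self):
        if not self.pixels:
            raise ValueError(f"mask {self.object_id!r} is empty")
        rows, cols = self.frame_shape
        for r, c in self.pixels:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(
                    f"mask {self.object_id!r}: pixel ({r}, {c}) outside "
                    f"frame {self.frame_shape}")

    def indices(self):
        arr = np.asarray(self.pixels, dtype=int)
        return arr[:, 0], arr[:, 1]


def read_temperature_csv(path, unit: str = "C") -> TemperatureSeries:
    """Read a tidy temperature series (columns time_s, object_id,
    temperature_C — or temperature_K with ``unit='K'``).

    Malformed temperature cells are kept as quality='missing' records (with
    a logged line-ish context), never silently dropped. Duplicate
    (time, object) pairs are rejected.
    """
    df = pd.read_csv(path)
    temp_col = f"temperature_{unit}"
    required = {"time_s", "object_id", temp_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if df.duplicated(subset=["time_s", "object_id"]).any():
        dup = df[df.duplicated(subset=["time_s", "object_id"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate (time, object) record at time_s="
            f"{dup['time_s']}, object_id={dup['object_id']!r}")
    vals = pd.to_numeric(df[temp_col], errors="coerce")
    bad = vals.isna() & df[temp_col].notna()
    for i in df.index[bad]:
        logger.warning("%s: non-numeric temperature %r at row %d flagged "
                       "missing", path, df.loc[i, temp_col], i + 2)
    df = df.assign(_temp=vals)
    wide = df.pivot(index="time_s", columns="object_id", values="_temp")
    wide = wide.sort_index()
    temps = wide.to_numpy(dtype=float)
    if unit == "C":
        temps = temps + 273.15
    quality = np.where(np.isnan(temps), "missing", "ok").astype(object)
    roles = None
    if "role" in df.columns:
        roles = dict(df.groupby("object_id")["role"].first())
    return TemperatureSeries(times=wide.index.to_numpy(dtype=float),
                             object_ids=list(wide.columns),
                             temperatures=temps, quality=quality, roles=roles)


def write_temperature_csv(series: TemperatureSeries, path) -> None:
    """Write a series as tidy CSV (time_s, object_id, role, temperature_C,
    quality), 6 significant digits."""
    series.to_frame().to_csv(path, index=False, float_format="%.6g")


def read_environment_csv(path) -> list[EnvironmentState]:
    """Read environment sensor records: columns time_s, T_air_C, RH_air
    (fraction) and optionally P_atm_Pa, wind_m_s, PPFD."""
    df = pd.read_csv(path)
    required = {"time_s", "T_air_C", "RH_air"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if df["time_s"].duplicated().any():
        raise ValueError(f"{path}: duplicate time_s records")
    out = []
    for _, row in df.sort_values("time_s").iterrows():
        out.append(EnvironmentState.from_celsius(
            time=float(row["time_s"]), T_air_C=float(row["T_air_C"]),
            RH_air=float(row["RH_air"]),
            P_atm=float(row.get("P_atm_Pa", 101325.0)),
            wind=float(row["wind_m_s"]) if "wind_m_s" in df.columns else None,
            PPFD=float(row["PPFD"]) if "PPFD" in df.columns else None))
    return out


def write_environment_csv(env: list[EnvironmentState], path) -> None:
    pd.DataFrame({
        "time_s": [e.time for e in env],
        "T_air_C": [e.T_air - 273.15 for e in env],
        "RH_air": [e.RH_air for e in env],
        "P_atm_Pa": [e.P_atm for e in env],
        "wind_m_s": [e.wind for e in env],
        "PPFD": [e.PPFD for e in env],
    }).to_csv(path, index=False, float_format="%.6g")


def read_al_spec_csv(path) -> pd.DataFrame:
    """Read an artificial-leaf specification table.

    Columns: id, role, and optionally PA_um2, PD_per_mm2, l_um, eps_top,
    eps_bottom, alpha_sw, g_pw. Geometry columns are converted to SI
    (PA m², PD m⁻², l m) in the returned frame.
    """
    df = pd.read_csv(path)
    missing = {"id", "role"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate AL ids")
    if "PA_um2" in df.columns:
        df["PA_m2"] = df["PA_um2"] * 1e-12
    if "PD_per_mm2" in df.columns:
        df["PD_m2"] = df["PD_per_mm2"] * 1e6
    if "l_um" in df.columns:
        df["l_m"] = df["l_um"] * 1e-6
    return df


def extract_roi_series(stack_path, masks: list[RoiMask], frame_times,
                       unit: str = "C") -> TemperatureSeries:
    """Mean masked temperature per frame of a radiometric TIFF stack.

    Pixel values must already be temperatures (°C by default, K with
    ``unit='K'``); raw-count calibration is the camera vendor's job.
    """
    import tifffile

    frames = tifffile.imread(stack_path)
    frames = np.atleast_3d(frames)
    if frames.ndim == 2:
        frames = frames[None]
    frame_times = np.asarray(frame_times, dtype=float)
    if frames.shape[0] != frame_times.size:
        raise ValueError(
            f"{stack_path}: {frames.shape[0]} frames but "
            f"{frame_times.size} frame times")
    ids = [m.object_id for m in masks]
    if len(set(ids)) != len(ids):
        raise ValueError("mask object_ids must be unique")
    temps = np.empty((frame_times.size, len(masks)))
    for j, mask in enumerate(masks):
        if mask.frame_shape != frames.shape[1:]:
            raise ValueError(
                f"mask {mask.object_id!r} frame_shape {mask.frame_shape} "
                f"does not match stack frames {frames.shape[1:]}")
        rr, cc = mask.indices()
        temps[:, j] = frames[:, rr, cc].mean(axis=1)
    if unit == "C":
        temps = temps + 273.15
    return TemperatureSeries(times=frame_times, object_ids=ids,
                             temperatures=temps)


def align_streams(temps: TemperatureSeries, env: list[EnvironmentState],
                  max_gap: float = 1.0) -> pd.DataFrame:
    """Nearest-neighbor join of temperature timepoints to environment
    records; joins farther than ``max_gap`` seconds are kept but flagged.

    Returns a tidy frame: time_s, object_id, temperature_K, env_time_s,
    T_air_K, RH_air, P_atm_Pa, wind_m_s, PPFD, gap_s, gap_flagged.
    """
    if temps.times.size == 0 or not env:
        raise ValueError("both streams must be non-empty")
    env_t = np.array([e.time for e in env])
    order = np.argsort(env_t)
    env_t = env_t[order]
    env_sorted = [env[i] for i in order]
    idx = np.clip(np.searchsorted(env_t, temps.times), 0, env_t.size - 1)
    left = np.clip(idx - 1, 0, env_t.size - 1)
    idx = np.where(np.abs(env_t[left] - temps.times)
                   <= np.abs(env_t[idx] - temps.times), left, idx)
    gap = np.abs(env_t[idx] - temps.times)
    rows = []
    for i, t in enumerate(temps.times):
        e = env_sorted[idx[i]]
        for j, oid in enumerate(temps.object_ids):
            rows.append({
                "time_s": t, "object_id": oid,
                "temperature_K": temps.temperatures[i, j],
                "env_time_s": e.time, "T_air_K": e.T_air,
                "RH_air": e.RH_air, "P_atm_Pa": e.P_atm,
                "wind_m_s": e.wind, "PPFD": e.PPFD,
                "gap_s": gap[i], "gap_flagged": bool(gap[i] > max_gap),
            })
    return pd.DataFrame(rows)
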