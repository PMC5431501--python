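"""Pressure-trace handling and unit conversions.

The bench sensors report in psi; traces are converted to mmHg for
plotting and to kPa for analysis.  Recordings are sampled at 1 Hz; the
summary statistic of a recording is the maximum pressure it attains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PSI_TO_MMHG",
    "MMHG_TO_KPA",
    "PressureRecording",
    "MaxPressure",
    "convert_pressure",
    "convert_flow",
    "extract_max",
    "delivery_duration",
    "recordings_to_frame",
    "frame_to_recordings",
]

PSI_TO_MMHG = 51.7149
MMHG_TO_KPA = 0.1333224

# factor taking one unit of each kind to kPa
_TO_KPA = {
    "kPa": 1.0,
    "mmHg": MMHG_TO_KPA,
    "psi": PSI_TO_MMHG * MMHG_TO_KPA,
}


def convert_pressure(x, from_unit: str, to_unit: str):
    """Convert pressure between psi, mmHg and kPa (exact linear maps).

    Accepts scalars or arrays.  1 psi = 51.7149 mmHg; 1 mmHg = 0.1333224
    kPa (so the 30 mmHg intraosseous threshold is 4.000 kPa).
    """
    for u in (from_unit, to_unit):
        if u not in _TO_KPA:
            raise ValueError(f"unknown pressure unit {u!r}")
    return np.asarray(x) * (_TO_KPA[from_unit] / _TO_KPA[to_unit]) if isinstance(
        x, (list, tuple, np.ndarray)
    ) else x * (_TO_KPA[from_unit] / _TO_KPA[to_unit])


def convert_flow(q_ml_min: float, digits: int | None = None) -> float:
    """Flow rate mL/min -> mL/s (``Q / 60``), optionally rounded.

    With ``digits`` the result is rounded as flow rates are printed in this
    field (e.g. 15.6 -> 0.26 at 2 digits, 9.5 -> 0.158 at 3).
    """
    if q_ml_min < 0:
        raise ValueError("flow rate must be >= 0")
    q = q_ml_min / 60.0
    return round(q, digits) if digits is not None else q


@dataclass
class PressureRecording:
    """One channel's 1 Hz gauge-pressure time series.

    ``channel_id`` is ``"test"`` (needle canal) or ``"adjacent"`` (the
    parallel canal); ``group_id`` identifies the experimental condition.
    """

    channel_id: str
    group_id: str
    times: np.ndarray  # s, strictly increasing at 1 s spacing
    pressures: np.ndarray
    unit: str = "kPa"
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.times.shape != self.pressures.shape:
            raise ValueError("times and pressures must have equal length")
        if self.times.size == 0:
            raise ValueError("recording must contain at least one sample")
        if self.unit not in _TO_KPA:
            raise ValueError(f"unknown pressure unit {self.unit!r}")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1.0, atol=1e-9):
                raise ValueError("samples must be spaced at exactly 1 s (1 Hz)")

    def to_unit(self, unit: str) -> "PressureRecording":
        if unit == self.unit:
            return self
        return PressureRecording(
            channel_id=self.channel_id,
            group_id=self.group_id,
            times=self.times,
            pressures=convert_pressure(self.pressures, self.unit, unit),
            unit=unit,
            replicate=self.replicate,
        )


@dataclass(frozen=True)
class MaxPressure:
    """Maximum pressure of one recording and the first time it is attained."""

    value: float
    time_of_max: float
    unit: str = "kPa"


def extract_max(rec: PressureRecording) -> MaxPressure:
    """Maximum sample of a recording (earliest attaining time on ties)."""
    i = int(np.argmax(rec.pressures))  # argmax returns the first maximum
    return MaxPressure(
        value=float(rec.pressures[i]), time_of_max=float(rec.times[i]), unit=rec.unit
    )


def delivery_duration(flow) -> float:
    """Seconds needed to deliver ``delivered_volume`` mL at ``flow_rate``
    mL/min: ``60 * volume / Q``.  Zero volume takes zero time."""
    if flow.delivered_volume == 0:
        return 0.0
    if flow.flow_rate <= 0:
        raise ValueError("flow rate must be > 0 for a finite delivery")
    return 60.0 * flow.delivered_volume / flow.flow_rate


# ---------------------------------------------------------------------------
# the long-format recording CSV dialect
# ---------------------------------------------------------------------------

_FRAME_COLUMNS = ["time_s", "pressure", "unit", "channel", "group", "replicate"]


def recordings_to_frame(recordings) -> pd.DataFrame:
    """Stack recordings into the long CSV dialect (one row per sample)."""
    parts = []
    for rec in recordings:
        parts.append(
            pd.DataFrame(
                {
                    "time_s": rec.times,
                    "pressure": rec.pressures,
                    "unit": rec.unit,
                    "channel": rec.channel_id,
                    "group": rec.group_id,
                    "replicate": rec.replicate,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=_FRAME_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def frame_to_recordings(frame: pd.DataFrame) -> list[PressureRecording]:
    """Rebuild recordings from the long CSV dialect."""
    missing = set(_FRAME_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"recording table missing columns {sorted(missing)}")
    out = []
    for (group, channel, rep), sub in frame.groupby(
        ["group", "channel", "replicate"], sort=True
    ):
        sub = sub.sort_values("time_s")
        units = sub["unit"].unique()
        if len(units) != 1:
            raise ValueError(f"mixed units in recording {group}/{channel}/{rep}")
        out.append(
            PressureRecording(
                channel_id=str(channel),
                group_id=str(group),
                times=sub["time_s"].to_numpy(),
                pressures=sub["pressure"].to_numpy(),
                unit=str(units[0]),
                replicate=int(rep),
            )
        )
    return out
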