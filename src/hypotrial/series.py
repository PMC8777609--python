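"""Per-patient mean arterial pressure (MAP) time series and trial containers.

A surgery is represented by a :class:`MAPSeries`: timestamped MAP values in
mmHg, nominally one sample every 20 s (the update cadence of advanced
hemodynamic monitors that compute MAP from the arterial waveform).  Between
samples the trace is interpreted as piecewise linear; the raw 100 Hz waveform
is out of scope.

A two-arm trial is a :class:`TrialDataset`: one :class:`Patient` per subject,
each carrying an arm label (``intervention`` or ``control``), optionally a MAP
series, a hypotension burden summary, and pre/post biomarker panels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARMS = ("intervention", "control")

#: default nominal sampling interval, seconds
DEFAULT_STEP = 20.0


class SeriesError(ValueError):
    """Base class for MAP-series validation failures."""


class SeriesFormatError(SeriesError):
    """Input file lacks the required columns or cannot be parsed."""


class SeriesOrderingError(SeriesError):
    """Timestamps are not strictly increasing."""


class EmptySeriesError(SeriesError):
    """No usable samples remain after cleaning."""


class DegenerateGridError(SeriesError):
    """Requested resampling grid has fewer than two points."""


@dataclass(frozen=True)
class MAPSeries:
    """A validated MAP record for one surgery.

    Parameters
    ----------
    patient_id:
        Opaque identifier.
    times:
        Sample times in seconds from surgery start, strictly increasing,
        first time >= 0.
    values:
        MAP in mmHg; finite and positive.
    surgery_duration:
        Total surgery duration in **minutes**; the last sample must not lie
        beyond it.
    nominal_step:
        Expected sampling interval in seconds. Irregular spacing is allowed
        but flagged via :attr:`is_uniform`.
    """

    patient_id: str
    times: np.ndarray
    values: np.ndarray
    surgery_duration: float
    nominal_step: float = DEFAULT_STEP

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise SeriesFormatError("times and values must be 1-D and equal length")
        if t.size == 0:
            raise EmptySeriesError(f"series {self.patient_id!r} is empty")
        if not np.all(np.isfinite(t)):
            raise SeriesOrderingError("non-finite timestamps")
        if np.any(np.diff(t) <= 0):
            raise SeriesOrderingError(
                f"series {self.patient_id!r}: times must be strictly increasing"
            )
        if t[0] < 0:
            raise SeriesOrderingError("first timestamp is negative")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise SeriesError("MAP values must be finite and > 0 mmHg")
        if self.surgery_duration <= 0:
            raise SeriesError("surgery_duration must be positive (minutes)")
        # small tolerance for float round-off in generated grids
        if t[-1] > self.surgery_duration * 60.0 + 1e-6:
            raise SeriesError(
                f"last sample at {t[-1]:.1f}s exceeds surgery duration "
                f"{self.surgery_duration:.1f} min"
            )
        if self.nominal_step <= 0:
            raise SeriesError("nominal_step must be positive")
        if not self.is_uniform:
            logger.debug(
                "series %s: irregular sampling (nominal step %.0f s)",
                self.patient_id, self.nominal_step,
            )

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        """Seconds covered from first to last sample."""
        return float(self.times[-1] - self.times[0])

    @property
    def is_uniform(self) -> bool:
        """True when all sampling intervals match ``nominal_step`` (0.1 s tol)."""
        if self.n < 2:
            return True
        return bool(np.allclose(np.diff(self.times), self.nominal_step, atol=0.1))

    def value_at(self, t: float) -> float:
        """Piecewise-linear MAP at time ``t`` (clamped to the sampled range)."""
        return float(np.interp(t, self.times, self.values))


def read_series(
    path: str | Path,
    *,
    time_col: str = "time_s",
    map_col: str = "map_mmhg",
    delimiter: str = ",",
    patient_id: Optional[str] = None,
    duration_min: Optional[float] = None,
    nominal_step: float = DEFAULT_STEP,
) -> MAPSeries:
    """Read one MAP series from delimited text.

    The file must have a header naming a time column (seconds) and a MAP
    column (mmHg).  Rows whose MAP is non-finite are dropped and counted;
    the drop count is reported through the module logger.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, delimiter=delimiter)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SeriesFormatError(f"{path}: cannot parse ({exc})") from exc
    missing = {time_col, map_col} - set(df.columns)
    if missing:
        raise SeriesFormatError(f"{path}: missing column(s) {sorted(missing)}")
    t = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
    v = pd.to_numeric(df[map_col], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(v) & np.isfinite(t)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_series %s: dropped %d row(s) with non-finite MAP", path, dropped)
    t, v = t[keep], v[keep]
    if t.size == 0:
        raise EmptySeriesError(f"{path}: no usable rows after cleaning")
    if np.any(np.diff(t) <= 0):
        raise SeriesOrderingError(f"{path}: time column not strictly increasing")
    if duration_min is None:
        duration_min = float(t[-1]) / 60.0 if t[-1] > 0 else 1.0 / 60.0
    return MAPSeries(
        patient_id=patient_id or path.stem,
        times=t,
        values=v,
        surgery_duration=duration_min,
        nominal_step=nominal_step,
    )


def write_series(
    series: MAPSeries,
    path: str | Path,
    *,
    time_col: str = "time_s",
    map_col: str = "map_mmhg",
) -> None:
    """Write a series as CSV with full float precision (round-trip safe)."""
    df = pd.DataFrame({time_col: series.times, map_col: series.values})
    df.to_csv(path, index=False, float_format="%.12g")


def resample_to_grid(series: MAPSeries, step: float) -> MAPSeries:
    """Linearly interpolate onto a uniform grid from first to last timestamp.

    Endpoints are preserved: if the span is not an exact multiple of ``step``
    the final sample is appended at the last original timestamp.
    """
    if step <= 0:
        raise DegenerateGridError("step must be positive")
    if step > series.span:
        raise DegenerateGridError(
            f"step {step:g}s exceeds series span {series.span:g}s"
        )
    t0, t1 = float(series.times[0]), float(series.times[-1])
    ngrid = int(np.floor((t1 - t0) / step + 1e-9)) + 1
    grid = t0 + step * np.arange(ngrid)
    if grid[-1] < t1 - 1e-9:
        grid = np.append(grid, t1)
    else:
        grid[-1] = t1
    vals = np.interp(grid, series.times, series.values)
    return replace(series, times=grid, values=vals, nominal_step=step)


# ---------------------------------------------------------------------------
# trial-level containers
# ---------------------------------------------------------------------------

@dataclass
class Patient:
    """One trial subject: arm assignment plus whatever data are available."""

    patient_id: str
    arm: str
    series: Optional[MAPSeries] = None
    pre_panel: Optional["object"] = None   # BiomarkerPanel at T0
    post_panel: Optional["object"] = None  # BiomarkerPanel at T2
    summary: Optional["object"] = None     # HypotensionSummary cache

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")


@dataclass
class TrialDataset:
    """A two-arm trial: unique patients, each in exactly one arm."""

    patients: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_id in trial")
        for p in self.patients:
            if p.arm not in ARMS:
                raise ValueError(f"invalid arm {p.arm!r}")

    def arm(self, label: str) -> list:
        if label not in ARMS:
            raise ValueError(f"unknown arm {label!r}")
        return [p for p in self.patients if p.arm == label]

    @property
    def n(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def read_manifest(
    manifest_path: str | Path,
    *,
    time_col: str = "time_s",
    map_col: str = "map_mmhg",
    nominal_step: float = DEFAULT_STEP,
) -> TrialDataset:
    """Load a trial from a manifest CSV.

    Columns: ``patient_id``, ``arm``, ``series_path`` (relative to the
    manifest), ``duration_min``.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"patient_id", "arm", "series_path", "duration_min"}
    missing = required - set(df.columns)
    if missing:
        raise SeriesFormatError(f"{manifest_path}: missing column(s) {sorted(missing)}")
    patients = []
    for row in df.itertuples(index=False):
        spath = manifest_path.parent / str(row.series_path)
        series = read_series(
            spath,
            time_col=time_col,
            map_col=map_col,
            patient_id=str(row.patient_id),
            duration_min=float(row.duration_min),
            nominal_step=nominal_step,
        )
        patients.append(Patient(patient_id=str(row.patient_id), arm=str(row.arm), series=series))
    return TrialDataset(patients=patients)
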