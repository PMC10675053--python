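"""Raw accelerometer ingestion, timebase synchronisation and magnitude.

A session is recorded by a body-worn triaxial accelerometer (nominally
100 Hz, saturating at 8 g).  Real loggers drift slightly around their
preset rate, so analysis starts by resampling each axis onto a uniform
timebase by linear interpolation and collapsing the three axes into the
orientation-free acceleration magnitude ``sqrt(ax^2 + ay^2 + az^2)``.
All accelerations are in g, all times in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ParameterError, RangeError, StateError

#: Physical saturation limit of the sensors, in g.
SATURATION_G = 8.0

#: Relative tolerance used when deciding whether a timebase is uniform.
_UNIFORM_RTOL = 1e-6


@dataclass(frozen=True)
class ColumnDialect:
    """Column mapping for delimited-text accelerometer exports.

    ``time_format`` is ``"seconds"`` for numeric timestamps or
    ``"iso8601"`` for datetime strings (converted to seconds from the
    first sample).
    """

    time: str = "time"
    x: str = "x"
    y: str = "y"
    z: str = "z"
    time_format: str = "seconds"
    delimiter: str = ","

    def __post_init__(self) -> None:
        if self.time_format not in ("seconds", "iso8601"):
            raise ParameterError(
                f"time_format must be 'seconds' or 'iso8601', got {self.time_format!r}"
            )


@dataclass(frozen=True)
class TriaxialRecording:
    """Timestamped X/Y/Z accelerations for one sensor.

    Timestamps are strictly increasing but not necessarily uniform.
    """

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sensor_label: str = ""
    nominal_rate: float = 100.0

    def __post_init__(self) -> None:
        for name in ("timestamps", "ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.timestamps.size
        if n < 2:
            raise DataError("a recording needs at least 2 samples")
        if any(getattr(self, a).size != n for a in ("ax", "ay", "az")):
            raise DataError("axis arrays must match the timestamp length")
        if not np.all(np.diff(self.timestamps) > 0):
            raise DataError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def is_uniform(self, rtol: float = _UNIFORM_RTOL) -> bool:
        dt = np.diff(self.timestamps)
        return bool(np.allclose(dt, dt.mean(), rtol=rtol, atol=rtol * max(dt.mean(), 1e-12)))


@dataclass(frozen=True)
class MagnitudeSeries:
    """Uniformly sampled scalar acceleration-magnitude signal, in g."""

    start_time: float
    rate: float
    values: np.ndarray
    sensor_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if np.any(self.values < 0):
            raise DataError("magnitude values must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    def extract(self, start_time: float, duration: float) -> "MagnitudeSeries":
        """Cut out ``round(duration * rate)`` samples starting at ``start_time``.

        Raises :class:`SelectionError` if the window overruns the series.
        """
        from .errors import SelectionError

        i0 = int(round((start_time - self.start_time) * self.rate))
        n = int(round(duration * self.rate))
        if i0 < 0 or i0 + n > self.values.size:
            raise SelectionError(
                f"extract [{start_time:.3f}, {start_time + duration:.3f}] s overruns "
                f"series spanning [{self.start_time:.3f}, {self.end_time:.3f}] s"
            )
        return MagnitudeSeries(
            start_time=self.start_time + i0 / self.rate,
            rate=self.rate,
            values=self.values[i0 : i0 + n],
            sensor_label=self.sensor_label,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times(), "magnitude": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, sensor_label: str = "") -> "MagnitudeSeries":
        df = pd.read_csv(path)
        t = df["time"].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt.mean(), rtol=1e-6):
            raise DataError("magnitude CSV must carry a uniform timebase")
        return cls(
            start_time=float(t[0]),
            rate=float(1.0 / dt.mean()),
            values=df["magnitude"].to_numpy(dtype=float),
            sensor_label=sensor_label,
        )

    def to_hdf5(self, group) -> None:
        """Write into an open ``h5py`` group."""
        group.create_dataset("values", data=self.values)
        group.attrs["start_time"] = self.start_time
        group.attrs["rate"] = self.rate
        group.attrs["sensor_label"] = self.sensor_label

    @classmethod
    def from_hdf5(cls, group) -> "MagnitudeSeries":
        return cls(
            start_time=float(group.attrs["start_time"]),
            rate=float(group.attrs["rate"]),
            values=group["values"][...],
            sensor_label=str(group.attrs.get("sensor_label", "")),
        )


def load_recording(
    path,
    dialect: ColumnDialect | None = None,
    sensor_label: str = "",
    saturation_g: float = SATURATION_G,
) -> TriaxialRecording:
    """Load a delimited-text triaxial trace and validate it.

    Duplicate timestamps are collapsed to their first occurrence with a
    warning; any axis sample beyond ``saturation_g`` raises
    :class:`RangeError` because a saturated trace cannot be trusted.
    """
    dialect = dialect or ColumnDialect()
    df = pd.read_csv(path, delimiter=dialect.delimiter)
    missing = [c for c in (dialect.time, dialect.x, dialect.y, dialect.z) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if len(df) < 2:
        raise DataError(f"{path}: need at least 2 samples, found {len(df)}")

    if dialect.time_format == "iso8601":
        ts = pd.to_datetime(df[dialect.time])
        t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy(dtype=float)
    else:
        t = df[dialect.time].to_numpy(dtype=float)

    dup = np.zeros(t.size, dtype=bool)
    dup[1:] = t[1:] == t[:-1]
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicated timestamp(s) collapsed to first occurrence",
            stacklevel=2,
        )
        keep = ~dup
        df = df.loc[keep]
        t = t[keep]
    if not np.all(np.diff(t) > 0):
        raise DataError(f"{path}: timestamps not monotonically increasing")

    axes = {c: df[c].to_numpy(dtype=float) for c in (dialect.x, dialect.y, dialect.z)}
    for name, vals in axes.items():
        peak = float(np.max(np.abs(vals)))
        if peak > saturation_g:
            raise RangeError(
                f"{path}: column {name!r} reaches {peak:.3f} g, beyond the "
                f"{saturation_g:g} g saturation limit"
            )

    dt_med = float(np.median(np.diff(t)))
    return TriaxialRecording(
        timestamps=t,
        ax=axes[dialect.x],
        ay=axes[dialect.y],
        az=axes[dialect.z],
        sensor_label=sensor_label,
        nominal_rate=1.0 / dt_med,
    )


def synchronize_timebase(rec: TriaxialRecording, target_rate: float) -> TriaxialRecording:
    """Resample all three axes onto a uniform grid by linear interpolation.

    The grid spans exactly the original timestamp range — nothing is
    extrapolated beyond the recorded span.
    """
    if target_rate <= 0:
        raise ParameterError("target_rate must be positive")
    t0, t1 = rec.timestamps[0], rec.timestamps[-1]
    n = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    new_t = t0 + np.arange(n) / target_rate
    return TriaxialRecording(
        timestamps=new_t,
        ax=np.interp(new_t, rec.timestamps, rec.ax),
        ay=np.interp(new_t, rec.timestamps, rec.ay),
        az=np.interp(new_t, rec.timestamps, rec.az),
        sensor_label=rec.sensor_label,
        nominal_rate=target_rate,
    )


def magnitude(rec: TriaxialRecording) -> MagnitudeSeries:
    """Orientation-free acceleration magnitude of a uniformly sampled recording."""
    if not rec.is_uniform():
        raise StateError("magnitude requires a uniform timebase; call synchronize_timebase first")
    dt = np.diff(rec.timestamps).mean()
    return MagnitudeSeries(
        start_time=float(rec.timestamps[0]),
        rate=float(1.0 / dt),
        values=np.sqrt(rec.ax**2 + rec.ay**2 + rec.az**2),
        sensor_label=rec.sensor_label,
    )
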