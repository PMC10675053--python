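"""Two-dimensional Fourier transform (2DFT) gait features.

A 3-s *slab* of the acceleration-magnitude signal is cut into short
overlapping segments (0.3 s, overlap factor 2), each segment is
demeaned, Hann-tapered and Fourier-transformed (first transform,
magnitude kept), and a second Fourier transform is taken along the
segment-time axis of the resulting spectrogram (magnitude kept again).
The outcome is a signal-frequency × repetition-rate image: walking, a
quasi-periodic movement, shows up as energy at the step harmonics
repeating at the cadence.  Because both transforms keep magnitudes
only, the feature is insensitive to where in the gait cycle the slab
starts.

Features come in two densities.  The *low-density* matrix holds one
2DFT per hand-selected 3-s slab (ten per walking condition).  The
*high-density* matrix re-computes each slab's 2DFT at 0.1-s start-time
shifts over one second, multiplying the rows tenfold (300 in a full
three-condition session) — the training database for the discriminant
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.signal import get_window

from .errors import ParameterError, SelectionError, SizeError
from .io import MagnitudeSeries


@dataclass(frozen=True)
class SpectralParams:
    """Parameters of the two-stage spectral decomposition.

    ``slab_length``
        Duration of one feature extract, seconds.  3 s spans at least
        one gait cycle at any self-selected walking speed.
    ``temporal_resolution``
        Duration of one short-time segment (the first transform's
        window), seconds.
    ``overlap_factor``
        Segment hop = temporal_resolution / overlap_factor; a factor of
        2 makes adjacent segments share half their samples.
    ``window``
        Taper applied per segment (any name scipy.signal.get_window
        accepts).
    ``rate``
        Sampling rate of the magnitude signal, Hz.
    ``max_frequency``
        Optional cap on the signal-frequency axis retained in the
        feature, Hz; ``None`` keeps the full one-sided range.
    """

    slab_length: float = 3.0
    temporal_resolution: float = 0.3
    overlap_factor: int = 2
    window: str = "hann"
    rate: float = 100.0
    max_frequency: float | None = None

    def __post_init__(self) -> None:
        if not (self.slab_length >= self.temporal_resolution > 0):
            raise ParameterError("need slab_length >= temporal_resolution > 0")
        if self.overlap_factor < 1 or int(self.overlap_factor) != self.overlap_factor:
            raise ParameterError("overlap_factor must be an integer >= 1")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if self.segment_samples % self.overlap_factor != 0:
            raise ParameterError(
                f"segment of {self.segment_samples} samples does not divide by "
                f"overlap factor {self.overlap_factor}"
            )

    @property
    def segment_samples(self) -> int:
        return int(round(self.temporal_resolution * self.rate))

    @property
    def hop_samples(self) -> int:
        return self.segment_samples // int(self.overlap_factor)

    @property
    def slab_samples(self) -> int:
        return int(round(self.slab_length * self.rate))

    @property
    def hop_seconds(self) -> float:
        return self.hop_samples / self.rate


@dataclass(frozen=True)
class SlabSelection:
    """One labelled 3-s extract of known walking."""

    condition: str
    start_time: float
    slab_length: float = 3.0


@dataclass(frozen=True)
class TwoDftSpectrum:
    """One slab's 2DFT image and its flattened feature vector.

    ``matrix`` is indexed (signal frequency, repetition rate); the
    feature vector is the row-major (frequency-major) flattening, i.e.
    all repetition-rate bins of the lowest frequency first.
    """

    matrix: np.ndarray
    freqs: np.ndarray
    rep_rates: np.ndarray
    condition: str = ""
    origin_time: float = 0.0

    @property
    def feature_vector(self) -> np.ndarray:
        return self.matrix.ravel(order="C")


@dataclass(frozen=True)
class FeatureMatrix:
    """Stacked labelled 2DFT feature vectors (rows × features)."""

    rows: np.ndarray
    labels: np.ndarray
    density: str
    freqs: np.ndarray
    rep_rates: np.ndarray
    params: SpectralParams
    provenance: str = ""
    origin_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        if self.rows.ndim != 2 or self.labels.size != self.rows.shape[0]:
            raise ParameterError("rows must be 2-D with one label per row")
        if self.origin_times is None:
            object.__setattr__(self, "origin_times", np.zeros(self.rows.shape[0]))

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def n_features(self) -> int:
        return self.rows.shape[1]

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.rows)
        df.insert(0, "condition", self.labels)
        df.insert(1, "origin_time_s", self.origin_times)
        df.to_csv(path, index=False)

    def to_hdf5(self, path_or_group) -> None:
        own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
        g = h5py.File(path_or_group, "w") if own else path_or_group
        try:
            g.create_dataset("rows", data=self.rows)
            g.create_dataset("labels", data=np.array([str(s) for s in self.labels], dtype="S"))
            g.create_dataset("freqs", data=self.freqs)
            g.create_dataset("rep_rates", data=self.rep_rates)
            g.create_dataset("origin_times", data=self.origin_times)
            g.attrs["density"] = self.density
            g.attrs["provenance"] = self.provenance
            for k in ("slab_length", "temporal_resolution", "overlap_factor", "window", "rate"):
                g.attrs[f"params_{k}"] = getattr(self.params, k)
            if self.params.max_frequency is not None:
                g.attrs["params_max_frequency"] = self.params.max_frequency
        finally:
            if own:
                g.close()

    @classmethod
    def from_hdf5(cls, path_or_group) -> "FeatureMatrix":
        own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
        g = h5py.File(path_or_group, "r") if own else path_or_group
        try:
            params = SpectralParams(
                slab_length=float(g.attrs["params_slab_length"]),
                temporal_resolution=float(g.attrs["params_temporal_resolution"]),
                overlap_factor=int(g.attrs["params_overlap_factor"]),
                window=str(g.attrs["params_window"]),
                rate=float(g.attrs["params_rate"]),
                max_frequency=float(g.attrs["params_max_frequency"])
                if "params_max_frequency" in g.attrs
                else None,
            )
            return cls(
                rows=g["rows"][...],
                labels=np.array([s.decode() for s in g["labels"][...]], dtype=object),
                density=str(g.attrs["density"]),
                freqs=g["freqs"][...],
                rep_rates=g["rep_rates"][...],
                params=params,
                provenance=str(g.attrs.get("provenance", "")),
                origin_times=g["origin_times"][...],
            )
        finally:
            if own:
                g.close()


def segment_signal(values: np.ndarray, params: SpectralParams) -> np.ndarray:
    """Cut a slab into overlapping equal-length segments.

    Returns a (n_segments, segment_samples) array; segments that would
    overrun the slab are dropped rather than zero-padded.
    """
    values = np.asarray(values, dtype=float)
    w, hop = params.segment_samples, params.hop_samples
    n = values.size
    if n < w:
        raise SizeError(f"slab of {n} samples shorter than one {w}-sample segment")
    starts = np.arange(0, n - w + 1, hop)
    return np.stack([values[s : s + w] for s in starts])


def short_time_spectrum(windows: np.ndarray, params: SpectralParams) -> np.ndarray:
    """One-sided magnitude spectrogram of a stack of segments.

    Each segment has its mean removed (the ~1 g gravity offset would
    otherwise dominate every feature) and is tapered before the DFT.
    Rows are ordered by segment start time; columns are frequency bins
    0..floor(n/2).
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    if windows.size == 0:
        raise SizeError("no segments to transform")
    taper = get_window(params.window, windows.shape[1], fftbins=True)
    demeaned = windows - windows.mean(axis=1, keepdims=True)
    return np.abs(np.fft.rfft(demeaned * taper, axis=1))


def two_dft(slab: MagnitudeSeries, params: SpectralParams) -> TwoDftSpectrum:
    """2DFT of one slab: second DFT along the segment-time axis.

    The input must be exactly ``slab_length`` long.  Axis 0 of the
    result is signal frequency (Hz, resolution 1/temporal_resolution);
    axis 1 is the repetition rate of spectral features (cycles/s,
    resolution 1/(n_segments × hop)).
    """
    expected = params.slab_samples
    if slab.n_samples != expected:
        raise SizeError(
            f"slab has {slab.n_samples} samples; expected {expected} "
            f"({params.slab_length:g} s at {params.rate:g} Hz)"
        )
    spect = short_time_spectrum(segment_signal(slab.values, params), params)
    # second transform across segment start times; magnitudes only
    second = np.abs(np.fft.rfft(spect, axis=0))
    matrix = second.T  # (frequency, repetition rate)
    freqs = np.fft.rfftfreq(params.segment_samples, d=1.0 / params.rate)
    rep_rates = np.fft.rfftfreq(spect.shape[0], d=params.hop_seconds)
    if params.max_frequency is not None:
        keep = freqs <= params.max_frequency
        matrix, freqs = matrix[keep], freqs[keep]
    return TwoDftSpectrum(
        matrix=matrix,
        freqs=freqs,
        rep_rates=rep_rates,
        condition="",
        origin_time=slab.start_time,
    )


def _validated_slab(
    series: MagnitudeSeries, sel: SlabSelection, start_time: float
) -> MagnitudeSeries:
    try:
        return series.extract(start_time, sel.slab_length)
    except SelectionError as exc:
        raise SelectionError(
            f"selection ({sel.condition!r}, start {sel.start_time:.3f} s) "
            f"shifted to {start_time:.3f} s does not fit the recording"
        ) from exc


def _build_matrix(
    series: MagnitudeSeries,
    selections: Sequence[SlabSelection],
    params: SpectralParams,
    shifts: np.ndarray,
    density: str,
) -> FeatureMatrix:
    ordered = sorted(selections, key=lambda s: (s.condition, s.start_time))
    rows, labels, origins = [], [], []
    freqs = rep_rates = None
    for sel in ordered:
        for shift in shifts:
            slab = _validated_slab(series, sel, sel.start_time + float(shift))
            spec = two_dft(slab, params)
            rows.append(spec.feature_vector)
            labels.append(sel.condition)
            origins.append(slab.start_time)
            freqs, rep_rates = spec.freqs, spec.rep_rates
    return FeatureMatrix(
        rows=np.stack(rows),
        labels=np.array(labels, dtype=object),
        density=density,
        freqs=freqs,
        rep_rates=rep_rates,
        params=params,
        provenance=series.sensor_label,
        origin_times=np.array(origins),
    )


def build_low_density_matrix(
    series: MagnitudeSeries,
    selections: Sequence[SlabSelection],
    params: SpectralParams,
) -> FeatureMatrix:
    """One 2DFT per selection, rows ordered by (condition, start time)."""
    return _build_matrix(series, selections, params, np.array([0.0]), "low")


def build_high_density_matrix(
    series: MagnitudeSeries,
    selections: Sequence[SlabSelection],
    params: SpectralParams,
    increment: float = 0.1,
    span: float = 1.0,
) -> FeatureMatrix:
    """Temporal scan: each selection re-transformed at start-time shifts.

    Shifts run forward from each selection start in steps of
    ``increment`` over ``span`` seconds (span/increment slabs per
    selection), labelled with the parent selection's condition.
    """
    if increment <= 0 or span < increment:
        raise ParameterError("need span >= increment > 0")
    n_shifts = int(round(span / increment))
    shifts = np.arange(n_shifts) * increment
    return _build_matrix(series, selections, params, shifts, "high")


def read_selections(path, slab_length: float = 3.0) -> list[SlabSelection]:
    """Read a selections CSV with columns ``condition,start_time_s``."""
    df = pd.read_csv(path)
    missing = [c for c in ("condition", "start_time_s") if c not in df.columns]
    if missing:
        from .errors import FormatError

        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        SlabSelection(condition=str(r.condition), start_time=float(r.start_time_s),
                      slab_length=slab_length)
        for r in df.itertuples()
    ]


def write_selections(selections: Sequence[SlabSelection], path) -> None:
    pd.DataFrame(
        {
            "condition": [s.condition for s in selections],
            "start_time_s": [s.start_time for s in selections],
        }
    ).to_csv(path, index=False)
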