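"""Seeded synthetic accelerometer sessions for three walking speeds.

Real sessions consist of three blocks (self-selected slow, normal and
fast walking), each made of ten straight-line bouts separated by short
turn/deceleration phases that are excluded from analysis.  The
generator emulates that structure: per bout the vertical axis carries a
gravity baseline plus a sum of cadence harmonics

    a(t) = g + Σ_h A_h · cos(2π h f t + φ_h)

and one heel-strike impact transient per step — a short damped
oscillation around ~12 Hz whose amplitude grows with walking speed, the
dominant high-frequency feature of body-worn accelerometer traces.
Cadence drifts a little from bout to bout, both cadence and each
harmonic's amplitude are re-jittered every stride, white measurement
noise sits on every axis, and scaled copies of the vertical waveform
leak onto the two horizontal axes.  Turn gaps contain only gravity and
noise.  Faster walking gets a higher cadence, larger harmonic
amplitudes and sharper impacts — the features that separate the
conditions in the 2DFT.

Everything is deterministic under a fixed seed; per-condition substreams
are spawned from the session seed so conditions are independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .features import SlabSelection
from .io import ColumnDialect, TriaxialRecording

#: Fraction of the vertical gait waveform leaked onto the two horizontal axes.
_LATERAL_SCALES = (0.40, 0.25)

#: Default per-harmonic amplitudes (g) for normal-paced walking.
_BASE_AMPLITUDES = (0.45, 0.22, 0.10)


@dataclass(frozen=True)
class GaitConditionSpec:
    """Generative parameters of one walking condition."""

    label: str
    cadence: float  # steps/s
    harmonic_amplitudes: tuple[float, ...] = _BASE_AMPLITUDES
    amplitude_jitter: float = 0.10  # fractional SD, per stride and harmonic
    cadence_jitter: float = 0.03  # fractional SD, per stride
    bout_cadence_jitter: float = 0.03  # fractional SD of each bout's base cadence
    impact_amplitude: float = 0.50  # g, heel-strike transient peak
    impact_freq: float = 12.0  # Hz, transient ring frequency
    impact_width: float = 0.03  # s, transient Gaussian envelope SD
    noise_sd: float = 0.05  # g, white, per axis
    bout_length: float = 8.0  # s of straight-line walking
    n_bouts: int = 10
    turn_gap: float = 2.0  # s between bouts

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ParameterError("cadence must be positive")
        if any(a < 0 for a in self.harmonic_amplitudes):
            raise ParameterError("harmonic amplitudes must be nonnegative")
        if min(self.amplitude_jitter, self.cadence_jitter, self.bout_cadence_jitter,
               self.noise_sd, self.impact_amplitude) < 0:
            raise ParameterError("jitters, noise_sd and impact_amplitude must be nonnegative")
        if self.bout_length <= 0 or self.n_bouts < 1 or self.turn_gap < 0:
            raise ParameterError("invalid bout structure")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonic_amplitudes)


@dataclass(frozen=True)
class SessionSpec:
    """One full three-condition recording session."""

    conditions: tuple[GaitConditionSpec, GaitConditionSpec, GaitConditionSpec]
    rate: float = 100.0
    seed: int = 0
    gravity: float = 1.0  # g, baseline on the vertical axis
    rest_gap: float = 5.0  # s of quiet standing between condition blocks
    slab_length: float = 3.0
    scan_margin: float = 1.0  # extra seconds needed after each slab (high-density scan)
    n_selections: int = 10  # slab selections per condition
    sensor_label: str = "sacrum"

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(self.conditions) != 3 or len(set(labels)) != 3:
            raise ParameterError("a session needs three conditions with distinct labels")
        for c in self.conditions:
            if c.bout_length < self.slab_length + self.scan_margin:
                raise ParameterError(
                    f"condition {c.label!r}: bout_length {c.bout_length:g} s too short for a "
                    f"{self.slab_length:g} s slab plus {self.scan_margin:g} s scan margin"
                )
        if self.n_selections > min(c.n_bouts for c in self.conditions):
            raise ParameterError("cannot select more slabs than bouts per condition")


def default_session_spec(
    seed: int = 0,
    cadences: tuple[float, float, float] = (1.5, 1.9, 2.3),
    amplitude_scales: tuple[float, float, float] = (0.8, 1.0, 1.25),
    **condition_overrides,
) -> SessionSpec:
    """Standard slow/normal/fast session.

    Cadences default to 1.5 / 1.9 / 2.3 steps/s — under, roughly at,
    and above two steps per second — with harmonic amplitudes scaling
    up with speed, as impact accelerations do.
    """
    base_impact = condition_overrides.pop("impact_amplitude", 0.50)
    conditions = tuple(
        GaitConditionSpec(
            label=label,
            cadence=cad,
            harmonic_amplitudes=tuple(scale * a for a in _BASE_AMPLITUDES),
            impact_amplitude=base_impact * scale,
            **condition_overrides,
        )
        for label, cad, scale in zip(("slow", "normal", "fast"), cadences, amplitude_scales)
    )
    return SessionSpec(conditions=conditions, seed=seed)


def _bout_waveform(
    n: int, rate: float, spec: GaitConditionSpec,
    harmonic_phases: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """Vertical gait waveform of one bout (gravity excluded).

    Cadence is redrawn per stride around a bout-level base, each
    harmonic's amplitude is re-jittered per stride, and each step
    onset carries a heel-strike transient — a Gaussian-windowed ring at
    ``impact_freq`` — so the waveform is quasi-periodic rather than a
    pure tone.
    """
    t = np.arange(n) / rate
    duration = n / rate
    nh = spec.n_harmonics
    phase = np.empty(n)
    ampfac = np.empty((nh, n))
    impacts = np.zeros(n)
    base_cadence = spec.cadence * max(
        1.0 + spec.bout_cadence_jitter * rng.standard_normal(), 0.1
    )
    t_edge, k = 0.0, 0
    while t_edge < duration:
        f = base_cadence * max(1.0 + spec.cadence_jitter * rng.standard_normal(), 0.1)
        period = 1.0 / f
        in_stride = (t >= t_edge) & (t < t_edge + period)
        phase[in_stride] = 2 * np.pi * (k + (t[in_stride] - t_edge) / period)
        ampfac[:, in_stride] = np.maximum(
            1.0 + spec.amplitude_jitter * rng.standard_normal(nh), 0.0
        )[:, None]
        if spec.impact_amplitude > 0:
            a_imp = spec.impact_amplitude * max(
                1.0 + spec.amplitude_jitter * rng.standard_normal(), 0.0
            )
            near = np.abs(t - t_edge) < 4 * spec.impact_width
            dt = t[near] - t_edge
            impacts[near] += (
                a_imp
                * np.exp(-0.5 * (dt / spec.impact_width) ** 2)
                * np.cos(2 * np.pi * spec.impact_freq * dt)
            )
        t_edge += period
        k += 1
    w = impacts
    for h, amp in enumerate(spec.harmonic_amplitudes, start=1):
        w = w + amp * ampfac[h - 1] * np.cos(h * phase + harmonic_phases[h - 1])
    return w


def generate_condition_signal(
    spec: GaitConditionSpec,
    rate: float,
    seed: int | np.random.SeedSequence,
    gravity: float = 1.0,
    harmonic_phases: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Triaxial trace of one condition block.

    Returns ``(ax, ay, az, bout_starts)`` where ``bout_starts`` are the
    straight-line bout onset times in seconds relative to the block
    start.  The block ends with its last bout (no trailing turn gap).

    ``harmonic_phases`` fixes the relative phases of the cadence
    harmonics — the walker's waveform shape.  A session shares one set
    across its conditions (one walker, one gait pattern); when omitted
    it is drawn from the condition's own stream.
    """
    rng = np.random.default_rng(seed)
    bout_n = int(round(spec.bout_length * rate))
    gap_n = int(round(spec.turn_gap * rate))
    total_n = spec.n_bouts * bout_n + (spec.n_bouts - 1) * gap_n

    if harmonic_phases is None:
        phases = 2 * np.pi * rng.random(spec.n_harmonics)
    else:
        phases = np.asarray(harmonic_phases, dtype=float)
    vertical = np.zeros(total_n)
    bout_starts = []
    for b in range(spec.n_bouts):
        i0 = b * (bout_n + gap_n)
        bout_starts.append(i0 / rate)
        vertical[i0 : i0 + bout_n] = _bout_waveform(bout_n, rate, spec, phases, rng)

    ax = _LATERAL_SCALES[0] * vertical + spec.noise_sd * rng.standard_normal(total_n)
    ay = _LATERAL_SCALES[1] * vertical + spec.noise_sd * rng.standard_normal(total_n)
    az = gravity + vertical + spec.noise_sd * rng.standard_normal(total_n)
    return ax, ay, az, np.array(bout_starts)


def generate_session(spec: SessionSpec) -> tuple[TriaxialRecording, list[SlabSelection]]:
    """Full session: concatenated condition blocks plus ground-truth slabs.

    Returns the uniform-rate recording and ``n_selections`` slab
    selections per condition, each placed inside a straight-line bout
    with enough headroom for the high-density temporal scan.
    """
    root = np.random.SeedSequence(spec.seed)
    cond_seeds = root.spawn(len(spec.conditions) + 2)
    pick_rng = np.random.default_rng(cond_seeds[-1])
    # the walker's waveform shape is a session-level trait
    n_harm = max(c.n_harmonics for c in spec.conditions)
    harmonic_phases = 2 * np.pi * np.random.default_rng(cond_seeds[-2]).random(n_harm)

    rate = spec.rate
    gap_n = int(round(spec.rest_gap * rate))
    segments, selections = [], []
    t_offset = 0.0
    for cond, sseq in zip(spec.conditions, cond_seeds):
        ax, ay, az, bout_starts = generate_condition_signal(
            cond, rate, sseq, spec.gravity, harmonic_phases[: cond.n_harmonics]
        )
        segments.append((ax, ay, az))
        # slab start may roam inside the bout but must leave scan headroom
        max_offset = cond.bout_length - spec.slab_length - spec.scan_margin
        chosen = pick_rng.choice(cond.n_bouts, size=spec.n_selections, replace=False)
        for b in sorted(chosen):
            offset = pick_rng.uniform(0.0, max_offset)
            start = t_offset + bout_starts[b] + round(offset * rate) / rate
            selections.append(
                SlabSelection(condition=cond.label, start_time=start,
                              slab_length=spec.slab_length)
            )
        t_offset += ax.size / rate + spec.rest_gap
        rest_rng = np.random.default_rng(sseq.spawn(1)[0])
        rest = (
            cond.noise_sd * rest_rng.standard_normal((3, gap_n))
            + np.array([[0.0], [0.0], [spec.gravity]])
        )
        segments.append(tuple(rest))

    segments = segments[:-1]  # no trailing rest after the final block
    ax = np.concatenate([s[0] for s in segments])
    ay = np.concatenate([s[1] for s in segments])
    az = np.concatenate([s[2] for s in segments])
    t = np.arange(ax.size) / rate
    rec = TriaxialRecording(
        timestamps=t, ax=ax, ay=ay, az=az,
        sensor_label=spec.sensor_label, nominal_rate=rate,
    )
    return rec, selections


def write_session_csv(
    rec: TriaxialRecording, path, dialect: ColumnDialect | None = None
) -> None:
    """Emit a recording in the same delimited dialect the loader reads."""
    dialect = dialect or ColumnDialect()
    pd.DataFrame(
        {
            dialect.time: rec.timestamps,
            dialect.x: rec.ax,
            dialect.y: rec.ay,
            dialect.z: rec.az,
        }
    ).to_csv(path, index=False, sep=dialect.delimiter)
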