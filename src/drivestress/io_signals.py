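"""Signal file I/O, study configuration and experiment-stage handling.

A recording session consists of two synchronized, uniformly sampled traces —
single-lead ECG (mV) and vehicle longitudinal acceleration (m/s²) — stored as
two-column CSV files (``time_s,value``), plus a YAML manifest binding the files
to subject metadata, the stage schedule and analysis configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SignalTrace",
    "StageAnnotation",
    "SubjectMeta",
    "StudyConfig",
    "MalformedInputError",
    "SamplingError",
    "STAGES",
    "read_signal_csv",
    "write_signal_csv",
    "apply_stages",
    "read_manifest",
    "write_manifest",
]

#: canonical stage order of a driving session
STAGES = ("before", "driving", "after")

_REL_TOL = 1e-6  # relative tolerance on time-step uniformity


class MalformedInputError(ValueError):
    """Raised when a signal file violates its basic contract."""


class SamplingError(ValueError):
    """Raised when the time column is not uniformly sampled."""


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled time series (ECG in mV or acceleration in m/s²).

    Sample ``i`` is located at ``t0 + i / fs`` seconds.
    """

    t0: float
    fs: float
    values: np.ndarray
    kind: Literal["ecg", "accel"]
    units: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if self.kind not in ("ecg", "accel"):
            raise ValueError(f"unknown signal kind {self.kind!r}")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Span from the first to one step past the last sample (s)."""
        return self.n / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.n / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass(frozen=True)
class StageAnnotation:
    """Half-open stage intervals ``[start, end)`` in seconds, plus the
    equipment warm-up duration discarded at the very start of the recording."""

    before: tuple[float, float] = (0.0, 60.0)
    driving: tuple[float, float] = (60.0, 560.0)
    after: tuple[float, float] = (560.0, 660.0)
    discard_head: float = 0.5

    def __post_init__(self) -> None:
        iv = [self.before, self.driving, self.after]
        for lo, hi in iv:
            if not hi > lo:
                raise ValueError(f"empty or inverted stage interval ({lo}, {hi})")
        for (_, hi), (lo, _) in zip(iv, iv[1:]):
            if lo < hi:
                raise ValueError("stage intervals must be ordered and disjoint")
        if self.discard_head < 0:
            raise ValueError("discard_head must be >= 0")

    def interval(self, stage: str) -> tuple[float, float]:
        return {"before": self.before, "driving": self.driving, "after": self.after}[stage]


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    age: int
    group: Literal["elderly", "young"]

    def __post_init__(self) -> None:
        if self.age < 16:
            raise ValueError("subjects are licensed drivers; age must be >= 16")
        if self.group not in ("elderly", "young"):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class StudyConfig:
    """Analysis configuration.

    Parameters
    ----------
    mtw_s:
        Maximum Time Window — lookback (s) linking a flagged RR interval to
        the preceding vehicle motion.
    hist_min, hist_max, hist_bin:
        Acceleration range and bin width (m/s²) for the gradient-validation
        histogram.
    norm_window_s:
        Length (s) of the contiguous ECG normalization windows.
    k:
        Number of RR clusters (low/medium/high tension by default).
    vigorous_fraction:
        Lower bound of the vigorous-exercise heart-rate zone, as a fraction
        of the age-predicted maximum heart rate ``220 - age``; sizes the
        R-peak search window.
    direction:
        Which side of the cluster threshold counts as "tense": ``above``
        flags long RR intervals (the literal published rule), ``below``
        flags short ones (tachycardic response).
    rr_mode:
        ``raw`` clusters individual RR values; ``sdrr30`` clusters the
        standard deviation of RR over 30-s windows.
    """

    mtw_s: float = 30.0
    hist_min: float = 1.0
    hist_max: float = 6.5
    hist_bin: float = 0.1
    norm_window_s: float = 2.0
    k: int = 3
    seed: int = 0
    vigorous_fraction: float = 0.77
    direction: Literal["above", "below"] = "above"
    rr_mode: Literal["raw", "sdrr30"] = "raw"
    sdrr_window_s: float = 30.0
    #: RR artifact gate as fractions of the driving-stage median RR;
    #: intervals outside [low, high] x median are detection artifacts.
    artifact_gate_low: float = 0.5
    artifact_gate_high: float = 1.3
    artifact_gate: bool = True

    def __post_init__(self) -> None:
        if self.mtw_s <= 0:
            raise ValueError("mtw_s must be positive")
        if not self.hist_min < self.hist_max:
            raise ValueError("hist_min must be below hist_max")
        if self.hist_bin <= 0:
            raise ValueError("hist_bin must be positive")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.vigorous_fraction <= 1:
            raise ValueError("vigorous_fraction must lie in (0, 1]")
        if self.direction not in ("above", "below"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.rr_mode not in ("raw", "sdrr30"):
            raise ValueError(f"unknown rr_mode {self.rr_mode!r}")
        if not 0 <= self.artifact_gate_low < 1 < self.artifact_gate_high:
            raise ValueError("artifact gate must straddle the median (low < 1 < high)")

    def with_overrides(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)


def read_signal_csv(path: str | Path, kind: Literal["ecg", "accel"]) -> SignalTrace:
    """Read a two-column ``time_s,value`` CSV into a :class:`SignalTrace`.

    The sampling rate is inferred from the median time step; the time column
    must be strictly increasing and uniform to within a relative tolerance
    of 1e-6.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise MalformedInputError(f"{path}: expected a time column and a value column")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise MalformedInputError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 1
        raise MalformedInputError(f"{path}: time column not strictly increasing at row {bad}")
    # the shortest step is the nominal period: acquisition glitches (dropped
    # or delayed samples) only ever lengthen the apparent step
    step = float(dt.min())
    off = np.abs(dt - step) > _REL_TOL * max(abs(step), 1.0)
    if np.any(off):
        bad = int(np.argmax(off)) + 1
        raise SamplingError(f"{path}: non-uniform sampling at index {bad} (dt={dt[bad - 1]:g}, expected {step:g})")
    step = float(np.median(dt))
    units = "mV" if kind == "ecg" else "m/s^2"
    return SignalTrace(t0=float(t[0]), fs=1.0 / step, values=v, kind=kind, units=units)


def write_signal_csv(path: str | Path, trace: SignalTrace) -> None:
    """Write a trace as ``time_s,value`` CSV (full float round-trip precision)."""
    df = pd.DataFrame({"time_s": trace.times(), "value": trace.values})
    df.to_csv(path, index=False, float_format="%.17g")


def _slice(trace: SignalTrace, lo: float, hi: float) -> SignalTrace:
    """Samples with time in the half-open interval ``[lo, hi)``."""
    # tiny slack guards against float round-off on grid-aligned boundaries
    i0 = int(np.ceil((lo - trace.t0) * trace.fs - 1e-9))
    i1 = int(np.ceil((hi - trace.t0) * trace.fs - 1e-9))
    i0, i1 = max(i0, 0), min(i1, trace.n)
    if i1 - i0 < 2:
        raise ValueError(f"stage [{lo}, {hi}) leaves fewer than 2 samples")
    return SignalTrace(
        t0=trace.t0 + i0 / trace.fs,
        fs=trace.fs,
        values=trace.values[i0:i1],
        kind=trace.kind,
        units=trace.units,
    )


def apply_stages(trace: SignalTrace, stages: StageAnnotation) -> dict[str, SignalTrace]:
    """Split a trace into its before / driving / after stage segments.

    Samples inside the first ``discard_head`` seconds of the recording are
    dropped (they belong to no segment); the stage intervals must lie within
    the span of the trace.
    """
    for name in STAGES:
        lo, hi = stages.interval(name)
        if lo < trace.t0 - 0.5 / trace.fs or hi > trace.t_end + 0.5 / trace.fs:
            raise ValueError(
                f"stage {name} [{lo}, {hi}) outside trace span [{trace.t0}, {trace.t_end})"
            )
    out: dict[str, SignalTrace] = {}
    for name in STAGES:
        lo, hi = stages.interval(name)
        if name == "before":
            lo = max(lo, trace.t0 + stages.discard_head)
        out[name] = _slice(trace, lo, hi)
    return out


# ---------------------------------------------------------------------------
# session manifest


def write_manifest(
    path: str | Path,
    *,
    ecg_file: str,
    accel_file: str,
    subject: SubjectMeta,
    stages: StageAnnotation,
    config: StudyConfig,
) -> None:
    doc = {
        "ecg_file": ecg_file,
        "accel_file": accel_file,
        "subject": {"subject_id": subject.subject_id, "age": subject.age, "group": subject.group},
        "stages": {
            "before": list(stages.before),
            "driving": list(stages.driving),
            "after": list(stages.after),
            "discard_head": stages.discard_head,
        },
        "config": {
            "mtw_s": config.mtw_s,
            "hist_min": config.hist_min,
            "hist_max": config.hist_max,
            "hist_bin": config.hist_bin,
            "norm_window_s": config.norm_window_s,
            "k": config.k,
            "seed": config.seed,
            "vigorous_fraction": config.vigorous_fraction,
            "direction": config.direction,
            "rr_mode": config.rr_mode,
            "sdrr_window_s": config.sdrr_window_s,
            "artifact_gate_low": config.artifact_gate_low,
            "artifact_gate_high": config.artifact_gate_high,
            "artifact_gate": config.artifact_gate,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path: str | Path):
    """Load a session manifest.

    Returns ``(ecg_path, accel_path, subject, stages, config)``; the signal
    paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("ecg_file", "accel_file", "subject", "stages"):
        if key not in doc:
            raise MalformedInputError(f"{path}: manifest missing key {key!r}")
    base = path.parent
    subject = SubjectMeta(**doc["subject"])
    st = doc["stages"]
    stages = StageAnnotation(
        before=tuple(st["before"]),
        driving=tuple(st["driving"]),
        after=tuple(st["after"]),
        discard_head=float(st.get("discard_head", 0.0)),
    )
    config = StudyConfig(**doc.get("config", {}))
    return base / doc["ecg_file"], base / doc["accel_file"], subject, stages, config
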