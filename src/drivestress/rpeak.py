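"""Lightweight R-peak detection for noisy in-vehicle ECG.

The detector is deliberately simple — designed for low-quality mobile
recordings rather than clinical delineation:

1. **Windowed normalization.** The raw ECG is z-scored over short contiguous
   windows, which removes baseline drift and makes detection invariant to the
   absolute QRS amplitude (elderly subjects often present much weaker QRS
   complexes).
2. **Statistical candidate threshold.** Within each experiment stage, samples
   exceeding the stage mean plus one standard deviation of the normalized
   signal are R-peak candidates.
3. **TWRD max-picking.** Time is tiled into frames of length TWRD (the
   R-peak search window, sized from the age-predicted vigorous-exercise
   heart rate, so that at most one true beat can fall in a frame); the
   largest candidate per frame is kept.
4. **Refractory cleanup.** Of any two accepted peaks closer than the
   age-predicted maximum-heart-rate period, the later one is deleted as a
   duplicate.

RR intervals are the successive peak-to-peak differences within a stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_signals import SignalTrace, StudyConfig
from .stats import GroupSummary, summarize

__all__ = [
    "NormalizedTrace",
    "RPeakSeries",
    "RRSeries",
    "AgeWindows",
    "normalize_ecg",
    "age_windows",
    "detect_rpeaks",
    "rr_from_peaks",
    "stage_rr_summary",
]


@dataclass(frozen=True)
class NormalizedTrace:
    """Windowed z-score of an ECG trace (dimensionless)."""

    t0: float
    fs: float
    values: np.ndarray
    norm_window_s: float

    @property
    def n(self) -> int:
        return int(self.values.size)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass(frozen=True)
class RPeakSeries:
    """Detected beat fiducials: times (s), normalized amplitudes, stage labels."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    stage: np.ndarray  # str label per peak

    @property
    def n(self) -> int:
        return int(self.peak_times.size)


@dataclass(frozen=True)
class RRSeries:
    """Inter-beat intervals (ms), stamped at the later peak of each pair."""

    rr_ms: np.ndarray
    rr_times: np.ndarray
    stage: np.ndarray

    @property
    def n(self) -> int:
        return int(self.rr_ms.size)

    def for_stage(self, stage: str) -> "RRSeries":
        m = self.stage == stage
        return RRSeries(self.rr_ms[m], self.rr_times[m], self.stage[m])


@dataclass(frozen=True)
class AgeWindows:
    """Age-dependent detector windows (seconds)."""

    twrd_s: float
    refractory_s: float

    def __post_init__(self) -> None:
        if not 0 < self.refractory_s < self.twrd_s:
            raise ValueError("need 0 < refractory_s < twrd_s")


def normalize_ecg(trace: SignalTrace, norm_window_s: float = 2.0) -> NormalizedTrace:
    """Z-score an ECG trace over contiguous non-overlapping windows.

    Each sample is mapped to ``(value - window mean) / window SD`` using the
    statistics of its own window (sample SD, n-1 denominator). Windows of
    zero variance — flat leads, disconnection artifacts — map to 0.
    """
    if trace.kind != "ecg":
        raise ValueError("normalize_ecg expects an ECG trace")
    w = int(round(norm_window_s * trace.fs))
    if w < 8:
        raise ValueError("normalization window must contain at least 8 samples")
    if w > trace.n:
        raise ValueError(
            f"normalization window ({norm_window_s} s) longer than trace ({trace.duration:.3f} s)"
        )
    v = trace.values
    out = np.empty_like(v)
    n_full = v.size // w
    if n_full:
        block = v[: n_full * w].reshape(n_full, w)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        live = sd > 1e-10 * np.maximum(np.abs(mu), 1.0)  # flat lead -> 0, not float fuzz
        z = np.divide(block - mu, sd, out=np.zeros_like(block), where=live)
        out[: n_full * w] = z.ravel()
    rem = v[n_full * w :]
    if rem.size:
        sd_r = rem.std(ddof=1) if rem.size >= 2 else 0.0
        if sd_r > 1e-10 * max(abs(float(rem.mean())), 1.0):
            out[n_full * w :] = (rem - rem.mean()) / sd_r
        else:
            out[n_full * w :] = 0.0
    return NormalizedTrace(t0=trace.t0, fs=trace.fs, values=out, norm_window_s=norm_window_s)


def age_windows(age: int, config: StudyConfig | None = None) -> AgeWindows:
    """Size the detector windows from the subject's age.

    The maximum credible heart rate is ``220 - age`` bpm; during driving a
    subject cannot sustain even the lower bound of the vigorous-exercise zone
    (a fraction ``vigorous_fraction``, default 0.77, of maximum). Hence at
    most one beat can occur per ``twrd_s = 60 / (0.77 * (220 - age))``
    seconds, and two detections closer than the maximum-heart-rate period
    ``refractory_s = 60 / (220 - age)`` must share one beat.
    """
    if not 16 <= age <= 100:
        raise ValueError(f"age {age} outside supported range [16, 100]")
    frac = config.vigorous_fraction if config is not None else 0.77
    max_hr = 220.0 - age
    return AgeWindows(twrd_s=60.0 / (frac * max_hr), refractory_s=60.0 / max_hr)


def _detect_one_stage(
    norm: NormalizedTrace, windows: AgeWindows, stage_stats: tuple[float, float] | None
) -> tuple[np.ndarray, np.ndarray]:
    v = norm.values
    if v.size == 0:
        return np.empty(0), np.empty(0)
    if stage_stats is None:
        mu, sd = float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0
    else:
        mu, sd = stage_stats
    cand = np.flatnonzero(v > mu + sd)
    if cand.size == 0:
        return np.empty(0), np.empty(0)
    # frames of length twrd_s anchored at the stage start; max candidate per frame
    frame = (cand / (windows.twrd_s * norm.fs)).astype(np.int64)
    order = np.lexsort((v[cand], frame))
    cand, frame = cand[order], frame[order]
    last_of_frame = np.flatnonzero(np.diff(frame, append=frame[-1] + 1) != 0)
    picked = cand[last_of_frame]
    picked.sort()
    # refractory pass: two picks closer than refractory_s are duplicate
    # detections of one beat — keep the larger (the true apex; a QRS tail
    # crossing a frame edge yields a smaller pick one frame early), deleting
    # the later one on ties
    min_gap = windows.refractory_s * norm.fs
    kept: list[int] = []
    for idx in picked:
        if kept and idx - kept[-1] < min_gap:
            if v[idx] > v[kept[-1]]:
                kept[-1] = int(idx)
            continue
        kept.append(int(idx))
    kept_arr = np.asarray(kept, dtype=np.int64)
    return norm.t0 + kept_arr / norm.fs, v[kept_arr]


def detect_rpeaks(
    norm: NormalizedTrace | dict[str, NormalizedTrace],
    windows: AgeWindows,
    stage_stats: dict[str, tuple[float, float]] | None = None,
) -> RPeakSeries:
    """Detect R-peaks in normalized ECG, per stage.

    ``norm`` is either one trace (treated as a single unnamed stage) or a
    mapping of stage label to normalized segment. Candidate thresholds use
    the mean + SD of the normalized values within each stage, unless
    ``stage_stats`` supplies ``{stage: (mean, sd)}`` overrides.
    """
    segments = {"all": norm} if isinstance(norm, NormalizedTrace) else norm
    times, vals, labels = [], [], []
    for name, seg in segments.items():
        st = stage_stats.get(name) if stage_stats else None
        t, v = _detect_one_stage(seg, windows, st)
        times.append(t)
        vals.append(v)
        labels.append(np.full(t.size, name, dtype=object))
    t = np.concatenate(times) if times else np.empty(0)
    return RPeakSeries(
        peak_times=t,
        peak_values=np.concatenate(vals) if vals else np.empty(0),
        stage=np.concatenate(labels) if labels else np.empty(0, dtype=object),
    )


def rr_from_peaks(peaks: RPeakSeries) -> RRSeries:
    """Successive peak-to-peak intervals in ms, never crossing a stage boundary.

    Each interval is stamped at the time of the later peak of its pair.
    """
    rr, times, labels = [], [], []
    for name in dict.fromkeys(peaks.stage):  # preserve stage order
        m = peaks.stage == name
        t = np.sort(peaks.peak_times[m])
        if t.size < 2:
            continue
        rr.append(np.diff(t) * 1000.0)
        times.append(t[1:])
        labels.append(np.full(t.size - 1, name, dtype=object))
    if not rr:
        return RRSeries(np.empty(0), np.empty(0), np.empty(0, dtype=object))
    return RRSeries(np.concatenate(rr), np.concatenate(times), np.concatenate(labels))


def stage_rr_summary(rr: RRSeries) -> dict[str, GroupSummary]:
    """Per-stage mean and sample SD of the RR intervals (ms)."""
    out: dict[str, GroupSummary] = {}
    for name in dict.fromkeys(rr.stage):
        out[name] = summarize(rr.rr_ms[rr.stage == name])
    return out
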