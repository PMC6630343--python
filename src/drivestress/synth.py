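"""Synthetic in-vehicle driving sessions with known ground truth.

Emulates what a chest-worn mobile ECG unit plus the vehicle's longitudinal
accelerometer record during a staged driving experiment (relax / drive /
relax), with every quantity the analysis pipeline estimates planted by
construction:

* **RR dynamics** — per-stage baseline RR intervals (defaults follow the
  published group means: elderly ≈ 812/753/803 ms before/driving/after,
  young ≈ 649/625/658 ms) with Gaussian beat-to-beat jitter. A fixed cardiac
  lag ``L`` after each acceleration burst, the RR interval shortens by a
  fixed fraction for a few beats (a tachycardic episode — the physiological
  stress response); a bradycardic episode mode is available as a positive
  control for the long-RR flagging rule.
* **ECG** — each beat renders a narrow Gaussian QRS template (apex amplitude
  age-dependent: elderly QRS is markedly weaker) on a zero baseline, plus
  additive noise modeled as low-frequency baseline wander (motion artifact,
  the dominant term in a vehicle) and white sensor noise.
* **Acceleration** — near-zero baseline with white noise and smooth
  raised-cosine bursts of known peak ``A*`` at known times.

Beat times are snapped to the ECG sample grid and burst times to the
acceleration grid, so noise-free recovery is exact to the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .io_signals import (
    SignalTrace,
    StageAnnotation,
    StudyConfig,
    SubjectMeta,
    write_manifest,
    write_signal_csv,
)
from .rpeak import RRSeries

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "RR_BASELINES_MS",
    "generate_rr",
    "rr_to_ecg",
    "generate_accel",
    "generate_session",
    "threshold_session_params",
    "noise_for_snr",
]

#: published per-stage mean RR (ms) by group: (before, driving, after)
RR_BASELINES_MS = {
    "elderly": (812.29, 752.87, 803.36),
    "young": (649.43, 624.63, 657.93),
}


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition parameters of one synthetic session."""

    group: Literal["elderly", "young"] = "elderly"
    stages: StageAnnotation = field(default_factory=StageAnnotation)
    fs_ecg: float = 256.0
    fs_accel: float = 50.0
    rr_baseline_ms: tuple[float, float, float] | None = None  # None -> group default
    rr_jitter_sd_ms: float = 10.0
    burst_times: tuple[float, ...] = (120.0, 180.0, 240.0, 300.0, 360.0, 420.0, 480.0)
    burst_peak: float = 3.2  # A*, m/s²
    burst_peaks: tuple[float, ...] | None = None  # per-burst peaks; None -> burst_peak for all
    response_threshold: float | None = None  # bursts below this peak trigger no cardiac episode
    burst_width_s: float = 4.0
    cardiac_lag_s: float = 14.0  # L
    tachy_drop_frac: float = 0.3
    tachy_duration_beats: int = 5
    episode_mode: Literal["tachy", "brady"] = "tachy"
    qrs_amplitude_mv: float | None = None  # None -> 0.4 elderly, 1.0 young
    qrs_sigma_s: float = 0.008  # Gaussian QRS template SD (~40 ms full width)
    noise_sd_mv: float = 0.01  # white sensor noise floor
    wander_sd_mv: float = 0.02  # low-frequency motion-artifact wander
    accel_noise_sd: float = 0.02  # m/s²
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_ecg < 100:
            raise ValueError("fs_ecg below 100 Hz cannot resolve the QRS template")
        if not 0 < self.tachy_drop_frac < 1:
            raise ValueError("tachy_drop_frac must lie in (0, 1)")
        if self.cardiac_lag_s <= 0 or self.burst_width_s <= 0:
            raise ValueError("durations must be positive")
        bt = np.asarray(self.burst_times, dtype=float)
        if self.burst_peaks is not None and len(self.burst_peaks) != bt.size:
            raise ValueError("burst_peaks must match burst_times in length")
        if bt.size:
            rr_drv = self.baselines_ms()[1] / 1000.0
            episode_len = self.tachy_duration_beats * rr_drv + 2.0
            if np.any(np.diff(bt) < episode_len):
                raise ValueError("bursts closer than one cardiac episode; responses would overlap")

    def peak_of(self) -> np.ndarray:
        """Peak amplitude per burst (m/s²)."""
        if self.burst_peaks is not None:
            return np.asarray(self.burst_peaks, dtype=float)
        return np.full(len(self.burst_times), self.burst_peak)

    def triggering_bursts(self) -> np.ndarray:
        """Burst times whose peak reaches the cardiac response threshold."""
        bt = np.asarray(self.burst_times, dtype=float)
        order = np.argsort(bt)
        bt, pk = bt[order], self.peak_of()[order]
        if self.response_threshold is None:
            return bt
        return bt[pk >= self.response_threshold]

    def baselines_ms(self) -> tuple[float, float, float]:
        return self.rr_baseline_ms or RR_BASELINES_MS[self.group]

    def qrs_amplitude(self) -> float:
        if self.qrs_amplitude_mv is not None:
            return self.qrs_amplitude_mv
        return 0.4 if self.group == "elderly" else 1.0

    @property
    def duration_s(self) -> float:
        return self.stages.after[1]

    def with_overrides(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted (never read by the analysis pipeline)."""

    true_peak_times: np.ndarray  # s, ECG-grid-aligned beat times
    true_palpitation_times: np.ndarray  # s, beats stamping episode RR intervals
    a_star: float  # planted burst peak, m/s²
    lag_s: float  # planted cardiac lag L, s
    burst_times: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        flagged = np.isin(self.true_peak_times, self.true_palpitation_times)
        return pd.DataFrame({"beat_time_s": self.true_peak_times, "palpitation": flagged.astype(int)})


def _stage_of(t: float, stages: StageAnnotation) -> str | None:
    for name in ("before", "driving", "after"):
        lo, hi = stages.interval(name)
        if lo <= t < hi:
            return name
    return None


def generate_rr(params: GeneratorParams) -> tuple[RRSeries, GroundTruth]:
    """Simulate beat times and the RR series with planted cardiac episodes.

    Each RR interval is the baseline of the stage it starts in plus Gaussian
    jitter. The cardiac state switches ``cardiac_lag_s`` after each
    (triggering) burst peak: starting with the interval in progress at that
    instant, ``tachy_duration_beats`` intervals are multiplied by
    ``1 - drop`` (tachy) or ``1 + drop`` (brady). Beat times are snapped to
    the ECG sample grid.
    """
    rng = np.random.default_rng(params.seed)
    base = {s: b / 1000.0 for s, b in zip(("before", "driving", "after"), params.baselines_ms())}
    factor = (
        1.0 - params.tachy_drop_frac if params.episode_mode == "tachy" else 1.0 + params.tachy_drop_frac
    )
    bursts = list(params.triggering_bursts())
    next_burst = 0
    remaining = 0  # episode beats still to emit
    t = params.stages.discard_head + 0.5
    beats: list[float] = []
    palp: list[float] = []
    while True:
        stage = _stage_of(t, params.stages)
        if stage is None:
            break
        beats.append(round(t * params.fs_ecg) / params.fs_ecg)
        rr = base[stage] + rng.normal(0.0, params.rr_jitter_sd_ms / 1000.0)
        rr = max(rr, 0.25)
        # the cardiac state switches at burst + L: the interval in progress
        # at that instant is the first one affected
        if next_burst < len(bursts) and t + rr >= bursts[next_burst] + params.cardiac_lag_s:
            remaining = params.tachy_duration_beats
            next_burst += 1
        if remaining > 0:
            rr *= factor
            remaining -= 1
            palp.append(round((t + rr) * params.fs_ecg) / params.fs_ecg)
        t += rr
    beat_times = np.asarray(beats)
    a_star = params.response_threshold if params.response_threshold is not None else params.burst_peak
    truth = GroundTruth(
        true_peak_times=beat_times,
        true_palpitation_times=np.asarray(palp),
        a_star=a_star,
        lag_s=params.cardiac_lag_s,
        burst_times=np.asarray(bursts),
    )
    # RR series labelled by the later beat's stage, never crossing stages
    rr_ms, rr_t, labels = [], [], []
    for t0, t1 in zip(beat_times, beat_times[1:]):
        s0, s1 = _stage_of(t0, params.stages), _stage_of(t1, params.stages)
        if s0 is None or s1 != s0:
            continue
        rr_ms.append((t1 - t0) * 1000.0)
        rr_t.append(t1)
        labels.append(s1)
    rr_series = RRSeries(np.asarray(rr_ms), np.asarray(rr_t), np.asarray(labels, dtype=object))
    return rr_series, truth


def threshold_session_params(
    a_star: float = 3.2,
    seed: int = 0,
    group: Literal["elderly", "young"] = "elderly",
    **overrides,
) -> GeneratorParams:
    """Session layout with a sharp planted safe-driving threshold at ``a_star``.

    Driving contains bursts every 30 s with graded peaks: several below the
    threshold (no cardiac response), a dense group just above it and a sparse
    tail further up. The palpitation-count histogram then carries its largest
    count gap at the bin edge nearest ``a_star``, which the gradient
    validation should recover.
    """
    times = tuple(90.0 + 30.0 * i for i in range(15))
    below = [a_star - d for d in (1.6, 1.35, 1.1, 0.85, 0.6, 0.35)]
    dense = [a_star + d for d in (0.02, 0.03, 0.04, 0.05, 0.06, 0.08)]
    tail = [a_star + 0.25, a_star + 0.45, a_star + 0.85]
    # interleave so neighbouring bursts alternate between regimes
    pools = [iter(below), iter(dense), iter(tail)]
    peaks: list[float] = []
    i = 0
    while len(peaks) < 15:
        try:
            peaks.append(next(pools[i % 3]))
        except StopIteration:
            pass
        i += 1
    return GeneratorParams(
        group=group,
        seed=seed,
        burst_times=times,
        burst_peaks=tuple(peaks),
        response_threshold=a_star,
        **overrides,
    )


def noise_for_snr(clean: np.ndarray, snr_db: float, wander_fraction: float = 0.8) -> tuple[float, float]:
    """White-noise and wander SDs giving a target total SNR (power ratio).

    SNR is defined as ``10 log10(P_signal / P_noise)`` with ``P_signal`` the
    mean square of the clean ECG and the noise budget split between baseline
    wander (default 80%, the dominant in-vehicle term) and white noise.
    """
    p_signal = float(np.mean(np.square(clean)))
    p_noise = p_signal / 10.0 ** (snr_db / 10.0)
    return float(np.sqrt((1 - wander_fraction) * p_noise)), float(np.sqrt(wander_fraction * p_noise))


def _render_clean_ecg(beat_times: np.ndarray, params: GeneratorParams) -> np.ndarray:
    n = int(round(params.duration_s * params.fs_ecg))
    v = np.zeros(n)
    amp, sig = params.qrs_amplitude(), params.qrs_sigma_s
    half = int(np.ceil(4 * sig * params.fs_ecg))
    for tb in beat_times:
        c = int(round(tb * params.fs_ecg))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        tt = (np.arange(lo, hi) / params.fs_ecg) - tb
        v[lo:hi] += amp * np.exp(-0.5 * (tt / sig) ** 2)
    return v


def rr_to_ecg(beat_times: np.ndarray, params: GeneratorParams) -> SignalTrace:
    """Render an ECG trace from beat times.

    Each beat contributes a Gaussian QRS bump centred on the (grid-aligned)
    beat time; additive noise is white Gaussian of ``noise_sd_mv`` plus slow
    sinusoidal baseline wander of total SD ``wander_sd_mv``.
    """
    rng = np.random.default_rng(params.seed + 1)
    v = _render_clean_ecg(np.asarray(beat_times, dtype=float), params)
    n = v.size
    tt = np.arange(n) / params.fs_ecg
    if params.wander_sd_mv > 0:
        # two incommensurate slow components, random phases; total SD as requested
        comp_sd = params.wander_sd_mv / np.sqrt(2)
        for f in (0.14, 0.33):
            v += comp_sd * np.sqrt(2) * np.sin(2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi))
    if params.noise_sd_mv > 0:
        v += rng.normal(0.0, params.noise_sd_mv, size=n)
    return SignalTrace(t0=0.0, fs=params.fs_ecg, values=v, kind="ecg", units="mV")


def generate_accel(params: GeneratorParams) -> SignalTrace:
    """Vehicle longitudinal acceleration: noise floor plus raised-cosine bursts.

    Each burst is ``A*/2 (1 + cos(2 pi (t - tb) / w))`` for ``|t - tb| <= w/2``
    — maximum exactly ``A*`` at the (grid-aligned) burst time.
    """
    rng = np.random.default_rng(params.seed + 2)
    n = int(round(params.duration_s * params.fs_accel))
    v = rng.normal(0.0, params.accel_noise_sd, size=n) if params.accel_noise_sd > 0 else np.zeros(n)
    for tb, peak in zip(params.burst_times, params.peak_of()):
        tb = round(tb * params.fs_accel) / params.fs_accel
        lo = max(int(np.ceil((tb - params.burst_width_s / 2) * params.fs_accel)), 0)
        hi = min(int(np.floor((tb + params.burst_width_s / 2) * params.fs_accel)) + 1, n)
        tt = np.arange(lo, hi) / params.fs_accel - tb
        v[lo:hi] += peak / 2.0 * (1.0 + np.cos(2 * np.pi * tt / params.burst_width_s))
    return SignalTrace(t0=0.0, fs=params.fs_accel, values=v, kind="accel", units="m/s^2")


def generate_session(
    params: GeneratorParams,
    outdir: str | Path | None = None,
    subject_id: str = "synthetic",
    config: StudyConfig | None = None,
):
    """Compose a full session: ECG, acceleration and ground truth.

    With ``outdir`` given, writes ``ecg.csv``, ``accel.csv``,
    ``ground_truth.csv`` and ``manifest.yaml`` there (the ground-truth file
    is for evaluation only and is not referenced by the manifest).

    Returns ``(ecg, accel, truth, manifest_path_or_None)``.
    """
    rr, truth = generate_rr(params)
    ecg = rr_to_ecg(truth.true_peak_times, params)
    accel = generate_accel(params)
    manifest_path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_signal_csv(outdir / "ecg.csv", ecg)
        write_signal_csv(outdir / "accel.csv", accel)
        truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)
        age = 65 if params.group == "elderly" else 27
        cfg = config or StudyConfig(seed=params.seed)
        write_manifest(
            outdir / "manifest.yaml",
            ecg_file="ecg.csv",
            accel_file="accel.csv",
            subject=SubjectMeta(subject_id=subject_id, age=age, group=params.group),
            stages=params.stages,
            config=cfg,
        )
        manifest_path = outdir / "manifest.yaml"
    return ecg, accel, truth, manifest_path
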