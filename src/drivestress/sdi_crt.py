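"""Safe Driving Intensity (SDI) and Cardiac Response Time (CRT).

For each palpitation event at time ``t``, the maximum magnitude of vehicle
acceleration within the preceding Maximum Time Window ``[t - MTW, t]``
(MTW default 30 s) is located. SDI is the mean of those per-event maxima
(m/s²) — how much acceleration the driver tolerates before the heart flags —
and CRT is the mean lag from each acceleration peak to its cardiac event (s).

The single-axis acceleration trace is median-centred before taking
magnitudes, removing any gravity/DC offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_signals import SignalTrace, StudyConfig
from .palpitation import PalpitationEvents
from .stats import GroupSummary, TTestResult, summarize, t_test

__all__ = ["SDIResult", "max_accel_before", "compute_sdi_crt", "group_compare", "GroupComparison"]


@dataclass(frozen=True)
class SDIResult:
    """Per-event (max-acceleration, lag) pairs and their means."""

    event_times: np.ndarray  # s
    a_max: np.ndarray  # m/s² per event
    t_amax: np.ndarray  # s, time of the in-window acceleration maximum
    lag_s: np.ndarray  # event_time - t_amax
    sdi: float | None  # mean a_max; None when no events survive
    crt: float | None  # mean lag_s
    n_events: int
    n_dropped: int = 0  # events whose lookback window missed the trace
    truncated: int = 0  # events whose window was clipped at the trace start

    def per_event_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_time_s": self.event_times,
                "a_max": self.a_max,
                "t_amax": self.t_amax,
                "lag_s": self.lag_s,
            }
        )


def _centered_magnitude(accel: SignalTrace) -> np.ndarray:
    return np.abs(accel.values - np.median(accel.values))


def max_accel_before(
    accel: SignalTrace, t_event: float, mtw_s: float
) -> tuple[float, float, bool]:
    """Largest acceleration magnitude in the closed window ``[t_event - mtw_s, t_event]``.

    Returns ``(a_max, t_amax, truncated)`` with ``t_amax`` the time of the
    *first* occurrence of the maximum; ``truncated`` marks a window clipped
    at the start of the trace. Raises if the window misses the trace entirely.
    """
    if accel.kind != "accel":
        raise ValueError("max_accel_before expects an acceleration trace")
    lo, hi = t_event - mtw_s, t_event
    if hi < accel.t0 - 0.5 / accel.fs or lo > accel.t_end:
        raise ValueError(f"window [{lo:.3f}, {hi:.3f}] lies outside the acceleration trace")
    i0 = int(np.ceil((lo - accel.t0) * accel.fs - 1e-9))
    i1 = int(np.floor((hi - accel.t0) * accel.fs + 1e-9)) + 1
    truncated = i0 < 0
    i0, i1 = max(i0, 0), min(i1, accel.n)
    if i1 <= i0:
        raise ValueError(f"window [{lo:.3f}, {hi:.3f}] contains no samples")
    mag = _centered_magnitude(accel)[i0:i1]
    j = int(np.argmax(mag))  # argmax returns the first occurrence on ties
    return float(mag[j]), accel.t0 + (i0 + j) / accel.fs, truncated


def compute_sdi_crt(
    events: PalpitationEvents, accel: SignalTrace, config: StudyConfig
) -> SDIResult:
    """Apply the lookback-maximum rule to every event and average.

    Events whose lookback window has no overlap with the acceleration trace
    are dropped and counted; an all-dropped result keeps ``sdi``/``crt`` as
    ``None`` (distinct from "no events", where ``n_events`` is 0).
    """
    ev_t, a_max, t_amax, lags = [], [], [], []
    n_dropped = truncated_n = 0
    for t in np.asarray(events.event_times, dtype=float):
        try:
            a, ta, trunc = max_accel_before(accel, t, config.mtw_s)
        except ValueError:
            n_dropped += 1
            continue
        truncated_n += trunc
        ev_t.append(t)
        a_max.append(a)
        t_amax.append(ta)
        lags.append(t - ta)
    n = len(ev_t)
    return SDIResult(
        event_times=np.asarray(ev_t),
        a_max=np.asarray(a_max),
        t_amax=np.asarray(t_amax),
        lag_s=np.asarray(lags),
        sdi=float(np.mean(a_max)) if n else None,
        crt=float(np.mean(lags)) if n else None,
        n_events=n,
        n_dropped=n_dropped,
        truncated=truncated_n,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of subject-level SDI and CRT."""

    sdi_g1: GroupSummary
    sdi_g2: GroupSummary
    sdi_test: TTestResult
    crt_g1: GroupSummary
    crt_g2: GroupSummary
    crt_test: TTestResult


def group_compare(
    group1: "list[SDIResult | tuple[float, float]]",
    group2: "list[SDIResult | tuple[float, float]]",
) -> GroupComparison:
    """Compare subject-level SDI and CRT between two groups.

    Accepts per-subject :class:`SDIResult` objects or plain ``(sdi, crt)``
    pairs; uses the pooled (equal-variance) two-sample t-test.
    """

    def unpack(group):
        sdi, crt = [], []
        for r in group:
            if isinstance(r, SDIResult):
                if r.sdi is None:
                    continue
                sdi.append(r.sdi)
                crt.append(r.crt)
            else:
                sdi.append(float(r[0]))
                crt.append(float(r[1]))
        return sdi, crt

    sdi1, crt1 = unpack(group1)
    sdi2, crt2 = unpack(group2)
    if len(sdi1) < 2 or len(sdi2) < 2:
        raise ValueError("each group needs at least 2 subjects with results")
    return GroupComparison(
        sdi_g1=summarize(sdi1),
        sdi_g2=summarize(sdi2),
        sdi_test=t_test(sdi1, sdi2),
        crt_g1=summarize(crt1),
        crt_g2=summarize(crt2),
        crt_test=t_test(crt1, crt2),
    )
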