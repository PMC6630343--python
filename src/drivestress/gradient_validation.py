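"""Gradient validation (GV) of the SDI estimate.

An independent, histogram-based estimate of the safe-driving acceleration
threshold: palpitation events are counted per 0.1 m/s² acceleration bin over
1.0–6.5 m/s² (using the same per-event maximum acceleration that feeds SDI),
and the shared edge of the adjacent bin pair with the largest absolute count
difference — the "highest gap" — is taken as the threshold. A sharp drop in
palpitation counts marks the acceleration level beyond which driving became
stressful. When no clear gap exists the estimate is undetermined, which the
method reports rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_signals import StudyConfig
from .stats import GroupSummary, TTestResult, pearson, summarize, t_test

__all__ = [
    "GVHistogram",
    "UndeterminedThresholdError",
    "build_gv_histogram",
    "gv_threshold",
    "validate_sdi",
    "SDIValidation",
]


class UndeterminedThresholdError(ValueError):
    """Too little histogram mass to locate a gap."""


@dataclass(frozen=True)
class GVHistogram:
    """Event counts per acceleration bin, with successive-count gradients."""

    bin_edges: np.ndarray  # len = n_bins + 1, m/s²
    counts: np.ndarray  # events per half-open bin [edge, edge + width)
    n_outside: int  # events outside [hist_min, hist_max)

    @property
    def gradients(self) -> np.ndarray:
        return np.diff(self.counts.astype(np.int64))


def build_gv_histogram(a_max: np.ndarray, config: StudyConfig | None = None) -> GVHistogram:
    """Bin per-event maximum accelerations into the GV histogram.

    Bins are half-open ``[edge, edge + bin)`` over
    ``[hist_min, hist_max)`` (defaults 1.0–6.5 m/s², 0.1 m/s² wide); events
    outside the range are excluded and counted separately.
    """
    cfg = config or StudyConfig()
    a = np.asarray(a_max, dtype=float)
    n_bins = int(round((cfg.hist_max - cfg.hist_min) / cfg.hist_bin))
    edges = cfg.hist_min + cfg.hist_bin * np.arange(n_bins + 1)
    inside = (a >= cfg.hist_min) & (a < edges[-1])
    idx = np.floor((a[inside] - cfg.hist_min) / cfg.hist_bin).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return GVHistogram(bin_edges=edges, counts=counts, n_outside=int(a.size - inside.sum()))


def gv_threshold(hist: GVHistogram) -> float:
    """Shared edge of the adjacent bin pair with the largest |count gap|.

    Ties resolve to the lowest edge. Requires at least two bins with data;
    with less there is no gap to read and the threshold is undetermined.
    """
    if int((hist.counts > 0).sum()) < 2:
        raise UndeterminedThresholdError("fewer than 2 bins with data; no gap to locate")
    g = hist.gradients
    # |gap| per interior edge; edge j sits between bins j-1 and j
    best = int(np.argmax(np.abs(g)))  # argmax -> first (lowest-edge) maximum
    return float(hist.bin_edges[best + 1])


@dataclass(frozen=True)
class SDIValidation:
    """Paired comparison of per-subject SDI and GV threshold estimates."""

    t_test: TTestResult
    r: float
    sdi_summary: GroupSummary
    gv_summary: GroupSummary


def validate_sdi(sdi_per_subject, gv_per_subject) -> SDIValidation:
    """Compare the two threshold estimators across subjects.

    Equal-variance two-sample t-test on the value lists, Pearson correlation
    on the pairs, and per-method M (SD).
    """
    sdi = np.asarray(sdi_per_subject, dtype=float)
    gv = np.asarray(gv_per_subject, dtype=float)
    if sdi.size != gv.size:
        raise ValueError("SDI and GV lists must be paired (equal length)")
    if sdi.size < 3:
        raise ValueError("need at least 3 subjects")
    return SDIValidation(
        t_test=t_test(sdi, gv),
        r=pearson(sdi, gv),
        sdi_summary=summarize(sdi),
        gv_summary=summarize(gv),
    )
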