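"""Detection of "heart palpitation" RR intervals via 1-D k-means.

The driving-stage RR intervals are clustered with k-means (Lloyd's algorithm,
k-means++ seeding; delegated to scikit-learn). A single tension threshold is
derived from the cluster summary,

    threshold = (1/k) * sum_i (mu_i + sigma_i),

the unweighted mean over clusters of centroid plus within-cluster sample SD.
Giving every cluster equal weight lets a small high-tension cluster pull the
threshold away from the dominant baseline mass — which is what makes the
rule a usable separator — but it also makes the threshold sensitive to
artifact clusters, so detection dropouts should be gated out first (see
:func:`gate_artifacts`). RR values
on the flagged side of the threshold are labelled palpitation events:

* ``direction="above"`` flags RR >= threshold — the literal published rule
  (long intervals as "high-tensioned");
* ``direction="below"`` flags RR <= (1/k) * sum_i (mu_i - sigma_i) — the
  mirrored rule, consistent with tachycardia physiology where tension means a
  *shorter* RR interval.

Both are exposed because the two readings of the rule conflict; the default
is the literal one. Optionally the clustering variable can be the standard
deviation of RR over 30-s windows (SDRR) instead of raw RR values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.cluster import KMeans

from .rpeak import RRSeries

__all__ = [
    "ClusterModel",
    "PalpitationEvents",
    "kmeans_rr",
    "tension_threshold",
    "select_palpitations",
    "gate_artifacts",
    "sdrr_windows",
]


@dataclass(frozen=True)
class ClusterModel:
    """Fitted 1-D k-means over RR values (ms)."""

    k: int
    centroids: np.ndarray  # ms, ascending
    spreads: np.ndarray  # per-cluster sample SD of members (ms); 0 for singletons
    assignments: np.ndarray  # cluster index per input value
    inertia: float  # sum of squared member-centroid distances
    k_reduced: bool = False  # True when k was cut to the distinct-value count


@dataclass(frozen=True)
class PalpitationEvents:
    event_times: np.ndarray  # s, strictly increasing
    event_rr_ms: np.ndarray
    threshold_ms: float
    direction: Literal["above", "below"]

    @property
    def n(self) -> int:
        return int(self.event_times.size)


def kmeans_rr(values_or_rr: RRSeries | np.ndarray, k: int, seed: int = 0) -> ClusterModel:
    """Cluster 1-D RR values (ms) with Lloyd's k-means.

    k-means++ seeding with a fixed seed and multiple restarts keeps the fit
    deterministic and, on the small 1-D inputs that arise here, reliably at
    the global optimum. If the data hold fewer distinct values than ``k``,
    ``k`` is reduced to the distinct-value count and the model flagged.
    """
    x = values_or_rr.rr_ms if isinstance(values_or_rr, RRSeries) else np.asarray(values_or_rr, float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("need a non-empty 1-D value array")
    if not np.all(np.isfinite(x)):
        raise ValueError("RR values must be finite")
    n_distinct = np.unique(x).size
    k_eff, reduced = (n_distinct, True) if n_distinct < k else (k, False)
    if x.size < k_eff:
        raise ValueError(f"need at least k={k_eff} values, got {x.size}")
    km = KMeans(n_clusters=k_eff, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(x.reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    # relabel clusters by ascending centroid for reproducible reporting
    order = np.argsort(centroids)
    rank = np.empty_like(order)
    rank[order] = np.arange(k_eff)
    centroids = centroids[order]
    labels = rank[labels]
    spreads = np.zeros(k_eff)
    for i in range(k_eff):
        members = x[labels == i]
        if members.size > 1:
            spreads[i] = members.std(ddof=1)
    inertia = float(np.sum((x - centroids[labels]) ** 2))
    return ClusterModel(
        k=k_eff,
        centroids=centroids,
        spreads=spreads,
        assignments=labels,
        inertia=inertia,
        k_reduced=reduced,
    )


def tension_threshold(model: ClusterModel, direction: Literal["above", "below"]) -> float:
    """Cluster-summary threshold (ms) for the chosen flag direction.

    Mean over clusters of ``mu_i + sigma_i`` (``above``) or its mirror
    ``mu_i - sigma_i`` (``below``).
    """
    if direction == "above":
        return float(np.mean(model.centroids + model.spreads))
    return float(np.mean(model.centroids - model.spreads))


def select_palpitations(
    model: ClusterModel,
    rr: RRSeries,
    direction: Literal["above", "below"] = "above",
) -> PalpitationEvents:
    """Flag tense RR intervals against the cluster-summary threshold.

    ``above`` keeps RR >= threshold, ``below`` keeps RR <= the mirrored
    threshold (see :func:`tension_threshold`). Returned events carry the
    timestamps of the flagged intervals for downstream alignment with
    vehicle acceleration.
    """
    if direction not in ("above", "below"):
        raise ValueError(f"unknown direction {direction!r}")
    thr = tension_threshold(model, direction)
    if rr.n == 0:
        return PalpitationEvents(np.empty(0), np.empty(0), thr, direction)
    mask = rr.rr_ms >= thr if direction == "above" else rr.rr_ms <= thr
    order = np.argsort(rr.rr_times[mask], kind="stable")
    return PalpitationEvents(
        event_times=rr.rr_times[mask][order],
        event_rr_ms=rr.rr_ms[mask][order],
        threshold_ms=thr,
        direction=direction,
    )


def gate_artifacts(rr: RRSeries, low: float = 0.5, high: float = 1.3) -> RRSeries:
    """Drop RR intervals that can only be detection artifacts.

    Keeps intervals within ``[low, high]`` times the series median. The short
    side mostly duplicates the detector's refractory rule; the long side
    removes dropout artifacts (a missed beat doubles the apparent interval;
    an instantaneous heart-rate drop beyond ~30% of the session median does
    not occur during driving). Standard preprocessing in heart-rate
    variability work before any statistic is formed.
    """
    if rr.n == 0:
        return rr
    med = float(np.median(rr.rr_ms))
    keep = (rr.rr_ms >= low * med) & (rr.rr_ms <= high * med)
    return RRSeries(rr.rr_ms[keep], rr.rr_times[keep], rr.stage[keep])


def sdrr_windows(rr: RRSeries, window_s: float = 30.0) -> RRSeries:
    """Collapse an RR series to per-window SDRR values (ms).

    Windows of ``window_s`` tile the RR timestamps from the first one;
    each window with >= 2 intervals yields the sample SD of its RR values,
    stamped at the window end. The result reuses the RRSeries container so it
    can feed the same clustering/selection path as raw RR values.
    """
    if rr.n == 0:
        return rr
    t_start = float(rr.rr_times.min())
    idx = ((rr.rr_times - t_start) / window_s).astype(np.int64)
    sdrr, times, stages = [], [], []
    for w in np.unique(idx):
        m = idx == w
        if m.sum() < 2:
            continue
        sdrr.append(float(rr.rr_ms[m].std(ddof=1)))
        times.append(t_start + (w + 1) * window_s)
        stages.append(rr.stage[m][0])
    return RRSeries(np.asarray(sdrr), np.asarray(times), np.asarray(stages, dtype=object))
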