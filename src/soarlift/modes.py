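"""Flight-mode classification of track segments.

Segments are clustered on two features — elevation change (m) and
directional variance — with K-means; the number of clusters is chosen by the
gap statistic, and with three clusters the modes are labelled by their
centroid geometry: glides lose height on a straight course, circular soaring
gains height with highly dispersed headings, linear (slope) soaring gains
height on a straight course.  Segments near cluster boundaries are excluded
so the retained modes are distinct.

Features are z-score standardized before clustering: elevation change spans
hundreds of metres while directional variance lives in [0, 1], and raw
K-means would otherwise ignore the second axis entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "GLIDING", "CIRCULAR", "LINEAR", "EXCLUDED",
    "GapCurve", "ClusterModel",
    "gap_statistic", "select_k", "kmeans_fit", "label_modes",
    "boundary_exclusion", "classify_segments",
]

GLIDING = "gliding"
CIRCULAR = "circular_soaring"
LINEAR = "linear_soaring"
EXCLUDED = "excluded"

FEATURES = ["elevation_change_m", "directional_variance"]


@dataclass
class GapCurve:
    """Gap values and bootstrap standard errors for k = 1..k_max."""

    k_values: np.ndarray
    gap: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.k_values) == len(self.gap) == len(self.se)):
            raise ValueError("k_values, gap and se must have equal length")
        if np.any(self.se < 0):
            raise ValueError("standard errors must be non-negative")


@dataclass
class ClusterModel:
    """A fitted K-means model in standardized feature space."""

    centroids: np.ndarray        # (k, n_features), standardized units
    assignments: np.ndarray      # (n,) cluster index per segment
    feature_means: np.ndarray
    feature_sds: np.ndarray

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def centroids_original(self) -> np.ndarray:
        """Centroids mapped back to the original feature units."""
        return self.centroids * self.feature_sds + self.feature_means


def _standardize(features: np.ndarray):
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("features are degenerate: zero variance on every axis")
    sd = np.where(sd == 0, 1.0, sd)
    return (features - mu) / sd, mu, sd


def _dispersion(x: np.ndarray, k: int, seed: int, n_init: int = 10) -> float:
    """Total within-cluster sum of squares of a K-means fit."""
    if k == 1:
        return float(((x - x.mean(axis=0)) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return float(km.inertia_)


def gap_statistic(features, k_max: int = 10, B: int = 1000,
                  seed: int = 0, n_init: int = 10) -> GapCurve:
    """Gap statistic of K-means clusterings for k = 1..k_max.

    For each k, ``gap(k) = mean_b log W*_b(k) - log W(k)`` where ``W`` is the
    within-cluster dispersion of the (standardized) data and ``W*_b`` that of
    the b-th reference set, drawn uniformly over each observed feature range.
    The standard error carries the ``sqrt(1 + 1/B)`` bootstrap factor.

    Seeding is deterministic: reference sets come from
    ``numpy.random.default_rng(seed)`` as one ``(B, n, p)`` uniform draw, the
    data clustering uses ``random_state=seed`` and reference set ``b`` uses
    ``random_state=seed + 1 + b``, for every k.
    """
    x = np.asarray(features, float)
    if x.ndim != 2:
        raise ValueError("features must be an n x p table")
    n = x.shape[0]
    if n < k_max:
        raise ValueError("need at least k_max observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    x, _, _ = _standardize(x)

    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    refs = rng.uniform(lo, hi, size=(B, n, x.shape[1]))

    ks = np.arange(1, k_max + 1)
    gap = np.empty(k_max)
    se = np.empty(k_max)
    for i, k in enumerate(ks):
        log_w = math.log(_dispersion(x, k, seed, n_init))
        log_wb = np.array([
            math.log(_dispersion(refs[b], k, seed + 1 + b, n_init))
            for b in range(B)
        ])
        gap[i] = log_wb.mean() - log_w
        se[i] = log_wb.std(ddof=1) * math.sqrt(1 + 1 / B)
    return GapCurve(ks, gap, se)


def select_k(curve: GapCurve) -> int:
    """Optimal cluster count by the first-SE-max rule.

    Locates the first local maximum of the gap curve and returns the smallest
    k whose gap value is within one standard error of that maximum — the
    first maximum that does not overlap the standard error of earlier
    observations.
    """
    g, s = curve.gap, curve.se
    m = len(g) - 1
    for i in range(len(g) - 1):
        if g[i] >= g[i + 1]:
            m = i
            break
    for i in range(m + 1):
        if g[i] >= g[m] - s[m]:
            return int(curve.k_values[i])
    return int(curve.k_values[m])


def kmeans_fit(features, k: int, seed: int = 0, n_init: int = 25) -> ClusterModel:
    """K-means on z-standardized features, k-means++ with multiple restarts."""
    x = np.asarray(features, float)
    if k > x.shape[0]:
        raise ValueError("k cannot exceed the number of observations")
    xs, mu, sd = _standardize(x)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(xs)
    return ClusterModel(km.cluster_centers_, km.labels_, mu, sd)


def label_modes(model: ClusterModel) -> tuple[np.ndarray, dict[int, str]]:
    """Assign flight-mode names to a three-cluster model.

    The cluster with the lowest mean elevation change is gliding; of the two
    soaring clusters, the one with higher mean directional variance is
    circular soaring and the other linear soaring.  Ties on elevation change
    are broken by directional variance (the straighter cluster glides).
    Returns per-segment labels and the cluster-index -> mode mapping.
    """
    if model.k != 3:
        raise ValueError(f"mode labelling requires exactly 3 clusters, got {model.k}")
    cents = model.centroids_original
    order = np.lexsort((cents[:, 1], cents[:, 0]))  # elev change, then dir. variance
    glide = order[0]
    rest = [c for c in range(3) if c != glide]
    if cents[rest[0], 1] >= cents[rest[1], 1]:
        circular, linear = rest[0], rest[1]
    else:
        circular, linear = rest[1], rest[0]
    mapping = {glide: GLIDING, circular: CIRCULAR, linear: LINEAR}
    labels = np.array([mapping[c] for c in model.assignments])
    return labels, mapping


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def boundary_exclusion(labels: np.ndarray, features, model: ClusterModel,
                       frac: float = 0.15, elev_threshold_m: float = 15.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exclude segments that sit at cluster boundaries.

    Three rules: gliding segments with elevation change above
    ``-elev_threshold_m``; soaring segments with elevation change below
    ``+elev_threshold_m``; and the fraction ``frac`` (round-half-up count) of
    the remaining soaring segments whose standardized directional variance
    lies closest to the midpoint between the circular- and linear-soaring
    centroids.  Exclusion never relabels: a segment is either kept with its
    label or marked ``excluded``.

    Returns the new label array and a parallel array of exclusion reasons
    (empty string for retained segments).
    """
    x = np.asarray(features, float)
    labels = np.asarray(labels, dtype=object).copy()
    reasons = np.full(len(labels), "", dtype=object)
    elev = x[:, 0]

    glide_bad = (labels == GLIDING) & (elev > -elev_threshold_m)
    soar = (labels == CIRCULAR) | (labels == LINEAR)
    soar_bad = soar & (elev < elev_threshold_m)
    labels[glide_bad] = EXCLUDED
    reasons[glide_bad] = "glide_elevation_change"
    labels[soar_bad] = EXCLUDED
    reasons[soar_bad] = "soaring_elevation_change"

    remaining = np.flatnonzero((labels == CIRCULAR) | (labels == LINEAR))
    n_excl = _round_half_up(frac * len(remaining))
    if n_excl > 0:
        _, mapping = label_modes(model)
        inv = {v: k for k, v in mapping.items()}
        dv_std = (x[:, 1] - model.feature_means[1]) / model.feature_sds[1]
        mid = (model.centroids[inv[CIRCULAR], 1] + model.centroids[inv[LINEAR], 1]) / 2
        dist = np.abs(dv_std[remaining] - mid)
        chosen = remaining[np.argsort(dist, kind="stable")[:n_excl]]
        labels[chosen] = EXCLUDED
        reasons[chosen] = "mode_boundary"
    return labels, reasons


def classify_segments(table: pd.DataFrame, k_max: int = 10, B: int = 1000,
                      seed: int = 0, frac: float = 0.15,
                      elev_threshold_m: float = 15.0,
                      force_k: int | None = None) -> pd.DataFrame:
    """Full classification of a segment table.

    Runs the gap statistic on (elevation change, directional variance),
    selects k by the first-SE-max rule (or uses ``force_k``), requires three
    clusters, labels the modes and applies the boundary exclusions.  Returns
    a copy of ``table`` with ``mode``, ``excluded_reason`` and ``selected_k``
    columns.
    """
    feats = table[FEATURES].to_numpy(float)
    if force_k is None:
        curve = gap_statistic(feats, k_max=k_max, B=B, seed=seed)
        k = select_k(curve)
    else:
        k = force_k
    if k != 3:
        raise ValueError(
            f"gap statistic selected k={k}; mode labelling is defined for k=3 "
            "(rerun with force_k to override)")
    model = kmeans_fit(feats, 3, seed=seed)
    labels, _ = label_modes(model)
    labels, reasons = boundary_exclusion(labels, feats, model, frac=frac,
                                         elev_threshold_m=elev_threshold_m)
    out = table.copy()
    out["mode"] = labels
    out["excluded_reason"] = reasons
    out["selected_k"] = k
    return out
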