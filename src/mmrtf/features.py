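"""Quasi-likelihood map, time-frequency features, centroids, and surprise.

The grand compromise projection G is interpreted through a quasi-likelihood
estimate (qLE): each value of G is mapped through the *squared* smoothed CDF
of the per-point minimum bound B (the pointwise maximum over the condition
compromise projections).  Thresholding the qLE (default 0.8) yields a binary
mask whose 8-connected components are the spectral-temporal features of the
oddball response — in the emulated paradigm, a beta-gamma wave packet, an
early theta-1 oscillation, and a later theta-2 oscillation whose offset may
appear as a distinct theta-2b sub-peak.

Per feature and condition, temporal and spectral marginal distributions are
the masked surface averaged across scales and across time respectively, and
the feature centroid is the joint maximum of the two distributions.  The
spectral-temporal separation of theta-1 and theta-2 finally feeds a scalar
"surprise" statistic  S = -log(dF / (C * dT)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .kde import smoothed_cdf

__all__ = [
    "Feature",
    "FeatureSet",
    "Centroid",
    "SurpriseInput",
    "minimum_bound",
    "qle_map",
    "extract_features",
    "feature_distributions",
    "feature_centroids",
    "centroid_table",
    "estimate_surprise_inputs",
    "surprise",
]

THETA_MAX_HZ = 8.0
SPLIT_FREQ_HZ = 12.0
_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class Feature:
    """One labeled supra-threshold region: name + binary scales x time mask."""

    name: str
    mask: np.ndarray
    peak_freq_hz: float = np.nan
    peak_latency_ms: float = np.nan


@dataclass
class FeatureSet:
    """qLE map, global mask H, and the labeled features."""

    qle: np.ndarray
    H: np.ndarray
    features: list
    threshold: float
    B: np.ndarray | None = None
    scale_freqs_hz: np.ndarray | None = None
    time_ms: np.ndarray | None = None


@dataclass
class Centroid:
    feature: str
    condition: str
    freq_hz: float
    latency_ms: float
    rp: float


@dataclass(frozen=True)
class SurpriseInput:
    """Inputs to the surprise statistic.

    ``dF``/``dT`` are the probabilities of the theta-1 vs theta-2 frequency
    and latency differences; ``c_cfc`` is a positive constant encoding the
    latency of the cross-frequency-coupling effect.
    """

    dF: float
    dT: float
    c_cfc: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.dF <= 1.0 and 0.0 < self.dT <= 1.0):
            raise ValueError("dF and dT must lie in (0, 1]")
        if self.c_cfc <= 0:
            raise ValueError("c_cfc must be positive")


def minimum_bound(g_list: list[np.ndarray]) -> np.ndarray:
    """Pointwise maximum over the condition compromise projections."""
    if not g_list:
        raise ValueError("at least one condition surface is required")
    mats = [np.asarray(g, dtype=float) for g in g_list]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("condition surfaces must share a common shape")
    return np.maximum.reduce(mats)


def qle_map(G: np.ndarray, B: np.ndarray, method: str = "kde") -> np.ndarray:
    """Squared smoothed-CDF mapping of G against the pooled values of B."""
    G = np.asarray(G, dtype=float)
    B = np.asarray(B, dtype=float)
    if G.shape != B.shape:
        raise ValueError("G and B must have the same shape")
    if np.ptp(B) == 0:
        warnings.warn("degenerate minimum bound; qLE set to 0.25 everywhere", stacklevel=2)
        return np.full(G.shape, 0.25)
    return smoothed_cdf(B.ravel(), G, method=method) ** 2


def _band_partitions(freqs: np.ndarray) -> list[np.ndarray]:
    """Row partitions at the beta-gamma boundary (regions spanning it are
    split into a low and a high part)."""
    low = freqs < SPLIT_FREQ_HZ
    return [low, ~low]


def extract_features(
    qle: np.ndarray,
    scale_freqs_hz: np.ndarray,
    time_ms: np.ndarray,
    threshold: float = 0.8,
) -> FeatureSet:
    """Threshold the qLE map and label its connected regions as features.

    Supra-threshold points (qLE >= threshold) are grouped by 8-connected
    component labeling, separately below and above the 12 Hz beta-gamma
    boundary so a region spanning it is split.  Components are named by
    band and latency order: ``theta-1``, ``theta-2``, ... for peaks at or
    below 8 Hz, ``beta-gamma`` (optionally several, latency-ordered) at or
    above 12 Hz, ``alpha`` in between.
    """
    qle = np.asarray(qle, dtype=float)
    freqs = np.asarray(scale_freqs_hz, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    H = (qle >= threshold).astype(np.int8)
    raw: list[Feature] = []
    for rows in _band_partitions(freqs):
        part = H * rows[:, None]
        labeled, n = ndimage.label(part, structure=_EIGHT_CONN)
        for i in range(1, n + 1):
            mask = labeled == i
            kk, jj = np.nonzero(mask)
            peak = np.argmax(np.where(mask, qle, -np.inf))
            pk, pj = np.unravel_index(peak, qle.shape)
            raw.append(
                Feature(
                    name="",
                    mask=mask,
                    peak_freq_hz=float(freqs[pk]),
                    peak_latency_ms=float(time_ms[pj]),
                )
            )
    if not raw:
        warnings.warn("no time-frequency point exceeds the qLE threshold", stacklevel=2)
        return FeatureSet(qle=qle, H=H, features=[], threshold=threshold,
                          scale_freqs_hz=freqs, time_ms=time_ms)

    theta = sorted((f for f in raw if f.peak_freq_hz <= THETA_MAX_HZ),
                   key=lambda f: f.peak_latency_ms)
    high = sorted((f for f in raw if f.peak_freq_hz >= SPLIT_FREQ_HZ),
                  key=lambda f: f.peak_latency_ms)
    mid = [f for f in raw if THETA_MAX_HZ < f.peak_freq_hz < SPLIT_FREQ_HZ]
    for i, f in enumerate(theta):
        f.name = f"theta-{i + 1}"
    for i, f in enumerate(high):
        f.name = "beta-gamma" if len(high) == 1 else f"beta-gamma-{i + 1}"
    for i, f in enumerate(mid):
        f.name = "alpha" if len(mid) == 1 else f"alpha-{i + 1}"
    feats = theta + high + mid
    return FeatureSet(qle=qle, H=H, features=feats, threshold=threshold,
                      scale_freqs_hz=freqs, time_ms=time_ms)


def feature_distributions(h: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Temporal and spectral marginal distributions of a masked surface.

    ``y_T`` is the mean of ``h * g`` across scales (one value per time
    point); ``y_F`` the mean across time (one value per scale).  An empty
    mask yields zero distributions with a warning.
    """
    h = np.asarray(h, dtype=float)
    g = np.asarray(g, dtype=float)
    if h.shape != g.shape:
        raise ValueError("mask and surface must have the same shape")
    if not h.any():
        warnings.warn("empty feature mask; distributions are zero", stacklevel=2)
    masked = h * g
    return masked.mean(axis=0), masked.mean(axis=1)


def _significant_peaks(y: np.ndarray, rel_prominence: float) -> np.ndarray:
    if np.ptp(y) == 0:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(y, prominence=rel_prominence * np.ptp(y))
    interior = peaks
    # include a boundary maximum (find_peaks misses plateau edges)
    gmax = int(np.argmax(y))
    if gmax not in interior and (gmax in (0, y.size - 1)):
        interior = np.sort(np.append(interior, gmax))
    return interior


def _split_mask(mask: np.ndarray, y: np.ndarray, peaks: np.ndarray, axis: int) -> list[np.ndarray]:
    """Split a mask at the valleys between consecutive peaks along an axis."""
    cuts = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        cuts.append(a + int(np.argmin(y[a : b + 1])))
    bounds = [0, *[c + 1 for c in cuts], mask.shape[axis]]
    parts = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        sel = np.zeros(mask.shape[axis], dtype=bool)
        sel[a:b] = True
        sub = mask & (sel[:, None] if axis == 0 else sel[None, :])
        if sub.any():
            parts.append(sub)
    return parts


def feature_centroids(
    y_T: np.ndarray,
    y_F: np.ndarray,
    h: np.ndarray,
    g: np.ndarray,
    scale_freqs_hz: np.ndarray,
    time_ms: np.ndarray,
    feature: str = "",
    condition: str = "",
    rel_prominence: float = 0.25,
    allow_split: bool = True,
) -> list[Centroid]:
    """Centroid(s) of one feature: the joint maximum of its distributions.

    The primary centroid is (argmax of ``y_F``, argmax of ``y_T``, surface
    value at that joint point).  A local-maxima search splits composite
    features: two or more separated spectral peaks split a beta-gamma region
    into gamma and beta centroids (ordered by frequency descending), and two
    or more temporal peaks split a theta region into onset and offset
    centroids.  Flat distributions fall back to the earliest /
    lowest-frequency point, with a warning.
    """
    freqs = np.asarray(scale_freqs_hz, dtype=float)
    times = np.asarray(time_ms, dtype=float)
    if not h.any() or not np.any(y_T) and not np.any(y_F):
        return []
    if np.ptp(y_F[h.any(axis=1)]) == 0 and np.ptp(y_T[h.any(axis=0)]) == 0:
        warnings.warn("flat feature distributions; earliest/lowest point chosen", stacklevel=2)
        kk, jj = np.nonzero(h)
        k, j = kk.min(), jj.min()
        return [Centroid(feature, condition, float(freqs[k]), float(times[j]), float(g[k, j]))]

    if allow_split:
        f_peaks = _significant_peaks(y_F, rel_prominence)
        parts = _split_mask(h, y_F, f_peaks, axis=0) if f_peaks.size >= 2 else [h]
        # within each spectral part, search for onset/offset temporal peaks
        final_parts = []
        for sub in parts:
            yt_sub, _ = feature_distributions(sub, g)
            t_peaks = _significant_peaks(yt_sub, rel_prominence)
            if t_peaks.size >= 2:
                final_parts.extend(_split_mask(sub, yt_sub, t_peaks, axis=1))
            else:
                final_parts.append(sub)
        parts = final_parts
    else:
        parts = [h]

    cents = []
    for sub in parts:
        yt, yf = feature_distributions(sub, g)
        k = int(np.argmax(yf))
        j = int(np.argmax(yt))
        cents.append(
            Centroid(feature, condition, float(freqs[k]), float(times[j]), float(g[k, j]))
        )
    # composite high-band features report by frequency descending (gamma first)
    if len(cents) > 1 and freqs[h.any(axis=1)].max() >= SPLIT_FREQ_HZ:
        cents.sort(key=lambda c: -c.freq_hz)
    return cents


def _subfeature_names(base: str, cents: list[Centroid]) -> list[str]:
    if len(cents) == 1:
        return [base]
    if base.startswith("beta-gamma"):
        names = []
        for c in cents:
            names.append("gamma" if c.freq_hz >= 25.0 else "beta")
        # de-duplicate
        out, seen = [], {}
        for n in names:
            seen[n] = seen.get(n, 0) + 1
            out.append(n if seen[n] == 1 else f"{n}-{seen[n]}")
        return out
    return [base if i == 0 else f"{base}b" if i == 1 else f"{base}{chr(ord('b') + i - 1)}"
            for i in range(len(cents))]


def centroid_table(fs: FeatureSet, condition_means: dict) -> pd.DataFrame:
    """Per-feature, per-condition centroid table.

    For every labeled feature and every condition compromise projection,
    computes the marginal distributions, runs the local-maxima centroid
    search (splitting composite gamma/beta and theta onset/offset peaks),
    and returns rows of (feature, condition, frequency Hz, latency ms, RP).
    """
    rows = []
    for feat in fs.features:
        for cond, g in condition_means.items():
            y_t, y_f = feature_distributions(feat.mask, g)
            cents = feature_centroids(
                y_t, y_f, feat.mask, g, fs.scale_freqs_hz, fs.time_ms,
                feature=feat.name, condition=cond,
            )
            names = _subfeature_names(feat.name, cents)
            for name, c in zip(names, cents):
                rows.append(
                    {"feature": name, "condition": cond, "freq_hz": c.freq_hz,
                     "latency_ms": c.latency_ms, "rp": c.rp}
                )
    return pd.DataFrame(rows, columns=["feature", "condition", "freq_hz", "latency_ms", "rp"])


def estimate_surprise_inputs(
    y_f1: np.ndarray, y_f2: np.ndarray,
    y_t1: np.ndarray, y_t2: np.ndarray,
    c_cfc: float = 1.0,
) -> SurpriseInput:
    """Overlap-based estimator of the surprise inputs (experimental).

    ``dF`` is the overlap coefficient (sum of pointwise minima after L1
    normalization) of the theta-1 and theta-2 spectral distributions; ``dT``
    the same for the temporal distributions.  Larger spectral/temporal
    separation between the two theta components gives smaller overlap and
    hence larger surprise.  This is one admissible operationalization of the
    probability of a frequency/latency difference; it is not uniquely
    determined by the definition of S.
    """

    def _overlap(a, b):
        a = np.clip(np.asarray(a, dtype=float), 0, None)
        b = np.clip(np.asarray(b, dtype=float), 0, None)
        if a.sum() == 0 or b.sum() == 0:
            raise ValueError("degenerate distribution: zero mass")
        return float(np.minimum(a / a.sum(), b / b.sum()).sum())

    eps = 1e-12
    return SurpriseInput(
        dF=max(_overlap(y_f1, y_f2), eps),
        dT=max(_overlap(y_t1, y_t2), eps),
        c_cfc=c_cfc,
    )


def surprise(si: SurpriseInput) -> float:
    """Surprise statistic ``S = -ln(dF / (c_cfc * dT))``.

    Zero when the frequency-difference probability equals the (scaled)
    latency-difference probability; increases as the spectral separation
    grows relative to the temporal separation.  The proportionality constant
    is fixed at 1, natural logarithm.
    """
    return float(-np.log(si.dF / (si.c_cfc * si.dT)))
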