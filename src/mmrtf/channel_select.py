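"""Montage optimization by spatial PCA of bootstrapped difference waveforms.

A quality-control analysis reproducing the rationale for the single-channel
montage used by the pipeline: per channel, a bootstrap estimate of the
deviant-minus-standard difference waveform is computed; the per-subject
estimates are normalized and concatenated, and a spatial PCA of the channel
covariance yields signed per-channel loadings.  For an auditory generator the
vertex channels load positively and the mastoids negatively (the dipole's
polarity inversion), which justifies recording Cz against linked mastoids.
The pipeline default montage is Cz re-referenced to linked mastoids
regardless of this analysis' outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochedBlock

__all__ = ["ChannelLoadings", "bootstrap_channel_differences", "spatial_pca_loadings"]


@dataclass
class ChannelLoadings:
    """Signed per-channel loadings plus the PCA variance structure."""

    channels: list
    loadings: np.ndarray
    pvaf: np.ndarray
    retained_components: int


def bootstrap_channel_differences(
    block: EpochedBlock, n_boot: int = 1001, seed: int = 0, normalize: bool = True
) -> np.ndarray:
    """Per-channel bootstrap estimate of the deviant-standard difference.

    For each channel independently, the estimate is the mean over ``n_boot``
    draws (with replacement) of (random deviant trial - random standard
    trial).  With ``normalize`` the channels x time estimate is divided by
    its Frobenius norm so subjects can be concatenated on equal footing.
    """
    if block.trials.ndim != 3:
        raise ValueError("multichannel trials x channels x time block required")
    labels = np.asarray(block.labels)
    dev = np.flatnonzero(labels == "deviant")
    std = np.flatnonzero(labels == "standard")
    if dev.size == 0 or std.size == 0:
        raise ValueError("both deviant and standard trials are required")
    rng = np.random.default_rng(seed)
    n_ch = block.trials.shape[1]
    est = np.empty((n_ch, block.trials.shape[2]))
    for c in range(n_ch):
        cd = np.bincount(rng.integers(0, dev.size, n_boot), minlength=dev.size) / n_boot
        cs = np.bincount(rng.integers(0, std.size, n_boot), minlength=std.size) / n_boot
        est[c] = cd @ block.trials[dev, c, :] - cs @ block.trials[std, c, :]
    if normalize:
        norm = np.linalg.norm(est)
        if norm > 0:
            est = est / norm
    return est


def spatial_pca_loadings(
    group_estimates: list[np.ndarray], cum_pvaf: float = 0.90
) -> ChannelLoadings:
    """Spatial PCA of concatenated per-subject difference estimates.

    Eigendecomposition of the channel covariance of the (time-concatenated)
    estimates; components are sorted by variance fraction and the smallest
    prefix reaching ``cum_pvaf`` cumulative variance is retained.  The
    loading magnitude per channel is the mean squared eigenvector weight
    over the retained components; its sign is taken from the first retained
    eigenvector (oriented so its largest-magnitude element is positive),
    which restores the polarity the squared formulation destroys.
    """
    mats = [np.asarray(e, dtype=float) for e in group_estimates]
    n_ch = mats[0].shape[0]
    if n_ch < 2:
        raise ValueError("at least 2 channels are required")
    if any(m.shape[0] != n_ch for m in mats):
        raise ValueError("all estimates must share the channel dimension")
    x = np.concatenate(mats, axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / max(x.shape[1] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    total = evals.sum()
    if total == 0:
        raise ValueError("zero-variance estimates")
    pvaf = evals / total
    rank = int(np.linalg.matrix_rank(cov))
    n_keep = int(np.searchsorted(np.cumsum(pvaf), cum_pvaf) + 1)
    if n_keep > rank:
        warnings.warn(
            "rank-deficient covariance: retaining all available components", stacklevel=2
        )
        n_keep = max(rank, 1)
    w = evecs[:, :n_keep]
    first = w[:, 0] * np.sign(w[np.argmax(np.abs(w[:, 0])), 0] or 1.0)
    magnitude = (w**2).mean(axis=1)
    signs = np.sign(first)
    signs[signs == 0] = 1.0
    return ChannelLoadings(
        channels=[],
        loadings=magnitude * signs,
        pvaf=pvaf,
        retained_components=n_keep,
    )
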