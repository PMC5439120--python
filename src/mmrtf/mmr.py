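"""The probabilistic time-frequency mismatch response (MMR_TF).

For one subject and contrast block, the MMR_TF is the probability that the
complex mean of the deviant-minus-standard difference exceeds zero at each
time-frequency point.  It is estimated in three steps:

1. *Bootstrap difference*: the signal estimate ``M`` is the squared complex
   modulus of the mean, over ``n_boot`` draws with replacement, of (random
   deviant trial - random standard trial); the error estimate ``E`` repeats
   the procedure with pairs drawn label-blind from the whole block.  Taking
   the complex mean *before* the modulus makes the estimator sensitive to
   phase-consistent differences only.
2. *Scale normalization*: per scale, ``M`` and ``E`` are jointly divided by
   the root of their pooled squared sum, equating energy across scales.
3. *Probability mapping*: each normalized signal value is replaced by its
   value under the kernel-smoothed CDF of the pooled normalized signal and
   error values, yielding a [0, 1] probability surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kde import smoothed_cdf
from .tfr import TFTensor

__all__ = [
    "BootstrapEstimates",
    "MMRSurface",
    "bootstrap_difference",
    "scale_normalize",
    "probability_map",
    "compute_mmr_surface",
]


@dataclass
class BootstrapEstimates:
    """Raw (M, E) and scale-normalized (MM, EE) difference estimates.

    All four are real, non-negative scales x time matrices; ``zero_scales``
    flags scales whose pooled energy was identically zero (their MM/EE rows
    are set to 0 instead of dividing by zero).
    """

    M: np.ndarray
    E: np.ndarray
    scale_freqs_hz: np.ndarray
    time_ms: np.ndarray
    n_boot: int
    seed: int
    MM: np.ndarray | None = None
    EE: np.ndarray | None = None
    zero_scales: np.ndarray | None = None


@dataclass
class MMRSurface:
    """The MMR_TF: a scales x time probability map with its axes."""

    p: np.ndarray
    scale_freqs_hz: np.ndarray
    time_ms: np.ndarray
    subject: str = ""
    condition: str = ""

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.scale_freqs_hz), len(self.time_ms)):
            raise ValueError("surface must be scales x time")


def _weighted_mean(coeffs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Mean over bootstrap draws expressed as a weighted trial sum.

    ``coeffs`` is trials x time x scales; ``weights`` counts how often each
    trial was drawn (signed for the label-blind pairs).  Returns scales x
    time (complex).
    """
    flat = coeffs.reshape(coeffs.shape[0], -1)
    mean = (weights.astype(flat.real.dtype) @ flat).reshape(coeffs.shape[1:])
    return mean.T  # -> scales x time


def bootstrap_difference(t: TFTensor, n_boot: int = 1001, seed: int = 0) -> BootstrapEstimates:
    """Bootstrap signal (M) and label-blind error (E) difference estimates."""
    labels = np.asarray(t.labels)
    dev = np.flatnonzero(labels == "deviant")
    std = np.flatnonzero(labels == "standard")
    if dev.size == 0 or std.size == 0:
        raise ValueError("both deviant and standard trials are required")
    rng = np.random.default_rng(seed)

    cd = np.bincount(rng.integers(0, dev.size, n_boot), minlength=dev.size) / n_boot
    cs = np.bincount(rng.integers(0, std.size, n_boot), minlength=std.size) / n_boot
    mean_m = _weighted_mean(t.coeffs[dev], cd) - _weighted_mean(t.coeffs[std], cs)

    n_all = t.n_trials
    ca = np.bincount(rng.integers(0, n_all, n_boot), minlength=n_all)
    cb = np.bincount(rng.integers(0, n_all, n_boot), minlength=n_all)
    mean_e = _weighted_mean(t.coeffs, (ca - cb) / n_boot)

    return BootstrapEstimates(
        M=np.abs(mean_m.astype(np.complex128)) ** 2,
        E=np.abs(mean_e.astype(np.complex128)) ** 2,
        scale_freqs_hz=np.asarray(t.scale_freqs_hz),
        time_ms=np.asarray(t.time_ms),
        n_boot=n_boot,
        seed=seed,
    )


def scale_normalize(est: BootstrapEstimates) -> BootstrapEstimates:
    """Jointly normalize M and E per scale.

    For every scale ``k`` both rows are divided by
    ``sqrt(sum_j M[k,j]^2 + sum_j E[k,j]^2)``, so afterwards the squared sums
    of MM and EE together equal one per scale.  All-zero scales are flagged
    and left at zero.
    """
    if est.M.shape != est.E.shape:
        raise ValueError("M and E must have the same shape")
    m = est.M.astype(np.float64)
    e = est.E.astype(np.float64)
    denom = np.sqrt((m**2).sum(axis=1) + (e**2).sum(axis=1))
    zero = denom == 0
    safe = np.where(zero, 1.0, denom)
    est.MM = m / safe[:, None]
    est.EE = e / safe[:, None]
    est.zero_scales = zero
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero scales left unnormalized", stacklevel=2)
    return est


def probability_map(
    est: BootstrapEstimates,
    method: str = "kde",
    subject: str = "",
    condition: str = "",
) -> MMRSurface:
    """Map normalized signal values through the pooled signal+error CDF.

    The smoothed CDF ``C`` of the pooled MM and EE values is evaluated at
    every MM value, giving the probability surface.  ``method="ecdf"``
    switches to the raw empirical CDF (also the test oracle).
    """
    if est.MM is None or est.EE is None:
        est = scale_normalize(est)
    pooled = np.concatenate([est.MM.ravel(), est.EE.ravel()])
    if not np.isfinite(pooled).all():
        raise ValueError("non-finite values in normalized estimates")
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate pooled distribution; surface set to 0.5", stacklevel=2)
    p = smoothed_cdf(pooled, est.MM, method=method)
    return MMRSurface(
        p=p,
        scale_freqs_hz=est.scale_freqs_hz,
        time_ms=est.time_ms,
        subject=subject,
        condition=condition,
    )


def compute_mmr_surface(
    t: TFTensor,
    n_boot: int = 1001,
    seed: int = 0,
    method: str = "kde",
    subject: str = "",
    condition: str = "",
) -> MMRSurface:
    """Convenience chain: bootstrap -> scale-normalize -> probability map."""
    est = scale_normalize(bootstrap_difference(t, n_boot=n_boot, seed=seed))
    return probability_map(est, method=method, subject=subject, condition=condition)
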