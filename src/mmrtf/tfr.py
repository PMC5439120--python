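"""Trial whitening and complex Morlet wavelet transform.

Single-trial EEG epochs are PCA-whitened along the trial dimension, then
transformed with a 6-cycle complex Morlet continuous wavelet transform on 128
log-spaced scales spanning center frequencies 1.94-48.40 Hz.  The transform
is always computed on the full epoch and only afterwards truncated to
-100..700 ms, keeping the analysis window clear of epoch-edge artifacts; the
complex pre-stimulus mean (-100..0 ms) is subtracted per trial and scale, and
trials with outlying total squared magnitude are rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt

from .preprocess import EpochedBlock

logger = logging.getLogger(__name__)

__all__ = [
    "TFTensor",
    "morlet_wavelet_name",
    "center_frequencies",
    "whiten_trials",
    "cwt_morlet",
    "truncate_and_baseline",
    "reject_magnitude",
]

#: Morlet carrier parameter: "6-cycle" Morlet, omega0 = 6.
OMEGA0 = 6.0
F_MIN, F_MAX, N_SCALES = 1.94, 48.40, 128


@dataclass
class TFTensor:
    """Complex wavelet coefficients, trials x time x scales.

    ``scale_freqs_hz`` maps the scale axis to wavelet center frequencies
    (strictly increasing, log-spaced).
    """

    coeffs: np.ndarray
    scale_freqs_hz: np.ndarray
    time_ms: np.ndarray
    labels: np.ndarray
    fs: float

    def __post_init__(self):
        self.scale_freqs_hz = np.asarray(self.scale_freqs_hz, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.coeffs.shape != (len(self.labels), self.time_ms.size, self.scale_freqs_hz.size):
            raise ValueError("coeffs must be trials x time x scales")

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]


def morlet_wavelet_name(omega0: float = OMEGA0) -> str:
    """PyWavelets name of the complex Morlet with carrier ``omega0``.

    ``cmorB-C`` is exp(2*pi*i*C*t) * exp(-t^2/B); B=2 gives a unit-SD
    Gaussian envelope and C = omega0/(2*pi) the matching carrier.
    """
    return f"cmor2.0-{omega0 / (2 * np.pi):.16f}"


def center_frequencies(
    fmin: float = F_MIN, fmax: float = F_MAX, n_scales: int = N_SCALES
) -> np.ndarray:
    """Log-spaced wavelet center frequencies in Hz (increasing)."""
    return np.geomspace(fmin, fmax, n_scales)


def whiten_trials(block: EpochedBlock, min_pvaf: float = 1e-4) -> EpochedBlock:
    """Center and whiten an epoched block along the trial dimension via PCA.

    The trial dimension indexes the observations: each trial is one draw of
    the J time-point variables.  Centering subtracts the mean across trials
    (the average evoked response — deviant-minus-standard differences are
    unaffected); PCA of the time-point covariance then yields components
    whose eigenvalue spectrum follows the 1/f power distribution of the EEG,
    all components explaining at least ``min_pvaf`` (default 0.01%) of the
    total variance are retained and rescaled to unit variance, and the data
    are mapped back to the original coordinates (ZCA).  The net effect is a
    spectral flattening: low-frequency background power no longer dominates
    the wavelet coefficients.  Rows stay aligned with their stimulus labels.
    """
    if block.trials.ndim != 2:
        raise ValueError("whitening expects a single-channel trials x time block")
    if block.n_trials < 2:
        raise ValueError("whitening requires at least 2 trials")
    x = block.trials - block.trials.mean(axis=0, keepdims=True)
    n_i = x.shape[0]
    # time-point covariance from the trial ensemble; rank <= n_trials - 1
    cov = x.T @ x / (n_i - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    pvaf = evals / evals.sum()
    keep = pvaf >= min_pvaf
    if not keep.any():
        keep[0] = True
    v = evecs[:, keep]
    inv_sqrt = 1.0 / np.sqrt(evals[keep])
    white = (x @ v) * inv_sqrt[None, :] @ v.T
    logger.info(
        "whitening retained %d/%d temporal components", int(keep.sum()), evals.size
    )
    return replace(block, trials=white)


def cwt_morlet(
    block: EpochedBlock,
    n_scales: int = N_SCALES,
    omega0: float = OMEGA0,
    fmin: float = F_MIN,
    fmax: float = F_MAX,
    dtype=np.complex64,
    _chunk: int = 16,
) -> TFTensor:
    """Complex Morlet CWT of every trial on log-spaced scales.

    The center frequency of scale ``s`` (in samples) is
    ``omega0 * fs / (2*pi*s)``; scales are chosen so the ``n_scales`` center
    frequencies run ``fmin``..``fmax`` Hz.  Computed scale-chunked with FFT
    convolution on the *full* epoch; truncation to the analysis window is a
    separate step so edge artifacts stay outside it.
    """
    if block.trials.ndim != 2:
        raise ValueError("CWT expects a single-channel trials x time block")
    fs = block.fs
    if fmax >= fs / 2:
        raise ValueError("fmax must be below the Nyquist frequency")
    freqs = center_frequencies(fmin, fmax, n_scales)
    # Envelope SD of the slowest wavelet, in seconds.
    s_max = omega0 / (2 * np.pi * fmin)
    duration = (block.time_ms[-1] - block.time_ms[0]) / 1000.0
    if duration < np.sqrt(2.0) * s_max:
        raise ValueError(
            f"epoch ({duration:.3f} s) too short for the cone-of-influence of "
            f"the lowest scale (envelope SD {s_max:.3f} s)"
        )
    name = morlet_wavelet_name(omega0)
    scales = pywt.frequency2scale(name, freqs / fs)
    n_trials, n_time = block.trials.shape
    out = np.empty((n_trials, n_time, n_scales), dtype=dtype)
    data = np.ascontiguousarray(block.trials, dtype=float)
    for a in range(0, n_scales, _chunk):
        b = min(a + _chunk, n_scales)
        coeff, _ = pywt.cwt(data, scales[a:b], name, method="fft", axis=-1)
        # analytic-amplitude convention: rescale per scale so a pure sinusoid's
        # ridge peaks at its own center frequency (removes the sqrt-scale tilt)
        coeff /= scales[a:b][:, None, None]
        out[:, :, a:b] = np.transpose(coeff, (1, 2, 0))
    return TFTensor(
        coeffs=out,
        scale_freqs_hz=freqs,
        time_ms=block.time_ms.copy(),
        labels=block.labels.copy(),
        fs=fs,
    )


def truncate_and_baseline(
    t: TFTensor,
    window_ms: tuple = (-100.0, 700.0),
    baseline_ms: tuple = (-100.0, 0.0),
    omega0: float = OMEGA0,
) -> TFTensor:
    """Restrict to the analysis window and subtract the complex pre-stimulus
    mean per trial and scale.

    Warns when the margin between the kept window and the original epoch
    edges is inside the cone-of-influence (sqrt(2) envelope SDs) of the
    slowest scales — residual edge leakage is then possible at those scales.
    """
    keep = (t.time_ms >= window_ms[0]) & (t.time_ms <= window_ms[1])
    if not keep.any():
        raise ValueError("analysis window is outside the epoch time axis")
    margin_s = min(
        (window_ms[0] - t.time_ms[0]) / 1000.0,
        (t.time_ms[-1] - window_ms[1]) / 1000.0,
    )
    coi = np.sqrt(2.0) * omega0 / (2 * np.pi * t.scale_freqs_hz)
    n_inside = int((coi > margin_s).sum())
    if n_inside:
        warnings.warn(
            f"{n_inside} low-frequency scales have a cone-of-influence wider "
            f"than the {margin_s * 1e3:.0f} ms edge margin; residual edge "
            "leakage is possible at those scales",
            stacklevel=2,
        )
    coeffs = t.coeffs[:, keep, :]
    time_ms = t.time_ms[keep]
    bl = (time_ms >= baseline_ms[0]) & (time_ms < baseline_ms[1])
    coeffs = coeffs - coeffs[:, bl, :].mean(axis=1, keepdims=True)
    return replace(t, coeffs=coeffs, time_ms=time_ms)


def reject_magnitude(t: TFTensor, z: float = 2.5) -> TFTensor:
    """Drop trials whose total squared coefficient magnitude is an outlier.

    The per-trial statistic is the sum of |coeff|^2 over time and scale;
    trials above ``mean + z*SD`` are removed from the tensor.
    """
    if t.n_trials < 10:
        raise ValueError("magnitude rejection needs at least 10 trials")
    stat = np.einsum(
        "ijk->i", (t.coeffs.real.astype(float) ** 2 + t.coeffs.imag.astype(float) ** 2)
    )
    if not np.isfinite(z):
        return t
    sd = stat.std()
    keep = np.ones(t.n_trials, dtype=bool) if sd == 0 else stat <= stat.mean() + z * sd
    if not keep.any():
        raise ValueError("magnitude rejection removed every trial; review the z threshold")
    if (~keep).any():
        logger.info("magnitude rejection dropped %d/%d trials", int((~keep).sum()), t.n_trials)
    return replace(t, coeffs=t.coeffs[keep], labels=t.labels[keep])
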