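"""Continuous-EEG conditioning: filtering, re-referencing, epoching, rejection.

The processing chain mirrors standard evoked-response practice for oddball
recordings: a 2-50 Hz zero-phase FIR band-pass (high-pass above sleep
slow-wave activity, low-pass below line/muscle noise), re-referencing to the
common average or to linked mastoids, segmentation into -500..1500 ms epochs
baseline-corrected to the pre-stimulus interval, and joint-probability
artifact rejection at 2.5 SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "SCALP_CHANNELS",
    "ContinuousEEG",
    "EpochedBlock",
    "bandpass",
    "rereference",
    "epoch",
    "reject_joint_probability",
]

#: The 11-channel 10-20 montage used throughout (eye channel excluded).
SCALP_CHANNELS = ("F5", "Fz", "F6", "C5", "Cz", "C6", "P5", "Pz", "P6", "M1", "M2")


@dataclass
class ContinuousEEG:
    """Continuous multichannel EEG: ``data`` is channels x samples in µV."""

    data: np.ndarray
    fs: float
    channel_names: list
    reference: str = "nasion"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = list(self.channel_names)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be channels x samples matching channel_names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    def pick(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


@dataclass
class EpochedBlock:
    """Per-trial matrix with labels and a time axis anchored at onset (0 ms).

    ``trials`` is trials x time (single channel) or trials x channels x time;
    ``retained_mask`` marks trials that survived artifact rejection.
    """

    trials: np.ndarray
    labels: np.ndarray
    time_ms: np.ndarray
    fs: float
    retained_mask: np.ndarray = None
    channel_names: list | None = None

    def __post_init__(self):
        self.trials = np.asarray(self.trials)
        self.labels = np.asarray(self.labels, dtype=object)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.trials.shape[-1] != self.time_ms.size:
            raise ValueError("time axis length must match trial length")
        if not (self.time_ms.min() <= 0.0 <= self.time_ms.max()):
            raise ValueError("time axis must include stimulus onset (0 ms)")
        if self.retained_mask is None:
            self.retained_mask = np.ones(self.trials.shape[0], dtype=bool)
        else:
            self.retained_mask = np.asarray(self.retained_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def retained(self) -> "EpochedBlock":
        """Copy containing only the retained trials."""
        m = self.retained_mask
        return EpochedBlock(
            trials=self.trials[m],
            labels=self.labels[m],
            time_ms=self.time_ms.copy(),
            fs=self.fs,
            channel_names=self.channel_names,
        )


def _design_bandpass(fs: float, lo: float, hi: float) -> np.ndarray:
    """Windowed-sinc band-pass with transition bands set for a measured
    rolloff of roughly 24 dB/octave at the band edges."""
    # Transition widths: the Hamming-window FIR drops ~53 dB across the
    # transition band; spreading that drop over ~2.2 octaves below `lo` and
    # ~2 octaves above `hi` gives the gentle 24 dB/octave slope.
    trans_lo = min(1.8, lo * 0.9)
    trans_hi = min(110.0, 0.9 * (fs / 2 - hi))
    if trans_hi <= 0:
        raise ValueError("upper cutoff too close to Nyquist")
    width = min(trans_lo, trans_hi)
    numtaps = int(np.ceil(3.3 * fs / width)) | 1  # odd for exact delay comp.
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")


def bandpass(cont: ContinuousEEG, lo: float = 2.0, hi: float = 50.0) -> ContinuousEEG:
    """Zero-phase FIR band-pass, default 2-50 Hz.

    Linear-phase windowed-sinc taps applied with exact group-delay
    compensation (odd symmetric kernel, centered convolution), so the net
    phase response is zero.  Raises when the recording is shorter than three
    filter lengths, where edge contamination would dominate.
    """
    if hi >= cont.fs / 2:
        raise ValueError("upper cutoff must be below the Nyquist frequency")
    taps = _design_bandpass(cont.fs, lo, hi)
    if cont.data.shape[1] < 3 * taps.size:
        raise ValueError(
            f"signal ({cont.data.shape[1]} samples) shorter than 3x filter "
            f"length ({taps.size} taps); edges would contaminate the output"
        )
    out = np.empty_like(cont.data)
    for i, ch in enumerate(cont.data):
        out[i] = signal.fftconvolve(ch, taps, mode="same")
    return replace(cont, data=out)


def rereference(cont: ContinuousEEG, scheme: str = "common_average") -> ContinuousEEG:
    """Re-reference: ``common_average`` (mean of the 11 scalp channels),
    ``linked_mastoids`` ((M1+M2)/2), or ``nasion`` (recording reference,
    identity)."""
    if scheme == "nasion":
        return replace(cont, reference="nasion")
    if scheme == "common_average":
        scalp = [i for i, ch in enumerate(cont.channel_names) if ch in SCALP_CHANNELS]
        if not scalp:
            scalp = list(range(len(cont.channel_names)))
        ref = cont.data[scalp].mean(axis=0)
    elif scheme == "linked_mastoids":
        try:
            m1 = cont.pick("M1")
            m2 = cont.pick("M2")
        except ValueError as err:
            raise ValueError("linked_mastoids reference requires channels M1 and M2") from err
        ref = 0.5 * (m1 + m2)
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    return replace(cont, data=cont.data - ref, reference=scheme)


def epoch(
    cont: ContinuousEEG,
    events: pd.DataFrame,
    window_ms: tuple = (-500.0, 1500.0),
    baseline_ms: tuple = (-500.0, 0.0),
    channel: str | None = None,
) -> EpochedBlock:
    """Segment continuous EEG into onset-locked, baseline-corrected epochs.

    The epoch window is inclusive of both endpoints (2001 samples for
    -500..1500 ms at 1000 Hz); the baseline interval is closed on the left
    and open on the right.  Events whose window extends past the recording
    edge are dropped with a logged warning.
    """
    fs = cont.fs
    i0 = int(round(window_ms[0] * fs / 1000.0))
    i1 = int(round(window_ms[1] * fs / 1000.0))
    time_ms = (np.arange(i0, i1 + 1)) * 1000.0 / fs

    data = cont.data if channel is None else cont.pick(channel)[None, :]
    n_samples = data.shape[1]

    kept_trials, kept_labels, dropped = [], [], 0
    for onset, lab in zip(events["onset_sample"].to_numpy(), events["label"].to_numpy()):
        a, b = int(onset) + i0, int(onset) + i1 + 1
        if a < 0 or b > n_samples:
            dropped += 1
            continue
        kept_trials.append(data[:, a:b])
        kept_labels.append(lab)
    if dropped:
        logger.warning("dropped %d events without full window support", dropped)
    if not kept_trials:
        raise ValueError("no event has full window support inside the recording")

    trials = np.stack(kept_trials)  # trials x channels x time
    bl = (time_ms >= baseline_ms[0]) & (time_ms < baseline_ms[1])
    trials = trials - trials[:, :, bl].mean(axis=2, keepdims=True)
    if channel is not None or trials.shape[1] == 1:
        trials = trials[:, 0, :]
        names = None if channel is None else [channel]
    else:
        names = list(cont.channel_names)
    return EpochedBlock(
        trials=trials,
        labels=np.asarray(kept_labels, dtype=object),
        time_ms=time_ms,
        fs=fs,
        channel_names=names,
    )


def _jointprob_scores(trials2d: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Per-trial improbability score: summed negative log of the empirical
    probability of each sample amplitude, estimated from a histogram over all
    trials' samples (the classic single-channel joint-probability measure)."""
    x = trials2d.ravel()
    if n_bins is None:
        n_bins = max(10, int(np.ceil(2 * x.size ** (1 / 3))))  # Rice rule
    counts, edges = np.histogram(x, bins=n_bins)
    p = counts / counts.sum()
    p = np.clip(p, 1e-12, None)
    idx = np.clip(np.searchsorted(edges, trials2d, side="right") - 1, 0, n_bins - 1)
    return -np.log(p[idx]).sum(axis=-1)


def reject_joint_probability(block: EpochedBlock, z: float = 2.5) -> EpochedBlock:
    """Flag trials improbable under the joint amplitude distribution.

    Per channel, each trial is scored by the summed negative log-probability
    of its sample amplitudes; trials whose score exceeds ``mean + z*SD``
    (computed over trials, per channel) are flagged in ``retained_mask``.
    The data themselves are not modified, and the mask is label-blind.
    """
    if block.n_trials < 10:
        raise ValueError("joint-probability rejection needs at least 10 trials")
    trials = block.trials
    multi = trials.ndim == 3
    chans = trials.shape[1] if multi else 1
    rejected = np.zeros(block.n_trials, dtype=bool)
    if np.isfinite(z):
        for c in range(chans):
            t2d = trials[:, c, :] if multi else trials
            scores = _jointprob_scores(t2d)
            sd = scores.std()
            if sd == 0:
                continue
            rejected |= scores > scores.mean() + z * sd
    if rejected.all():
        raise ValueError(
            "joint-probability rejection removed every trial; review the z threshold"
        )
    if rejected.any():
        logger.info("joint-probability rejection flagged %d/%d trials", rejected.sum(), block.n_trials)
    return replace(block, retained_mask=~rejected)
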