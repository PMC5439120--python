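"""Synthetic sleep-EEG oddball simulator.

Generates oddball stimulus sequences and continuous multichannel EEG blocks
with a *known* deviant-response cascade, so that every downstream stage of the
pipeline can be validated against ground truth.  The emulated recording
conditions follow the auditory oddball protocol the rest of the package
analyzes: 1000 Hz sampling, an 11-channel 10-20 montage (F5, Fz, F6, C5, Cz,
C6, P5, Pz, P6, M1, M2), ~600-trial blocks at 85% standard / 15% deviant with
no two deviants in succession and a 1200 ms inter-stimulus interval.

The deviant response is modeled as a cascade of Hann-windowed oscillatory
bursts — an onset gamma burst (~34 Hz) shifting into a beta burst (~17 Hz),
temporally coupled with a theta-1 oscillation (~5 Hz), followed by a later
theta-2 oscillation (~6 Hz, optionally sweeping down toward ~3 Hz).  Burst
center frequencies, latencies, durations, amplitudes and phase jitter are all
parameters.  Background activity is spectrally shaped Gaussian noise
(1/f**alpha) with an additive delta/theta band emphasis mimicking
low-frequency-dominated infant sleep EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import SCALP_CHANNELS, ContinuousEEG

__all__ = [
    "ParadigmSpec",
    "BurstSpec",
    "NoiseSpec",
    "DEFAULT_TOPOGRAPHY",
    "generate_sequence",
    "subject_cascade",
    "burst_waveform",
    "synthesize_block",
    "default_cascade",
    "write_events_tsv",
]


@dataclass(frozen=True)
class ParadigmSpec:
    """Oddball block layout: trial count, deviant ratio, timing, seed."""

    n_trials: int = 600
    deviant_fraction: float = 0.15
    isi_ms: float = 1200.0
    no_successive_deviants: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0.0 <= self.deviant_fraction <= 1.0:
            raise ValueError("deviant_fraction must lie in [0, 1]")

    @property
    def n_deviant(self) -> int:
        return int(round(self.n_trials * self.deviant_fraction))


@dataclass(frozen=True)
class BurstSpec:
    """One oscillatory burst of the deviant-response cascade.

    The burst is a Hann-tapered sinusoid (or linear chirp when
    ``chirp_end_freq_hz`` is set) whose envelope peaks ``peak_latency_ms``
    after stimulus onset and spans ``duration_ms``.
    """

    band_label: str
    center_freq_hz: float
    peak_latency_ms: float
    duration_ms: float
    amplitude: float
    chirp_end_freq_hz: float | None = None
    phase: float = 0.0

    def __post_init__(self):
        if not 2.0 <= self.center_freq_hz <= 48.0:
            raise ValueError("center_freq_hz must lie in [2, 48] Hz")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise model: 1/f**alpha Gaussian noise with band emphasis.

    ``band_power_weights`` maps band names (``delta``: 2-4 Hz, ``theta``:
    4-8 Hz, ``alpha``: 8-12 Hz) to additive amplitude-gain factors emulating
    the low-frequency dominance of infant sleep EEG.
    """

    spectral_exponent: float = 1.0
    band_power_weights: dict = field(
        default_factory=lambda: {"delta": 0.5, "theta": 0.3}
    )
    channel_count: int = 11
    amplitude_sd: float = 15.0

    def __post_init__(self):
        if self.amplitude_sd <= 0:
            raise ValueError("amplitude_sd must be positive")
        if self.channel_count < 1:
            raise ValueError("channel_count must be at least 1")


_BAND_EDGES = {"delta": (2.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0)}

# Dipolar scalp projection of the auditory response: positive at the vertex,
# inverted at the mastoids (below the axial plane of the generator).
DEFAULT_TOPOGRAPHY = {
    "F5": 0.4, "Fz": 0.6, "F6": 0.4,
    "C5": 0.6, "Cz": 1.0, "C6": 0.6,
    "P5": 0.3, "Pz": 0.5, "P6": 0.3,
    "M1": -0.5, "M2": -0.5,
}


def generate_sequence(paradigm: ParadigmSpec) -> np.ndarray:
    """Draw an ordered standard/deviant label sequence for one block.

    The number of deviants is exact — ``round(n_trials * deviant_fraction)`` —
    and, when ``no_successive_deviants`` is set, no two deviants are adjacent.
    Subject to those constraints the arrangement is uniform-random (sampled
    through the stars-and-bars bijection between non-adjacent subsets and
    unrestricted subsets) and reproducible under the paradigm seed.

    Returns
    -------
    ndarray of str, values ``"standard"`` / ``"deviant"``.
    """
    n, k = paradigm.n_trials, paradigm.n_deviant
    rng = np.random.default_rng(paradigm.seed)
    labels = np.full(n, "standard", dtype=object)
    if k == 0:
        return labels
    if paradigm.no_successive_deviants:
        if k > (n + 1) // 2:
            raise ValueError(
                f"infeasible paradigm: {k} deviants cannot be placed in "
                f"{n} trials with no two deviants in succession "
                f"(at most {(n + 1) // 2} fit)"
            )
        slots = rng.choice(n - k + 1, size=k, replace=False)
        positions = np.sort(slots) + np.arange(k)
    else:
        positions = rng.choice(n, size=k, replace=False)
    labels[positions] = "deviant"
    return labels


def burst_waveform(burst: BurstSpec, fs: float, n_samples: int, phase: float = 0.0) -> np.ndarray:
    """Render one burst on a trial-long time axis starting at stimulus onset.

    Returns a length-``n_samples`` waveform (µV, unscaled by topography).  The
    Hann envelope is centered on ``peak_latency_ms``; for chirps the
    instantaneous frequency sweeps linearly from ``center_freq_hz`` at the
    window start to ``chirp_end_freq_hz`` at the window end.
    """
    if burst.center_freq_hz >= fs / 2 or (
        burst.chirp_end_freq_hz is not None and burst.chirp_end_freq_hz >= fs / 2
    ):
        raise ValueError(
            f"burst frequency {burst.center_freq_hz} Hz at or above the "
            f"Nyquist frequency ({fs / 2} Hz)"
        )
    t = np.arange(n_samples) / fs
    t0 = (burst.peak_latency_ms - burst.duration_ms / 2) / 1000.0
    dur = burst.duration_ms / 1000.0
    u = (t - t0) / dur  # 0..1 inside the burst window
    env = np.where((u >= 0) & (u <= 1), 0.5 - 0.5 * np.cos(2 * np.pi * np.clip(u, 0, 1)), 0.0)
    tau = np.clip(u, 0, 1) * dur
    if burst.chirp_end_freq_hz is None:
        inst_phase = 2 * np.pi * burst.center_freq_hz * tau
    else:
        # constant carrier up to the envelope peak, then a linear sweep so the
        # instantaneous frequency at the peak is center_freq_hz and reaches
        # chirp_end_freq_hz at the window end (the down-sweeping tail).
        half = dur / 2.0
        sweep = (burst.chirp_end_freq_hz - burst.center_freq_hz) / half
        pre = np.minimum(tau, half)
        post = np.clip(tau - half, 0.0, None)
        inst_phase = 2 * np.pi * (
            burst.center_freq_hz * pre
            + burst.center_freq_hz * post
            + 0.5 * sweep * post**2
        )
    return burst.amplitude * env * np.cos(inst_phase + burst.phase + phase)


def default_cascade(
    gamma_amp: float = 2.5,
    beta_amp: float = 2.0,
    theta1_amp: float = 5.0,
    theta2_amp: float = 2.0,
    latency_shift_ms: float = 0.0,
    chirped_theta: bool = True,
) -> list[BurstSpec]:
    """The default deviant-response cascade.

    Gamma (34 Hz, 25 ms) -> beta (17 Hz, 60 ms) wave packet coupled with a
    theta-1 oscillation (5 Hz, 70 ms), followed by a later theta-2 oscillation
    (6 Hz, 220 ms).  With ``chirped_theta`` (the default) both theta
    components sweep downward after their envelope peak (theta-1 toward
    ~2.2 Hz, theta-2 toward ~3 Hz) — the down-sweeping tails that keep the two
    theta ridges separated diagonally in the time-frequency plane.
    ``latency_shift_ms`` delays the whole cascade, emulating
    harder-to-discriminate contrasts.

    Amplitudes are in µV at the vertex before the dipolar topography and are
    deliberately small relative to the background (a few percent of the noise
    SD): the difference estimator detects phase-consistent structure in the
    complex mean, and single-trial evoked responses in real recordings are
    far below the background amplitude.  The defaults are calibrated so that
    single-block probability surfaces localize each component at ~600 trials.
    """
    d = latency_shift_ms
    bursts = [
        BurstSpec("gamma", 34.0, 25.0 + d, 120.0, gamma_amp),
        BurstSpec("beta", 17.0, 60.0 + d, 180.0, beta_amp),
    ]
    if chirped_theta:
        bursts += [
            BurstSpec("theta1", 5.0, 70.0 + d, 180.0, theta1_amp, chirp_end_freq_hz=2.2),
            BurstSpec("theta2", 6.0, 220.0 + d, 200.0, theta2_amp, chirp_end_freq_hz=3.0),
        ]
    else:
        bursts += [
            BurstSpec("theta1", 5.0, 70.0 + d, 180.0, theta1_amp),
            BurstSpec("theta2", 6.0, 220.0 + d, 200.0, theta2_amp),
        ]
    return bursts


def subject_cascade(
    bursts: list[BurstSpec],
    rng: np.random.Generator,
    latency_sd_ms: float = 20.0,
    freq_sd_rel: float = 0.08,
) -> list[BurstSpec]:
    """Individualize a cascade for one subject.

    Real cohorts vary: each subject's response components sit at slightly
    different latencies and frequencies around the population mean.  Burst
    latencies receive Gaussian jitter (``latency_sd_ms``) and center (and
    chirp-end) frequencies log-normal jitter (``freq_sd_rel`` relative SD),
    clipped to the valid 2-48 Hz band.  The population means remain the
    nominal cascade values.
    """
    out = []
    for b in bursts:
        factor = float(np.exp(rng.normal(0.0, freq_sd_rel)))
        f0 = float(np.clip(b.center_freq_hz * factor, 2.0, 48.0))
        f1 = b.chirp_end_freq_hz
        if f1 is not None:
            f1 = float(np.clip(f1 * factor, 2.0, 48.0))
        lat = float(max(b.peak_latency_ms + rng.normal(0.0, latency_sd_ms), b.duration_ms / 2 * 0.0))
        out.append(replace(b, center_freq_hz=f0, chirp_end_freq_hz=f1, peak_latency_ms=lat))
    return out


def _shaped_noise(rng, n_ch, n_samples, fs, spec: NoiseSpec) -> np.ndarray:
    """Gaussian noise with 1/f**alpha spectrum plus delta/theta emphasis."""
    freqs = np.fft.rfftfreq(n_samples, 1 / fs)
    gain = np.ones_like(freqs)
    nz = freqs > 0
    f_ref = 10.0  # unity gain reference frequency, Hz
    gain[nz] = (freqs[nz] / f_ref) ** (-spec.spectral_exponent / 2.0)
    gain[0] = 0.0
    for band, w in spec.band_power_weights.items():
        lo, hi = _BAND_EDGES[band]
        c, s = 0.5 * (lo + hi), (hi - lo)  # gentle, wide emphasis
        gain *= 1.0 + w * np.exp(-0.5 * ((freqs - c) / s) ** 2)
    white = rng.standard_normal((n_ch, n_samples))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * gain, n=n_samples, axis=1)
    shaped *= spec.amplitude_sd / shaped.std(axis=1, keepdims=True)
    return shaped


def synthesize_block(
    paradigm: ParadigmSpec,
    bursts: list[BurstSpec],
    noise: NoiseSpec,
    fs: float = 1000.0,
    *,
    standard_response: list[BurstSpec] | None = None,
    topography: dict | None = None,
    phase_jitter: float = 0.0,
    pad_s: float = 3.0,
    block_id: str = "block0",
) -> tuple[ContinuousEEG, pd.DataFrame]:
    """Synthesize one continuous oddball EEG block plus its event table.

    Standard trials contain background noise plus a common (smaller) onset
    response; deviant trials additionally contain each burst of the cascade.
    Bursts are phase-locked by default; ``phase_jitter`` (in radians, uniform
    on ±jitter) degrades the phase consistency the downstream complex-mean
    difference estimator depends on.

    Returns ``(ContinuousEEG, events)`` where *events* has columns
    ``onset_sample``, ``label``, ``block_id``.
    """
    for b in bursts:
        if b.center_freq_hz >= fs / 2:
            raise ValueError(
                f"burst {b.band_label!r} at {b.center_freq_hz} Hz exceeds the "
                f"Nyquist frequency {fs / 2} Hz"
            )
    topo = dict(DEFAULT_TOPOGRAPHY if topography is None else topography)
    channels = list(SCALP_CHANNELS[: noise.channel_count]) if noise.channel_count <= 11 else [
        f"ch{i}" for i in range(noise.channel_count)
    ]
    labels = generate_sequence(paradigm)
    isi_samples = int(round(paradigm.isi_ms * fs / 1000.0))
    pad = int(round(pad_s * fs))
    n_samples = 2 * pad + paradigm.n_trials * isi_samples
    rng = np.random.default_rng(np.random.SeedSequence([paradigm.seed, 0x5EED]))

    data = _shaped_noise(rng, len(channels), n_samples, fs, noise)
    weights = np.array([topo.get(ch, 0.0) for ch in channels])
    onsets = pad + np.arange(paradigm.n_trials) * isi_samples
    trial_len = isi_samples

    common = standard_response
    if common is None:
        common = [BurstSpec("onset", 4.0, 120.0, 250.0, 1.5)]

    for i, (onset, lab) in enumerate(zip(onsets, labels)):
        active = list(common) + (list(bursts) if lab == "deviant" else [])
        if not active:
            continue
        wave = np.zeros(trial_len)
        for b in active:
            phase = rng.uniform(-phase_jitter, phase_jitter) if phase_jitter > 0 else 0.0
            wave += burst_waveform(b, fs, trial_len, phase=phase)
        data[:, onset : onset + trial_len] += weights[:, None] * wave

    eeg = ContinuousEEG(data=data, fs=fs, channel_names=channels, reference="nasion")
    events = pd.DataFrame(
        {"onset_sample": onsets, "label": labels, "block_id": block_id}
    )
    return eeg, events


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)
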