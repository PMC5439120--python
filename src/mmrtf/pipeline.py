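"""End-to-end orchestration: synth -> preprocess -> tfr -> mmr -> group -> features.

A single :class:`RunConfig` drives the whole chain.  In synthetic mode the
simulator generates one oddball block per subject and condition with a known
response cascade; in file mode each block is read from disk (EDF/BDF or HDF5
continuous EEG plus a TSV event table).  Every stochastic stage draws its
seed deterministically from the master seed and the (subject, condition)
identity, so group runs are reproducible while blocks stay independent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import distatis, features, io, mmr, preprocess, synth, tfr
from ._utils import derive_seed

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "save_heatmap"]


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Synthetic-cohort fields are used when ``inputs`` is empty; otherwise
    ``inputs`` lists dicts with keys ``recording`` (EDF/BDF/HDF5 path),
    ``events`` (TSV path), ``subject`` and ``condition``.
    """

    out_dir: str | None = None
    seed: int = 0

    # synthetic cohort
    conditions: tuple = ("nonspeech", "vowel", "consonant")
    n_subjects: int = 12
    n_trials: int = 600
    deviant_fraction: float = 0.15
    isi_ms: float = 1200.0
    fs: float = 1000.0
    noise_alpha: float = 1.0
    noise_sd: float = 15.0
    phase_jitter: float = 0.0
    burst_scale: float = 1.0
    subject_latency_sd_ms: float = 20.0
    subject_freq_sd_rel: float = 0.06
    condition_latency_shift_ms: dict = field(
        default_factory=lambda: {"nonspeech": 0.0, "vowel": 0.0, "consonant": 100.0}
    )
    inputs: list = field(default_factory=list)

    # preprocessing
    filter_lo: float = 2.0
    filter_hi: float = 50.0
    reference: str = "linked_mastoids"
    channel: str = "Cz"
    epoch_window_ms: tuple = (-500.0, 1500.0)
    baseline_ms: tuple = (-500.0, 0.0)
    reject_z: float = 2.5

    # time-frequency
    n_scales: int = 128
    omega0: float = 6.0
    fmin: float = 1.94
    fmax: float = 48.40
    tf_window_ms: tuple = (-100.0, 700.0)
    tf_baseline_ms: tuple = (-100.0, 0.0)
    tf_reject_z: float = 2.5
    whiten_min_pvaf: float = 1e-4

    # statistics
    n_boot: int = 1001
    cdf_method: str = "kde"
    pvaf_min: float = 0.01
    qle_threshold: float = 0.8

    def validate(self) -> None:
        if not 0.0 <= self.deviant_fraction <= 1.0:
            raise ValueError("deviant_fraction must lie in [0, 1]")
        if not 0.0 <= self.qle_threshold <= 1.0:
            raise ValueError("qle_threshold must lie in [0, 1]")
        if not 0.0 <= self.pvaf_min <= 1.0:
            raise ValueError("pvaf_min must lie in [0, 1]")
        if self.fmax >= self.fs / 2:
            raise ValueError("fmax must be below the Nyquist frequency")
        if self.n_boot < 1 or self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as f:
            raw = tomllib.load(f)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        for key in ("epoch_window_ms", "baseline_ms", "tf_window_ms", "tf_baseline_ms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=list)


@dataclass
class PipelineResult:
    """Bundle of all stage outputs plus a summary report."""

    surfaces: list
    compromise: distatis.CompromiseSet
    projections: distatis.ProjectionSet
    feature_set: features.FeatureSet
    centroids: pd.DataFrame
    surprise: float | None
    report: dict


def _process_block(
    cont: preprocess.ContinuousEEG,
    events: pd.DataFrame,
    cfg: RunConfig,
    subject: str,
    condition: str,
) -> tuple[mmr.MMRSurface, dict]:
    filt = preprocess.bandpass(cont, cfg.filter_lo, cfg.filter_hi)
    reref = preprocess.rereference(filt, cfg.reference)
    block = preprocess.epoch(
        reref, events, window_ms=cfg.epoch_window_ms, baseline_ms=cfg.baseline_ms,
        channel=cfg.channel,
    )
    block = preprocess.reject_joint_probability(block, z=cfg.reject_z)
    n_rej_amp = int((~block.retained_mask).sum())
    block = block.retained()
    block = tfr.whiten_trials(block, min_pvaf=cfg.whiten_min_pvaf)
    tensor = tfr.cwt_morlet(
        block, n_scales=cfg.n_scales, omega0=cfg.omega0, fmin=cfg.fmin, fmax=cfg.fmax
    )
    tensor = tfr.truncate_and_baseline(
        tensor, window_ms=cfg.tf_window_ms, baseline_ms=cfg.tf_baseline_ms, omega0=cfg.omega0
    )
    n_before = tensor.n_trials
    tensor = tfr.reject_magnitude(tensor, z=cfg.tf_reject_z)
    surface = mmr.compute_mmr_surface(
        tensor,
        n_boot=cfg.n_boot,
        seed=derive_seed(cfg.seed, "mmr", subject, condition),
        method=cfg.cdf_method,
        subject=subject,
        condition=condition,
    )
    stats = {
        "subject": subject,
        "condition": condition,
        "n_trials": len(events),
        "rejected_amplitude": n_rej_amp,
        "rejected_magnitude": n_before - tensor.n_trials,
        "n_retained": tensor.n_trials,
    }
    return surface, stats


def _synthetic_blocks(cfg: RunConfig):
    noise = synth.NoiseSpec(
        spectral_exponent=cfg.noise_alpha, amplitude_sd=cfg.noise_sd, channel_count=11
    )
    for si in range(cfg.n_subjects):
        subject = f"s{si:02d}"
        subj_rng = np.random.default_rng(derive_seed(cfg.seed, "subject", subject))
        for cond in cfg.conditions:
            shift = cfg.condition_latency_shift_ms.get(cond, 0.0)
            bursts = synth.default_cascade(latency_shift_ms=shift)
            if cfg.burst_scale != 1.0:
                bursts = [
                    dataclasses.replace(b, amplitude=b.amplitude * cfg.burst_scale)
                    for b in bursts
                ]
            if cfg.subject_latency_sd_ms > 0 or cfg.subject_freq_sd_rel > 0:
                bursts = synth.subject_cascade(
                    bursts, subj_rng,
                    latency_sd_ms=cfg.subject_latency_sd_ms,
                    freq_sd_rel=cfg.subject_freq_sd_rel,
                )
            paradigm = synth.ParadigmSpec(
                n_trials=cfg.n_trials,
                deviant_fraction=cfg.deviant_fraction,
                isi_ms=cfg.isi_ms,
                seed=derive_seed(cfg.seed, "synth", subject, cond),
            )
            cont, events = synth.synthesize_block(
                paradigm, bursts, noise, fs=cfg.fs,
                phase_jitter=cfg.phase_jitter, block_id=cond,
            )
            yield subject, cond, cont, events


def _file_blocks(cfg: RunConfig):
    for item in cfg.inputs:
        path = Path(item["recording"])
        if not path.exists():
            raise FileNotFoundError(f"recording not found: {path}")
        ev_path = Path(item["events"])
        if not ev_path.exists():
            raise FileNotFoundError(f"event file not found: {ev_path}")
        cont = io.read_continuous(path)
        events = io.read_events_tsv(ev_path)
        yield str(item.get("subject", path.stem)), str(item.get("condition", "default")), cont, events


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full analysis chain and (optionally) write its artifacts.

    Writes, when ``cfg.out_dir`` is set: the resolved config, per-block
    surfaces (HDF5), the centroid table (CSV), heat maps of the grand and
    condition compromises (PNG), and a JSON report with trial/rejection
    counts, rc values and retained-component counts.
    """
    cfg.validate()
    t0 = time.time()
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(cfg.to_json())

    blocks = _file_blocks(cfg) if cfg.inputs else _synthetic_blocks(cfg)
    surfaces, block_stats = [], []
    for subject, cond, cont, events in blocks:
        try:
            surface, stats = _process_block(cont, events, cfg, subject, cond)
        except Exception as err:
            raise RuntimeError(
                f"pipeline failed at block subject={subject} condition={cond}: {err}"
            ) from err
        logger.info(
            "block %s/%s: %d trials retained (%d amp-rejected, %d magnitude-rejected)",
            subject, cond, stats["n_retained"], stats["rejected_amplitude"],
            stats["rejected_magnitude"],
        )
        surfaces.append(surface)
        block_stats.append(stats)

    cs, ps = distatis.group_analysis(surfaces, pvaf_min=cfg.pvaf_min)
    B = features.minimum_bound(list(ps.condition_means.values()))
    qle = features.qle_map(ps.grand_mean, B, method=cfg.cdf_method)
    fset = features.extract_features(
        qle, surfaces[0].scale_freqs_hz, surfaces[0].time_ms, threshold=cfg.qle_threshold
    )
    fset.B = B
    centroids = features.centroid_table(fset, ps.condition_means)

    surprise_val = None
    names = {f.name: f for f in fset.features}
    if "theta-1" in names and "theta-2" in names:
        y_t1, y_f1 = features.feature_distributions(names["theta-1"].mask, ps.grand_mean)
        y_t2, y_f2 = features.feature_distributions(names["theta-2"].mask, ps.grand_mean)
        try:
            surprise_val = features.surprise(
                features.estimate_surprise_inputs(y_f1, y_f2, y_t1, y_t2)
            )
        except ValueError:
            surprise_val = None

    report = {
        "blocks": block_stats,
        "n_surfaces": len(surfaces),
        "rc_F": cs.rc_f,
        "rc_T": cs.rc_t,
        "retained_components_F": int(cs.w_f.shape[1]),
        "retained_components_T": int(cs.w_t.shape[1]),
        "n_features": len(fset.features),
        "feature_names": [f.name for f in fset.features],
        "max_qle": float(fset.qle.max()),
        "surprise": surprise_val,
        "seed": cfg.seed,
        "runtime_s": round(time.time() - t0, 2),
    }

    if out_dir:
        io.save_surfaces_h5(surfaces, out_dir / "surfaces.h5", metadata={"seed": cfg.seed})
        centroids.to_csv(out_dir / "centroids.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        save_heatmap(
            ps.grand_mean, surfaces[0].scale_freqs_hz, surfaces[0].time_ms,
            out_dir / "grand_compromise.png", title="Grand compromise (RP)",
        )
        for cond, g in ps.condition_means.items():
            save_heatmap(
                g, surfaces[0].scale_freqs_hz, surfaces[0].time_ms,
                out_dir / f"condition_{cond}.png", title=f"{cond} compromise (RP)",
            )
        save_heatmap(
            fset.qle, surfaces[0].scale_freqs_hz, surfaces[0].time_ms,
            out_dir / "qle.png", title="Quasi-likelihood estimate",
        )

    return PipelineResult(
        surfaces=surfaces, compromise=cs, projections=ps,
        feature_set=fset, centroids=centroids, surprise=surprise_val, report=report,
    )


def save_heatmap(surface, scale_freqs_hz, time_ms, path, title="") -> None:
    """Time-frequency heat map (log frequency axis) written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    mesh = ax.pcolormesh(time_ms, scale_freqs_hz, surface, cmap="magma", shading="auto")
    ax.set_yscale("log")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="relative probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
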