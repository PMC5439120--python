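"""File I/O: HDF5 artifacts, event TSVs, EDF/BDF reading.

HDF5 is the native interchange format between pipeline stages (complex
tensors are stored as paired real/imag datasets).  Continuous EEG can also be
read from EDF/BDF via :mod:`mne`; EDF *writing* additionally requires an EDF
export backend (``edfio``) and raises a clear error when none is installed.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .mmr import MMRSurface
from .preprocess import ContinuousEEG, EpochedBlock
from .tfr import TFTensor

__all__ = [
    "read_continuous",
    "save_continuous_h5",
    "save_edf",
    "read_events_tsv",
    "save_block_h5",
    "load_block_h5",
    "save_tensor_h5",
    "load_tensor_h5",
    "save_surfaces_h5",
    "load_surfaces_h5",
]

_STR = h5py.string_dtype(encoding="utf-8")


def read_events_tsv(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    required = {"onset_sample", "label"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table {path} lacks columns: {sorted(missing)}")
    return events


def read_continuous(path) -> ContinuousEEG:
    """Read continuous EEG from EDF/BDF (via mne) or from our HDF5 layout."""
    path = str(path)
    if path.endswith((".edf", ".bdf")):
        import mne

        reader = mne.io.read_raw_edf if path.endswith(".edf") else mne.io.read_raw_bdf
        raw = reader(path, preload=True, verbose="error")
        return ContinuousEEG(
            data=raw.get_data() * 1e6,  # volts -> µV
            fs=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
        )
    with h5py.File(path, "r") as f:
        return ContinuousEEG(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channel_names=[s.decode() if isinstance(s, bytes) else s for s in f["channel_names"][()]],
            reference=str(f.attrs.get("reference", "nasion")),
        )


def save_continuous_h5(cont: ContinuousEEG, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cont.data)
        f.create_dataset("channel_names", data=np.array(cont.channel_names, dtype=_STR))
        f.attrs["fs"] = cont.fs
        f.attrs["reference"] = cont.reference


def save_edf(cont: ContinuousEEG, path) -> None:
    """Export continuous EEG to EDF (requires the ``edfio`` backend)."""
    import mne

    info = mne.create_info(cont.channel_names, cont.fs, ch_types="eeg")
    raw = mne.io.RawArray(cont.data * 1e-6, info, verbose="error")
    try:
        mne.export.export_raw(str(path), raw, fmt="edf", overwrite=True, verbose="error")
    except (ImportError, RuntimeError, ValueError) as err:
        raise ImportError(
            "EDF export needs the 'edfio' package; install it or use save_continuous_h5"
        ) from err


def save_block_h5(block: EpochedBlock, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=block.trials)
        f.create_dataset("labels", data=np.array([str(l) for l in block.labels], dtype=_STR))
        f.create_dataset("time_ms", data=block.time_ms)
        f.create_dataset("retained", data=block.retained_mask.astype(np.int8))
        f.attrs["fs"] = block.fs
        if block.channel_names:
            f.create_dataset("channel_names", data=np.array(block.channel_names, dtype=_STR))


def load_block_h5(path) -> EpochedBlock:
    with h5py.File(path, "r") as f:
        names = None
        if "channel_names" in f:
            names = [s.decode() if isinstance(s, bytes) else s for s in f["channel_names"][()]]
        return EpochedBlock(
            trials=f["trials"][()],
            labels=np.array([s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]], dtype=object),
            time_ms=f["time_ms"][()],
            fs=float(f.attrs["fs"]),
            retained_mask=f["retained"][()].astype(bool),
            channel_names=names,
        )


def save_tensor_h5(t: TFTensor, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coeffs_real", data=t.coeffs.real)
        f.create_dataset("coeffs_imag", data=t.coeffs.imag)
        f.create_dataset("scale_freqs_hz", data=t.scale_freqs_hz)
        f.create_dataset("time_ms", data=t.time_ms)
        f.create_dataset("labels", data=np.array([str(l) for l in t.labels], dtype=_STR))
        f.attrs["fs"] = t.fs


def load_tensor_h5(path) -> TFTensor:
    with h5py.File(path, "r") as f:
        coeffs = f["coeffs_real"][()].astype(np.float32) + 1j * f["coeffs_imag"][()].astype(np.float32)
        return TFTensor(
            coeffs=coeffs.astype(np.complex64),
            scale_freqs_hz=f["scale_freqs_hz"][()],
            time_ms=f["time_ms"][()],
            labels=np.array([s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]], dtype=object),
            fs=float(f.attrs["fs"]),
        )


def save_surfaces_h5(surfaces: list[MMRSurface], path, metadata: dict | None = None) -> None:
    """Store per-subject/condition probability surfaces in one file."""
    with h5py.File(path, "w") as f:
        for i, s in enumerate(surfaces):
            grp = f.create_group(f"surface_{i:04d}")
            grp.create_dataset("p", data=s.p)
            grp.attrs["subject"] = s.subject
            grp.attrs["condition"] = s.condition
        f.create_dataset("scale_freqs_hz", data=surfaces[0].scale_freqs_hz)
        f.create_dataset("time_ms", data=surfaces[0].time_ms)
        if metadata:
            f.attrs["metadata"] = json.dumps(metadata)


def load_surfaces_h5(path) -> list[MMRSurface]:
    out = []
    with h5py.File(path, "r") as f:
        freqs = f["scale_freqs_hz"][()]
        time_ms = f["time_ms"][()]
        for key in sorted(k for k in f.keys() if k.startswith("surface_")):
            grp = f[key]
            out.append(
                MMRSurface(
                    p=grp["p"][()],
                    scale_freqs_hz=freqs,
                    time_ms=time_ms,
                    subject=str(grp.attrs.get("subject", "")),
                    condition=str(grp.attrs.get("condition", "")),
                )
            )
    return out
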