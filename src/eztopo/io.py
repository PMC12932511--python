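"""Reading and writing recordings, cohorts and report artifacts.

Real recordings come in as EDF/EDF+ (read through :mod:`mne`, honoring
per-channel sampling rates by resampling to the lowest common rate).
Simulated cohorts are persisted as NPZ arrays with a JSON sidecar
carrying labels and provenance, plus a CSV manifest for cohort runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Recording

__all__ = [
    "save_recording",
    "read_montage",
    "write_montage",
    "read_region_map",
    "write_connectivity",
    "write_network",
    "load_recording",
    "save_cohort",
    "load_cohort",
    "read_edf",
]


def _sidecar(rec: Recording) -> dict:
    return {
        "patient_id": rec.patient_id,
        "modality": rec.modality,
        "state": rec.state,
        "sampling_rate": rec.sampling_rate,
        "channel_labels": list(rec.channel_labels),
        "ez_mask": None if rec.ez_mask is None else rec.ez_mask.astype(int).tolist(),
        "ez_region_mask": None if rec.ez_region_mask is None
        else np.asarray(rec.ez_region_mask).astype(int).tolist(),
        "provenance": rec.provenance,
    }


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write one recording as ``<stem>.npz`` + ``<stem>.json`` sidecar."""
    path = Path(path)
    stem = path.with_suffix("")
    np.savez_compressed(stem.with_suffix(".npz"), data=rec.data)
    stem.with_suffix(".json").write_text(json.dumps(_sidecar(rec), indent=1))
    return stem.with_suffix(".npz")


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    stem = path.with_suffix("")
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npz"))["data"]
    return Recording(
        patient_id=meta["patient_id"],
        modality=meta["modality"],
        state=meta["state"],
        data=data,
        sampling_rate=meta["sampling_rate"],
        channel_labels=meta["channel_labels"],
        ez_mask=None if meta["ez_mask"] is None else np.asarray(meta["ez_mask"], bool),
        ez_region_mask=None if meta.get("ez_region_mask") is None
        else np.asarray(meta["ez_region_mask"], bool),
        provenance=meta.get("provenance", {}),
    )


def save_cohort(recordings, outdir: str | Path) -> Path:
    """Write every recording plus a CSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        name = f"{rec.patient_id}_{rec.modality}_{rec.state}"
        save_recording(rec, outdir / name)
        rows.append({"patient_id": rec.patient_id, "modality": rec.modality,
                     "state": rec.state, "file": f"{name}.npz",
                     "n_channels": rec.data.shape[0],
                     "sampling_rate": rec.sampling_rate})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest: str | Path) -> list[Recording]:
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    return [load_recording(manifest.parent / f) for f in table["file"]]


def read_edf(path: str | Path, ez_channels=None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    ``ez_channels`` is an optional list of channel names to mark as EZ;
    without it the mask is left unset (label later from clinical data).
    A JSON sidecar next to the file (same stem) is honored if present.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if ez_channels is None and meta.get("ez_mask") is not None:
        ez_mask = np.asarray(meta["ez_mask"], dtype=bool)
    elif ez_channels is not None:
        ez_mask = np.asarray([ch in set(ez_channels) for ch in labels])
    else:
        ez_mask = None
    return Recording(
        patient_id=meta.get("patient_id", path.stem),
        modality=meta.get("modality", "seeg"),
        state=meta.get("state", "interictal"),
        data=raw.get_data(),
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        ez_mask=ez_mask,
        provenance={"source": str(path)},
    )


def read_montage(path: str | Path):
    """Plain-text montage: ``label x y z`` per line (unit-sphere coords)."""
    labels, positions = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"montage line needs 'label x y z': {line!r}")
        labels.append(parts[0])
        positions.append([float(v) for v in parts[1:]])
    return labels, np.asarray(positions)


def write_montage(labels, positions, path: str | Path) -> None:
    lines = [f"{lab} {x:.6f} {y:.6f} {z:.6f}"
             for lab, (x, y, z) in zip(labels, positions)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_region_map(path: str | Path) -> pd.DataFrame:
    """Region map CSV with columns source_index, region_label[, hemisphere]."""
    table = pd.read_csv(path)
    required = {"source_index", "region_label"}
    if not required <= set(table.columns):
        raise ValueError(f"region map needs columns {sorted(required)}")
    return table.sort_values("source_index").reset_index(drop=True)


def write_connectivity(conn, path: str | Path) -> None:
    """Correlation matrix as labeled CSV."""
    pd.DataFrame(conn.values, index=conn.node_labels,
                 columns=conn.node_labels).to_csv(path)


def write_network(net, path: str | Path) -> None:
    """Adjacency as labeled CSV plus a JSON summary next to it."""
    path = Path(path)
    pd.DataFrame(net.adjacency, index=net.node_labels,
                 columns=net.node_labels).to_csv(path)
    n = net.n_nodes
    summary = {
        "band": net.band, "state": net.state, "threshold": net.threshold,
        "n_nodes": n, "n_edges": net.n_edges,
        "density": net.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0,
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=1))
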