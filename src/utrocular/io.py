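"""On-disk interchange: NIfTI volumes, BIDS-style events tables, trial TSVs.

Simulated runs are written as 4D NIfTI files (the 2D voxel sheet becomes an
``nx x ny x 1 x time`` volume) with an ROI mask volume and a per-run events
TSV (columns ``onset``, ``duration``, ``trial_type``); reading the trio back
reconstructs the in-memory :class:`~utrocular.samples.RunData` exactly.
Generator parameters travel in a JSON sidecar so every dataset is
self-describing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .behavior import BehavioralSession
from .samples import FIXATION, RunData


def _affine(voxel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
    return aff


def write_run_nifti(
    run: RunData, voxel_shape: tuple[int, int], path, voxel_mm: float = 1.5
) -> Path:
    """Write one run as a 4D NIfTI (sheet voxels unfolded to nx x ny x 1 x T)."""
    path = Path(path)
    nx, ny = voxel_shape
    if nx * ny != run.n_voxels:
        raise ValueError(f"voxel_shape {voxel_shape} does not match {run.n_voxels} voxels")
    vol = run.data.reshape(nx, ny, 1, run.n_volumes)
    img = nib.Nifti1Image(vol.astype(np.float32), _affine(voxel_mm))
    img.header.set_zooms((voxel_mm, voxel_mm, voxel_mm, run.tr_s))
    nib.save(img, str(path))
    return path


def write_mask_nifti(mask: np.ndarray, path, voxel_mm: float = 1.5) -> Path:
    path = Path(path)
    m = np.asarray(mask, dtype=np.uint8)
    if m.ndim == 2:
        m = m[:, :, None]
    nib.save(nib.Nifti1Image(m, _affine(voxel_mm)), str(path))
    return path


def write_events_tsv(run: RunData, path) -> Path:
    """BIDS-style events table for one run: onset (s), duration (s), trial_type."""
    path = Path(path)
    rows = []
    current, start = None, 0
    labels = list(run.volume_labels) + [None]
    for t, lab in enumerate(labels):
        if lab != current:
            if current is not None and current != FIXATION:
                rows.append(
                    {
                        "onset": start * run.tr_s,
                        "duration": (t - start) * run.tr_s,
                        "trial_type": current,
                    }
                )
            current, start = lab, t
    pd.DataFrame(rows, columns=["onset", "duration", "trial_type"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_run(
    nifti_path, events_path, mask_path=None, run_index: int = 0
) -> RunData:
    """Reassemble a RunData from a 4D NIfTI, events TSV and optional ROI mask."""
    img = nib.load(str(nifti_path))
    vol = np.asarray(img.dataobj, dtype=float)
    tr_s = float(img.header.get_zooms()[3])
    data = vol.reshape(-1, vol.shape[3])
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool).reshape(-1)
        data = data[mask]
    events = pd.read_csv(events_path, sep="\t")
    labels = [FIXATION] * data.shape[1]
    for _, ev in events.iterrows():
        t0 = int(round(ev["onset"] / tr_s))
        n = int(round(ev["duration"] / tr_s))
        for t in range(t0, min(t0 + n, len(labels))):
            labels[t] = ev["trial_type"]
    return RunData(data=data, volume_labels=labels, tr_s=tr_s, run_index=run_index)


def write_behavior_tsv(session: BehavioralSession, path) -> Path:
    path = Path(path)
    session.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_behavior_tsv(path, dominant_eye: str = "L", subject_id: str = "s0"):
    df = pd.read_csv(path, sep="\t")
    return BehavioralSession.from_frame(df, dominant_eye=dominant_eye, subject_id=subject_id)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> Path:
    """Serialize (nested dataclasses / numpy included) to pretty JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
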