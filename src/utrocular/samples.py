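"""Core data containers shared across the pipeline.

A scanning run is a voxels x volumes matrix with one condition token per
volume (``RunData``).  Preprocessing collapses each stimulation block into a
single voxel vector (``PatternSample``), and the decoder consumes stacks of
those vectors (``SampleSet``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EYES = ("L", "R")
SFS = ("low", "high")
FIXATION = "fix"

#: The four stimulus conditions in canonical order: eye x spatial frequency.
CONDITIONS = tuple(f"{eye}_{sf}" for sf in SFS for eye in EYES)


def condition_label(eye: str, sf: str) -> str:
    """Canonical token for a condition, e.g. ``"L_low"``."""
    if eye not in EYES:
        raise ValueError(f"unknown eye token {eye!r}; expected one of {EYES}")
    if sf not in SFS:
        raise ValueError(f"unknown sf token {sf!r}; expected one of {SFS}")
    return f"{eye}_{sf}"


def parse_condition(label: str) -> tuple[str, str]:
    """Split a condition token into its (eye, sf) parts."""
    eye, _, sf = label.partition("_")
    if eye not in EYES or sf not in SFS:
        raise ValueError(f"not a condition token: {label!r}")
    return eye, sf


@dataclass
class RunData:
    """One scanning run: voxels x volumes plus per-volume labels.

    Parameters
    ----------
    data
        Array of shape ``(n_voxels, n_volumes)`` in arbitrary response units
        (z-units after normalization).
    volume_labels
        One token per volume: a condition label (``"L_low"`` ...) during
        stimulation or :data:`FIXATION` during blanks.
    tr_s
        Repetition time in seconds (volume sampling interval).
    run_index
        Zero-based run number within the session.
    """

    data: np.ndarray
    volume_labels: Sequence[str]
    tr_s: float
    run_index: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.volume_labels = list(self.volume_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a voxels x volumes matrix")
        if len(self.volume_labels) != self.data.shape[1]:
            raise ValueError(
                f"label vector length {len(self.volume_labels)} does not match "
                f"{self.data.shape[1]} volumes"
            )
        labels = set(self.volume_labels)
        if FIXATION not in labels or labels == {FIXATION}:
            raise ValueError("run must contain both fixation and stimulation volumes")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class PatternSample:
    """One stimulation block collapsed to a voxel vector."""

    values: np.ndarray
    eye: str
    sf: str
    run_index: int
    block_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.eye not in EYES or self.sf not in SFS:
            raise ValueError(f"invalid condition tokens ({self.eye!r}, {self.sf!r})")

    @property
    def condition(self) -> str:
        return condition_label(self.eye, self.sf)


class SampleSet:
    """A stack of pattern samples with aligned label arrays.

    Attributes
    ----------
    X : ndarray, shape (n_samples, n_voxels)
    eye, sf : ndarray of str tokens per sample
    run, block : ndarray of int per sample
    """

    def __init__(self, X, eye, sf, run, block=None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.eye = np.asarray(eye, dtype=object)
        self.sf = np.asarray(sf, dtype=object)
        self.run = np.asarray(run, dtype=int)
        self.block = (
            np.arange(len(self.run)) if block is None else np.asarray(block, dtype=int)
        )
        n = self.X.shape[0]
        if not (len(self.eye) == len(self.sf) == len(self.run) == len(self.block) == n):
            raise ValueError("label arrays must match the number of samples")

    @classmethod
    def from_patterns(cls, patterns: Iterable[PatternSample]) -> "SampleSet":
        patterns = list(patterns)
        if not patterns:
            raise ValueError("empty pattern list")
        return cls(
            X=np.vstack([p.values for p in patterns]),
            eye=[p.eye for p in patterns],
            sf=[p.sf for p in patterns],
            run=[p.run_index for p in patterns],
            block=[p.block_index for p in patterns],
        )

    @property
    def labels(self) -> np.ndarray:
        """Condition token per sample."""
        return np.array(
            [condition_label(e, s) for e, s in zip(self.eye, self.sf)], dtype=object
        )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def subset(self, mask) -> "SampleSet":
        mask = np.asarray(mask)
        return SampleSet(
            self.X[mask], self.eye[mask], self.sf[mask], self.run[mask], self.block[mask]
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples as rows, voxels as columns, plus eye/sf/run/block labels."""
        df = pd.DataFrame(self.X, columns=[f"v{i}" for i in range(self.n_voxels)])
        df.insert(0, "block", self.block)
        df.insert(0, "run", self.run)
        df.insert(0, "sf", self.sf)
        df.insert(0, "eye", self.eye)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSet":
        voxel_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        return cls(
            X=df[voxel_cols].to_numpy(dtype=float),
            eye=df["eye"].to_numpy(),
            sf=df["sf"].to_numpy(),
            run=df["run"].to_numpy(dtype=int),
            block=df["block"].to_numpy(dtype=int),
        )
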