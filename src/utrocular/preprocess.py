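"""From labelled run time series to one pattern sample per block.

Each run's voxel time courses are z-score normalized over the full run
(stimulation plus fixation), so responses are expressed relative to the
run's baseline.  Stimulation blocks are then located from the volume
labels, the assignment window is shifted forward by a fixed number of
volumes to compensate for the hemodynamic lag (one volume = one TR by
default), and the volumes of each block are averaged into a single voxel
vector — the "sample" unit that all decoding operates on.
"""

from __future__ import annotations

import numpy as np

from .samples import FIXATION, PatternSample, RunData, SampleSet, parse_condition


def znormalize_run(run: RunData, per_pattern: bool = False) -> RunData:
    """Z-score normalize a run's time courses.

    By default each voxel's time course is normalized to mean 0, SD 1 over
    the run (population-SD convention); voxels with zero variance map to
    all-zeros.  ``per_pattern=True`` instead normalizes each volume across
    voxels — an alternative reading of per-run normalization, exposed as an
    option but not the default.
    """
    if run.n_volumes < 2:
        raise ValueError("need at least 2 volumes to normalize")
    axis = 0 if per_pattern else 1
    mean = run.data.mean(axis=axis, keepdims=True)
    sd = run.data.std(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (run.data - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return RunData(
        data=z, volume_labels=run.volume_labels, tr_s=run.tr_s, run_index=run.run_index
    )


def _find_blocks(labels) -> list[tuple[int, int, str]]:
    """Maximal constant-label stimulation stretches as (start, stop, label)."""
    blocks = []
    start = None
    current = None
    for t, lab in enumerate(list(labels) + [FIXATION]):
        if lab != current:
            if current is not None and current != FIXATION:
                blocks.append((start, t, current))
            start, current = t, lab
    return blocks


def extract_samples(run: RunData, lag_volumes: int = 1) -> list[PatternSample]:
    """Average each stimulation block into one pattern sample.

    The averaging window of a block occupying volumes ``t0..t1-1`` is
    shifted to ``t0+lag..t1-1+lag``; volumes shifted past the end of the
    run are dropped from the average.  A block left with no contributing
    volumes is an error.
    """
    if lag_volumes < 0:
        raise ValueError("lag_volumes must be >= 0")
    samples = []
    for block_index, (t0, t1, label) in enumerate(_find_blocks(run.volume_labels)):
        lo = t0 + lag_volumes
        hi = min(t1 + lag_volumes, run.n_volumes)
        if lo >= hi:
            raise ValueError(
                f"block {block_index} ({label}, volumes {t0}..{t1 - 1}) has no "
                f"contributing volumes after a {lag_volumes}-volume shift"
            )
        eye, sf = parse_condition(label)
        samples.append(
            PatternSample(
                values=run.data[:, lo:hi].mean(axis=1),
                eye=eye,
                sf=sf,
                run_index=run.run_index,
                block_index=block_index,
            )
        )
    return samples


def samples_from_runs(
    runs, lag_volumes: int = 1, normalize: bool = True
) -> SampleSet:
    """Normalize runs, extract block samples, and stack them into a SampleSet."""
    patterns = []
    for run in runs:
        if normalize:
            run = znormalize_run(run)
        patterns.extend(extract_samples(run, lag_volumes))
    return SampleSet.from_patterns(patterns)
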