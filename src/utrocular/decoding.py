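"""Template classifiers with leave-one-run-out cross-validation.

The decoder discriminates two conditions from block-wise voxel patterns.
Within every cross-validation fold, voxels are first ranked on the
*training runs only* — either by the absolute two-sample T statistic
contrasting the two conditions (pattern decoding) or by mean response
amplitude (univariate decoding of the most visually responsive voxels) —
and the top ``n_voxels_cutoff`` (100 by default) are kept.  Per-condition
mean training patterns form the templates; a held-out sample is assigned to
the condition whose template it correlates with most strongly (Pearson), or,
for the univariate variant, whose scalar mean-template it is closest to.
Accuracy is the mean over folds of the proportion of correct test
classifications.

Performing voxel selection inside each fold is what keeps the procedure
non-circular: on pure-noise data the selected voxels carry no generalizable
information and accuracy stays at chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .samples import SampleSet


@dataclass(frozen=True)
class DecodingConfig:
    """Classifier family, voxel cutoff and the binary problem to solve."""

    n_voxels_cutoff: int = 100
    classifier: str = "pattern_correlation"  # or "univariate_difference"
    problem: tuple[str, str] = ("L_low", "R_low")
    tie_break: str = "first"  # lowest index in canonical (problem) order

    def __post_init__(self) -> None:
        if self.n_voxels_cutoff < 1:
            raise ValueError("n_voxels_cutoff must be >= 1")
        if self.classifier not in ("pattern_correlation", "univariate_difference"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if len(self.problem) != 2 or self.problem[0] == self.problem[1]:
            raise ValueError("problem must be a pair of distinct condition labels")
        if self.tie_break != "first":
            raise ValueError(f"unknown tie_break rule {self.tie_break!r}")


@dataclass
class DecodingResult:
    """Per-fold and overall accuracy for one binary problem."""

    fold_accuracies: np.ndarray
    accuracy: float
    selected_voxels_per_fold: list[np.ndarray]
    fold_runs: np.ndarray
    n_ties: int
    config: DecodingConfig

    def to_dict(self) -> dict:
        return {
            "accuracy": float(self.accuracy),
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "fold_runs": [int(r) for r in self.fold_runs],
            "selected_voxels_per_fold": [
                [int(i) for i in sel] for sel in self.selected_voxels_per_fold
            ],
            "n_ties": int(self.n_ties),
            "config": {
                "n_voxels_cutoff": self.config.n_voxels_cutoff,
                "classifier": self.config.classifier,
                "problem": list(self.config.problem),
                "tie_break": self.config.tie_break,
            },
        }


def two_sample_tstat(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample T per voxel (column).

    Degenerate voxels follow a deterministic convention: zero pooled
    variance with zero mean difference gives T = 0 (no signal); zero pooled
    variance with a nonzero difference gives +/-inf (perfect separation).
    """
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    na, nb = Xa.shape[0], Xb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per condition for a two-sample T")
    diff = Xa.mean(axis=0) - Xb.mean(axis=0)
    sp2 = ((na - 1) * Xa.var(axis=0, ddof=1) + (nb - 1) * Xb.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero_var = denom == 0
    t[zero_var & (diff == 0)] = 0.0
    t[zero_var & (diff > 0)] = np.inf
    t[zero_var & (diff < 0)] = -np.inf
    return t


def _rank_descending(score: np.ndarray, cutoff: int) -> np.ndarray:
    """Indices of the top-``cutoff`` scores; ties broken by lowest index."""
    order = np.argsort(-score, kind="stable")
    return order[: min(cutoff, len(order))]


def tstat_rank_voxels(
    train: SampleSet, cond_a: str, cond_b: str, cutoff: int
) -> np.ndarray:
    """Select the ``cutoff`` voxels with the largest |T| between two conditions.

    The sign of T is ignored: a voxel strongly preferring either condition
    is equally discriminative.  Ranking uses the supplied (training) samples
    only; if fewer voxels than ``cutoff`` exist, all are returned.
    """
    labels = train.labels
    Xa = train.X[labels == cond_a]
    Xb = train.X[labels == cond_b]
    if len(Xa) == 0 or len(Xb) == 0:
        raise ValueError(f"condition absent from training set: {cond_a!r}/{cond_b!r}")
    t = two_sample_tstat(Xa, Xb)
    return _rank_descending(np.abs(t), cutoff)


def select_responsive_voxels(samples: SampleSet | np.ndarray, cutoff: int) -> np.ndarray:
    """Select the voxels with the largest mean response across samples.

    Samples are assumed to be in z-units relative to the run baseline, so a
    large positive mean marks a visually responsive voxel.  Clamps to the
    available voxel count.
    """
    X = samples.X if isinstance(samples, SampleSet) else np.atleast_2d(samples)
    return _rank_descending(X.mean(axis=0), cutoff)


def build_templates(
    train: SampleSet, selected: np.ndarray, conditions: Sequence[str]
) -> dict[str, np.ndarray]:
    """Mean training pattern per condition, restricted to selected voxels."""
    labels = train.labels
    out = {}
    for cond in conditions:
        Xc = train.X[labels == cond]
        if len(Xc) == 0:
            raise ValueError(f"no training samples for condition {cond!r}")
        out[cond] = Xc.mean(axis=0)[selected]
    return out


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    du = u - u.mean()
    dv = v - v.mean()
    denom = np.sqrt((du @ du) * (dv @ dv))
    if denom == 0:
        return np.nan
    return float((du @ dv) / denom)


def classify_correlation(
    test_values: np.ndarray, templates: dict[str, np.ndarray], tie_break: str = "first"
) -> tuple[str, bool]:
    """Assign a test pattern to the template with the larger Pearson r.

    Returns (predicted condition, tie flag).  Correlating after subtracting
    each vector's mean makes the decision invariant to adding a constant or
    positively rescaling the test sample.  A zero-variance test pattern (or
    an exact correlation tie) cannot be resolved by correlation; the
    tie-break rule picks the first condition in canonical order and the
    tie flag is set.
    """
    conds = list(templates)
    rs = np.array([_pearson(np.asarray(test_values), templates[c]) for c in conds])
    if np.all(np.isnan(rs)):
        return conds[0], True
    rs = np.where(np.isnan(rs), -np.inf, rs)
    best = np.max(rs)
    winners = np.flatnonzero(rs == best)
    return conds[winners[0]], len(winners) > 1


def classify_univariate(
    test_values: np.ndarray | float,
    templates: dict[str, np.ndarray | float],
    tie_break: str = "first",
) -> tuple[str, bool]:
    """Assign by mean signal: nearest scalar template wins.

    Test sample and templates are reduced to their mean across voxels; the
    condition with the smaller absolute difference is predicted.  Exact
    midpoints invoke the tie-break rule and set the tie flag.
    """
    t = float(np.mean(test_values))
    conds = list(templates)
    dists = np.array([abs(t - float(np.mean(templates[c]))) for c in conds])
    best = np.min(dists)
    winners = np.flatnonzero(dists == best)
    return conds[winners[0]], len(winners) > 1


def loro_cv(
    samples: SampleSet,
    config: DecodingConfig,
    labels_override: np.ndarray | None = None,
) -> DecodingResult:
    """Leave-one-run-out cross-validated decoding of one binary problem.

    For each fold, samples from all runs but one form the training set used
    for voxel selection (T-statistic ranking for the pattern classifier,
    responsiveness ranking for the univariate one) and for the condition
    templates; the held-out run's samples are then classified.

    ``labels_override`` substitutes the per-sample condition labels without
    touching the data — the hook used by permutation inference.
    """
    labels = samples.labels if labels_override is None else np.asarray(
        labels_override, dtype=object
    )
    if len(labels) != samples.n_samples:
        raise ValueError("label override length mismatch")
    cond_a, cond_b = config.problem
    keep = (labels == cond_a) | (labels == cond_b)
    X = samples.X[keep]
    lab = labels[keep]
    run = samples.run[keep]

    runs = np.unique(run)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    for r in runs:
        for c in config.problem:
            if not np.any((run == r) & (lab == c)):
                raise ValueError(f"run {r} has no sample for condition {c!r}")

    univariate = config.classifier == "univariate_difference"
    fold_acc = np.empty(len(runs))
    selected_per_fold = []
    n_ties = 0
    for i, r in enumerate(runs):
        train_mask = run != r
        train = _LabelledSamples(X[train_mask], lab[train_mask], run[train_mask])
        if univariate:
            sel = select_responsive_voxels(train.X, config.n_voxels_cutoff)
        else:
            sel = tstat_rank_voxels(train, cond_a, cond_b, config.n_voxels_cutoff)
        templates = build_templates(train, sel, config.problem)
        if univariate:
            templates = {c: float(np.mean(v)) for c, v in templates.items()}

        test_idx = np.flatnonzero(~train_mask)
        if len(test_idx) == 0:
            raise ValueError(f"empty test set for run {r}")
        correct = 0
        for j in test_idx:
            vec = X[j, sel]
            if univariate:
                pred, tie = classify_univariate(vec, templates, config.tie_break)
            else:
                pred, tie = classify_correlation(vec, templates, config.tie_break)
            n_ties += tie
            correct += pred == lab[j]
        fold_acc[i] = correct / len(test_idx)
        selected_per_fold.append(sel)

    return DecodingResult(
        fold_accuracies=fold_acc,
        accuracy=float(fold_acc.mean()),
        selected_voxels_per_fold=selected_per_fold,
        fold_runs=runs,
        n_ties=n_ties,
        config=config,
    )


class _LabelledSamples:
    """Minimal SampleSet stand-in with explicit labels (internal to CV)."""

    def __init__(self, X, labels, run):
        self.X = X
        self._labels = labels
        self.run = run

    @property
    def labels(self):
        return self._labels

    @property
    def n_samples(self):
        return self.X.shape[0]
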