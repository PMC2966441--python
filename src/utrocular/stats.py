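"""Inference layer: permutation tests for decoding, Bonferroni correction,
and the analytic t / correlation tests used for group summaries.

The permutation test asks whether a cross-validated decoding accuracy
exceeds chance: under the null hypothesis that the two conditions are
exchangeable, their labels are flipped independently within each run and
the full decoding pipeline — training-only voxel selection, template
construction, leave-one-run-out cross-validation — is re-run on every
permuted labelling.  The p-value uses the add-one estimator
p = (1 + #{null >= observed}) / (1 + n_permutations), which is never zero
and is exact for Monte-Carlo tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import t as t_dist

from .decoding import DecodingConfig, loro_cv
from .samples import SampleSet


@dataclass
class TestResult:
    """Analytic test outcome: statistic, degrees of freedom, two-tailed p."""

    statistic: float
    df: int
    p_two_tailed: float
    kind: str = "t"
    r: float | None = None


@dataclass
class PermutationTestResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_permutations: int
    corrected_p: float
    family_size: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_accuracy": float(self.observed_accuracy),
            "p_value": float(self.p_value),
            "corrected_p": float(self.corrected_p),
            "n_permutations": int(self.n_permutations),
            "family_size": int(self.family_size),
            "seed": int(self.seed),
        }


def t_pvalue(t: float, df: int) -> float:
    """Two-tailed p-value of a Student-t statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * t_dist.sf(abs(t), df))


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> TestResult:
    """One-sample t-test of the mean against ``mu0`` (sample-SD convention)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; t undefined")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    return TestResult(statistic=float(t), df=n - 1, p_two_tailed=t_pvalue(t, n - 1))


def paired_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Paired t-test: one-sample t on the element-wise differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def pearson_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with its exact t-based two-tailed p-value.

    t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.  A
    perfect correlation makes the statistic unbounded; the p-value is then
    reported at the numerical floor rather than exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input; correlation undefined")
    dx = x - x.mean()
    dy = y - y.mean()
    r = float((dx @ dy) / np.sqrt((dx @ dx) * (dy @ dy)))
    r = float(np.clip(r, -1.0, 1.0))
    denom = max(1.0 - r * r, 1e-300)
    t = r * np.sqrt((n - 2) / denom)
    return TestResult(
        statistic=float(t), df=n - 2, p_two_tailed=t_pvalue(t, n - 2), kind="r", r=r
    )


def bonferroni(p_values, family_size: int):
    """Multiply each p-value by the family size, clipping at 1."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    p = np.asarray(p_values, dtype=float)
    out = np.minimum(1.0, p * family_size)
    return float(out) if out.ndim == 0 else out


def permute_labels_within_runs(
    labels: np.ndarray, run: np.ndarray, problem: tuple[str, str], rng
) -> np.ndarray:
    """Flip the two problem labels within each run, independently at random.

    Samples of other conditions are untouched.  This respects the run
    structure that the cross-validation folds are built on: under the null,
    the two conditions are exchangeable within a run.
    """
    cond_a, cond_b = problem
    out = labels.copy()
    for r in np.unique(run):
        if rng.integers(2):
            in_run = run == r
            a_mask = in_run & (labels == cond_a)
            b_mask = in_run & (labels == cond_b)
            out[a_mask] = cond_b
            out[b_mask] = cond_a
    return out


def permutation_test(
    samples: SampleSet,
    config: DecodingConfig,
    n_permutations: int = 1000,
    seed: int = 0,
    family_size: int = 3,
) -> PermutationTestResult:
    """Permutation test of above-chance leave-one-run-out decoding accuracy.

    Re-runs the complete pipeline (voxel selection, templates, CV) for every
    within-run label flip; ``family_size`` applies a Bonferroni correction
    for the number of simultaneous tests (default 3, one per ROI).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99 to resolve p < 0.05")
    labels = samples.labels
    keep = (labels == config.problem[0]) | (labels == config.problem[1])
    if len(np.unique(samples.run[keep])) < 2:
        raise ValueError("degenerate permutation space: need at least 2 runs")

    observed = loro_cv(samples, config).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = permute_labels_within_runs(labels, samples.run, config.problem, rng)
        null[i] = loro_cv(samples, config, labels_override=perm).accuracy
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_permutations)
    return PermutationTestResult(
        observed_accuracy=observed,
        null_accuracies=null,
        p_value=float(p),
        n_permutations=n_permutations,
        corrected_p=bonferroni(p, family_size),
        family_size=family_size,
        seed=seed,
    )
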