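"""Behavioral analysis of utrocular-discrimination sessions.

Observers judge which eye (left or right) received a brief monocular
stimulus.  Beyond raw accuracy, performance is summarized with
equal-variance signal detection theory, treating "dominant eye stimulated"
as the signal class: sensitivity d' = z(hit rate) - z(false-alarm rate) and
response criterion c = -(z(hit) + z(fa)) / 2, where z is the inverse
standard-normal CDF.  Positive c means the observer is conservative about
reporting the dominant eye.

Extreme hit/false-alarm rates (0 or 1) would make z infinite, so the
log-linear correction is applied throughout: 0.5 is added to each cell
count and 1 to each denominator.  The correction is always applied; results
flag the sessions where it actually mattered (a raw rate of exactly 0 or 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

EYES = ("L", "R")
SFS = ("low", "high")


@dataclass
class BehavioralSession:
    """Trial-level records of one utrocular-discrimination session."""

    stimulus_eye: np.ndarray
    sf: np.ndarray
    response_eye: np.ndarray
    dominant_eye: str = "L"
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        self.stimulus_eye = np.asarray(self.stimulus_eye, dtype=object)
        self.sf = np.asarray(self.sf, dtype=object)
        self.response_eye = np.asarray(self.response_eye, dtype=object)
        n = len(self.stimulus_eye)
        if n == 0:
            raise ValueError("session has no trials")
        if not (len(self.sf) == len(self.response_eye) == n):
            raise ValueError("trial arrays must have equal length")
        for arr, valid in (
            (self.stimulus_eye, EYES),
            (self.response_eye, EYES),
            (self.sf, SFS),
        ):
            bad = set(arr) - set(valid)
            if bad:
                raise ValueError(f"invalid tokens {bad}; expected {valid}")
        if self.dominant_eye not in EYES:
            raise ValueError(f"invalid dominant eye {self.dominant_eye!r}")

    @property
    def n_trials(self) -> int:
        return len(self.stimulus_eye)

    @property
    def correct(self) -> np.ndarray:
        return self.response_eye == self.stimulus_eye

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "stimulus_eye": self.stimulus_eye,
                "sf": self.sf,
                "response_eye": self.response_eye,
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, dominant_eye: str = "L", subject_id: str = "s0"
    ) -> "BehavioralSession":
        return cls(
            stimulus_eye=df["stimulus_eye"].to_numpy(),
            sf=df["sf"].to_numpy(),
            response_eye=df["response_eye"].to_numpy(),
            dominant_eye=dominant_eye,
            subject_id=subject_id,
        )


@dataclass
class SDTResult:
    """Signal-detection summary for one spatial frequency."""

    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    correction_applied: bool
    n_signal: int
    n_noise: int


def accuracy_by_sf(session: BehavioralSession) -> dict[str, float]:
    """Proportion of trials with response_eye == stimulus_eye, per sf level.

    A spatial-frequency level with no trials is omitted with a warning.
    """
    out: dict[str, float] = {}
    correct = session.correct
    for sf_level in SFS:
        mask = session.sf == sf_level
        if not mask.any():
            warnings.warn(f"no trials at sf={sf_level!r}; omitted from accuracy map")
            continue
        out[sf_level] = float(correct[mask].mean())
    return out


def dprime_criterion(hit_rate: float, fa_rate: float) -> tuple[float, float]:
    """d' and criterion from (already corrected) hit and false-alarm rates."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must lie strictly inside (0, 1); apply a correction")
    zh = norm.ppf(hit_rate)
    zf = norm.ppf(fa_rate)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def sdt_analysis(session: BehavioralSession, sf: str) -> SDTResult:
    """Equal-variance SDT analysis for one spatial frequency.

    Signal trials are those stimulating the dominant eye; a hit is
    responding "dominant" on a signal trial, a false alarm is responding
    "dominant" on a non-dominant-eye trial.  The log-linear correction
    (+0.5 per cell, +1 per denominator) is always applied;
    ``correction_applied`` is True when a raw rate was exactly 0 or 1.
    """
    if sf not in SFS:
        raise ValueError(f"unknown sf token {sf!r}")
    mask = session.sf == sf
    stim = session.stimulus_eye[mask]
    resp = session.response_eye[mask]
    is_signal = stim == session.dominant_eye
    say_dom = resp == session.dominant_eye

    n_signal = int(is_signal.sum())
    n_noise = int((~is_signal).sum())
    if n_signal == 0 or n_noise == 0:
        raise ValueError(
            f"sf={sf!r} needs at least one dominant-eye and one non-dominant-eye trial"
        )
    hits = int((say_dom & is_signal).sum())
    fas = int((say_dom & ~is_signal).sum())

    raw_extreme = hits in (0, n_signal) or fas in (0, n_noise)
    hit_rate = (hits + 0.5) / (n_signal + 1)
    fa_rate = (fas + 0.5) / (n_noise + 1)
    d, c = dprime_criterion(hit_rate, fa_rate)
    return SDTResult(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        dprime=d,
        criterion=c,
        correction_applied=raw_extreme,
        n_signal=n_signal,
        n_noise=n_noise,
    )


def recover_generative_sdt(
    sessions: Iterable[BehavioralSession],
) -> dict[str, dict[str, float]]:
    """Aggregate SDT estimates across simulated sessions.

    Returns, per spatial frequency, the mean and SD (across sessions) of the
    estimated d' and criterion — the parameter-recovery summary used to
    check the behavioral generator against its own generative model.
    """
    per_sf: dict[str, dict[str, list[float]]] = {
        s: {"dprime": [], "criterion": []} for s in SFS
    }
    n = 0
    for session in sessions:
        n += 1
        for s in SFS:
            res = sdt_analysis(session, s)
            per_sf[s]["dprime"].append(res.dprime)
            per_sf[s]["criterion"].append(res.criterion)
    if n == 0:
        raise ValueError("no sessions supplied")
    out: dict[str, dict[str, float]] = {}
    for s in SFS:
        d = np.asarray(per_sf[s]["dprime"])
        c = np.asarray(per_sf[s]["criterion"])
        out[s] = {
            "dprime_mean": float(d.mean()),
            "dprime_sd": float(d.std(ddof=1)) if n > 1 else 0.0,
            "criterion_mean": float(c.mean()),
            "criterion_sd": float(c.std(ddof=1)) if n > 1 else 0.0,
            "n_sessions": n,
        }
    return out
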