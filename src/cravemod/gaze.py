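"""Pavlovian sign-tracking analysis.

The gaze index of a conditioning trial is the proportion of fixation time
on the conditioned-stimulus (CS) location minus the proportion on the
outcome (US) location during the last second of cue presentation, both
normalised by the full analysis window.  Regressing the gaze index on the
CS reward value (in CHF) within a subject yields the sign-tracking slope:
larger slopes mean stronger orienting toward reward-predictive cues
(sign-tracking); smaller or negative slopes mean goal-tracking.

Validity of the preceding conditioning is checked with the forced-choice
task: subjects whose error rate exceeds 10% (strictly) are flagged for
exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError


@dataclass(frozen=True)
class GazeTrialSummary:
    """Per-trial AOI-resolved fixation times (ms) within the analysis window."""

    t_cs_ms: float
    t_us_ms: float
    t_background_ms: float
    cs_value: float            # CHF, in {-2, -1, 0, +1, +2}
    window_ms: float = 1000.0

    def __post_init__(self):
        times = (self.t_cs_ms, self.t_us_ms, self.t_background_ms)
        if any(t < 0 for t in times):
            raise DataError("fixation times must be >= 0")
        if sum(times) > self.window_ms + 1e-9:
            raise DataError("fixation times exceed the analysis window")


@dataclass(frozen=True)
class SignTrackingResult:
    slope: float               # gaze-index units per CHF
    intercept: float
    se: float
    n_trials: int


def gaze_index(trial: GazeTrialSummary) -> float:
    """(CS time - US time) / window length; dimensionless, in [-1, 1]."""
    return (trial.t_cs_ms - trial.t_us_ms) / trial.window_ms


def sign_tracking_slope(trials) -> SignTrackingResult:
    """Ordinary least squares of gaze index on CS value for one subject.

    ``trials`` is an iterable of :class:`GazeTrialSummary` or a DataFrame
    with columns ``t_cs_ms, t_us_ms, t_background_ms, cs_value`` (and an
    optional ``window_ms``).
    """
    if isinstance(trials, pd.DataFrame):
        window = trials["window_ms"] if "window_ms" in trials.columns else 1000.0
        trials = [
            GazeTrialSummary(r.t_cs_ms, r.t_us_ms, r.t_background_ms, r.cs_value,
                             float(w))
            for r, w in zip(trials.itertuples(), np.broadcast_to(window, len(trials)))
        ]
    trials = list(trials)
    values = np.array([t.cs_value for t in trials], dtype=float)
    if len(np.unique(values)) < 2:
        raise DataError("sign-tracking regression needs >= 2 distinct CS values")
    y = np.array([gaze_index(t) for t in trials])
    res = sps.linregress(values, y)
    return SignTrackingResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se=float(res.stderr),
        n_trials=len(trials),
    )


@dataclass(frozen=True)
class ForcedChoiceResult:
    error_rate: float
    n_valid: int
    exclude: bool


def forced_choice_exclusion(choices: pd.DataFrame, threshold: float = 0.10) -> ForcedChoiceResult:
    """Error rate on the forced-choice task and the exclusion flag.

    ``choices`` needs columns ``value_a``, ``value_b`` (the CHF values of
    the two presented CSs) and ``choice`` ("a" or "b").  Pairs with equal
    values have no correct answer and are excluded from the denominator
    with a warning.  The flag is strict: exclusion requires an error rate
    strictly above ``threshold``.
    """
    for col in ("value_a", "value_b", "choice"):
        if col not in choices.columns:
            raise DataError(f"forced-choice table missing column {col!r}")
    if len(choices) != 30:
        warnings.warn(f"expected 30 forced-choice trials, got {len(choices)}")
    ties = choices["value_a"] == choices["value_b"]
    if ties.any():
        warnings.warn(f"{int(ties.sum())} equal-value pair(s) excluded from the error rate")
    valid = choices[~ties]
    if len(valid) == 0:
        raise DataError("no valid forced-choice pairs")
    correct_side = np.where(valid["value_a"] > valid["value_b"], "a", "b")
    errors = (valid["choice"].to_numpy() != correct_side).sum()
    rate = errors / len(valid)
    return ForcedChoiceResult(float(rate), int(len(valid)), bool(rate > threshold))
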