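"""Synthetic Pavlovian fixation records with a gaze index linear in CS value.

Each subject receives a true sign-tracking slope drawn from a configurable
distribution; per-trial gaze indices are ``slope * cs_value + noise`` and
are converted into CS/US/background fixation times within the 1000 ms
analysis window (the last second of cue presentation).  Proportions are
kept valid — clipping, when noise would push them outside [0, 1], is
logged as a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigError
from .tasks import TaskConfig, build_session


@dataclass(frozen=True)
class GazeEffectSpec:
    slope_mean: float = 0.05       # gaze-index units per CHF
    slope_sd: float = 0.03         # between-subject slope SD
    noise_sd: float = 0.10         # per-trial gaze-index noise
    total_aoi_prop: float = 0.8    # CS + US fixation share of the window
    window_ms: float = 1000.0
    n_trials: int = 80

    def __post_init__(self):
        if self.noise_sd < 0 or self.slope_sd < 0:
            raise ConfigError("noise scales must be >= 0")
        if not 0 < self.total_aoi_prop <= 1:
            raise ConfigError("total_aoi_prop must lie in (0, 1]")


def simulate_gaze_dataset(
    n_subjects: int,
    spec: GazeEffectSpec | None = None,
    seed: int = 0,
    true_slopes: np.ndarray | None = None,
):
    """Simulate per-trial AOI fixation summaries for ``n_subjects``.

    Returns ``(table, truth)``; the table has one row per trial with
    columns ``subject, trial_index, cs_value, t_cs_ms, t_us_ms,
    t_background_ms, window_ms`` and ``truth`` carries each subject's
    generating slope.
    """
    spec = spec or GazeEffectSpec()
    rng = np.random.default_rng(seed)
    if true_slopes is None:
        true_slopes = rng.normal(spec.slope_mean, spec.slope_sd, n_subjects)
    true_slopes = np.asarray(true_slopes, dtype=float)
    if true_slopes.shape != (n_subjects,):
        raise ConfigError("true_slopes must have one value per subject")

    rows = []
    n_clipped = 0
    for i in range(n_subjects):
        session = build_session(
            TaskConfig("pavlovian", seed=int(rng.integers(2**31)),
                       params={"n_trials": spec.n_trials})
        )
        values = session["cs_value"].to_numpy(dtype=float)
        idx = true_slopes[i] * values + rng.normal(0.0, spec.noise_sd, len(values))
        # invert: t_cs - t_us = idx * window, t_cs + t_us = total_aoi * window
        p_cs = (spec.total_aoi_prop + idx) / 2.0
        p_us = (spec.total_aoi_prop - idx) / 2.0
        bad = (p_cs < 0) | (p_cs > 1) | (p_us < 0) | (p_us > 1) | (p_cs + p_us > 1)
        if bad.any():
            n_clipped += int(bad.sum())
            p_cs = np.clip(p_cs, 0.0, 1.0)
            p_us = np.clip(p_us, 0.0, 1.0)
            over = p_cs + p_us
            scale = np.where(over > 1.0, 1.0 / over, 1.0)
            p_cs, p_us = p_cs * scale, p_us * scale
        t_cs = p_cs * spec.window_ms
        t_us = p_us * spec.window_ms
        t_bg = spec.window_ms - t_cs - t_us
        for t, v in enumerate(values):
            rows.append((i, t, v, t_cs[t], t_us[t], t_bg[t], spec.window_ms))
    if n_clipped:
        warnings.warn(f"{n_clipped} trial(s) clipped to keep proportions valid")

    table = pd.DataFrame(
        rows,
        columns=["subject", "trial_index", "cs_value", "t_cs_ms", "t_us_ms",
                 "t_background_ms", "window_ms"],
    )
    truth = {"true_slopes": true_slopes, "spec": spec, "seed": seed,
             "n_clipped": n_clipped}
    return table, truth


def simulate_forced_choice(
    error_rate: float = 0.0, seed: int = 0, n_repeats: int = 3
) -> pd.DataFrame:
    """Forced-choice responses with a configured error probability.

    Builds the full pair enumeration (each unordered CS pair repeated
    ``n_repeats`` times) and chooses the higher-valued CS, flipping each
    response to an error with probability ``error_rate``.
    """
    rng = np.random.default_rng(seed)
    session = build_session(TaskConfig("forced_choice", seed=seed,
                                       params={"n_repeats": n_repeats}))
    correct = np.where(session["value_a"] > session["value_b"], "a", "b")
    flip = rng.random(len(session)) < error_rate
    wrong = np.where(correct == "a", "b", "a")
    session = session.copy()
    session["choice"] = np.where(flip, wrong, correct)
    return session
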