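"""Synthetic behavioural datasets: explicit-liking ratings, SRC reaction
times, and Go/NoGo performance summaries with known ground truth.

The rating generator injects a devaluation effect as the session x category
interaction contrast of the four cell means, parameterised directly by its
within-subject Cohen's d (contrast mean over contrast SD), so recovery and
power behave as designed by construction.  Baseline liking matches the
cohort it emulates (mean 69.1, SD 14.0 on the 0-100 analogue scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigError

SESSIONS = ("pre", "post")
CATEGORIES = ("go", "nogo")


@dataclass(frozen=True)
class BehavEffectSpec:
    """Ground-truth effects for the behavioural simulator.

    ``devaluation_d`` is the within-subject Cohen's d of the interaction
    contrast (pre - post difference larger for NoGo than Go items);
    ``wanting_effect_ms`` plays the same role for implicit wanting.
    """

    baseline_liking_mean: float = 69.1
    baseline_liking_sd: float = 14.0
    session_drop: float = 5.0          # general pre->post liking drop (both categories)
    devaluation_d: float = 0.8         # interaction effect size (Cohen's d)
    cell_noise_sd: float = 5.0         # per-cell within-subject noise (rating points)
    item_noise_sd: float = 8.0         # item-level rating noise
    n_items_per_category: int = 17
    rating_rt_median_ms: float = 1500.0
    fast_rating_rate: float = 0.02     # ratings filled faster than 300 ms
    wanting_effect_ms: float = 0.0     # IW interaction contrast (ms); 0 = null
    src_rt_median_ms: float = 650.0
    src_rt_sigma: float = 0.25         # lognormal shape of SRC RTs
    src_trials_per_cell: int = 50
    fast_src_rate: float = 0.02        # SRC trials faster than 200 ms
    fa_rate_mean: float = 0.10
    miss_rate_mean: float = 0.05

    def __post_init__(self):
        for name in ("cell_noise_sd", "item_noise_sd", "baseline_liking_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("fast_rating_rate", "fast_src_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")


def _cell_means(spec: BehavEffectSpec, rng, n_subjects: int,
                subject_devaluation: np.ndarray) -> np.ndarray:
    """(n_subjects, 4) liking cell means in order pre_go, pre_nogo,
    post_go, post_nogo."""
    base = rng.normal(spec.baseline_liking_mean, spec.baseline_liking_sd, n_subjects)
    cells = np.tile(base[:, None], (1, 4))
    cells[:, 2:] -= spec.session_drop
    # interaction contrast (pre_go - pre_nogo - post_go + post_nogo) = -delta
    cells[:, 3] -= subject_devaluation
    cells += rng.normal(0.0, spec.cell_noise_sd, size=cells.shape)
    return cells


def simulate_behavioural_dataset(
    n_subjects: int,
    spec: BehavEffectSpec | None = None,
    seed: int = 0,
    subject_devaluation: np.ndarray | None = None,
):
    """Simulate rating, SRC and Go/NoGo performance tables.

    ``subject_devaluation`` optionally fixes each subject's extra NoGo
    post-training liking drop (rating points); by default it is constant at
    ``devaluation_d * 2 * cell_noise_sd`` so the interaction contrast has
    the requested within-subject Cohen's d.

    Returns ``(tables, truth)`` with ``tables`` holding ``ratings``,
    ``src`` and ``gng_performance`` DataFrames.
    """
    spec = spec or BehavEffectSpec()
    rng = np.random.default_rng(seed)
    if subject_devaluation is None:
        delta = spec.devaluation_d * 2.0 * spec.cell_noise_sd
        subject_devaluation = np.full(n_subjects, delta)
    subject_devaluation = np.asarray(subject_devaluation, dtype=float)
    if subject_devaluation.shape != (n_subjects,):
        raise ConfigError("subject_devaluation must have one value per subject")

    cells = _cell_means(spec, rng, n_subjects, subject_devaluation)

    cell_labels = [(s, c) for s in SESSIONS for c in CATEGORIES]
    rating_rows = []
    for i in range(n_subjects):
        for j, (sess, cat) in enumerate(cell_labels):
            n_items = spec.n_items_per_category
            ratings = np.clip(
                rng.normal(cells[i, j], spec.item_noise_sd, n_items), 0, 100
            )
            rt = rng.lognormal(np.log(spec.rating_rt_median_ms), 0.4, n_items)
            fast = rng.random(n_items) < spec.fast_rating_rate
            rt[fast] = rng.uniform(50, 299, fast.sum())
            for item in range(n_items):
                rating_rows.append(
                    (i, f"{cat}_{item}", sess, cat, ratings[item], rt[item])
                )
    ratings = pd.DataFrame(
        rating_rows, columns=["subject", "item", "session", "category", "rating", "rt_ms"]
    )

    src_rows = []
    iw_base = rng.normal(30.0, 40.0, n_subjects)     # stable per-subject wanting
    for i in range(n_subjects):
        for sess in SESSIONS:
            for cat in CATEGORIES:
                iw = iw_base[i]
                if sess == "post" and cat == "nogo":
                    iw -= spec.wanting_effect_ms
                for direction in ("away", "toward"):
                    n = spec.src_trials_per_cell
                    mu = spec.src_rt_median_ms + (iw / 2 if direction == "away" else -iw / 2)
                    rt = rng.lognormal(np.log(max(mu, 250.0)), spec.src_rt_sigma, n)
                    fast = rng.random(n) < spec.fast_src_rate
                    rt[fast] = rng.uniform(50, 199, fast.sum())
                    for v in rt:
                        src_rows.append((i, sess, cat, direction, v))
    src = pd.DataFrame(
        src_rows, columns=["subject", "session", "category", "direction", "rt_ms"]
    )

    perf_rows = []
    for i in range(n_subjects):
        for sess in SESSIONS:
            fa = float(np.clip(rng.beta(2, 2 / spec.fa_rate_mean - 2), 0, 1))
            miss = float(np.clip(rng.beta(2, 2 / spec.miss_rate_mean - 2), 0, 1))
            perf_rows.append((i, sess, fa, miss))
    perf = pd.DataFrame(perf_rows, columns=["subject", "session", "fa_rate", "miss_rate"])

    truth = {
        "cell_means": cells,
        "subject_devaluation": subject_devaluation,
        "devaluation_d": spec.devaluation_d,
        "wanting_effect_ms": spec.wanting_effect_ms,
        "fast_rating_rate": spec.fast_rating_rate,
        "fast_src_rate": spec.fast_src_rate,
        "seed": seed,
    }
    return {"ratings": ratings, "src": src, "gng_performance": perf}, truth
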