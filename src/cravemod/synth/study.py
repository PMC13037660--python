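"""Cohort-level study simulator.

Draws per-subject learning traits (sign-tracking slope, model-based weight
w), couples them to the training-induced devaluation through configurable
moderation slopes, and emits every table the analysis pipeline consumes:
explicit-liking ratings, SRC reaction times, Go/NoGo performance,
Pavlovian fixation records, forced-choice responses, two-step choice
sequences, and (optionally) ERP epochs.  All ground truth is returned in a
sidecar dictionary so end-to-end recovery can be verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigError
from .behaviour import BehavEffectSpec, simulate_behavioural_dataset
from .eeg import EegEffectSpec, default_components, simulate_eeg_dataset
from .gazegen import GazeEffectSpec, simulate_forced_choice, simulate_gaze_dataset


@dataclass(frozen=True)
class StudyEffects:
    """Ground-truth configuration of one simulated study cohort."""

    n_subjects: int = 56
    n_subjects_eeg: int = 16
    behav: BehavEffectSpec = field(default_factory=BehavEffectSpec)
    gaze: GazeEffectSpec = field(default_factory=GazeEffectSpec)
    eeg: EegEffectSpec | None = None
    n2_interaction_uv: float = 0.0     # session x category contrast on N2
    moderation_beta_sign: float = 0.0  # liking-delta points per slope unit
    moderation_beta_w: float = 0.0     # liking-delta points per unit w
    devaluation_noise_sd: float = 2.0  # between-subject devaluation SD (points)
    forced_choice_error_rate: float = 0.02
    two_step_trials: int = 201
    simulate_eeg: bool = True

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ConfigError("n_subjects must be at least 4")
        if self.devaluation_noise_sd < 0:
            raise ConfigError("devaluation_noise_sd must be >= 0")


def simulate_study(effects: StudyEffects, seed: int = 0) -> dict:
    """Simulate one full pre/post cohort.

    Returns a bundle with keys ``ratings``, ``src``, ``gng_performance``,
    ``gaze``, ``forced_choice`` (per-subject list), ``two_step``
    (per-subject trial tables), ``eeg`` (per-subject condition epochs, or
    None), and ``truth``.
    """
    # two-step machinery lives in the rl module; imported here to keep the
    # generators importable on their own
    from ..rl import RLParams, TransitionModel, gaussian_walk, simulate_agent

    rng = np.random.default_rng(seed)
    n = effects.n_subjects

    # per-subject traits
    slopes = rng.normal(effects.gaze.slope_mean, effects.gaze.slope_sd, n)
    w_true = rng.uniform(0.0, 1.0, n)

    # devaluation coupled to traits (moderation ground truth)
    base_delta = effects.behav.devaluation_d * 2.0 * effects.behav.cell_noise_sd
    delta = (
        base_delta
        + effects.moderation_beta_sign * (slopes - slopes.mean())
        + effects.moderation_beta_w * (w_true - w_true.mean())
        + rng.normal(0.0, effects.devaluation_noise_sd, n)
    )

    behav_tables, behav_truth = simulate_behavioural_dataset(
        n, effects.behav, seed=int(rng.integers(2**31)), subject_devaluation=delta
    )
    gaze_table, gaze_truth = simulate_gaze_dataset(
        n, effects.gaze, seed=int(rng.integers(2**31)), true_slopes=slopes
    )
    forced = [
        simulate_forced_choice(effects.forced_choice_error_rate,
                               seed=int(rng.integers(2**31)))
        for _ in range(n)
    ]

    walk = gaussian_walk(effects.two_step_trials, seed=int(rng.integers(2**31)))
    two_step = []
    rl_params = []
    for i in range(n):
        params = RLParams(
            alpha1=float(rng.uniform(0.3, 0.7)),
            alpha2=float(rng.uniform(0.3, 0.7)),
            beta1=5.0,
            beta2=5.0,
            lam=float(rng.uniform(0.3, 0.7)),
            w=float(w_true[i]),
            pi=float(rng.normal(0.0, 0.2)),
        )
        trans = TransitionModel(boat0_to_island1=bool(rng.random() < 0.5))
        two_step.append(
            {
                "trials": simulate_agent(params, walk, trans,
                                         seed=int(rng.integers(2**31))),
                "transition": trans,
            }
        )
        rl_params.append(params)

    eeg_data = eeg_truth = None
    if effects.simulate_eeg:
        eeg_spec = effects.eeg or EegEffectSpec(
            components=default_components(n2_interaction_uv=effects.n2_interaction_uv),
            n_epochs=24,
        )
        eeg_data, eeg_truth = simulate_eeg_dataset(
            effects.n_subjects_eeg, eeg_spec, seed=int(rng.integers(2**31))
        )

    truth = {
        "sign_tracking_slopes": slopes,
        "w": w_true,
        "rl_params": rl_params,
        "subject_devaluation": delta,
        "moderation_beta_sign": effects.moderation_beta_sign,
        "moderation_beta_w": effects.moderation_beta_w,
        "behaviour": behav_truth,
        "gaze": gaze_truth,
        "eeg": eeg_truth,
        "reward_walk": walk,
        "seed": seed,
    }
    return {
        **behav_tables,
        "gaze": gaze_table,
        "forced_choice": forced,
        "two_step": two_step,
        "eeg": eeg_data,
        "truth": truth,
    }
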