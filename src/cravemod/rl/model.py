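"""Hybrid model-free / model-based model of the two-step task.

The seven-parameter hybrid combines SARSA(lambda) model-free values with
model-based values planned through the known first-stage transition
structure (common transitions with probability .7), mixed by the weight
``w`` — the index of model-based (high w) versus model-free (low w)
reliance.  First-stage choices follow a softmax over the mixed values with
inverse temperature ``beta1`` plus a perseveration bonus ``pi`` for
repeating the previous first-stage choice; second-stage choices follow a
softmax over the stage-2 values with ``beta2``.

Reward probabilities of the four second-stage options drift as independent
Gaussian random walks (SD 0.025) reflected at 0.25 and 0.75.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from ..errors import ConfigError, DataError

LN2 = math.log(2.0)


@dataclass(frozen=True)
class RLParams:
    """Parameter vector of the hybrid model."""

    alpha1: float = 0.5   # stage-1 learning rate, [0, 1]
    alpha2: float = 0.5   # stage-2 learning rate, [0, 1]
    beta1: float = 5.0    # stage-1 inverse temperature, >= 0
    beta2: float = 5.0    # stage-2 inverse temperature, >= 0
    lam: float = 0.5      # eligibility trace weight, [0, 1]
    w: float = 0.5        # model-based weight, [0, 1]
    pi: float = 0.0       # stage-1 perseveration (unbounded)

    def __post_init__(self):
        for name in ("alpha1", "alpha2", "lam", "w"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("beta1", "beta2"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for f in fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise ConfigError(f"{f.name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.beta1, self.beta2,
                         self.lam, self.w, self.pi])

    @classmethod
    def from_array(cls, x) -> "RLParams":
        return cls(*[float(v) for v in x])


PARAM_NAMES = tuple(f.name for f in fields(RLParams))


@dataclass(frozen=True)
class TransitionModel:
    """First-stage transition structure: P(island | boat).

    ``common`` is the probability of the frequent transition; boat 0 leads
    to island 0 with that probability (swap via ``boat0_to_island1``).
    """

    common: float = 0.7
    boat0_to_island1: bool = False

    @property
    def matrix(self) -> np.ndarray:
        p = self.common
        m = np.array([[p, 1 - p], [1 - p, p]])
        if self.boat0_to_island1:
            m = m[:, ::-1]
        return m


def gaussian_walk(
    n_trials: int,
    n_options: int = 4,
    sd: float = 0.025,
    bounds: tuple = (0.25, 0.75),
    init=None,
    seed: int = 0,
) -> np.ndarray:
    """Reflected Gaussian random walk of reward probabilities.

    ``p(t+1) = reflect(p(t) + N(0, sd))`` into ``bounds``; ``init`` defaults
    to an independent uniform draw inside the bounds for each option.
    Returns an (n_trials, n_options) array.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ConfigError("bounds must be ordered")
    if sd < 0:
        raise ConfigError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    if init is None:
        init = rng.uniform(lo, hi, n_options)
    init = np.asarray(init, dtype=float)
    if ((init < lo) | (init > hi)).any():
        raise ConfigError("init must lie inside bounds")
    steps = rng.normal(0.0, sd, size=(n_trials - 1, n_options)) if n_trials > 1 else np.empty((0, n_options))
    walk = np.empty((n_trials, n_options))
    walk[0] = init
    period = 2 * (hi - lo)
    for t in range(1, n_trials):
        x = walk[t - 1] + steps[t - 1]
        y = np.mod(x - lo, period)
        walk[t] = lo + np.minimum(y, period - y)
    return walk


@dataclass
class HybridState:
    """Q-values carried across trials (stage-2: islands x monsters)."""

    q2: np.ndarray
    q1mf: np.ndarray
    prev_c1: int = -1

    @classmethod
    def initial(cls, q_init: float = 0.5) -> "HybridState":
        return cls(np.full((2, 2), q_init), np.full(2, q_init), -1)

    def copy(self) -> "HybridState":
        return HybridState(self.q2.copy(), self.q1mf.copy(), self.prev_c1)


def _check_trial(c1, s2, c2, r):
    if c1 not in (0, 1) or s2 not in (0, 1) or c2 not in (0, 1):
        raise DataError(f"invalid trial fields c1={c1}, s2={s2}, c2={c2}")
    if r not in (0, 1, 0.0, 1.0):
        raise DataError(f"reward must be 0 or 1, got {r}")


def hybrid_update(state: HybridState, trial, params: RLParams) -> HybridState:
    """One trial's model-free value update (pure; returns a new state).

    ``trial`` is a ``(c1, s2, c2, r)`` tuple or mapping.  Prediction errors
    use the pre-update stage-2 value: ``d1 = Q2(s2,c2) - Q1MF(c1)`` and
    ``d2 = r - Q2(s2,c2)``; then ``Q2(s2,c2) += alpha2*d2`` and
    ``Q1MF(c1) += alpha1*(d1 + lam*d2)``.  Model-based values are derived
    from Q2 and the transition matrix at choice time, not stored.
    """
    c1, s2, c2, r = _unpack_trial(trial)
    _check_trial(c1, s2, c2, r)
    new = state.copy()
    q2_old = new.q2[s2, c2]
    d2 = r - q2_old
    d1 = q2_old - new.q1mf[c1]
    new.q2[s2, c2] = q2_old + params.alpha2 * d2
    new.q1mf[c1] = new.q1mf[c1] + params.alpha1 * (d1 + params.lam * d2)
    new.prev_c1 = c1
    return new


def _unpack_trial(trial):
    if isinstance(trial, dict):
        return trial["c1"], trial["s2"], trial["c2"], trial["r"]
    return tuple(trial)[:4]


def stage1_values(state: HybridState, params: RLParams, trans: TransitionModel) -> np.ndarray:
    """Net first-stage values: w * model-based + (1 - w) * model-free."""
    qmb = trans.matrix @ state.q2.max(axis=1)
    return params.w * qmb + (1.0 - params.w) * state.q1mf


def stage1_probs(state: HybridState, params: RLParams, trans: TransitionModel) -> np.ndarray:
    qnet = stage1_values(state, params, trans)
    logits = params.beta1 * qnet
    if state.prev_c1 >= 0:
        logits = logits.copy()
        logits[state.prev_c1] += params.pi
    return _softmax(logits)


def stage2_probs(state: HybridState, params: RLParams, s2: int) -> np.ndarray:
    return _softmax(params.beta2 * state.q2[s2])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _trials_to_arrays(trials):
    if isinstance(trials, pd.DataFrame):
        cols = ["c1", "s2", "c2", "r"]
        missing = [c for c in cols if c not in trials.columns]
        if missing:
            raise DataError(f"trials table missing columns {missing}")
        return [tuple(int(v) for v in row) for row in trials[cols].to_numpy()]
    return [tuple(int(v) for v in _unpack_trial(t)) for t in trials]


def negloglik(params: RLParams, trials, trans: TransitionModel | None = None,
              q_init: float = 0.5) -> float:
    """Negative log-likelihood of both stages' choices under the hybrid model.

    The scalar loop is kept in plain floats for speed; it is the package's
    hot path during fitting.
    """
    trans = trans or TransitionModel()
    rows = _trials_to_arrays(trials)
    a1, a2 = params.alpha1, params.alpha2
    b1, b2 = params.beta1, params.beta2
    lam, w, pi = params.lam, params.w, params.pi
    m = trans.matrix
    m00, m01, m10, m11 = m[0, 0], m[0, 1], m[1, 0], m[1, 1]

    q2 = [[q_init, q_init], [q_init, q_init]]
    q1 = [q_init, q_init]
    prev = -1
    nll = 0.0
    for idx, (c1, s2, c2, r) in enumerate(rows):
        if c1 not in (0, 1) or s2 not in (0, 1) or c2 not in (0, 1) or r not in (0, 1):
            raise DataError(f"invalid trial fields at index {idx}")
        v0 = q2[0][0] if q2[0][0] >= q2[0][1] else q2[0][1]
        v1 = q2[1][0] if q2[1][0] >= q2[1][1] else q2[1][1]
        qn0 = w * (m00 * v0 + m01 * v1) + (1 - w) * q1[0]
        qn1 = w * (m10 * v0 + m11 * v1) + (1 - w) * q1[1]
        l0 = b1 * qn0 + (pi if prev == 0 else 0.0)
        l1 = b1 * qn1 + (pi if prev == 1 else 0.0)
        mx = l0 if l0 > l1 else l1
        lse = mx + math.log(math.exp(l0 - mx) + math.exp(l1 - mx))
        nll -= (l0 if c1 == 0 else l1) - lse

        ls0 = b2 * q2[s2][0]
        ls1 = b2 * q2[s2][1]
        mx = ls0 if ls0 > ls1 else ls1
        lse = mx + math.log(math.exp(ls0 - mx) + math.exp(ls1 - mx))
        nll -= (ls0 if c2 == 0 else ls1) - lse

        q2_old = q2[s2][c2]
        d2 = r - q2_old
        d1 = q2_old - q1[c1]
        q2[s2][c2] = q2_old + a2 * d2
        q1[c1] = q1[c1] + a1 * (d1 + lam * d2)
        prev = c1
    if not math.isfinite(nll):
        raise DataError("non-finite negative log-likelihood")
    return nll


def simulate_agent(
    params: RLParams,
    walk: np.ndarray,
    trans: TransitionModel | None = None,
    seed: int = 0,
    blocks=None,
    q_init: float = 0.5,
) -> pd.DataFrame:
    """Generate a two-step session from the hybrid model.

    ``walk`` is an (n_trials, 4) reward-probability array whose columns are
    ordered (island 0 monster 0, island 0 monster 1, island 1 monster 0,
    island 1 monster 1).  Returns a trial table with columns
    ``c1, s2, c2, r, block``.
    """
    trans = trans or TransitionModel()
    rng = np.random.default_rng(seed)
    n = len(walk)
    state = HybridState.initial(q_init)
    m = trans.matrix
    rows = []
    for t in range(n):
        p1 = stage1_probs(state, params, trans)
        c1 = int(rng.random() < p1[1])
        s2 = int(rng.random() < m[c1, 1])
        p2 = stage2_probs(state, params, s2)
        c2 = int(rng.random() < p2[1])
        r = int(rng.random() < walk[t, 2 * s2 + c2])
        rows.append((c1, s2, c2, r))
        state = hybrid_update(state, rows[-1], params)
    df = pd.DataFrame(rows, columns=["c1", "s2", "c2", "r"])
    df["block"] = np.asarray(blocks)[:n] if blocks is not None else 0
    return df
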