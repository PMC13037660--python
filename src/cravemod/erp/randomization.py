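"""Time-frame-wise within-subject randomization statistics.

For a complete 2 (session) x 2 (item category) within design the observed
statistic at each time frame is either

* ``measure="gfp"`` — the within-subject ANOVA F (1, n-1) of the per-subject
  global field power values for the requested effect, or
* ``measure="topography"`` — the global field power of the effect's +/-1
  contrast of the GFP-normalised condition-mean maps (the generalised
  topographic dissimilarity statistic of randomization map analyses).

The null distribution is built by randomly permuting the condition labels
independently within each subject; p-values use the add-one Monte-Carlo
estimator p = (1 + #{perm >= observed}) / (1 + n_perm).  A two-condition
(paired) design is supported for the registered fallback contrast, where
the permutation scheme reduces to per-subject label swaps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigError, DataError

CONDITIONS = ("pre_go", "pre_nogo", "post_go", "post_nogo")

#: +/-1 contrast weights over (pre_go, pre_nogo, post_go, post_nogo)
EFFECT_CONTRASTS = {
    "session": np.array([-1.0, -1.0, 1.0, 1.0]),
    "category": np.array([-1.0, 1.0, -1.0, 1.0]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}


@dataclass
class TfTestResult:
    effect: str
    measure: str
    p: np.ndarray                  # per-TF p-values
    observed: np.ndarray           # per-TF observed statistic
    n_perm: int
    seed: int
    alpha: float = 0.01
    min_run: int = 12
    conditions: tuple = CONDITIONS

    @property
    def significant_runs(self):
        return consecutive_runs(self.p, self.alpha, self.min_run)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tf": np.arange(len(self.p)), "stat": self.observed, "p": self.p})


def _stack(subject_erps, conditions) -> np.ndarray:
    """(n_subjects, n_conditions, n_channels, n_tf) array from SubjectErp set."""
    arrs = []
    for s in subject_erps:
        erps = s.erps if hasattr(s, "erps") else s
        missing = [c for c in conditions if c not in erps]
        if missing:
            raise DataError(f"subject is missing condition cell(s) {missing}")
        arrs.append(np.stack([np.asarray(erps[c], dtype=float) for c in conditions]))
    x = np.stack(arrs)
    if x.ndim != 4:
        raise DataError("ERPs must be channels x time arrays")
    return x


def _within_f(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """F(1, n-1) of the within-subject contrast.

    ``values``: (n_subjects, n_conditions, n_tf); returns per-TF F.
    """
    c = np.tensordot(values, weights, axes=([1], [0]))       # (n_sub, n_tf)
    n = c.shape[0]
    mean = c.mean(axis=0)
    var = c.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = n * mean**2 / var
    return np.where(var > 0, f, np.where(mean == 0, 0.0, np.inf))


def _topo_stat(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """GFP of the contrast of GFP-normalised condition-mean maps.

    ``x``: (n_subjects, n_cond, n_ch, n_tf); returns per-TF statistic.
    """
    m = x.mean(axis=0)                                       # (n_cond, ch, tf)
    m = m - m.mean(axis=1, keepdims=True)
    g = np.std(m, axis=1, keepdims=True)
    m = np.divide(m, g, out=np.zeros_like(m), where=g > 1e-15)
    contrast = np.tensordot(weights, m, axes=([0], [0]))     # (ch, tf)
    return np.std(contrast - contrast.mean(axis=0, keepdims=True), axis=0)


def randomization_anova(
    subject_erps,
    effect: str,
    measure: str = "gfp",
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.01,
    min_run: int = 12,
    conditions: tuple = CONDITIONS,
) -> TfTestResult:
    """Monte-Carlo randomization test at every time frame.

    ``subject_erps`` is a sequence of :class:`~cravemod.erp.containers.SubjectErp`
    (or plain ``{condition: channels x time}`` mappings), all common-average
    referenced.  ``conditions`` may name the four cells of the 2x2 design or
    exactly two cells for a paired (fallback) contrast, in which case
    ``effect`` must be ``"session"``.
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be at least 100")
    if measure not in ("gfp", "topography"):
        raise ConfigError(f"unknown measure {measure!r}")
    conditions = tuple(conditions)
    if len(conditions) == 4:
        if effect not in EFFECT_CONTRASTS:
            raise ConfigError(f"unknown effect {effect!r}")
        weights = EFFECT_CONTRASTS[effect]
    elif len(conditions) == 2:
        if effect != "session":
            raise ConfigError("a two-condition design only supports the paired 'session' contrast")
        weights = np.array([-1.0, 1.0])
    else:
        raise ConfigError("design must have exactly 2 or 4 condition cells")

    x = _stack(subject_erps, conditions)
    n_sub, n_cond, n_ch, n_tf = x.shape
    if n_sub < 2:
        raise DataError("at least 2 subjects are required")

    if measure == "gfp":
        vals = np.std(x - x.mean(axis=2, keepdims=True), axis=2)   # (sub, cond, tf)
        stat = lambda data: _within_f(data, weights)
        base = vals
    else:
        stat = lambda data: _topo_stat(data, weights)
        base = x

    observed = stat(base)

    rng = np.random.default_rng(seed)
    perms = np.array(list(itertools.permutations(range(n_cond))))
    draws = rng.integers(len(perms), size=(n_perm, n_sub))
    count_ge = np.zeros(n_tf, dtype=int)
    sub_idx = np.arange(n_sub)[:, None]
    for p in range(n_perm):
        order = perms[draws[p]]                                    # (n_sub, n_cond)
        perm_stat = stat(base[sub_idx, order])
        count_ge += perm_stat >= observed - 1e-12
    pvals = (1.0 + count_ge) / (1.0 + n_perm)

    return TfTestResult(
        effect=effect,
        measure=measure,
        p=pvals,
        observed=observed,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        min_run=min_run,
        conditions=conditions,
    )


def consecutive_runs(p_series, alpha: float = 0.01, min_len: int = 12):
    """Maximal runs of time frames with p < alpha, kept if length >= min_len.

    Returns a list of ``(onset_tf, offset_tf)`` inclusive index pairs.
    """
    p = np.asarray(p_series, dtype=float)
    if not np.isfinite(p).all():
        raise DataError("p-series contains non-finite values")
    sig = p < alpha
    out = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if i - start >= min_len:
                out.append((start, i - 1))
            start = None
    if start is not None and len(sig) - start >= min_len:
        out.append((start, len(sig) - 1))
    return out


def h1_decision(go_session_results, component_window, alpha: float = 0.01, min_run: int = 12) -> str:
    """Registered fallback logic for the ERP hypothesis.

    If the session (pre vs post) effect on the trained-"Go" items shows a
    qualifying run — at least ``min_run`` consecutive sub-alpha time frames
    on either measure — *within* the component window, the 2x2 interaction
    is replaced by a pre- vs post-training contrast on the "NoGo" items
    only.

    ``go_session_results`` is one :class:`TfTestResult` or an iterable of
    them (e.g. the GFP and topography tests); ``component_window`` is an
    inclusive ``(onset_tf, offset_tf)`` pair on the same time axis.
    """
    a, b = component_window
    if b < a:
        raise DataError("component window is empty")
    if isinstance(go_session_results, TfTestResult):
        go_session_results = [go_session_results]
    for res in go_session_results:
        runs = consecutive_runs(res.p[a : b + 1], alpha, min_run)
        if runs:
            return "nogo_prepost_contrast"
    return "interaction_2x2"
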