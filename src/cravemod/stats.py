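"""Registered behavioural statistics.

Implements the pre-registered filtering and inference chain: reaction-time
and rating-response-time floors, unscaled-MAD distribution-outlier tagging,
implicit wanting (RT away minus RT toward), the adaptive reaction-time
threshold, Go/NoGo performance exclusions, the 2x2 within-subject ANOVA
with partial Cohen's f and Levene / Greenhouse-Geisser reporting, the
BIC-approximated Bayes factor favouring the null, the paired Cohen's d
gate, the moderation regression, and the a-priori power calculator for the
repeated-measures design.

Alpha for behavioural tests defaults to .02 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ConfigError, DataError

ALPHA_BEHAVIOURAL = 0.02

CELL_ORDER = (("pre", "go"), ("pre", "nogo"), ("post", "go"), ("post", "nogo"))


# ---------------------------------------------------------------------------
# filters and flags
# ---------------------------------------------------------------------------


def filter_trials(records: pd.DataFrame, rt_floor_ms: float = 200.0,
                  rt_col: str = "rt_ms"):
    """Remove trials with reaction times strictly below the floor.

    Returns ``(filtered, report)`` where the report counts removals per
    subject (empty input gives an empty report).  Idempotent.
    """
    if rt_col not in records.columns:
        raise DataError(f"records missing RT column {rt_col!r}")
    keep = records[rt_col] >= rt_floor_ms
    if "subject" in records.columns and len(records):
        report = (
            (~keep).groupby(records["subject"]).sum().rename("n_removed").reset_index()
        )
    else:
        report = pd.DataFrame({"subject": [], "n_removed": []})
    return records[keep].reset_index(drop=True), report.assign(floor_ms=rt_floor_ms)


def filter_ratings(records: pd.DataFrame, floor_ms: float = 300.0,
                   rt_col: str = "rt_ms"):
    """Remove rating items filled in strictly less than ``floor_ms``."""
    return filter_trials(records, rt_floor_ms=floor_ms, rt_col=rt_col)


def mad_flags(values, k: float = 2.5) -> np.ndarray:
    """Distribution-outlier flags: |x - median| > k * MAD.

    MAD is the raw (unscaled) median absolute deviation — no 1.4826
    consistency factor.  A zero MAD flags nothing and warns.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DataError("MAD outlier tagging needs at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged")
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - med) > k * mad


def implicit_wanting(src: pd.DataFrame, rt_floor_ms: float = 200.0) -> pd.DataFrame:
    """Implicit wanting per subject x session x category cell (ms).

    IW = mean RT moving away - mean RT moving toward, computed after the
    200 ms trial filter.  Both directions must be present in every cell.
    """
    for col in ("subject", "session", "category", "direction", "rt_ms"):
        if col not in src.columns:
            raise DataError(f"SRC table missing column {col!r}")
    clean, _ = filter_trials(src, rt_floor_ms)
    cells = []
    for (subj, sess, cat), grp in clean.groupby(["subject", "session", "category"]):
        means = grp.groupby("direction")["rt_ms"].mean()
        if "away" not in means or "toward" not in means:
            raise DataError(
                f"cell (subject={subj}, session={sess}, category={cat}) lacks a direction"
            )
        cells.append((subj, sess, cat, float(means["away"] - means["toward"])))
    return pd.DataFrame(cells, columns=["subject", "session", "category", "iw_ms"])


def adaptive_rtt(rts) -> float:
    """Auto-adaptive reaction-time threshold: 1.10 x median RT (ms)."""
    x = np.asarray(rts, dtype=float)
    if x.size == 0:
        raise DataError("adaptive RTT needs at least one RT")
    return 1.10 * float(np.median(x))


def gng_performance_exclusion(fa_rate: float, miss_rate: float,
                              fa_limit: float = 0.70, miss_limit: float = 0.20) -> bool:
    """Flag participants not doing the task: FA > 70% or Miss > 20% (strict)."""
    for r in (fa_rate, miss_rate):
        if not 0.0 <= r <= 1.0:
            raise DataError("rates must lie in [0, 1]")
    return bool(fa_rate > fa_limit or miss_rate > miss_limit)


# ---------------------------------------------------------------------------
# 2x2 within ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    partial_f: float
    levene_stat: float
    levene_p: float
    gg_epsilon: float
    gg_applied: bool
    bf01: float | None = None
    n: int = 0


def _cell_matrix(table: pd.DataFrame, value_col: str) -> np.ndarray:
    """(n_subjects, 4) cell-mean matrix in CELL_ORDER; errors on gaps."""
    for col in ("subject", "session", "category", value_col):
        if col not in table.columns:
            raise DataError(f"table missing column {col!r}")
    wide = table.pivot_table(index="subject", columns=["session", "category"],
                             values=value_col, aggfunc="mean")
    missing = [c for c in CELL_ORDER if c not in wide.columns]
    if missing or wide.isna().any().any():
        bad = missing or wide.columns[wide.isna().any()].tolist()
        raise DataError(f"incomplete design cells: {bad}")
    return wide[list(CELL_ORDER)].to_numpy(), wide.index.to_numpy()


_EFFECT_WEIGHTS = {
    "session": np.array([-1.0, -1.0, 1.0, 1.0]),
    "category": np.array([-1.0, 1.0, -1.0, 1.0]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}


def anova_2x2_within(table: pd.DataFrame, value_col: str = "value",
                     effect: str = "interaction",
                     compute_bf: bool = True) -> AnovaResult:
    """Repeated-measures ANOVA effect for the 2 (session) x 2 (category)
    within design.

    Each 1-df effect F equals the squared one-sample t of the corresponding
    within-subject +/-1 contrast (exact closed form).  Partial Cohen's f is
    sqrt(F * df1 / df2).  Levene's test (median-centred) across the four
    cells checks homoscedasticity; the Greenhouse-Geisser epsilon is
    trivially 1 for two-level factors and reported for transparency.
    """
    if effect not in _EFFECT_WEIGHTS:
        raise ConfigError(f"unknown effect {effect!r}")
    cells, _ = _cell_matrix(table, value_col)
    n = cells.shape[0]
    if n < 2:
        raise DataError("need at least 2 subjects")
    c = cells @ _EFFECT_WEIGHTS[effect]
    var = c.var(ddof=1)
    if var == 0:
        f_stat = 0.0 if c.mean() == 0 else float("inf")
    else:
        f_stat = n * c.mean() ** 2 / var
    df1, df2 = 1, n - 1
    p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    partial_f = float(np.sqrt(f_stat * df1 / df2)) if np.isfinite(f_stat) else float("inf")
    lev_stat, lev_p = sps.levene(*[cells[:, j] for j in range(4)], center="median")
    gg_applied = lev_p < ALPHA_BEHAVIOURAL
    bf01 = _interaction_bf01(cells) if (compute_bf and effect == "interaction") else None
    return AnovaResult(
        effect=effect, F=float(f_stat), df1=df1, df2=df2, p=p,
        partial_f=partial_f, levene_stat=float(lev_stat), levene_p=float(lev_p),
        gg_epsilon=1.0, gg_applied=bool(gg_applied), bf01=bf01, n=n,
    )


def _long_design(cells: np.ndarray):
    n = cells.shape[0]
    y = cells.reshape(-1)
    subj = np.repeat(np.arange(n), 4)
    sess = np.tile([0.0, 0.0, 1.0, 1.0], n)
    cat = np.tile([0.0, 1.0, 0.0, 1.0], n)
    subj_dummies = (subj[:, None] == np.arange(1, n)[None, :]).astype(float)
    base = np.column_stack([np.ones_like(y), subj_dummies, sess, cat])
    return y, base, sess * cat


def _interaction_bf01(cells: np.ndarray) -> float:
    y, base, inter = _long_design(cells)
    with_term = sm.OLS(y, np.column_stack([base, inter])).fit()
    without = sm.OLS(y, base).fit()
    return bf01(with_term, without)


def bf01(model_with, model_without, n: int | None = None) -> float:
    """Bayes factor favouring the null via the BIC approximation.

    ``BF01 = exp((BIC_with - BIC_without) / 2)`` for two nested models fit
    on identical data; an approximation to the default-prior Bayes factor
    of the registered procedure.  Also accepts raw BIC floats.
    """
    if hasattr(model_with, "bic") and hasattr(model_without, "bic"):
        if int(model_with.nobs) != int(model_without.nobs):
            raise DataError("models were not fitted on identical data")
        if model_with.df_model <= model_without.df_model:
            raise DataError("the 'with' model must nest the 'without' model")
        bw, bo = float(model_with.bic), float(model_without.bic)
    else:
        bw, bo = float(model_with), float(model_without)
    return float(np.exp((bw - bo) / 2.0))


# ---------------------------------------------------------------------------
# effect-size gate, moderation, power
# ---------------------------------------------------------------------------


def paired_cohens_d(pre, post) -> float:
    """Cohen's d of the paired reduction: mean(pre - post) / SD(pre - post)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise DataError("pre and post must be paired vectors")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0
        raise DataError("Cohen's d undefined: zero variance of differences")
    return float(diff.mean() / sd)


def cohens_d_gate(pre, post, threshold: float = 0.4):
    """Smallest-effect-of-interest gate: proceed only if d >= threshold."""
    d = paired_cohens_d(pre, post)
    return d, bool(d >= threshold)


@dataclass
class ModerationResult:
    beta: float
    se: float
    t: float
    df: int
    p: float
    r2: float
    n: int


def moderation_fit(delta, bias, baseline) -> ModerationResult:
    """OLS of the liking delta on the learning bias with baseline liking as
    covariate: ``delta ~ bias + baseline``.

    The bias slope, its SE, t (df = n - 3), p and the model R^2 are
    returned.  Collinear predictors trigger a rank warning.
    """
    delta = np.asarray(delta, dtype=float)
    bias = np.asarray(bias, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    n = delta.size
    if not (bias.size == n and baseline.size == n):
        raise DataError("delta, bias and baseline must have equal length")
    if n <= 3:
        raise DataError("moderation model needs n > 3")
    x = sm.add_constant(np.column_stack([bias, baseline]))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn("rank-deficient design: bias and baseline are collinear")
    fit = sm.OLS(delta, x).fit()
    return ModerationResult(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        df=int(fit.df_resid),
        p=float(fit.pvalues[1]),
        r2=float(fit.rsquared),
        n=n,
    )


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power specification for the repeated-measures design."""

    effect_size_f: float
    alpha: float = 0.02
    power: float = 0.90
    n_levels: int = 2          # within-factor levels m of the tested effect
    rho: float = 0.5           # repeated-measures correlation
    epsilon: float = 1.0       # nonsphericity
    n_max: int = 10000

    def __post_init__(self):
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ConfigError("alpha and power must lie in (0, 1)")
        if self.effect_size_f <= 0:
            raise ConfigError("effect size must be > 0")
        if not 0 <= self.rho < 1:
            raise ConfigError("rho must lie in [0, 1)")


def power_rm_anova_at(n: int, spec: PowerSpec) -> float:
    """Achieved power at sample size n under the noncentral-F model.

    The noncentrality uses the error-df-based sample scaling
    ``lambda = (n - 1) * m * f^2 * eps / (1 - rho)`` with
    ``df1 = (m - 1) * eps`` and ``df2 = (n - 1)(m - 1) * eps``, matching
    the convention of the standard a-priori calculator for this design.
    """
    m, f2 = spec.n_levels, spec.effect_size_f**2
    lam = (n - 1) * m * f2 * spec.epsilon / (1.0 - spec.rho)
    df1 = (m - 1) * spec.epsilon
    df2 = (n - 1) * (m - 1) * spec.epsilon
    if df2 <= 0:
        return 0.0
    fcrit = sps.f.ppf(1 - spec.alpha, df1, df2)
    return float(1.0 - sps.ncf.cdf(fcrit, df1, df2, lam))


def power_rm_anova(spec: PowerSpec) -> int:
    """Smallest n whose repeated-measures ANOVA power reaches the target."""
    for n in range(3, spec.n_max + 1):
        if power_rm_anova_at(n, spec) >= spec.power:
            return n
    raise ConfigError(f"target power {spec.power} unreachable below n = {spec.n_max}")
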