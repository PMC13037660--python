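"""Task session builders and the Go/NoGo item categorisation.

Every builder is a pure, seeded function: the same :class:`TaskConfig`
always yields the byte-identical trial table.  Design constants default to
the study design they emulate:

* gamified Go/NoGo training — 70% Go / 30% NoGo trials;
* in-lab ERP Go/NoGo — 4 blocks of 200 trials (120 Go, 80 NoGo cues each);
* stimulus-response compatibility (SRC) — 50 trials per cue direction and
  item category, 200 total;
* Pavlovian conditioning — 80 trials over 5 conditioned stimuli whose
  reward values span -2..+2 CHF;
* forced choice — every unordered CS pair three times, 30 trials;
* sequential learning (two-step) — 201 trials in blocks of 67.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..errors import BalancingError, ConfigError, PartitionError

TASK_KINDS = (
    "gng_training",
    "erp_gng",
    "src",
    "pavlovian",
    "forced_choice",
    "two_step",
)

#: Reward value (CHF) attached to each of the five conditioned stimuli.
CS_VALUES = (-2, -1, 0, 1, 2)

#: Drink types of the 57-item sugary-drink picture set (type -> item count).
DRINK_TYPE_COUNTS = {
    "artificial_energy": 8,
    "natural_energy": 5,
    "iced_coffee": 4,
    "milky": 6,
    "citrus_soda": 16,
    "cola": 3,
    "other_soda": 2,
    "kombucha": 2,
    "iced_tea": 11,
}

_DEFAULTS: dict[str, dict] = {
    "gng_training": dict(n_trials=200, go_prop=0.70, n_go_items=17, n_nogo_items=17),
    "erp_gng": dict(
        n_blocks=4,
        trials_per_block=200,
        go_per_block=120,
        nogo_per_block=80,
        n_items=34,
        exact_item_balance=False,
    ),
    "src": dict(n_per_cell=50, n_practice=20, include_practice=False),
    "pavlovian": dict(n_trials=80, cs_values=CS_VALUES),
    "forced_choice": dict(n_cs=5, n_repeats=3, cs_values=CS_VALUES),
    "two_step": dict(n_trials=201, block_len=67),
}


@dataclass(frozen=True)
class TaskConfig:
    """Configuration of one task session.

    ``params`` holds kind-specific counts and proportions; unspecified keys
    take the design defaults above.
    """

    task_kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.task_kind not in TASK_KINDS:
            raise ConfigError(f"unknown task kind {self.task_kind!r}")
        unknown = set(self.params) - set(_DEFAULTS[self.task_kind])
        if unknown:
            raise ConfigError(f"unknown parameters for {self.task_kind}: {sorted(unknown)}")
        self._validate()

    @property
    def resolved(self) -> dict:
        p = dict(_DEFAULTS[self.task_kind])
        p.update(self.params)
        return p

    def _validate(self) -> None:
        p = self.resolved
        for key, val in p.items():
            if key.startswith(("n_", "trials", "go_per", "nogo_per", "block")) and isinstance(val, int):
                if val <= 0:
                    raise ConfigError(f"{key} must be positive, got {val}")
        if self.task_kind == "gng_training":
            if not 0.0 <= p["go_prop"] <= 1.0:
                raise ConfigError("go_prop must lie in [0, 1]")
        if self.task_kind == "erp_gng":
            if p["go_per_block"] + p["nogo_per_block"] != p["trials_per_block"]:
                raise ConfigError("go_per_block + nogo_per_block must equal trials_per_block")

    def with_seed(self, seed: int) -> "TaskConfig":
        return replace(self, seed=seed)


def build_session(cfg: TaskConfig) -> pd.DataFrame:
    """Build the trial table for one task session.

    Returns a DataFrame with a ``trial_index`` column plus kind-specific
    condition/identity/side columns.  Counts and proportions match the
    configuration exactly; generation is deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    builder = {
        "gng_training": _build_gng_training,
        "erp_gng": _build_erp_gng,
        "src": _build_src,
        "pavlovian": _build_pavlovian,
        "forced_choice": _build_forced_choice,
        "two_step": _build_two_step,
    }[cfg.task_kind]
    df = builder(cfg.resolved, rng)
    df.insert(0, "trial_index", np.arange(len(df)))
    return df


def _shuffled(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    return df.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31))).reset_index(drop=True)


def _build_gng_training(p: dict, rng: np.random.Generator) -> pd.DataFrame:
    n = p["n_trials"]
    n_go = round(p["go_prop"] * n)
    if not math.isclose(n_go, p["go_prop"] * n, abs_tol=1e-9):
        raise BalancingError(
            f"go_prop {p['go_prop']} times {n} trials is not an integer trial count"
        )
    cond = np.array(["go"] * n_go + ["nogo"] * (n - n_go))
    # items cycle within their condition so exposure is as even as possible
    go_items = np.arange(p["n_go_items"])
    nogo_items = p["n_go_items"] + np.arange(p["n_nogo_items"])
    item = np.empty(n, dtype=int)
    item[:n_go] = rng.permuted(np.resize(go_items, n_go))
    item[n_go:] = rng.permuted(np.resize(nogo_items, n - n_go))
    df = pd.DataFrame({"condition": cond, "item": item, "block": 0})
    return _shuffled(df, rng)


def _balanced_item_stream(n_slots: int, items: np.ndarray, rng, exact: bool, label: str) -> np.ndarray:
    if exact and n_slots % len(items):
        raise BalancingError(
            f"{n_slots} {label} cue trials cannot be split equally over {len(items)} items"
        )
    order = rng.permutation(items)
    return rng.permuted(np.resize(order, n_slots))


def _build_erp_gng(p: dict, rng: np.random.Generator) -> pd.DataFrame:
    items = np.arange(p["n_items"])
    blocks = []
    n_go_total = p["n_blocks"] * p["go_per_block"]
    n_nogo_total = p["n_blocks"] * p["nogo_per_block"]
    go_stream = _balanced_item_stream(n_go_total, items, rng, p["exact_item_balance"], "Go")
    nogo_stream = _balanced_item_stream(n_nogo_total, items, rng, p["exact_item_balance"], "NoGo")
    gi = ni = 0
    for b in range(p["n_blocks"]):
        cond = ["go"] * p["go_per_block"] + ["nogo"] * p["nogo_per_block"]
        item = np.concatenate(
            [
                go_stream[gi : gi + p["go_per_block"]],
                nogo_stream[ni : ni + p["nogo_per_block"]],
            ]
        )
        gi += p["go_per_block"]
        ni += p["nogo_per_block"]
        block = pd.DataFrame({"cue": cond, "item": item, "block": b})
        blocks.append(_shuffled(block, rng))
    return pd.concat(blocks, ignore_index=True)


def _build_src(p: dict, rng: np.random.Generator) -> pd.DataFrame:
    cells = [
        (cue, cat)
        for cue in ("away", "toward")
        for cat in ("go", "nogo")
    ]
    rows = []
    for cue, cat in cells:
        for _ in range(p["n_per_cell"]):
            rows.append((cue, cat))
    df = pd.DataFrame(rows, columns=["cue", "category"])
    df["manikin_above"] = rng.random(len(df)) < 0.5
    df = _shuffled(df, rng)
    df["practice"] = False
    if p["include_practice"]:
        prac = df.sample(n=p["n_practice"], replace=True,
                         random_state=np.random.RandomState(rng.integers(2**31)))
        prac = prac.assign(practice=True)
        df = pd.concat([prac, df], ignore_index=True)
    df["block"] = 0
    return df.reset_index(drop=True)


def _build_pavlovian(p: dict, rng: np.random.Generator) -> pd.DataFrame:
    values = list(p["cs_values"])
    n = p["n_trials"]
    if n % len(values):
        raise BalancingError(
            f"{n} Pavlovian trials cannot be split equally over {len(values)} CSs"
        )
    per = n // len(values)
    df = pd.DataFrame({"cs_value": np.repeat(values, per)})
    df["cs_id"] = df["cs_value"].map({v: i for i, v in enumerate(values)})
    df["cs_side"] = np.where(rng.random(n) < 0.5, "left", "right")
    df["block"] = 0
    return _shuffled(df, rng)


def _build_forced_choice(p: dict, rng: np.random.Generator) -> pd.DataFrame:
    values = list(p["cs_values"])[: p["n_cs"]]
    if len(values) < p["n_cs"]:
        values = list(range(p["n_cs"]))
    pairs = list(itertools.combinations(range(p["n_cs"]), 2))
    rows = []
    for rep in range(p["n_repeats"]):
        for a, b in pairs:
            rows.append((a, b, values[a], values[b], rep))
    df = pd.DataFrame(rows, columns=["cs_a", "cs_b", "value_a", "value_b", "repeat"])
    df["block"] = 0
    return _shuffled(df, rng)


def _build_two_step(p: dict, rng: np.random.Generator) -> pd.DataFrame:
    n = p["n_trials"]
    block = np.arange(n) // p["block_len"]
    df = pd.DataFrame(
        {
            "block": block,
            "stage1_swap": rng.random(n) < 0.5,
            "stage2_swap": rng.random(n) < 0.5,
        }
    )
    return df


# ---------------------------------------------------------------------------
# Go/NoGo item categorisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemCatalogue:
    """Items with a drink type and a baseline liking rating (0-100)."""

    table: pd.DataFrame  # columns: item, drink_type, liking

    def __post_init__(self):
        t = self.table
        for col in ("item", "drink_type", "liking"):
            if col not in t.columns:
                raise ConfigError(f"catalogue missing column {col!r}")
        if ((t["liking"] < 0) | (t["liking"] > 100)).any():
            raise ConfigError("liking ratings must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.table)


def default_catalogue(seed: int = 0) -> ItemCatalogue:
    """The 57-item sugary-drink set with seeded baseline likings.

    Type composition follows the study stimulus set; likings are drawn from
    a clipped normal matching the reported cohort baseline (69.1 +/- 14.0).
    """
    rng = np.random.default_rng(seed)
    types = np.repeat(list(DRINK_TYPE_COUNTS), list(DRINK_TYPE_COUNTS.values()))
    liking = np.clip(rng.normal(69.1, 14.0, len(types)), 0, 100)
    table = pd.DataFrame(
        {"item": np.arange(len(types)), "drink_type": types, "liking": np.round(liking, 1)}
    )
    return ItemCatalogue(table)


@dataclass(frozen=True)
class Categorisation:
    go_items: tuple
    nogo_items: tuple
    untrained_items: tuple
    go_types: tuple
    nogo_types: tuple
    mean_gap: float
    n_selected: int


def _nearest_even(x: float) -> int:
    lo = 2 * math.floor(x / 2)
    hi = lo + 2
    # nearest even count; ties resolve to the smaller set
    return lo if (x - lo) <= (hi - x) else hi


def categorise_items(catalogue: ItemCatalogue, top_fraction: float = 0.6) -> Categorisation:
    """Assign items to Go / NoGo / untrained.

    The ``top_fraction`` most liked items are selected for training (count
    rounded to the nearest even integer so the two conditions can hold the
    same number of items; rating ties broken by catalogue order).  Drink
    types are never split across conditions: the partition of types into two
    equal-item-count sets minimising the absolute difference in mean liking
    is found by exhaustive enumeration over type subsets.
    """
    t = catalogue.table.reset_index(drop=True)
    n_sel = _nearest_even(top_fraction * len(t))
    if n_sel < 2:
        raise ConfigError("fewer than two items selected for training")
    order = t.sort_values("liking", ascending=False, kind="stable")
    selected = order.iloc[:n_sel]
    untrained = tuple(order.iloc[n_sel:]["item"].tolist())

    groups = selected.groupby("drink_type", sort=True)
    type_names = list(groups.groups)
    if len(type_names) < 2:
        raise PartitionError("need at least 2 drink types among selected items")
    counts = groups.size().to_numpy()
    sums = groups["liking"].sum().to_numpy()
    half = n_sel // 2

    best = None
    n_types = len(type_names)
    for mask in range(1, 2**n_types - 1):
        idx = [(mask >> i) & 1 for i in range(n_types)]
        c = int(np.dot(idx, counts))
        if c != half:
            continue
        s = float(np.dot(idx, sums))
        gap = abs(s / half - (sums.sum() - s) / half)
        if best is None or gap < best[0] - 1e-12:
            best = (gap, mask)
    if best is None:
        raise PartitionError(
            "no partition of drink types yields equal Go/NoGo item counts "
            f"(need {half} items per condition from type sizes {dict(zip(type_names, counts.tolist()))})"
        )
    gap, mask = best
    go_types = tuple(type_names[i] for i in range(n_types) if (mask >> i) & 1)
    nogo_types = tuple(type_names[i] for i in range(n_types) if not (mask >> i) & 1)
    go_items = tuple(selected[selected["drink_type"].isin(go_types)]["item"].tolist())
    nogo_items = tuple(selected[selected["drink_type"].isin(nogo_types)]["item"].tolist())
    return Categorisation(
        go_items=go_items,
        nogo_items=nogo_items,
        untrained_items=untrained,
        go_types=go_types,
        nogo_types=nogo_types,
        mean_gap=float(gap),
        n_selected=n_sel,
    )
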