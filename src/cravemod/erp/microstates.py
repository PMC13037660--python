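"""Cluster-based ERP component segmentation (microstate analysis).

Grand-average maps from all conditions are pooled and clustered with a
polarity-sensitive atomise-and-agglomerate hierarchical scheme (event-
related data carry polarity, so maps are compared by signed spatial
correlation, not its absolute value).  For each candidate number of
template maps k the clustering is polished by modified k-means iterations;
k is then selected by the Krzanowski-Lai criterion, with a cross-validation
criterion acting as a feasibility screen (ties resolve to the smaller k).
Segments shorter than a minimum duration (quasi-stability is expected over
roughly 20-100 ms) are relabelled into their neighbours, and the resulting
per-condition component windows are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigError, DataError
from .measures import gfp_timecourse


@dataclass
class MicrostateModel:
    templates: np.ndarray          # k x channels, unit-norm, average-referenced
    k: int
    labels: dict                   # condition -> int array over time frames
    windows: dict                  # condition -> list of (label, onset_tf, offset_tf)
    criteria: pd.DataFrame         # columns: k, w, cv, kl
    converged: bool
    sfreq: float


def _normalise_maps(maps: np.ndarray):
    """Average-reference each row and scale to unit L2 norm."""
    v = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(v, axis=1)
    ok = norms > 1e-12
    u = np.zeros_like(v)
    u[ok] = v[ok] / norms[ok, None]
    return u, v, ok


def _assign(u: np.ndarray, templates: np.ndarray) -> np.ndarray:
    return np.argmax(u @ templates.T, axis=1)


def _centroids(u: np.ndarray, labels: np.ndarray, k: int, rng) -> np.ndarray:
    c = np.zeros((k, u.shape[1]))
    for j in range(k):
        members = u[labels == j]
        if len(members) == 0:      # re-seed an emptied cluster
            members = u[rng.integers(len(u))][None, :]
        m = members.mean(axis=0)
        n = np.linalg.norm(m)
        c[j] = m / n if n > 1e-12 else u[rng.integers(len(u))]
    return c


def _kmeans_polish(u, templates, max_iter, rng):
    labels = _assign(u, templates)
    for _ in range(max_iter):
        templates = _centroids(u, labels, len(templates), rng)
        new = _assign(u, templates)
        if np.array_equal(new, labels):
            return templates, new, True
        labels = new
    return templates, labels, False


def _taahc(u: np.ndarray, k_min: int) -> dict:
    """Atomise-and-agglomerate hierarchy: start from singleton clusters,
    repeatedly dissolve the worst cluster and reassign its members.
    Returns clusterings (label arrays) for every k down to ``k_min``."""
    n = len(u)
    clusters = [[i] for i in range(n)]
    out = {}

    def centroid(members):
        m = u[members].mean(axis=0)
        nm = np.linalg.norm(m)
        return m / nm if nm > 1e-12 else u[members[0]]

    cents = [centroid(c) for c in clusters]
    while len(clusters) >= k_min:
        k = len(clusters)
        labels = np.empty(n, dtype=int)
        for j, members in enumerate(clusters):
            labels[members] = j
        out[k] = labels
        if k == k_min:
            break
        # worst cluster: lowest mean member-to-centroid correlation
        quality = [float((u[m] @ c).mean()) for m, c in zip(clusters, cents)]
        worst = int(np.argmin(quality))
        orphans = clusters.pop(worst)
        cents.pop(worst)
        cent_mat = np.array(cents)
        for i in orphans:
            j = int(np.argmax(cent_mat @ u[i]))
            clusters[j].append(i)
        cents = [centroid(c) for c in clusters]
        cent_mat = None
    return out


def segment_microstates(
    grand_averages: dict,
    sfreq: float,
    k_range: tuple = (1, 6),
    min_duration_ms: float = 20.0,
    max_iter: int = 500,
    seed: int = 0,
) -> MicrostateModel:
    """Segment pooled grand-average ERPs into quasi-stable topographies.

    Parameters
    ----------
    grand_averages
        Mapping condition -> channels x time array (uV).
    k_range
        Inclusive range of candidate template counts.
    min_duration_ms
        Segments shorter than this are absorbed by their neighbours.
    """
    if len(grand_averages) < 1:
        raise DataError("at least one condition's grand average is required")
    conds = list(grand_averages)
    mats = [np.asarray(grand_averages[c], dtype=float) for c in conds]
    n_ch = mats[0].shape[0]
    if any(m.shape[0] != n_ch for m in mats):
        raise DataError("conditions must share the electrode set")
    n_tfs = [m.shape[1] for m in mats]
    maps = np.concatenate([m.T for m in mats], axis=0)      # (T_total, ch)
    t_total = len(maps)

    k_min, k_max = k_range
    if not (1 <= k_min <= k_max <= t_total):
        raise ConfigError(f"k_range {k_range} infeasible for {t_total} maps")

    u, v, ok = _normalise_maps(maps)
    rng = np.random.default_rng(seed)

    # hierarchy gives initial clusterings; polish each k by modified k-means
    hier = _taahc(u[ok], max(k_min, 1))
    results = {}
    converged_all = True
    denom = max(n_ch - 1, 1)
    for k in range(k_min, k_max + 1):
        if k == 1:
            m = u[ok].mean(axis=0)
            nm = np.linalg.norm(m)
            templates = (m / nm if nm > 1e-12 else u[ok][0])[None, :]
            labels_ok = np.zeros(ok.sum(), dtype=int)
            conv = True
        else:
            init_labels = hier.get(k)
            if init_labels is None:
                continue
            templates = _centroids(u[ok], init_labels, k, rng)
            templates, labels_ok, conv = _kmeans_polish(u[ok], templates, max_iter, rng)
        converged_all &= conv
        labels = np.zeros(t_total, dtype=int)
        labels[ok] = labels_ok
        # residual variance of the (unnormalised) maps given the templates
        proj = np.einsum("tc,tc->t", v, templates[labels])
        resid = float(np.sum(np.einsum("tc,tc->t", v, v) - proj**2))
        sigma2 = resid / (t_total * denom)
        cv = sigma2 * ((denom) / max(denom - k, 1)) ** 2
        w_disp = float(np.sum(np.sum((u - templates[labels]) ** 2, axis=1)[ok]))
        results[k] = dict(templates=templates, labels=labels, w=w_disp, cv=cv)

    ks = sorted(results)
    # Krzanowski-Lai criterion over the dispersion curve
    p = n_ch
    diff = {}
    for k in ks:
        if k - 1 in results and k >= 2:
            diff[k] = (k - 1) ** (2 / p) * results[k - 1]["w"] - k ** (2 / p) * results[k]["w"]
    kl = {}
    for k in ks:
        if k in diff and (k + 1) in diff and abs(diff[k + 1]) > 1e-300:
            kl[k] = abs(diff[k]) / abs(diff[k + 1])

    crit = pd.DataFrame(
        {
            "k": ks,
            "w": [results[k]["w"] for k in ks],
            "cv": [results[k]["cv"] for k in ks],
            "kl": [kl.get(k, np.nan) for k in ks],
        }
    )

    # degenerate screen: a single topography explains everything
    if results.get(1) is not None and results[1]["w"] <= ok.sum() * 1e-9:
        k_best = 1
    elif kl:
        # feasibility screen: cross-validation must still be improving at k
        feasible = [k for k in kl if results[k]["cv"] <= results[k - 1]["cv"] + 1e-15]
        pool = feasible if feasible else list(kl)
        best_val = max(kl[k] for k in pool)
        k_best = min(k for k in pool if kl[k] >= best_val - 1e-12)
    else:
        k_best = min(ks, key=lambda k: results[k]["cv"])

    chosen = results[k_best]
    min_len = max(1, int(round(min_duration_ms * sfreq / 1000.0)))
    labels_per_cond, windows = {}, {}
    offset = 0
    for c, n_tf in zip(conds, n_tfs):
        lab = chosen["labels"][offset : offset + n_tf].copy()
        lab = _smooth_labels(lab, u[offset : offset + n_tf], chosen["templates"], min_len)
        labels_per_cond[c] = lab
        windows[c] = _runs(lab)
        offset += n_tf

    return MicrostateModel(
        templates=chosen["templates"],
        k=k_best,
        labels=labels_per_cond,
        windows=windows,
        criteria=crit,
        converged=converged_all,
        sfreq=sfreq,
    )


def _runs(labels: np.ndarray):
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((int(labels[start]), start, i - 1))
            start = i
    return out


def _smooth_labels(labels, u, templates, min_len):
    """Absorb segments shorter than ``min_len`` into the better-matching
    neighbour segment (by mean signed correlation over the short run)."""
    labels = labels.copy()
    for _ in range(len(labels)):
        runs = _runs(labels)
        if len(runs) <= 1:
            break
        short = [r for r in runs if (r[2] - r[1] + 1) < min_len]
        if not short:
            break
        lab, a, b = min(short, key=lambda r: r[2] - r[1])
        i = runs.index((lab, a, b))
        cands = []
        if i > 0:
            cands.append(runs[i - 1][0])
        if i < len(runs) - 1:
            cands.append(runs[i + 1][0])
        seg = u[a : b + 1]
        fit = [float((seg @ templates[c]).mean()) for c in cands]
        labels[a : b + 1] = cands[int(np.argmax(fit))]
    return labels


def lock_to_gfp_peak(windows: dict, grand_averages: dict):
    """Re-centre each condition's component window on its GFP peak.

    ``windows`` maps condition -> (onset_tf, offset_tf) inclusive.  Within
    each window the time frame of maximal grand-average GFP is found (flat
    GFP ties break to the earliest frame, with a warning); windows are then
    re-centred on the peak with a common pre/post extent, the minimum
    across conditions.

    Returns ``(aligned_windows, peaks)``.
    """
    peaks = {}
    for cond, (a, b) in windows.items():
        if b < a:
            raise DataError(f"empty component window for condition {cond!r}")
        tc = gfp_timecourse(np.asarray(grand_averages[cond], dtype=float)[:, a : b + 1])
        if np.ptp(tc) < 1e-12:
            warnings.warn(f"flat GFP in window of {cond!r}; earliest frame used")
        peaks[cond] = a + int(np.argmax(tc))
    pre = min(peaks[c] - windows[c][0] for c in windows)
    post = min(windows[c][1] - peaks[c] for c in windows)
    aligned = {c: (peaks[c] - pre, peaks[c] + post) for c in windows}
    return aligned, peaks
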