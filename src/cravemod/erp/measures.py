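"""Global field power (GFP) and global map dissimilarity (GMD).

GFP is the spatial standard deviation of the scalp potential map at one
time frame (population convention: divide by the electrode count).  GMD is
the root-mean-square difference between two average-referenced maps after
each is scaled to unit GFP; it ranges from 0 (identical topographies) to 2
(polarity-inverted topographies) and satisfies the identity
``gmd(a, b) = sqrt(2 * (1 - r))`` with ``r`` the spatial Pearson
correlation of the average-referenced maps.
"""

from __future__ import annotations

import numpy as np

from ..errors import DataError


def _as_map(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise DataError("a scalp map must be one-dimensional (one value per electrode)")
    if v.size < 2:
        raise DataError("a scalp map needs at least 2 electrodes")
    if not np.isfinite(v).all():
        raise DataError("scalp map contains non-finite values")
    return v


def gfp(scalp_map) -> float:
    """Global field power (uV): population spatial SD of the map."""
    v = _as_map(scalp_map)
    return float(np.std(v - v.mean()))


def gmd(map_a, map_b) -> float:
    """Global map dissimilarity between two maps (dimensionless, in [0, 2])."""
    a = _as_map(map_a)
    b = _as_map(map_b)
    if a.size != b.size:
        raise DataError("maps must share the electrode set")
    a = a - a.mean()
    b = b - b.mean()
    ga, gb = np.std(a), np.std(b)
    if ga == 0 or gb == 0:
        raise DataError("GMD is undefined for a zero-GFP (flat) map")
    d = a / ga - b / gb
    return float(np.sqrt(np.mean(d**2)))


def gfp_timecourse(data: np.ndarray) -> np.ndarray:
    """GFP at every time frame of a channels x time array."""
    data = np.asarray(data, dtype=float)
    return np.std(data - data.mean(axis=0, keepdims=True), axis=0)
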