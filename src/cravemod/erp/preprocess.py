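"""Epoch-level ERP pre-processing: baseline correction, artifact-based
epoch rejection, per-condition averaging and common-average re-referencing.

Upstream continuous-data cleaning (filtering, line-noise removal, artifact
subspace reconstruction, blink handling, bad-channel interpolation) is out
of scope; this module starts from epoched data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigError, DataError, EmptyErpError
from .containers import ErpEpochs, SubjectErp


@dataclass
class RejectionReport:
    """Per-epoch retention decisions with reasons."""

    table: pd.DataFrame  # columns: epoch, retained, jump_uv, max_abs_uv, reasons

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())

    @property
    def n_rejected(self) -> int:
        return int((~self.table["retained"]).sum())


def preprocess_epochs(
    epochs: ErpEpochs,
    baseline_window_ms: tuple = (-100.0, 0.0),
    jump_limit_uv: float = 30.0,
    amp_limit_uv: float = 80.0,
):
    """Baseline-correct epochs and reject artifact-contaminated ones.

    The per-channel mean over ``baseline_window_ms`` is subtracted from each
    epoch.  An epoch is then rejected if, on any electrode, the absolute
    step between consecutive time frames exceeds ``jump_limit_uv`` (strictly)
    or any absolute voltage exceeds ``amp_limit_uv`` (strictly).

    Returns ``(clean_epochs, report)``; raises :class:`EmptyErpError` if no
    epoch survives.
    """
    t = epochs.times_ms
    lo, hi = baseline_window_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ConfigError(
            f"baseline window {baseline_window_ms} not inside epoch window "
            f"({t[0]:.1f}, {t[-1]:.1f}) ms"
        )
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        raise ConfigError("baseline window contains no time frame")

    data = epochs.data - epochs.data[:, sel, :].mean(axis=1, keepdims=True)

    jumps = np.abs(np.diff(data, axis=1)).max(axis=(0, 1)) if data.shape[1] > 1 else np.zeros(data.shape[2])
    amps = np.abs(data).max(axis=(0, 1))
    jump_bad = jumps > jump_limit_uv
    amp_bad = amps > amp_limit_uv
    retained = ~(jump_bad | amp_bad)

    reasons = [
        ";".join(
            r
            for r, bad in (("jump", jump_bad[i]), ("amplitude", amp_bad[i]))
            if bad
        )
        for i in range(data.shape[2])
    ]
    report = RejectionReport(
        pd.DataFrame(
            {
                "epoch": np.arange(data.shape[2]),
                "retained": retained,
                "jump_uv": jumps,
                "max_abs_uv": amps,
                "reasons": reasons,
            }
        )
    )
    if not retained.any():
        raise EmptyErpError("all epochs rejected; no ERP can be formed")
    return epochs.copy_with(data[:, :, retained]), report


def build_subject_erp(epochs_by_condition: dict) -> SubjectErp:
    """Average clean epochs per condition and re-reference to the common
    average (channel mean subtracted at every time frame)."""
    if not epochs_by_condition:
        raise DataError("no conditions supplied")
    erps, counts = {}, {}
    ref = None
    for cond, ep in epochs_by_condition.items():
        if ep is None or ep.n_epochs == 0:
            raise EmptyErpError(f"condition {cond!r} has no retained epochs")
        avg = ep.data.mean(axis=2)
        erps[cond] = avg - avg.mean(axis=0, keepdims=True)
        counts[cond] = ep.n_epochs
        if ref is None:
            ref = ep
        elif (ep.sfreq != ref.sfreq) or (ep.tmin_ms != ref.tmin_ms):
            raise DataError(f"condition {cond!r} has a mismatching time axis")
    return SubjectErp(erps, ref.sfreq, ref.tmin_ms, ref.ch_names, counts)
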