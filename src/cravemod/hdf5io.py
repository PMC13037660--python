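"""HDF5 container for simulated multi-subject ERP epochs.

Layout: one group per subject (``subject_000``, ...), one dataset per
condition (channels x time x epochs, uV), with sampling rate, epoch onset
and channel names stored as attributes.  Trial tables and behavioural data
travel as CSV; only the EEG epochs use HDF5.
"""

from __future__ import annotations

import h5py
import numpy as np

from .erp.containers import ErpEpochs


def save_eeg_dataset(path, data: list) -> None:
    """Write ``data[subject][condition] -> ErpEpochs`` to ``path``."""
    with h5py.File(path, "w") as f:
        for i, conds in enumerate(data):
            grp = f.create_group(f"subject_{i:03d}")
            for cond, ep in conds.items():
                ds = grp.create_dataset(cond, data=ep.data, compression="gzip")
                ds.attrs["sfreq"] = ep.sfreq
                ds.attrs["tmin_ms"] = ep.tmin_ms
                ds.attrs["ch_names"] = np.array(ep.ch_names, dtype="S")


def load_eeg_dataset(path) -> list:
    """Read the container written by :func:`save_eeg_dataset`."""
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            grp = f[key]
            conds = {}
            for cond in grp.keys():
                ds = grp[cond]
                conds[cond] = ErpEpochs(
                    ds[()],
                    float(ds.attrs["sfreq"]),
                    float(ds.attrs["tmin_ms"]),
                    [n.decode() for n in ds.attrs["ch_names"]],
                )
            out.append(conds)
    return out
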