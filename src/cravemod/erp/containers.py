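"""In-memory containers for epoched and averaged ERP data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigError

CONDITIONS = ("pre_go", "pre_nogo", "post_go", "post_nogo")


@dataclass
class ErpEpochs:
    """Single-subject, single-condition epochs: channels x time x epochs, uV."""

    data: np.ndarray
    sfreq: float
    tmin_ms: float
    ch_names: list

    def __init__(self, data, sfreq, tmin_ms, ch_names):
        data = np.asarray(data, dtype=float)
        if data.ndim != 3:
            raise ConfigError("epoch data must be channels x time x epochs")
        if not np.isfinite(data).all():
            raise ConfigError("epoch data must be finite")
        if len(ch_names) != data.shape[0]:
            raise ConfigError("ch_names length must match channel axis")
        self.data = data
        self.sfreq = float(sfreq)
        self.tmin_ms = float(tmin_ms)
        self.ch_names = list(ch_names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_times) * 1000.0 / self.sfreq

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times_ms - t_ms)))

    def copy_with(self, data: np.ndarray) -> "ErpEpochs":
        return ErpEpochs(data, self.sfreq, self.tmin_ms, self.ch_names)


@dataclass
class SubjectErp:
    """One subject's averaged, common-average-referenced ERPs per condition.

    ``erps[condition]`` is a channels x time array (uV); ``epoch_counts``
    records how many epochs entered each average.
    """

    erps: dict
    sfreq: float
    tmin_ms: float
    ch_names: list
    epoch_counts: dict = field(default_factory=dict)

    @property
    def times_ms(self) -> np.ndarray:
        n_times = next(iter(self.erps.values())).shape[1]
        return self.tmin_ms + np.arange(n_times) * 1000.0 / self.sfreq

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times_ms - t_ms)))
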