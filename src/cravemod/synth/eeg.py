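"""Multi-subject 64-channel ERP epoch simulator.

Each simulated epoch is a sum of scalp components — a fixed topography
template multiplied by a Gaussian temporal kernel and a condition-dependent
amplitude — plus spatially correlated, temporally white Gaussian noise.
The default components emulate an occipital P1-like deflection peaking at
85 ms and a frontocentral N2-like deflection peaking at 222 ms, the two
components relevant to a 2 (session: pre/post) x 2 (item category: trained
Go / trained NoGo) within design.  A ground-truth record (latencies,
injected 2x2 contrasts, per-subject amplitudes) is returned alongside the
data so downstream recovery can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..erp.containers import ErpEpochs
from ..errors import ConfigError

CONDITIONS = ("pre_go", "pre_nogo", "post_go", "post_nogo")

#: contrast coding: session (pre=-1, post=+1), category (go=-1, nogo=+1)
_COND_CODES = {
    "pre_go": (-1, -1),
    "pre_nogo": (-1, +1),
    "post_go": (+1, -1),
    "post_nogo": (+1, +1),
}


def channel_positions(n_channels: int = 64) -> np.ndarray:
    """Deterministic electrode positions on the upper unit hemisphere.

    A Fibonacci lattice restricted to z >= 0, oriented with +y anterior and
    +z vertex; adequate as a synthetic stand-in for a 64-channel montage.
    """
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = (i + 0.5) / n_channels          # height in (0, 1): upper hemisphere
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def channel_names(n_channels: int = 64) -> list[str]:
    return [f"E{i + 1:02d}" for i in range(n_channels)]


def _template(pos: np.ndarray, centre: np.ndarray, width: float, sign: float) -> np.ndarray:
    """Smooth scalp topography: Gaussian in chordal distance, average
    referenced and scaled to unit global field power."""
    centre = centre / np.linalg.norm(centre)
    d2 = ((pos - centre) ** 2).sum(axis=1)
    t = sign * np.exp(-d2 / (2 * width**2))
    t = t - t.mean()
    return t / t.std()


# canonical scalp directions (x right, y anterior, z up)
_TOPO_CENTRES = {
    "occipital": np.array([0.0, -0.85, 0.53]),
    "frontocentral": np.array([0.0, 0.55, 0.84]),
    "left_temporal": np.array([-0.9, 0.0, 0.44]),
}


@dataclass(frozen=True)
class ComponentSpec:
    """One simulated ERP component.

    Amplitudes are in uV at the temporal peak of the unit-GFP topography.
    ``session_effect``, ``category_effect`` and ``interaction_effect`` are
    the corresponding 2x2 contrasts of the four condition amplitudes
    (e.g. interaction = (post_nogo - post_go) - (pre_nogo - pre_go)).
    """

    name: str
    latency_ms: float
    width_ms: float
    topography: str  # key of _TOPO_CENTRES
    sign: float = 1.0
    base_amplitude_uv: float = 3.0
    session_effect: float = 0.0
    category_effect: float = 0.0
    interaction_effect: float = 0.0

    def amplitude(self, condition: str) -> float:
        s, c = _COND_CODES[condition]
        return (
            self.base_amplitude_uv
            + 0.5 * self.session_effect * s
            + 0.5 * self.category_effect * c
            + 0.25 * self.interaction_effect * s * c
        )


def default_components(n2_interaction_uv: float = 0.0,
                       go_session_uv: float = 0.0) -> tuple[ComponentSpec, ...]:
    """P1-like (85 ms occipital) and N2-like (222 ms frontocentral)
    components; an optional session x category interaction is injected only
    into the N2-like component."""
    p1 = ComponentSpec("P1", 85.0, 16.0, "occipital", sign=+1.0, base_amplitude_uv=3.0)
    n2 = ComponentSpec(
        "N2", 222.0, 30.0, "frontocentral", sign=-1.0, base_amplitude_uv=3.5,
        interaction_effect=n2_interaction_uv, session_effect=go_session_uv,
    )
    return (p1, n2)


@dataclass(frozen=True)
class EegEffectSpec:
    """Ground-truth effect specification for the ERP simulator."""

    components: tuple = field(default_factory=default_components)
    noise_sd_uv: float = 8.0           # per-sample single-trial noise
    spatial_scale: float = 0.6         # chordal length scale of noise kernel
    temporal_smoothing_ms: float = 8.0 # Gaussian autocorrelation scale; 0 = white
    subject_amp_sd: float = 0.5        # between-subject amplitude sd (uV)
    n_epochs: int = 160                # retained correct rejections per cell
    sfreq: float = 512.0
    window_ms: tuple = (-100.0, 700.0)
    n_channels: int = 64

    def __post_init__(self):
        if self.noise_sd_uv < 0 or self.subject_amp_sd < 0 or self.temporal_smoothing_ms < 0:
            raise ConfigError("noise scales must be >= 0")
        lo, hi = self.window_ms
        for comp in self.components:
            if not (lo <= comp.latency_ms <= hi):
                raise ConfigError(
                    f"epoch window {self.window_ms} does not cover component "
                    f"{comp.name} at {comp.latency_ms} ms"
                )


def _noise_chol(pos: np.ndarray, scale: float) -> np.ndarray:
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    k = np.exp(-d2 / (2 * scale**2)) + 1e-6 * np.eye(len(pos))
    return np.linalg.cholesky(k)


def _temporal_smooth(noise: np.ndarray, sigma_samples: float) -> np.ndarray:
    """Gaussian-filter noise along the time axis, renormalised to unit
    marginal variance (emulates band-limited recordings; sigma 0 = white)."""
    if sigma_samples <= 0:
        return noise
    from scipy.ndimage import gaussian_filter1d

    half = int(np.ceil(4 * sigma_samples))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_samples) ** 2)
    k /= k.sum()
    return gaussian_filter1d(noise, sigma_samples, axis=1, mode="wrap") / np.sqrt((k**2).sum())


def simulate_eeg_dataset(n_subjects: int, spec: EegEffectSpec, seed: int = 0):
    """Simulate per-subject, per-condition ERP epochs.

    Returns ``(data, truth)`` where ``data[subject][condition]`` is an
    :class:`ErpEpochs` (channels x time x epochs, uV) and ``truth`` records
    the generating components, effects and per-subject amplitude offsets.
    """
    if n_subjects < 2:
        raise ConfigError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    pos = channel_positions(spec.n_channels)
    names = channel_names(spec.n_channels)
    lo, hi = spec.window_ms
    n_tf = int(round((hi - lo) * spec.sfreq / 1000.0)) + 1
    times = lo + np.arange(n_tf) * 1000.0 / spec.sfreq

    topos = {
        c.name: _template(pos, _TOPO_CENTRES[c.topography], 0.8, c.sign)
        for c in spec.components
    }
    kernels = {
        c.name: np.exp(-0.5 * ((times - c.latency_ms) / c.width_ms) ** 2)
        for c in spec.components
    }
    chol = _noise_chol(pos, spec.spatial_scale) if spec.noise_sd_uv > 0 else None

    data = []
    subject_amp = rng.normal(0.0, spec.subject_amp_sd, size=(n_subjects, len(spec.components)))
    for s in range(n_subjects):
        conds = {}
        for cond in CONDITIONS:
            signal = np.zeros((spec.n_channels, n_tf))
            for j, comp in enumerate(spec.components):
                amp = comp.amplitude(cond) + subject_amp[s, j]
                signal += amp * topos[comp.name][:, None] * kernels[comp.name][None, :]
            epochs = np.repeat(signal[:, :, None], spec.n_epochs, axis=2)
            if spec.noise_sd_uv > 0:
                noise = rng.standard_normal((spec.n_channels, n_tf, spec.n_epochs))
                noise = _temporal_smooth(noise, spec.temporal_smoothing_ms * spec.sfreq / 1000.0)
                noise = np.einsum("cd,dte->cte", chol, noise) * spec.noise_sd_uv
                epochs = epochs + noise
            conds[cond] = ErpEpochs(epochs, spec.sfreq, float(lo), list(names))
        data.append(conds)

    truth = {
        "components": [
            {
                "name": c.name,
                "latency_ms": c.latency_ms,
                "width_ms": c.width_ms,
                "base_amplitude_uv": c.base_amplitude_uv,
                "session_effect": c.session_effect,
                "category_effect": c.category_effect,
                "interaction_effect": c.interaction_effect,
            }
            for c in spec.components
        ],
        "subject_amplitude_offsets": subject_amp,
        "topographies": topos,
        "times_ms": times,
        "seed": seed,
    }
    return data, truth
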