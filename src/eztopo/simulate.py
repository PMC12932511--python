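"""Synthetic EEG/SEEG cohorts with known EZ/NEZ network structure.

The generator emulates the statistical structure the downstream analysis
assumes, without modelling spike/HFO morphology or neural-mass dynamics:

* **SEEG** (depth recordings): every channel is a weighted mixture of two
  band-limited latent community sources — one shared by NEZ contacts, one
  shared by EZ contacts — plus a weak cross-leak term and independent
  band-limited channel noise.  With the interictal default couplings
  (``c_intra_nez > c_intra_ez > c_cross``) the EZ community is both
  internally looser and decoupled from the surrounding network, so EZ
  contacts come out with lower degree, clustering and local efficiency.
* **Ictal state**: beta/gamma/HF couplings surge (intra x ``surge``,
  cross x ``cross_surge``) and the EZ-internal delta coupling is boosted
  by ``delta_boost`` — slow-wave hypersynchrony confined to the focus.
* **Inter-patient heterogeneity**: a per-patient log-normal gain with a
  configurable coefficient of variation (0.4 for SEEG, 0.16 for scalp)
  multiplies all couplings, producing the positively skewed, overlapping
  cross-patient feature distributions that motivate the log + Z-score
  preprocessing.  A per-channel log-normal coupling jitter keeps pairwise
  correlations graded around the binarization threshold rather than
  all-or-nothing.
* **Scalp**: a high-amplitude delta/theta driver at the EZ source
  locations is projected through the spherical-head lead field together
  with low-amplitude broadband background at NEZ sources; ground truth
  lives at the source/parcel level.

Everything is reproducible bit-for-bit from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .bands import BAND_NAMES, NYQUIST_CAP, default_bands
from .signal import bandpass

__all__ = [
    "Coupling",
    "SimulationConfig",
    "Recording",
    "simulate_seeg",
    "simulate_scalp",
    "null_coupling",
]

#: Bands whose couplings surge in the ictal state.
SURGE_BANDS = ("beta", "gamma", "hf")


@dataclass(frozen=True)
class Coupling:
    """Mixing weights of the latent community sources, all in [0, 1]."""

    c_intra_nez: float = 0.8
    c_intra_ez: float = 0.55
    c_cross: float = 0.15

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"coupling {name}={v} outside [0, 1]")


def null_coupling(level: float = 0.45) -> Coupling:
    """A symmetric coupling block (EZ and NEZ statistically exchangeable).

    The default level puts the expected pairwise correlation near the 0.7
    binarization threshold so that edges are stochastic and paired tests
    stay informative under the null.
    """
    return Coupling(level, level, level)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort."""

    n_patients: int = 20
    modality: str = "seeg"
    state: str = "interictal"
    channels_mean: float = 113.0
    channels_sd: float = 20.0
    n_scalp_channels: int = 16
    ez_count_range: tuple[int, int] = (8, 30)
    sampling_rate: float = 2000.0
    epoch_length: float = 10.0
    coupling: Coupling = field(default_factory=Coupling)
    patient_gain_cv: float = 0.4
    channel_gain_cv: float = 0.2
    noise_sd: float = 0.4
    surge: float = 2.0
    cross_surge: float = 5.0
    delta_boost: float = 1.8
    source_amplitude: float = 1.0
    amplitude_ratio: float = 5.0
    ez_region_count_range: tuple[int, int] = (5, 31)
    seed: int = 0

    @classmethod
    def scalp_default(cls, **overrides) -> "SimulationConfig":
        base = dict(
            modality="scalp",
            sampling_rate=500.0,
            patient_gain_cv=0.16,
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        self.coupling.validate()
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.state not in ("ictal", "interictal"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.modality not in ("seeg", "scalp"):
            raise ValueError(f"unknown modality {self.modality!r}")
        lo, hi = self.ez_count_range
        if lo < 1 or hi < lo:
            raise ValueError("ez_count_range must satisfy 1 <= lo <= hi")
        n = self.epoch_length * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_length x sampling_rate must be an integer")
        if self.amplitude_ratio <= 1.0:
            raise ValueError("amplitude_ratio must exceed 1 (EZ driver must dominate)")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_length * self.sampling_rate))


@dataclass
class Recording:
    """A labeled multichannel epoch (channels x samples).

    ``ez_mask`` marks channels inside the epileptogenic zone.  For scalp
    sensor recordings the ground truth lives in source space instead, so
    ``ez_mask`` is ``None`` and ``ez_region_mask`` marks the EZ parcels.
    """

    patient_id: str
    modality: str
    state: str
    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    ez_mask: Optional[np.ndarray]
    provenance: dict = field(default_factory=dict)
    ez_region_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.ez_mask is not None:
            self.ez_mask = np.asarray(self.ez_mask, dtype=bool)
            if self.ez_mask.size != self.data.shape[0]:
                raise ValueError("ez_mask length must equal channel count")
            if not (self.ez_mask.any() and (~self.ez_mask).any()):
                raise ValueError("need at least one EZ and one NEZ channel")


def _lognormal_gain(rng: np.random.Generator, cv: float, size=None):
    """Log-normal multiplier(s) with mean 1 and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _band_noise(rng, shape, low, high, fs):
    """White noise band-passed into [low, high], unit variance per row."""
    x = bandpass(rng.standard_normal(shape), low, high, fs)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _state_couplings(config: SimulationConfig) -> dict[str, tuple[float, float, float]]:
    """(c_intra_nez, c_intra_ez, c_cross) per band after state adjustment."""
    c = config.coupling
    out = {}
    for name in BAND_NAMES:
        cn, ce, cx = c.c_intra_nez, c.c_intra_ez, c.c_cross
        if config.state == "ictal":
            if name in SURGE_BANDS:
                cn *= config.surge
                ce *= config.surge
                cx *= config.cross_surge
            if name == "delta":
                ce *= config.delta_boost
        out[name] = (cn, ce, cx)
    return out


def _patient_streams(config: SimulationConfig):
    """Per-patient (structure_rng, state_rng) pairs.

    The structure stream (channel count, EZ mask, gains) is shared across
    states, so cohorts from configs differing only in ``state`` are
    matched patient-for-patient — the paired ictal/interictal design.
    """
    root = np.random.SeedSequence(config.seed)
    for ss in root.spawn(config.n_patients):
        structure, interictal, ictal = ss.spawn(3)
        state_ss = ictal if config.state == "ictal" else interictal
        yield np.random.default_rng(structure), np.random.default_rng(state_ss)


def simulate_seeg(config: SimulationConfig) -> list[Recording]:
    """Generate a cohort of SEEG epochs with known EZ/NEZ labels."""
    config.validate()
    if config.modality != "seeg":
        raise ValueError("config.modality must be 'seeg'")
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be positive for SEEG simulation")
    bands = [b for b in default_bands(config.sampling_rate) if b.name != "full"]
    couplings = _state_couplings(config)
    n_samples = config.n_samples
    fs = config.sampling_rate
    recordings = []
    for p, (srng, xrng) in enumerate(_patient_streams(config)):
        ez_lo, ez_hi = config.ez_count_range
        n_ch = int(round(srng.normal(config.channels_mean, config.channels_sd)))
        n_ch = max(n_ch, ez_hi + 2, 4)
        n_ez = min(int(srng.integers(ez_lo, ez_hi + 1)), n_ch - 1)
        ez_mask = np.zeros(n_ch, dtype=bool)
        ez_mask[srng.choice(n_ch, size=n_ez, replace=False)] = True
        gain = _lognormal_gain(srng, config.patient_gain_cv)
        jitter = _lognormal_gain(srng, config.channel_gain_cv, size=n_ch)
        mix = gain * jitter  # per-channel coupling multiplier

        # The full-band signal is the sum of the six narrow-band layers.
        data = np.zeros((n_ch, n_samples))
        for band in bands:
            cn, ce, cx = couplings[band.name]
            s_nez, s_ez = _band_noise(xrng, (2, n_samples), band.low_hz, band.high_hz, fs)
            own_w = np.where(ez_mask, ce, cn) * mix
            own_src = np.where(ez_mask[:, None], s_ez[None, :], s_nez[None, :])
            leak_src = np.where(ez_mask[:, None], s_nez[None, :], s_ez[None, :])
            data += own_w[:, None] * own_src + (cx * mix)[:, None] * leak_src
            data += config.noise_sd * _band_noise(
                xrng, (n_ch, n_samples), band.low_hz, band.high_hz, fs
            )
        recordings.append(
            Recording(
                patient_id=f"P{p + 1:02d}",
                modality="seeg",
                state=config.state,
                data=data,
                sampling_rate=fs,
                channel_labels=[f"ch{i + 1}" for i in range(n_ch)],
                ez_mask=ez_mask,
                provenance={"seed": config.seed, "patient_index": p,
                            "config": asdict(config)},
            )
        )
    return recordings


def simulate_scalp(config: SimulationConfig, source_model) -> list[Recording]:
    """Generate scalp EEG by forward-projecting EZ/NEZ source activity.

    A spatially clustered set of EZ regions hosts a coherent
    high-amplitude delta/theta driver (``amplitude_ratio`` times the
    background); all other sources carry independent low-amplitude
    broadband background.  Sensor data are ``K @ J`` plus sensor noise.
    """
    config.validate()
    if config.modality != "scalp":
        raise ValueError("config.modality must be 'scalp'")
    n_e = source_model.lead_field.shape[0]
    if n_e != config.n_scalp_channels:
        raise ValueError(
            f"source model has {n_e} electrodes, expected {config.n_scalp_channels}"
        )
    fs = config.sampling_rate
    n_samples = config.n_samples
    grid = source_model.source_grid
    n_v = grid.shape[0]
    labels = np.asarray(source_model.parcellation)
    regions = np.asarray(source_model.region_labels)
    centroids = np.stack([grid[labels == r].mean(axis=0) for r in regions])

    recordings = []
    for p, (srng, xrng) in enumerate(_patient_streams(config)):
        lo, hi = config.ez_region_count_range
        n_ez_regions = int(srng.integers(lo, min(hi, len(regions) - 1) + 1))
        seed_region = int(srng.integers(len(regions)))
        order = np.argsort(np.linalg.norm(centroids - centroids[seed_region], axis=1))
        ez_region_mask = np.zeros(len(regions), dtype=bool)
        ez_region_mask[order[:n_ez_regions]] = True
        ez_source_mask = np.isin(labels, regions[ez_region_mask])

        gain = _lognormal_gain(srng, config.patient_gain_cv)
        # Radial dipole orientations: cortical generators are approximately
        # surface-normal, which in a spherical geometry means radial.
        norms = np.linalg.norm(grid, axis=1, keepdims=True)
        orient = np.divide(grid, norms, out=np.tile([[0.0, 0.0, 1.0]], (n_v, 1)),
                           where=norms > 0)

        # Coherent delta/theta driver shared by all EZ sources.
        driver = _band_noise(xrng, (1, n_samples), 0.5, 8.0, fs)[0]
        background = _band_noise(
            xrng, (n_v, n_samples), 0.5, NYQUIST_CAP * fs, fs
        )
        amp = config.source_amplitude * gain * np.where(
            ez_source_mask, config.amplitude_ratio, 1.0
        )
        moments = amp[:, None] * np.where(
            ez_source_mask[:, None], driver[None, :], background
        )
        j = (orient[:, :, None] * moments[:, None, :]).reshape(3 * n_v, n_samples)
        phi = source_model.lead_field @ j
        if config.noise_sd > 0:
            phi = phi + config.noise_sd * xrng.standard_normal(phi.shape)
        recordings.append(
            Recording(
                patient_id=f"P{p + 1:02d}",
                modality="scalp",
                state=config.state,
                data=phi,
                sampling_rate=fs,
                channel_labels=list(source_model.electrode_labels),
                ez_mask=None,
                ez_region_mask=ez_region_mask,
                provenance={"seed": config.seed, "patient_index": p,
                            "ez_source_mask": ez_source_mask.tolist(),
                            "config": asdict(config)},
            )
        )
    return recordings
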