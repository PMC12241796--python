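"""Seeded synthetic two-group evoked-potential generator.

Generates stimulus-locked single-channel epochs with the statistical
structure the downstream analyses assume:

* a deterministic evoked template — a sum of Gaussian-shaped components at
  stereotyped post-stimulus latencies (N1 ~18 ms, P1 ~40 ms, N2 ~66 ms,
  P2 ~98 ms, P3 ~272 ms);
* trial-level latency and amplitude jitter of each component;
* spectrally shaped ("power-law", amplitude proportional to f^(-chi/2))
  background noise rescaled to a target per-trial standard deviation;
* an ongoing band-limited oscillation whose phase is random before the
  stimulus and, for a configurable fraction of trials, resets to a common
  phase from a configurable post-stimulus time onward (the mechanism that
  produces an inter-trial phase-coherence rise);
* between-participant heterogeneity as a lognormal multiplier on the noise
  scale.

All outputs are pure functions of (configuration, seed). The default
design mirrors a two-group somatosensory stimulation study: 19
participants per group, 75 stimulation trials, 500 Hz sampling,
-200..+500 ms epochs, with the patient-like ("TS") group given a larger
noise scale, a flatter spectral exponent, and a weaker, delayed phase
reset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .epochs import (
    CLINICAL_COLUMNS,
    DomainError,
    EpochSet,
    GroupDataset,
    baseline_correct,
)

__all__ = [
    "ComponentSpec",
    "NoiseSpec",
    "PhaseResetSpec",
    "GroupSimConfig",
    "DEFAULT_COMPONENTS",
    "default_sim_configs",
    "gen_background_noise",
    "gen_evoked_template",
    "gen_participant_epochs",
    "gen_clinical_table",
    "gen_group_dataset",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One Gaussian-shaped evoked component.

    ``amplitude_uv`` is signed (negative for N components); ``width_ms`` is
    the Gaussian SD. Jitter SDs control trial-to-trial variability of the
    component's latency and amplitude.
    """

    name: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float
    latency_jitter_sd_ms: float = 0.0
    amplitude_jitter_sd_uv: float = 0.0

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise DomainError("component width must be positive")
        if self.latency_jitter_sd_ms < 0 or self.amplitude_jitter_sd_uv < 0:
            raise DomainError("jitter SDs must be non-negative")


#: Default component set. Latencies and the per-trial latency jitter SDs
#: follow the stereotyped component times (and their observed across-trial
#: timing variability) for median-nerve SEPs at a centro-parietal electrode;
#: amplitudes and widths are free parameters chosen to give realistic
#: single-trial signal-to-noise.
DEFAULT_COMPONENTS: tuple[ComponentSpec, ...] = (
    ComponentSpec("N1", 18.0, 4.0, -2.5, 1.6, 0.5),
    ComponentSpec("P1", 40.0, 8.0, 3.0, 2.0, 0.6),
    ComponentSpec("N2", 66.0, 10.0, -3.5, 2.9, 0.7),
    ComponentSpec("P2", 98.0, 12.0, 5.0, 3.3, 1.0),
    ComponentSpec("P3", 272.0, 30.0, 3.5, 6.5, 0.7),
)


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise model: per-trial SD (uV) and spectral exponent chi.

    Noise is synthesised in the frequency domain with amplitude
    proportional to ``f**(-chi/2)`` (so power falls as ``f**-chi``);
    ``chi = 0`` gives white noise.
    """

    sigma_uv: float = 4.0
    chi: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma_uv < 0 or self.chi < 0:
            raise DomainError("noise sigma and chi must be non-negative")


@dataclass(frozen=True)
class PhaseResetSpec:
    """Ongoing oscillation with partial post-stimulus phase reset.

    ``post_alignment`` is the fraction of trials whose oscillation phase
    locks to a common phase from ``reset_time_ms`` onward; the rest keep
    their trial-specific random phase throughout.
    """

    carrier_hz: float = 10.0
    pre_amp_uv: float = 2.0
    post_alignment: float = 0.85
    reset_time_ms: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.post_alignment <= 1.0:
            raise DomainError("post_alignment must lie in [0, 1]")
        if self.carrier_hz <= 0 or self.pre_amp_uv < 0:
            raise DomainError("carrier frequency must be positive, amplitude non-negative")


@dataclass(frozen=True)
class GroupSimConfig:
    """Full per-group simulation configuration."""

    group: str = "HC"
    n_participants: int = 19
    n_trials: int = 75
    fs: float = 500.0
    t_start_ms: float = -200.0
    t_end_ms: float = 500.0
    components: tuple[ComponentSpec, ...] = DEFAULT_COMPONENTS
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    phase_reset: PhaseResetSpec = field(default_factory=PhaseResetSpec)
    between_participant_scale_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2 or self.n_trials < 2:
            raise DomainError("need at least 2 participants and 2 trials")
        if self.between_participant_scale_sd < 0:
            raise DomainError("between-participant scale SD must be non-negative")

    @property
    def n_times(self) -> int:
        return int(round((self.t_end_ms - self.t_start_ms) / 1000.0 * self.fs)) + 1

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.n_times) * (1000.0 / self.fs)


def default_sim_configs(seed: int = 0) -> tuple[GroupSimConfig, GroupSimConfig]:
    """Default control-like (HC) and patient-like (TS) study conditions.

    The TS-like group has a 1.5x noise scale, a flatter spectral exponent,
    and a weaker phase reset delayed by 20 ms — the qualitative contrast
    the analysis pipeline is designed to detect.
    """
    hc = GroupSimConfig(
        group="HC",
        noise=NoiseSpec(sigma_uv=4.0, chi=2.0),
        phase_reset=PhaseResetSpec(carrier_hz=10.0, pre_amp_uv=2.0,
                                   post_alignment=0.85, reset_time_ms=5.0),
        seed=seed,
    )
    ts = GroupSimConfig(
        group="TS",
        noise=NoiseSpec(sigma_uv=6.0, chi=1.5),
        phase_reset=PhaseResetSpec(carrier_hz=10.0, pre_amp_uv=2.0,
                                   post_alignment=0.7, reset_time_ms=25.0),
        seed=seed + 10_000,
    )
    return hc, ts


def gen_background_noise(
    n_samples: int, fs: float, spec: NoiseSpec, rng: np.random.Generator,
    oversample: int = 4,
) -> np.ndarray:
    """Spectrally shaped noise: amplitude ~ f^(-chi/2), random phases, SD = sigma.

    Synthesised by inverse FFT of a one-sided spectrum with deterministic
    magnitudes and independent uniform phases, then rescaled so the sample
    SD equals ``sigma_uv`` exactly.

    The synthesis runs on a stretch ``oversample`` times the requested
    length and a random excerpt is returned. Epochs cut from a recording
    are excerpts of a continuous process, not signals periodic over the
    epoch; direct epoch-length circular synthesis would concentrate the
    low-frequency power of a steep spectrum in epoch-periodic components
    that baseline correction cannot remove, whereas in an excerpt that
    power appears as slow in-window drift, as in real data.
    """
    if n_samples < 8:
        raise DomainError("need at least 8 samples for spectral synthesis")
    if oversample < 1:
        raise DomainError("oversample factor must be >= 1")
    m = n_samples * oversample
    freqs = np.fft.rfftfreq(m, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-spec.chi / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    x = np.fft.irfft(amp * np.exp(1j * phases), n=m)
    start = int(rng.integers(0, m - n_samples + 1)) if m > n_samples else 0
    x = x[start : start + n_samples]
    sd = x.std()
    if spec.sigma_uv == 0.0 or sd == 0.0:
        return np.zeros(n_samples)
    return x * (spec.sigma_uv / sd)


def gen_evoked_template(
    components: Sequence[ComponentSpec], times_ms: np.ndarray
) -> np.ndarray:
    """Sum of Gaussian components evaluated on the given time axis (ms)."""
    times_ms = np.asarray(times_ms, dtype=float)
    template = np.zeros_like(times_ms)
    for comp in components:
        if not (times_ms[0] <= comp.latency_ms <= times_ms[-1]):
            raise DomainError(
                f"component {comp.name} latency {comp.latency_ms} ms outside time axis"
            )
        template += comp.amplitude_uv * np.exp(
            -((times_ms - comp.latency_ms) ** 2) / (2.0 * comp.width_ms**2)
        )
    return template


def gen_participant_epochs(
    cfg: GroupSimConfig,
    participant_index: int,
    rng: np.random.Generator | None = None,
) -> EpochSet:
    """Generate one participant's baseline-corrected epoch set.

    Each trial is evoked template (with per-trial latency/amplitude jitter
    per component) + background noise + the phase-reset oscillation. The
    participant's noise scale is the configured sigma times a lognormal
    factor with log-SD ``between_participant_scale_sd``.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, participant_index])
    t = cfg.times_ms
    n = cfg.n_times
    scale = float(np.exp(rng.normal(0.0, cfg.between_participant_scale_sd)))
    noise = NoiseSpec(cfg.noise.sigma_uv * scale, cfg.noise.chi)
    pr = cfg.phase_reset
    common_phase = rng.uniform(0.0, 2.0 * np.pi)

    data = np.empty((n, cfg.n_trials))
    for j in range(cfg.n_trials):
        trial = np.zeros(n)
        for comp in cfg.components:
            lat = comp.latency_ms
            if comp.latency_jitter_sd_ms > 0:
                lat += rng.normal(0.0, comp.latency_jitter_sd_ms)
            amp = comp.amplitude_uv
            if comp.amplitude_jitter_sd_uv > 0:
                amp += rng.normal(0.0, comp.amplitude_jitter_sd_uv)
            trial += amp * np.exp(-((t - lat) ** 2) / (2.0 * comp.width_ms**2))
        trial += gen_background_noise(n, cfg.fs, noise, rng)
        if pr.pre_amp_uv > 0:
            phi = rng.uniform(0.0, 2.0 * np.pi)
            osc = pr.pre_amp_uv * np.cos(2.0 * np.pi * pr.carrier_hz * t / 1000.0 + phi)
            if rng.random() < pr.post_alignment:
                post = t >= pr.reset_time_ms
                osc[post] = pr.pre_amp_uv * np.cos(
                    2.0 * np.pi * pr.carrier_hz * (t[post] - pr.reset_time_ms) / 1000.0
                    + common_phase
                )
            trial += osc
        data[:, j] = trial

    es = EpochSet(
        data=data,
        fs=cfg.fs,
        t_start_ms=cfg.t_start_ms,
        t_end_ms=cfg.t_end_ms,
        participant_id=f"{cfg.group}{participant_index + 1:02d}",
        group=cfg.group,
    )
    return baseline_correct(es)


def gen_clinical_table(
    n: int, rng: np.random.Generator, prefix: str = "TS"
) -> pd.DataFrame:
    """Synthetic clinical covariates within realistic adult-cohort ranges.

    Ages span 19-54 years, IQ (WASI) 80-128, premonitory-urge scores
    (PUTS-R) 16-80, and tic-severity (YGTSS) subscores chosen so the total
    falls within 14-81. Sex is balanced.
    """
    age = rng.integers(19, 55, n)
    sex = rng.permutation(np.array(["F", "M"] * ((n + 1) // 2))[:n])
    ehi = rng.integers(40, 101, n)
    wasi = rng.integers(80, 129, n)
    puts_r = rng.integers(16, 81, n)
    motor = rng.integers(5, 26, n)
    vocal = rng.integers(2, 21, n)
    impair = np.minimum(rng.integers(10, 41, n), 81 - motor - vocal)
    total = motor + vocal + impair
    return pd.DataFrame(
        {
            "participant_id": [f"{prefix}{i + 1:02d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "ehi": ehi,
            "wasi": wasi,
            "puts_r": puts_r,
            "ygtss_motor": motor,
            "ygtss_vocal": vocal,
            "ygtss_impairment": impair,
            "ygtss_total": total,
        }
    )[list(CLINICAL_COLUMNS)]


def gen_group_dataset(cfg_hc: GroupSimConfig, cfg_ts: GroupSimConfig) -> GroupDataset:
    """Generate both groups plus a synthetic clinical table for the TS group."""
    participants: list[EpochSet] = []
    for cfg in (cfg_hc, cfg_ts):
        for i in range(cfg.n_participants):
            participants.append(gen_participant_epochs(cfg, i))
    clin_rng = np.random.default_rng([cfg_ts.seed, 777])
    clinical = gen_clinical_table(cfg_ts.n_participants, clin_rng, prefix=cfg_ts.group)
    return GroupDataset(participants=participants, clinical=clinical)
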