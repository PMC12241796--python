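"""Inter-trial phase coherence (ITPC).

Instantaneous phase is extracted by complex Morlet wavelet convolution
(default 5 cycles, 1 Hz grid within each band). ITPC at a
(frequency, time) point is the modulus of the across-trial mean unit
phasor, |1/N sum exp(i phi)|, in [0, 1]; band values average over the
band's frequency grid. Raw ITPC is reported without chance-level
correction (the trial count is carried alongside so users can correct:
for uniform phases the expected resultant is ~ sqrt(pi) / (2 sqrt(N))).

Edge handling: wavelets are truncated at +-3 Gaussian SDs; samples closer
to an epoch edge than one wavelet half-length are flagged unreliable. A
frequency whose wavelet outgrows the epoch raises a domain error — with
700 ms epochs and 5 cycles this excludes the theta band, so band-level
helpers skip (with a warning) bands that do not fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .epochs import DomainError, EpochSet

__all__ = [
    "BandDefinition",
    "ItpcCurve",
    "THETA",
    "ALPHA",
    "BETA",
    "LOW_GAMMA",
    "DEFAULT_BANDS",
    "ANALYSIS_BANDS",
    "morlet_wavelet",
    "trial_phases",
    "itpc",
    "band_itpc",
    "prepost_means",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise DomainError("band bounds must satisfy 0 < f_lo < f_hi")

    def freq_grid(self, step: float = 1.0) -> np.ndarray:
        return np.arange(self.f_lo, self.f_hi + step / 2.0, step)


THETA = BandDefinition("theta", 4.0, 7.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 13.0, 30.0)
LOW_GAMMA = BandDefinition("low_gamma", 31.0, 45.0)

#: All bands of interest (theta requires epochs longer than ~700 ms at the
#: default 5 wavelet cycles and is skipped by band-level helpers when it
#: does not fit).
DEFAULT_BANDS: tuple[BandDefinition, ...] = (THETA, ALPHA, BETA, LOW_GAMMA)

#: The bands entering the pre/post-stimulus coherence analysis.
ANALYSIS_BANDS: tuple[BandDefinition, ...] = (ALPHA, BETA, LOW_GAMMA)


def morlet_wavelet(freq: float, fs: float, cycles: float = 5.0,
                   truncate_sd: float = 3.0) -> np.ndarray:
    """Complex Morlet wavelet at ``freq`` Hz, truncated at ``truncate_sd`` SDs."""
    if freq <= 0:
        raise DomainError("wavelet frequency must be positive")
    sd_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(truncate_sd * sd_t * fs))
    t = np.arange(-half, half + 1) / fs
    return np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sd_t**2))


def trial_phases(
    es: EpochSet, freqs: Sequence[float], cycles: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase per trial, frequency, and time point.

    Returns ``(phases, reliable)`` with shapes
    ``(n_trials, n_freqs, n_times)`` and ``(n_freqs, n_times)``; the
    boolean ``reliable`` mask is False within one wavelet half-length of
    either epoch edge.
    """
    if cycles < 3:
        raise DomainError("wavelet must have at least 3 cycles")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= es.fs / 2.0):
        raise DomainError("wavelet frequencies must lie below Nyquist")
    n_times = es.n_times
    phases = np.empty((es.n_trials, freqs.size, n_times))
    reliable = np.zeros((freqs.size, n_times), dtype=bool)
    for j, f in enumerate(freqs):
        w = morlet_wavelet(f, es.fs, cycles)
        if w.size > n_times:
            raise DomainError(
                f"wavelet at {f:g} Hz ({w.size} samples) is longer than the "
                f"epoch ({n_times} samples); use a longer epoch or fewer cycles"
            )
        conv = sp_signal.fftconvolve(es.data, w[:, None], mode="same", axes=0)
        phases[:, j, :] = np.angle(conv).T
        half = w.size // 2
        reliable[j, half : n_times - half] = True
    return phases, reliable


def itpc(phases: np.ndarray) -> np.ndarray:
    """Resultant length of the across-trial mean unit phasor.

    ``phases`` has shape ``(n_trials, ...)``; at least two trials are
    required (a single trial is trivially 1).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.shape[0] < 2:
        raise DomainError("ITPC requires at least two trials")
    return np.abs(np.exp(1j * phases).mean(axis=0))


@dataclass
class ItpcCurve:
    """Band-averaged ITPC time courses for one participant."""

    times_ms: np.ndarray
    n_trials: int
    bands: tuple[BandDefinition, ...]
    values: Mapping[str, np.ndarray]     # band name -> ITPC per time point
    reliable: Mapping[str, np.ndarray]   # band name -> bool per time point
    participant_id: str = ""


def band_itpc(
    es: EpochSet,
    bands: Sequence[BandDefinition] = ANALYSIS_BANDS,
    cycles: float = 5.0,
    freq_step: float = 1.0,
    strict: bool = False,
) -> ItpcCurve:
    """Band-averaged ITPC curves on a 1 Hz grid within each band.

    Bands whose lowest-frequency wavelet does not fit the epoch are
    skipped with a warning unless ``strict`` is set.
    """
    values: dict[str, np.ndarray] = {}
    reliable: dict[str, np.ndarray] = {}
    kept: list[BandDefinition] = []
    for band in bands:
        try:
            phases, rel = trial_phases(es, band.freq_grid(freq_step), cycles)
        except DomainError:
            if strict:
                raise
            warnings.warn(
                f"band {band.name!r} skipped: wavelet at {band.f_lo:g} Hz does "
                f"not fit a {es.n_times}-sample epoch at {cycles:g} cycles",
                stacklevel=2,
            )
            continue
        values[band.name] = itpc(phases).mean(axis=0)
        reliable[band.name] = rel.all(axis=0)
        kept.append(band)
    return ItpcCurve(
        times_ms=es.times_ms,
        n_trials=es.n_trials,
        bands=tuple(kept),
        values=values,
        reliable=reliable,
        participant_id=es.participant_id,
    )


def prepost_means(
    curve: ItpcCurve,
    pre: tuple[float, float] = (-50.0, 0.0),
    post: tuple[float, float] = (0.0, 100.0),
) -> pd.DataFrame:
    """Mean ITPC in the pre-stimulus and post-stimulus windows per band.

    The pre window is half-open ``[lo, hi)`` (stimulus onset is
    post-stimulus); the post window is closed. Window means use reliable
    (non-edge) samples when any exist; a window made entirely of flagged
    samples falls back to all its samples, with a warning (edge smoothing
    biases the pre window upward, making a post > pre contrast
    conservative).
    """
    t = curve.times_ms
    rows = []
    for band in curve.bands:
        vals = curve.values[band.name]
        rel = curve.reliable[band.name]
        means = {}
        for label, (lo, hi), closed_right in (("pre", pre, False), ("post", post, True)):
            mask = (t >= lo) & ((t <= hi) if closed_right else (t < hi))
            if not mask.any():
                raise DomainError(f"{label} window {(lo, hi)} contains no samples")
            sel = mask & rel
            if not sel.any():
                warnings.warn(
                    f"{label} window for band {band.name!r} lies entirely in the "
                    "wavelet edge region; using all its samples",
                    stacklevel=2,
                )
                sel = mask
            elif (mask & ~rel).any():
                warnings.warn(
                    f"{label} window for band {band.name!r} partially overlaps the "
                    "wavelet edge region; using the reliable subset",
                    stacklevel=2,
                )
            means[label] = float(vals[sel].mean())
        rows.append(
            {
                "band": band.name,
                "pre": means["pre"],
                "post": means["post"],
                "post_minus_pre": means["post"] - means["pre"],
            }
        )
    return pd.DataFrame(rows)
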