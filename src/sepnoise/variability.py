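"""Trial-by-trial variability metrics.

Pointwise across-trial standard deviation curves (raw and after per-trial
Z-scoring) and the epoch-wise median coefficient of variation (CV) — the
operationalisation of sensorimotor neural noise this package quantifies.

Conventions: sample (n-1) standard deviations throughout; the CV
denominator is the absolute across-trial mean, with near-zero-mean points
(|mean| < 1e-9 uV) flagged undefined (NaN) and excluded from window
medians. Each trial is Z-scored over the full epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .epochs import DomainError, EpochSet, QCError

__all__ = [
    "VariabilityCurve",
    "DEFAULT_CV_WINDOWS",
    "cv_window_label",
    "pointwise_sd",
    "zscore_trials",
    "cv_curve",
    "epoch_median_cv",
]

#: The four 100 ms analysis epochs spanning -200..+200 ms around stimulus
#: onset. Windows are closed intervals on the sample grid; the fourth is
#: kept one sample longer than the others, exactly as conventionally
#: printed ("100-200 ms"), rather than regularised.
DEFAULT_CV_WINDOWS: tuple[tuple[float, float], ...] = (
    (-200.0, -101.0),
    (-100.0, -1.0),
    (0.0, 99.0),
    (100.0, 200.0),
)


def cv_window_label(window: tuple[float, float]) -> str:
    return f"{window[0]:g}..{window[1]:g}"


@dataclass
class VariabilityCurve:
    """Per-time-point variability values on the epoch's time axis."""

    values: np.ndarray
    times_ms: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.shape != self.times_ms.shape:
            raise DomainError("variability values and time axis lengths differ")


def pointwise_sd(es: EpochSet) -> VariabilityCurve:
    """Sample SD across trials at each time point."""
    if es.n_trials < 2:
        raise DomainError("pointwise SD requires at least two trials")
    return VariabilityCurve(
        values=es.data.std(axis=1, ddof=1),
        times_ms=es.times_ms,
        participant_id=es.participant_id,
    )


def zscore_trials(es: EpochSet) -> tuple[EpochSet, list[int]]:
    """Standardise each trial over the full epoch (mean 0, SD 1).

    Degenerate (constant) trials cannot be standardised; they are dropped
    and their indices returned alongside the standardised epoch set.
    """
    means = es.data.mean(axis=0, keepdims=True)
    sds = es.data.std(axis=0, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sds[0] == 0.0)
    keep = sds[0] > 0.0
    if not keep.any():
        raise QCError(f"all trials are constant for participant {es.participant_id!r}")
    if degenerate.size:
        warnings.warn(
            f"dropped {degenerate.size} constant trial(s) during Z-scoring "
            f"for participant {es.participant_id!r}",
            stacklevel=2,
        )
    z = (es.data[:, keep] - means[:, keep]) / sds[:, keep]
    return replace(es, data=z), [int(i) for i in degenerate]


def cv_curve(es: EpochSet, eps: float = 1e-9) -> np.ndarray:
    """Coefficient of variation (SD / |mean|) across trials per time point.

    Points whose across-trial mean magnitude falls below ``eps`` are
    returned as NaN (undefined) and excluded from downstream medians.
    """
    if es.n_trials < 2:
        raise DomainError("CV requires at least two trials")
    mean = es.data.mean(axis=1)
    sd = es.data.std(axis=1, ddof=1)
    cv = np.full(mean.shape, np.nan)
    defined = np.abs(mean) >= eps
    cv[defined] = sd[defined] / np.abs(mean[defined])
    return cv


def epoch_median_cv(
    es: EpochSet,
    windows: tuple[tuple[float, float], ...] = DEFAULT_CV_WINDOWS,
) -> pd.Series:
    """Median of the defined per-time-point CV values within each window.

    A window whose CV values are all undefined yields NaN (flagged with a
    warning) rather than a silent zero.
    """
    t = es.times_ms
    cv = cv_curve(es)
    out = {}
    for window in windows:
        lo, hi = window
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            raise DomainError(f"CV window {window} lies outside the epoch span")
        mask = (t >= lo) & (t <= hi)
        vals = cv[mask]
        defined = vals[~np.isnan(vals)]
        if defined.size == 0:
            warnings.warn(
                f"CV undefined at every point of window {window} for "
                f"participant {es.participant_id!r}",
                stacklevel=2,
            )
            out[cv_window_label(window)] = np.nan
        else:
            out[cv_window_label(window)] = float(np.median(defined))
    return pd.Series(out, name=es.participant_id or "median_cv")
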