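"""Stimulus-locked EEG epoch handling.

Containers and entry-stage operations for single-channel, stimulus-locked
epoch matrices (time x trials, microvolts): plain-text I/O with a JSON
metadata sidecar, automatic artifact rejection (absolute amplitude and
voltage-step criteria), baseline correction, and a minimum-trial-count
quality gate.

Conventions
-----------
* The time axis is ``t = t_start_ms + k * (1000 / fs)`` for sample index
  ``k``; both endpoints are included when the epoch span is an exact
  multiple of the sample period (e.g. 351 samples for -200..+500 ms at
  500 Hz).
* The baseline window is half-open ``[-200, 0)`` ms, so the sample at
  stimulus onset counts as post-stimulus.
* The voltage-step criterion is evaluated on consecutive samples as
  ``|dv| / dt`` with ``dt = 1000 / fs`` ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "CLINICAL_COLUMNS",
    "DomainError",
    "EpochFormatError",
    "QCError",
    "EpochSet",
    "RejectionReport",
    "ClinicalRecord",
    "GroupDataset",
    "baseline_correct",
    "reject_artifacts",
    "require_min_trials",
    "read_epochs",
    "write_epochs",
    "read_clinical",
    "write_clinical",
]

GROUPS = ("HC", "TS")

CLINICAL_COLUMNS = (
    "participant_id",
    "age",
    "sex",
    "ehi",
    "wasi",
    "puts_r",
    "ygtss_motor",
    "ygtss_vocal",
    "ygtss_impairment",
    "ygtss_total",
)


class DomainError(ValueError):
    """An operation was asked to work outside its valid input domain."""


class EpochFormatError(ValueError):
    """An epoch file or its metadata sidecar is malformed or inconsistent."""


class QCError(RuntimeError):
    """A participant's data failed a quality-control gate."""


@dataclass(frozen=True)
class RejectionReport:
    """Accounting of an artifact-rejection pass over one epoch set."""

    n_input: int
    n_rejected_amplitude: int
    n_rejected_step: int
    n_rejected_manual: int
    kept_indices: tuple[int, ...]

    @property
    def n_kept(self) -> int:
        return len(self.kept_indices)

    @property
    def n_rejected(self) -> int:
        return self.n_rejected_amplitude + self.n_rejected_step + self.n_rejected_manual


@dataclass
class EpochSet:
    """Single-channel stimulus-locked epochs.

    Parameters
    ----------
    data
        Voltages in microvolts, shape ``(n_times, n_trials)``. A 1-D array
        is promoted to a single-trial column.
    fs
        Sampling rate in Hz.
    t_start_ms, t_end_ms
        Time of the first / last sample relative to stimulus onset (ms).
        The epoch must straddle onset (``t_start_ms < 0 < t_end_ms``).
    channel, participant_id, group
        Metadata carried through the pipeline; ``group`` is ``"HC"`` or
        ``"TS"``.
    """

    data: np.ndarray
    fs: float = 500.0
    t_start_ms: float = -200.0
    t_end_ms: float = 500.0
    channel: str = "CP3"
    participant_id: str = ""
    group: str = "HC"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
        if data.ndim != 2:
            raise EpochFormatError("epoch data must be a 2-D time x trials matrix")
        if data.shape[1] < 1:
            raise EpochFormatError("epoch set must contain at least one trial")
        if not np.all(np.isfinite(data)):
            raise EpochFormatError("epoch data contain non-finite values")
        if self.fs <= 0:
            raise DomainError("sampling rate must be positive")
        if not (self.t_start_ms < 0.0 < self.t_end_ms):
            raise DomainError("epoch must straddle stimulus onset (t_start < 0 < t_end)")
        expected = int(round((self.t_end_ms - self.t_start_ms) / 1000.0 * self.fs)) + 1
        if data.shape[0] != expected:
            raise EpochFormatError(
                f"epoch matrix has {data.shape[0]} rows but the declared span "
                f"{self.t_start_ms}..{self.t_end_ms} ms at {self.fs} Hz implies {expected}"
            )
        if self.group not in GROUPS:
            raise DomainError(f"group must be one of {GROUPS}, got {self.group!r}")
        self.data = data

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.n_times) * (1000.0 / self.fs)

    def sample_mask(self, lo_ms: float, hi_ms: float, include_right: bool = True) -> np.ndarray:
        """Boolean mask of samples with ``lo_ms <= t <= hi_ms`` (or ``< hi_ms``)."""
        t = self.times_ms
        if include_right:
            return (t >= lo_ms) & (t <= hi_ms)
        return (t >= lo_ms) & (t < hi_ms)


def baseline_correct(es: EpochSet, window: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract each trial's mean over the baseline window from the whole trial.

    The window is half-open ``[lo, hi)`` so the stimulus-onset sample is
    excluded from the baseline. Idempotent.
    """
    lo, hi = window
    t = es.times_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise DomainError(f"baseline window {window} lies outside the epoch span")
    mask = es.sample_mask(lo, hi, include_right=False)
    if mask.sum() < 2:
        raise DomainError("baseline window must contain at least two samples")
    corrected = es.data - es.data[mask].mean(axis=0, keepdims=True)
    return replace(es, data=corrected)


def reject_artifacts(
    es: EpochSet,
    amp_limit: float = 100.0,
    step_limit: float = 50.0,
    manual_exclude: Iterable[int] | None = None,
) -> tuple[EpochSet, RejectionReport]:
    """Drop trials exceeding amplitude or voltage-step limits.

    A trial is rejected if any sample satisfies ``|v| > amp_limit`` (uV) or
    any consecutive-sample difference satisfies ``|dv| / dt > step_limit``
    (uV/ms, ``dt = 1000 / fs``). Trials failing both criteria are counted
    under the amplitude criterion only, so the report's counts partition
    the input. An optional ``manual_exclude`` list of trial indices stands
    in for the manual vetoes of a semi-automatic inspection.
    """
    if amp_limit <= 0 or step_limit <= 0:
        raise DomainError("rejection limits must be positive")
    dt_ms = 1000.0 / es.fs
    amp_bad = np.any(np.abs(es.data) > amp_limit, axis=0)
    step_bad = np.any(np.abs(np.diff(es.data, axis=0)) / dt_ms > step_limit, axis=0)
    manual = np.zeros(es.n_trials, dtype=bool)
    if manual_exclude is not None:
        idx = np.asarray(list(manual_exclude), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= es.n_trials):
            raise DomainError("manual exclusion index out of range")
        manual[idx] = True
    keep = ~(amp_bad | step_bad | manual)
    kept_indices = tuple(int(i) for i in np.flatnonzero(keep))
    if not kept_indices:
        raise QCError(
            f"no usable trials remain for participant {es.participant_id!r} after rejection"
        )
    report = RejectionReport(
        n_input=es.n_trials,
        n_rejected_amplitude=int(amp_bad.sum()),
        n_rejected_step=int((step_bad & ~amp_bad).sum()),
        n_rejected_manual=int((manual & ~amp_bad & ~step_bad).sum()),
        kept_indices=kept_indices,
    )
    return replace(es, data=es.data[:, keep]), report


def require_min_trials(es: EpochSet, minimum: int = 50) -> EpochSet:
    """Pass the epoch set through unchanged if it has at least ``minimum`` trials."""
    if minimum < 1:
        raise DomainError("minimum trial count must be >= 1")
    if es.n_trials < minimum:
        raise QCError(
            f"participant {es.participant_id!r} has {es.n_trials} trials, "
            f"below the required minimum of {minimum}"
        )
    return es


# ---------------------------------------------------------------------------
# Text I/O: CSV matrix (rows = time points, columns = trials) + JSON sidecar.
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_epochs(es: EpochSet, path: str | Path) -> Path:
    """Write an epoch matrix as delimited text plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, es.data, delimiter=",", fmt="%.17g")
    meta = {
        "fs_hz": es.fs,
        "t_start_ms": es.t_start_ms,
        "t_end_ms": es.t_end_ms,
        "channel": es.channel,
        "participant_id": es.participant_id,
        "group": es.group,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Read an epoch matrix written by :func:`write_epochs`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise EpochFormatError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise EpochFormatError(f"malformed sidecar {sidecar}: {exc}") from exc
    try:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise EpochFormatError(f"could not parse epoch matrix {path}: {exc}") from exc
    try:
        return EpochSet(
            data=data,
            fs=float(meta["fs_hz"]),
            t_start_ms=float(meta["t_start_ms"]),
            t_end_ms=float(meta["t_end_ms"]),
            channel=str(meta.get("channel", "CP3")),
            participant_id=str(meta.get("participant_id", path.stem)),
            group=str(meta.get("group", "HC")),
        )
    except KeyError as exc:
        raise EpochFormatError(f"sidecar {sidecar} is missing key {exc}") from exc


# ---------------------------------------------------------------------------
# Clinical covariates (one row per participant).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalRecord:
    """Per-participant clinical covariates used as regression predictors."""

    participant_id: str
    age: float
    sex: str  # "F" or "M"
    ehi: float
    wasi: float
    puts_r: float
    ygtss_motor: float
    ygtss_vocal: float
    ygtss_impairment: float
    ygtss_total: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise DomainError(f"sex must be 'F' or 'M', got {self.sex!r}")
        for name in ("age", "ehi", "wasi", "puts_r", "ygtss_motor",
                     "ygtss_vocal", "ygtss_impairment", "ygtss_total"):
            if not np.isfinite(getattr(self, name)):
                raise DomainError(f"clinical score {name} must be finite")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical covariate table, validating columns and sex codes."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise EpochFormatError(f"clinical table {path} lacks columns {missing}")
    bad_sex = set(df["sex"].unique()) - {"F", "M"}
    if bad_sex:
        raise EpochFormatError(f"clinical table has invalid sex codes {sorted(bad_sex)}")
    return df[list(CLINICAL_COLUMNS)].copy()


def write_clinical(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[list(CLINICAL_COLUMNS)].to_csv(path, index=False)
    return path


@dataclass
class GroupDataset:
    """A collection of per-participant epoch sets plus clinical covariates."""

    participants: list[EpochSet] = field(default_factory=list)
    clinical: pd.DataFrame | None = None

    def by_group(self, group: str) -> list[EpochSet]:
        return [p for p in self.participants if p.group == group]

    @property
    def ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]
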