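"""Pipeline orchestration: configuration, per-group analysis, group comparison.

``run_analyze`` takes a directory of epoch CSVs (plus JSON sidecars and an
optional ``clinical.csv``), applies artifact rejection, baseline
correction and the minimum-trial gate, computes every per-participant
metric (SEP, SD and Z-scored SD curves, median CV per epoch window,
Welch PSD and semilog slope, band ITPC pre/post means, derived outcomes),
and writes them as CSVs with a run manifest. ``run_compare`` consumes two
such result directories and produces the group-level outputs: pointwise
effect-size curves with moderate-effect masks, a component timing table,
mixed ANOVAs for CV and coherence, and the clinical regressions.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .epochs import (
    DomainError,
    EpochSet,
    GroupDataset,
    baseline_correct,
    read_clinical,
    read_epochs,
    reject_artifacts,
    require_min_trials,
)
from .itpc import ANALYSIS_BANDS, BandDefinition, band_itpc, prepost_means
from .sep import ComponentWindow, DEFAULT_WINDOWS, participant_sep, trial_latency_stats
from .spectral import band_mean_psd, fit_semilog_slope, welch_psd
from .stats import effect_size_curve, hedges_g, mixed_anova_2way, ols_regression
from .variability import DEFAULT_CV_WINDOWS, epoch_median_cv, pointwise_sd, zscore_trials

__all__ = ["PipelineConfig", "run_analyze", "run_compare"]

#: Clinical predictor columns entering the regressions (sex is coded F=0, M=1).
PREDICTOR_COLUMNS = (
    "age", "sex", "wasi", "puts_r", "ygtss_motor", "ygtss_vocal", "ygtss_impairment",
)

OUTCOME_COLUMNS = (
    "p2_amplitude_uv",
    "alpha_itpc_post_minus_pre",
    "gamma_itpc_post_minus_pre",
    "cv_post_minus_pre",
    "mean_sd_uv",
    "mean_psd_25_45",
)


@dataclass
class PipelineConfig:
    """All tunable analysis parameters in one place."""

    amp_limit_uv: float = 100.0
    step_limit_uv_per_ms: float = 50.0
    min_trials: int = 50
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    component_windows: tuple[ComponentWindow, ...] = DEFAULT_WINDOWS
    cv_windows: tuple[tuple[float, float], ...] = DEFAULT_CV_WINDOWS
    bands: tuple[BandDefinition, ...] = ANALYSIS_BANDS
    itpc_cycles: float = 5.0
    itpc_pre_ms: tuple[float, float] = (-50.0, 0.0)
    itpc_post_ms: tuple[float, float] = (0.0, 100.0)
    psd_band_hz: tuple[float, float] = (1.0, 45.0)
    psd_mean_band_hz: tuple[float, float] = (25.0, 45.0)
    effect_threshold: float = 0.5

    def validate_against(self, es: EpochSet) -> None:
        """Fail fast if any configured window falls outside the epoch span."""
        t0, t1 = es.times_ms[0], es.times_ms[-1]
        windows = [self.baseline_window_ms, self.itpc_pre_ms, self.itpc_post_ms,
                   *self.cv_windows]
        windows += [(w.lo_ms, w.hi_ms) for w in self.component_windows]
        for lo, hi in windows:
            if lo < t0 - 1e-9 or hi > t1 + 1e-9:
                raise DomainError(
                    f"configured window ({lo}, {hi}) ms lies outside the epoch "
                    f"span ({t0}, {t1}) ms"
                )
        if self.psd_band_hz[1] > es.fs / 2 or self.psd_mean_band_hz[1] > es.fs / 2:
            raise DomainError("configured PSD band exceeds the Nyquist frequency")
        if self.effect_threshold <= 0:
            raise DomainError("effect-size threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        simple = {
            "amp_limit_uv", "step_limit_uv_per_ms", "min_trials", "itpc_cycles",
            "effect_threshold",
        }
        pairs = {
            "baseline_window_ms", "itpc_pre_ms", "itpc_post_ms",
            "psd_band_hz", "psd_mean_band_hz",
        }
        for key, value in raw.items():
            if key in simple:
                kwargs[key] = value
            elif key in pairs:
                kwargs[key] = tuple(value)
            elif key == "cv_windows":
                kwargs[key] = tuple(tuple(w) for w in value)
            elif key == "component_windows":
                kwargs[key] = tuple(
                    ComponentWindow(w["name"], w["center_ms"], w["halfwidth_ms"], w["polarity"])
                    for w in value
                )
            elif key == "bands":
                kwargs[key] = tuple(
                    BandDefinition(b["name"], b["f_lo"], b["f_hi"]) for b in value
                )
            else:
                raise DomainError(f"unknown configuration key {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["component_windows"] = [asdict(w) if not isinstance(w, dict) else w
                                  for w in d["component_windows"]]
        d["bands"] = [asdict(b) if not isinstance(b, dict) else b for b in d["bands"]]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def _discover_epoch_files(in_dir: Path) -> list[Path]:
    files = sorted(
        p for p in in_dir.glob("*.csv")
        if p.name != "clinical.csv" and p.with_suffix(".json").exists()
    )
    if not files:
        raise DomainError(f"no epoch CSVs with sidecars found in {in_dir}")
    return files


def _long_curve(participant: str, group: str, abscissa: np.ndarray,
                values: np.ndarray, abscissa_name: str) -> pd.DataFrame:
    return pd.DataFrame(
        {"participant_id": participant, "group": group,
         abscissa_name: abscissa, "value": values}
    )


def run_analyze(
    in_dir: str | Path,
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full per-participant pipeline over one input directory.

    Deterministic given the inputs and configuration. Returns the result
    bundle (a dict of DataFrames) and writes each as CSV under
    ``out_dir`` together with ``manifest.json``.
    """
    cfg = cfg or PipelineConfig()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = _discover_epoch_files(in_dir)

    # Validate configuration against the first participant before any work.
    cfg.validate_against(read_epochs(files[0]))

    sep_rows, sd_rows, zsd_rows, psd_rows = [], [], [], []
    cv_rows, comp_rows, fit_rows, itpc_rows = [], [], [], []
    trial_counts = {}
    cleaned: list[EpochSet] = []
    for f in files:
        es = read_epochs(f)
        pid = es.participant_id
        try:
            es, report = reject_artifacts(es, cfg.amp_limit_uv, cfg.step_limit_uv_per_ms)
            es = baseline_correct(es, cfg.baseline_window_ms)
            es = require_min_trials(es, cfg.min_trials)

            t = es.times_ms
            sep_rows.append(_long_curve(pid, es.group, t, participant_sep(es), "time_ms"))
            sd_rows.append(_long_curve(pid, es.group, t, pointwise_sd(es).values, "time_ms"))
            esz, _ = zscore_trials(es)
            zsd_rows.append(_long_curve(pid, es.group, t, pointwise_sd(esz).values, "time_ms"))

            for label, value in epoch_median_cv(es, cfg.cv_windows).items():
                cv_rows.append({"participant_id": pid, "group": es.group,
                                "window": label, "median_cv": value})

            measures = trial_latency_stats(es, cfg.component_windows)
            summ = measures.summary()
            summ.insert(0, "participant_id", pid)
            summ.insert(1, "group", es.group)
            comp_rows.append(summ)

            fit = fit_semilog_slope(welch_psd(es, cfg.psd_band_hz))
            psd_rows.append(_long_curve(pid, es.group, fit.freqs, fit.psd, "freq_hz"))
            fit_rows.append({
                "participant_id": pid, "group": es.group, "slope": fit.slope,
                "intercept": fit.intercept, "r2": fit.r2,
                "band_mean_psd": band_mean_psd(fit, cfg.psd_mean_band_hz),
            })

            curve = band_itpc(es, cfg.bands, cycles=cfg.itpc_cycles)
            pp = prepost_means(curve, cfg.itpc_pre_ms, cfg.itpc_post_ms)
            pp.insert(0, "participant_id", pid)
            pp.insert(1, "group", es.group)
            itpc_rows.append(pp)

            trial_counts[pid] = {"n_input": report.n_input, "n_kept": report.n_kept,
                                 "n_rejected_amplitude": report.n_rejected_amplitude,
                                 "n_rejected_step": report.n_rejected_step}
            cleaned.append(es)
        except Exception as exc:
            raise type(exc)(f"[stage failure, participant {pid}] {exc}") from exc

    clinical = None
    clinical_path = in_dir / "clinical.csv"
    if clinical_path.exists():
        clinical = read_clinical(clinical_path)

    from .stats import derived_outcomes  # local import avoids cycle at module load
    outcomes = derived_outcomes(
        GroupDataset(cleaned, clinical),
        itpc_pre=cfg.itpc_pre_ms, itpc_post=cfg.itpc_post_ms,
        psd_mean_band=cfg.psd_mean_band_hz, cycles=cfg.itpc_cycles,
    )

    bundle = {
        "sep_curves": pd.concat(sep_rows, ignore_index=True),
        "sd_curves": pd.concat(sd_rows, ignore_index=True),
        "zsd_curves": pd.concat(zsd_rows, ignore_index=True),
        "cv_table": pd.DataFrame(cv_rows),
        "component_stats": pd.concat(comp_rows, ignore_index=True),
        "psd_curves": pd.concat(psd_rows, ignore_index=True),
        "psd_fits": pd.DataFrame(fit_rows),
        "itpc_prepost": pd.concat(itpc_rows, ignore_index=True),
        "outcomes": outcomes,
    }
    for name, df in bundle.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    if clinical is not None:
        clinical.to_csv(out_dir / "clinical.csv", index=False)

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "n_participants": len(files),
        "trial_counts": trial_counts,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=list))
    return bundle


def _curve_matrix(df: pd.DataFrame, abscissa: str) -> tuple[np.ndarray, np.ndarray]:
    wide = df.pivot(index="participant_id", columns=abscissa, values="value")
    return wide.to_numpy(), wide.columns.to_numpy(dtype=float)


def _compare_curves(df_a, df_b, abscissa, threshold):
    mat_a, x_a = _curve_matrix(df_a, abscissa)
    mat_b, x_b = _curve_matrix(df_b, abscissa)
    if x_a.shape != x_b.shape or not np.allclose(x_a, x_b):
        raise DomainError("result bundles do not share an abscissa; configs incompatible")
    curve = effect_size_curve(mat_a, mat_b, threshold=threshold, abscissa=x_a)
    return pd.DataFrame({abscissa: curve.abscissa, "g": curve.g, "mask": curve.mask})


def run_compare(
    dir_hc: str | Path,
    dir_ts: str | Path,
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Compare two analyzed result bundles (control first, by convention)."""
    cfg = cfg or PipelineConfig()
    dir_hc, dir_ts, out_dir = Path(dir_hc), Path(dir_ts), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def load(d: Path, name: str) -> pd.DataFrame:
        path = d / f"{name}.csv"
        if not path.exists():
            raise DomainError(f"missing analysis output {path}")
        return pd.read_csv(path)

    bundle: dict[str, pd.DataFrame] = {}
    for name, abscissa in (("sep_curves", "time_ms"), ("sd_curves", "time_ms"),
                           ("zsd_curves", "time_ms"), ("psd_curves", "freq_hz")):
        bundle[f"effect_{name}"] = _compare_curves(
            load(dir_hc, name), load(dir_ts, name), abscissa, cfg.effect_threshold
        )

    # Component timing table: group means/SDs of per-participant summaries + G.
    comp_a = load(dir_hc, "component_stats")
    comp_b = load(dir_ts, "component_stats")
    rows = []
    for comp in comp_a["component"].unique():
        row = {"component": comp}
        for metric in ("mean_latency_ms", "sd_latency_ms", "mean_amplitude_uv"):
            a = comp_a.loc[comp_a["component"] == comp, metric].to_numpy()
            b = comp_b.loc[comp_b["component"] == comp, metric].to_numpy()
            row[f"hc_mean_{metric}"] = a.mean()
            row[f"hc_sd_{metric}"] = a.std(ddof=1)
            row[f"ts_mean_{metric}"] = b.mean()
            row[f"ts_sd_{metric}"] = b.std(ddof=1)
            try:
                row[f"g_{metric}"] = hedges_g(
                    a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
                )
            except DomainError:
                row[f"g_{metric}"] = np.nan
        rows.append(row)
    bundle["component_table"] = pd.DataFrame(rows)

    def load_tagged(d: Path, name: str, tag: str) -> pd.DataFrame:
        df = load(d, name)
        # distinct subject keys per side, so self-comparisons and id clashes
        # cannot collapse distinct subjects in the repeated-measures pivots
        df = df.assign(participant_id=tag + ":" + df["participant_id"].astype(str))
        return df

    # Mixed ANOVA on median CV (Group x Epoch window).
    cv = pd.concat([load_tagged(dir_hc, "cv_table", "a"),
                    load_tagged(dir_ts, "cv_table", "b")])
    wide = cv.pivot(index="participant_id", columns="window", values="median_cv")
    order = [w for w in cv["window"].unique() if w in wide.columns]
    wide = wide[order]
    group_of = cv.drop_duplicates("participant_id").set_index("participant_id")["group"]
    try:
        bundle["anova_cv"] = mixed_anova_2way(
            wide.to_numpy(), group_of.loc[wide.index].to_numpy(), within_labels=order
        )
    except DomainError as exc:
        warnings.warn(f"CV ANOVA skipped: {exc}", stacklevel=2)

    # Mixed ANOVA per band on ITPC (Group x Period).
    pp = pd.concat([load_tagged(dir_hc, "itpc_prepost", "a"),
                    load_tagged(dir_ts, "itpc_prepost", "b")])
    anova_rows = []
    try:
        for band in pp["band"].unique():
            sub = pp[pp["band"] == band]
            mat = sub.set_index("participant_id")[["pre", "post"]]
            grp = sub.set_index("participant_id")["group"]
            tab = mixed_anova_2way(mat.to_numpy(), grp.loc[mat.index].to_numpy(),
                                   within_labels=["pre", "post"])
            tab.insert(0, "band", band)
            anova_rows.append(tab)
        bundle["anova_itpc"] = pd.concat(anova_rows, ignore_index=True)
    except DomainError as exc:
        warnings.warn(f"coherence ANOVA skipped: {exc}", stacklevel=2)

    # Clinical regressions on the TS group, when a clinical table is present.
    clinical_path = dir_ts / "clinical.csv"
    if clinical_path.exists():
        clinical = read_clinical(clinical_path)
        outcomes = load(dir_ts, "outcomes")
        merged = outcomes.merge(clinical, on="participant_id", how="inner")
        X = merged[list(PREDICTOR_COLUMNS)].copy()
        X["sex"] = (X["sex"] == "M").astype(float)
        try:
            reg_rows = []
            for outcome in OUTCOME_COLUMNS:
                res = ols_regression(merged[outcome].to_numpy(), X)
                uni = res.univariate.copy()
                uni.insert(0, "outcome", outcome)
                uni["model_r2"] = res.r2
                uni["model_F"] = res.f_stat
                uni["model_p"] = res.f_p
                reg_rows.append(uni)
            bundle["regression"] = pd.concat(reg_rows, ignore_index=True)
        except DomainError as exc:
            warnings.warn(f"regression stage skipped: {exc}", stacklevel=2)
    else:
        warnings.warn("no clinical table found; regression stage skipped", stacklevel=2)

    for name, df in bundle.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(
        {"version": __version__, "config_digest": cfg.digest(),
         "inputs": [str(dir_hc), str(dir_ts)]}, indent=1))
    return bundle
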