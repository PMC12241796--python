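"""Group-level statistics.

Hedges' G effect sizes (scalar and pointwise curves with moderate-effect
marking), a classical two-way mixed-design ANOVA, multiple linear
regression of clinical predictors, and the derived per-participant
outcome table the regressions consume.

Effect-size conventions: G = J * (mean1 - mean2) / s_pooled with the
n-1-weighted pooled SD and the small-sample correction
J = 1 - 3 / (4 df - 1) (the exact gamma-ratio correction is available
behind a flag; the two differ by < 1e-3 for total n >= 20). Group 1 is
the control (HC) group by convention. Pointwise curves are marked where
|G| exceeds a threshold (default 0.5, a moderate effect) with no
cluster-size requirement and no multiple-comparison correction — an
exploratory display, not confirmatory inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sp_stats
import statsmodels.api as sm

from .epochs import DomainError, GroupDataset
from .itpc import ALPHA, LOW_GAMMA, band_itpc, prepost_means
from .sep import DEFAULT_WINDOWS, locate_component_peaks, participant_sep
from .spectral import band_mean_psd, fit_semilog_slope, welch_psd
from .variability import cv_curve, pointwise_sd

__all__ = [
    "EffectSizeCurve",
    "hedges_g",
    "effect_size_curve",
    "mixed_anova_2way",
    "ols_regression",
    "OlsResult",
    "derived_outcomes",
]


def hedges_g(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    exact_correction: bool = False,
) -> float:
    """Bias-corrected standardised mean difference between two groups."""
    if n1 < 2 or n2 < 2:
        raise DomainError("each group needs at least two observations")
    if sd1 < 0 or sd2 < 0:
        raise DomainError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    s_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    if s_pooled == 0:
        raise DomainError("pooled SD is zero; the effect size is undefined")
    if exact_correction:
        j = float(np.exp(special.gammaln(df / 2.0) - special.gammaln((df - 1) / 2.0))
                  / np.sqrt(df / 2.0))
    else:
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(j * (mean1 - mean2) / s_pooled)


@dataclass
class EffectSizeCurve:
    """Pointwise Hedges' G with a moderate-effect mask."""

    abscissa: np.ndarray
    g: np.ndarray
    mask: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def fraction_marked(self) -> float:
        return float(self.mask.mean())


def effect_size_curve(
    group1: np.ndarray,
    group2: np.ndarray,
    threshold: float = 0.5,
    abscissa: np.ndarray | None = None,
    exact_correction: bool = False,
) -> EffectSizeCurve:
    """Pointwise Hedges' G between two stacks of per-participant curves.

    ``group1`` and ``group2`` are arrays of shape (n_participants,
    n_points) sharing an abscissa; group 1 is the control group. Points
    with zero pooled SD yield NaN and are never marked.
    """
    a = np.atleast_2d(np.asarray(group1, dtype=float))
    b = np.atleast_2d(np.asarray(group2, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise DomainError("group curves do not share an abscissa")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DomainError("each group needs at least two participants")
    n1, n2 = a.shape[0], b.shape[0]
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / df
    if exact_correction:
        j = float(np.exp(special.gammaln(df / 2.0) - special.gammaln((df - 1) / 2.0))
                  / np.sqrt(df / 2.0))
    else:
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = j * (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2)
    g = np.where(sp2 > 0, g, np.nan)
    mask = np.abs(g) > threshold
    mask[np.isnan(g)] = False
    if abscissa is None:
        abscissa = np.arange(a.shape[1], dtype=float)
    return EffectSizeCurve(abscissa=abscissa, g=g, mask=mask, threshold=threshold)


def mixed_anova_2way(
    values: np.ndarray,
    groups: Sequence[str],
    within_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-way mixed-design ANOVA (between: Group; within: repeated levels).

    ``values`` is a balanced subjects x within-levels matrix (every subject
    measured at every level; missing cells are an error — no imputation).
    The between-subject sum of squares splits into Group and
    subjects-within-group error; the within-subject sum of squares splits
    into the within factor, the interaction, and the within x subjects
    error. No sphericity correction is applied. Returns an ANOVA table
    with columns source, ss, df, ms, F, p; a zero error mean square yields
    NaN F and p (degenerate).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise DomainError("values must be a subjects x levels matrix")
    if np.isnan(y).any():
        raise DomainError("missing cells in the within-subject design (no imputation)")
    groups = np.asarray(groups)
    n_subj, k = y.shape
    if groups.shape[0] != n_subj:
        raise DomainError("one group label per subject is required")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise DomainError("need at least two groups")
    counts = {g: int((groups == g).sum()) for g in labels}
    if min(counts.values()) < 2:
        raise DomainError("each group needs at least two subjects")

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    level_mean = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_mean - grand) ** 2).sum())
    ss_group = float(
        k * sum(counts[g] * (subj_mean[groups == g].mean() - grand) ** 2 for g in labels)
    )
    ss_subj_within = ss_between_subj - ss_group
    ss_within_factor = float(n_subj * ((level_mean - grand) ** 2).sum())
    ss_cells = float(
        sum(
            counts[g] * ((y[groups == g].mean(axis=0) - grand) ** 2).sum()
            for g in labels
        )
    )
    ss_interaction = ss_cells - ss_group - ss_within_factor
    ss_error_within = ss_total - ss_cells - ss_subj_within

    g_levels = len(labels)
    df_group = g_levels - 1
    df_subj = n_subj - g_levels
    df_within = k - 1
    df_inter = df_group * df_within
    df_err = df_subj * df_within

    def f_and_p(ss_eff: float, df_eff: int, ss_err: float, df_err_: int):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err_
        if ms_err == 0:
            return ms_eff, np.nan, np.nan
        f = ms_eff / ms_err
        return ms_eff, f, float(sp_stats.f.sf(f, df_eff, df_err_))

    rows = []
    ms, f, p = f_and_p(ss_group, df_group, ss_subj_within, df_subj)
    rows.append(("Group", ss_group, df_group, ms, f, p))
    rows.append(("Subjects(Group)", ss_subj_within, df_subj,
                 ss_subj_within / df_subj, np.nan, np.nan))
    ms, f, p = f_and_p(ss_within_factor, df_within, ss_error_within, df_err)
    rows.append(("Within", ss_within_factor, df_within, ms, f, p))
    ms, f, p = f_and_p(ss_interaction, df_inter, ss_error_within, df_err)
    rows.append(("Group x Within", ss_interaction, df_inter, ms, f, p))
    rows.append(("Within x Subjects", ss_error_within, df_err,
                 ss_error_within / df_err, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["source", "ss", "df", "ms", "F", "p"])
    table.attrs["within_labels"] = list(within_labels) if within_labels is not None else None
    return table


@dataclass
class OlsResult:
    """Full-model and per-predictor univariate regression statistics."""

    n: int
    r2: float
    f_stat: float
    f_p: float
    params: pd.Series
    pvalues: pd.Series
    univariate: pd.DataFrame  # predictor, r, r2, F, p, slope


def ols_regression(y: Sequence[float], X: pd.DataFrame) -> OlsResult:
    """OLS of an outcome on a predictor table, with univariate statistics.

    Alongside the full model (fit with an intercept), reports for every
    predictor the simple correlation r, univariate R^2, F and p — the
    form in which small-sample regression findings are conventionally
    summarised. Constant or collinear predictor columns raise an error
    naming the offending columns.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(X, pd.DataFrame):
        raise DomainError("predictors must be supplied as a DataFrame")
    n, kp = X.shape
    if y.shape[0] != n:
        raise DomainError("outcome and predictor row counts differ")
    if n <= kp + 1:
        raise DomainError(f"need more than {kp + 1} observations for {kp} predictors")
    Xf = X.astype(float)
    constant = [c for c in Xf.columns if Xf[c].std(ddof=0) == 0]
    if constant:
        raise DomainError(f"constant predictor column(s): {constant}")
    design = sm.add_constant(Xf)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        corr = Xf.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise DomainError(f"rank-deficient design; check collinear columns {list(worst)}")
    model = sm.OLS(y, design).fit()

    uni_rows = []
    for col in Xf.columns:
        res = sp_stats.linregress(Xf[col].to_numpy(), y)
        t2 = np.inf if res.rvalue**2 >= 1.0 else (
            res.rvalue**2 * (n - 2) / (1.0 - res.rvalue**2)
        )
        uni_rows.append(
            {
                "predictor": col,
                "r": float(res.rvalue),
                "r2": float(res.rvalue**2),
                "F": float(t2),
                "p": float(res.pvalue),
                "slope": float(res.slope),
            }
        )
    return OlsResult(
        n=n,
        r2=float(model.rsquared),
        f_stat=float(model.fvalue),
        f_p=float(model.f_pvalue),
        params=model.params,
        pvalues=model.pvalues,
        univariate=pd.DataFrame(uni_rows),
    )


def derived_outcomes(
    dataset: GroupDataset,
    itpc_pre: tuple[float, float] = (-50.0, 0.0),
    itpc_post: tuple[float, float] = (0.0, 100.0),
    cv_pre: tuple[float, float] = (-200.0, 0.0),
    cv_post: tuple[float, float] = (0.0, 200.0),
    psd_mean_band: tuple[float, float] = (25.0, 45.0),
    cycles: float = 5.0,
) -> pd.DataFrame:
    """Per-participant outcome table for the clinical regressions.

    One row per participant: P2 peak amplitude; alpha- and gamma-band
    coherence change across stimulation onset; mean CV change across
    onset; mean SD over the entire epoch; mean PSD over the high band.
    Stimulus-onset changes are reported under both sign conventions
    (``*_post_minus_pre`` and ``*_pre_minus_post``) since either reading
    of "subtracted from" occurs in practice; neither is canonical.
    Epoch sets are assumed cleaned and baseline-corrected.
    """
    p2_window = [w for w in DEFAULT_WINDOWS if w.name == "P2"]
    rows = []
    for es in dataset.participants:
        t = es.times_ms
        sep = participant_sep(es)
        _, p2_amp = locate_component_peaks(sep, t, p2_window)["P2"]

        curve = band_itpc(es, bands=(ALPHA, LOW_GAMMA), cycles=cycles)
        pp = prepost_means(curve, pre=itpc_pre, post=itpc_post).set_index("band")

        cv = cv_curve(es)
        pre_mask = (t >= cv_pre[0]) & (t < cv_pre[1])
        post_mask = (t >= cv_post[0]) & (t <= cv_post[1])
        cv_pre_mean = float(np.nanmean(cv[pre_mask]))
        cv_post_mean = float(np.nanmean(cv[post_mask]))

        mean_sd = float(pointwise_sd(es).values.mean())
        mean_psd = band_mean_psd(fit_semilog_slope(welch_psd(es)), psd_mean_band)

        row = {
            "participant_id": es.participant_id,
            "group": es.group,
            "p2_amplitude_uv": p2_amp,
            "mean_sd_uv": mean_sd,
            "mean_psd_25_45": mean_psd,
            "cv_post_minus_pre": cv_post_mean - cv_pre_mean,
            "cv_pre_minus_post": cv_pre_mean - cv_post_mean,
        }
        for band, col in (("alpha", "alpha_itpc"), ("low_gamma", "gamma_itpc")):
            delta = float(pp.loc[band, "post_minus_pre"])
            row[f"{col}_post_minus_pre"] = delta
            row[f"{col}_pre_minus_post"] = -delta
        rows.append(row)
    return pd.DataFrame(rows)
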