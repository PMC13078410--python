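"""Precision and comparison statistics for repeated measurements.

Covers the analysis chain of a two-session repeatability study:
Bland-Altman bias and limits of agreement, the coefficient of repeatability
(1.96 times the SD of inter-session differences, expressed as a percentage
of the group mean), the single-measurement absolute-agreement intraclass
correlation ICC(A,1), paired t-tests and Pearson correlations between
measurement methods with Benjamini-Hochberg false-discovery-rate control,
and one-way repeated-measures ANOVA across exercise stages.

Sample standard deviations use n-1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, ZeroVarianceError


@dataclass
class AgreementReport:
    """Bland-Altman agreement between two paired measurement sets."""

    bias: float  # mean(value_1 - value_2)
    loa_low: float  # bias - 1.96 * SD(d)
    loa_high: float  # bias + 1.96 * SD(d)
    sd_diff: float
    cr_percent: float  # 100 * 1.96 * SD(d) / group mean (NaN if mean <= 0)
    group_mean: float  # mean over all values of both sets
    n: int


def bland_altman(value_1, value_2) -> AgreementReport:
    """Bland-Altman analysis of paired measurements (differences d = v1 - v2)."""
    v1 = np.asarray(value_1, dtype=float)
    v2 = np.asarray(value_2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ConfigError("value_1 and value_2 must be 1D arrays of equal length")
    if v1.size < 2:
        raise ConfigError("need at least 2 pairs")
    d = v1 - v2
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    group_mean = float(np.concatenate([v1, v2]).mean())
    cr = 100.0 * 1.96 * sd / group_mean if group_mean > 0 else float("nan")
    return AgreementReport(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        cr_percent=cr,
        group_mean=group_mean,
        n=int(v1.size),
    )


def cr_from_summary(sd_diff: float, group_mean: float) -> float:
    """Coefficient of repeatability (%) from summary statistics:
    100 * 1.96 * SD(differences) / group mean."""
    if group_mean <= 0:
        raise DataError("group mean must be > 0 for a percentage CR")
    return 100.0 * 1.96 * sd_diff / group_mean


def repeatability_coefficient(value_1, value_2) -> float:
    """Inter-session coefficient of repeatability, % of the group mean.

    Scale-invariant: multiplying all measurements by k > 0 leaves it
    unchanged.
    """
    report = bland_altman(value_1, value_2)
    if report.group_mean <= 0:
        raise DataError("group mean must be > 0 for a percentage CR")
    return report.cr_percent


def icc_a1(matrix) -> float:
    """ICC(A,1): single-measurement absolute-agreement two-way model.

    From the two-way ANOVA decomposition of an n-subject x k-session matrix
    (k = 2 sessions here)::

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    The estimate is clipped to the reporting range [-1, 1].
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ConfigError("matrix must be subjects x sessions with >= 2 sessions")
    if x.shape[0] < 3:
        raise ConfigError("need at least 3 subjects")
    if np.any(~np.isfinite(x)):
        raise DataError("missing cells are not allowed")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        raise ZeroVarianceError("ICC undefined: data have no variance")
    return float(np.clip((ms_r - ms_e) / denom, -1.0, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ConfigError("p_values must be a nonempty 1D array")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class RMAnovaResult:
    """One-way repeated-measures ANOVA over conditions (complete cases only)."""

    f: float
    df_effect: int
    df_error: int
    p: float
    n_complete: int
    n_dropped: int


def rm_anova(table: pd.DataFrame) -> RMAnovaResult:
    """One-way RM-ANOVA across the columns of a subjects x conditions table.

    Subjects with any missing condition are dropped (listwise deletion), as
    when a stage could not be acquired in some subjects.
    """
    if table.shape[1] < 3:
        raise ConfigError("RM-ANOVA needs at least 3 conditions")
    complete = table.dropna()
    n_dropped = len(table) - len(complete)
    x = complete.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2:
        raise DataError("fewer than 2 complete cases")
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_effect = k - 1
    df_error = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    if ms_err == 0:
        raise ZeroVarianceError("RM-ANOVA undefined: zero error variance")
    f = ms_cond / ms_err
    p = float(sps.f.sf(f, df_effect, df_error))
    return RMAnovaResult(
        f=float(f), df_effect=df_effect, df_error=df_error, p=p,
        n_complete=n, n_dropped=n_dropped,
    )


def compare_conditions(table: pd.DataFrame, design: str = "paired") -> pd.DataFrame | RMAnovaResult:
    """Compare conditions of a subjects x conditions table.

    design="paired"
        All pairwise two-sided paired t-tests plus the Pearson correlation
        of each pair, with BH-adjusted p-values over the family of all
        pairwise comparisons within the table (one parameter = one family).
        Identical conditions give t = 0, p = 1.
    design="repeated"
        One-way repeated-measures ANOVA across all conditions (listwise
        deletion of incomplete subjects).
    """
    if design == "repeated":
        return rm_anova(table)
    if design != "paired":
        raise ConfigError(f"unknown design {design!r}")
    rows = []
    for a, b in combinations(table.columns, 2):
        pair = table[[a, b]].dropna()
        if len(pair) < 2:
            raise DataError(f"fewer than 2 complete pairs for {a} vs {b}")
        x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(x, y)
        if x.std() == 0 or y.std() == 0:
            r, rp = float("nan"), float("nan")
        else:
            r, rp = sps.pearsonr(x, y)
        rows.append(
            {"condition_a": a, "condition_b": b, "t": float(t), "p_raw": float(p),
             "r": float(r), "r_p_raw": float(rp), "n": len(pair)}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def repeatability_table(long_df: pd.DataFrame) -> pd.DataFrame:
    """Summarise a two-session study into one row per (stage, parameter).

    Input is long format with columns ``subject, session, stage, parameter,
    value`` (sessions labelled 1 and 2).  The output mirrors a repeatability
    table: the both-session group mean and the session-1 mean (labelled
    separately, since either convention occurs in the literature), the
    inter-session bias +/- SD of differences, the coefficient of
    repeatability (%), and ICC(A,1) where at least 3 complete subjects
    exist.
    """
    required = {"subject", "session", "stage", "parameter", "value"}
    if not required.issubset(long_df.columns):
        raise ConfigError(f"long table must have columns {sorted(required)}")
    rows = []
    for (stage, parameter), grp in long_df.groupby(["stage", "parameter"], sort=False):
        wide = grp.pivot_table(index="subject", columns="session", values="value").dropna()
        if wide.shape[1] != 2 or len(wide) < 2:
            continue
        s1, s2 = (wide.iloc[:, 0].to_numpy(float), wide.iloc[:, 1].to_numpy(float))
        report = bland_altman(s1, s2)
        try:
            icc = icc_a1(np.column_stack([s1, s2]))
        except (ConfigError, ZeroVarianceError):
            icc = float("nan")
        rows.append(
            {
                "stage": stage,
                "parameter": parameter,
                "n": report.n,
                "mean_both_sessions": report.group_mean,
                "mean_session_1": float(s1.mean()),
                "bias": report.bias,
                "sd_diff": report.sd_diff,
                "cr_percent": report.cr_percent,
                "icc_a1": icc,
            }
        )
    return pd.DataFrame(rows)


def bland_altman_plot(value_1, value_2, ax=None, label: str | None = None):
    """Basic Bland-Altman plot: per-pair mean vs difference with bias and
    limits of agreement."""
    import matplotlib.pyplot as plt

    report = bland_altman(value_1, value_2)
    v1 = np.asarray(value_1, dtype=float)
    v2 = np.asarray(value_2, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((v1 + v2) / 2.0, v1 - v2, color="k", s=20)
    ax.axhline(report.bias, color="k")
    for y in (report.loa_low, report.loa_high):
        ax.axhline(y, color="r", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference")
    if label:
        ax.set_title(label)
    return ax, report


__all__ = [
    "AgreementReport",
    "bland_altman",
    "repeatability_coefficient",
    "cr_from_summary",
    "icc_a1",
    "bh_adjust",
    "rm_anova",
    "RMAnovaResult",
    "compare_conditions",
    "repeatability_table",
    "bland_altman_plot",
]
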