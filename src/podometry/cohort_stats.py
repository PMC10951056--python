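"""Two-group comparisons, 2x2 contingency tests, correlations and report tables.

The comparison pipeline mirrors common biomedical practice: each variable is
gated through the D'Agostino-Pearson omnibus normality test; variables that
pass in both groups are compared with an unpaired t-test and summarised as
mean (sd), everything else with a two-sided Mann-Whitney U test and
summarised as median (IQR).  Proportions are compared with an uncorrected
chi-square test on the 2x2 table (no Yates continuity correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from podometry.errors import DegenerateStatisticError, ValidationError

ALPHA = 0.05
#: Minimum group size for the omnibus normality test; below it the
#: nonparametric branch is used unconditionally.
MIN_N_NORMALITY = 8


@dataclass(frozen=True)
class TwoGroupResult:
    variable: str
    test: str  # "t" or "mann_whitney"
    statistic: float
    p: float
    summary_a: str
    summary_b: str
    n_a: int
    n_b: int


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi_square: float
    p: float
    df: int = 1


def normality_gate(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = ALPHA
) -> str:
    """Return ``"parametric"`` iff both groups pass the omnibus normality test.

    Groups smaller than :data:`MIN_N_NORMALITY` are routed nonparametric by
    rule (the omnibus test is unreliable there).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if min(a.size, b.size) < MIN_N_NORMALITY:
        return "nonparametric"
    for sample in (a, b):
        if np.ptp(sample) == 0:
            return "nonparametric"
        if stats.normaltest(sample).pvalue <= alpha:
            return "nonparametric"
    return "parametric"


def _median_iqr(sample: np.ndarray) -> str:
    # quartiles by linear interpolation
    q1, med, q3 = np.percentile(sample, [25, 50, 75])
    return f"{med:.4g} ({q1:.4g}-{q3:.4g})"


def _mean_sd(sample: np.ndarray) -> str:
    return f"{np.mean(sample):.4g} ({np.std(sample, ddof=1):.4g})"


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sided Mann-Whitney U.

    The exact null distribution is used when the smaller group has at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    return stats.mannwhitneyu(a, b, alternative="two-sided", method=method)


def compare_groups(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variable: str = "",
    alpha: float = ALPHA,
) -> TwoGroupResult:
    """Normality-gated two-group comparison (see module docstring)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    branch = normality_gate(a, b, alpha)
    if branch == "parametric":
        res = stats.ttest_ind(a, b)
        return TwoGroupResult(
            variable=variable,
            test="t",
            statistic=float(res.statistic),
            p=float(res.pvalue),
            summary_a=_mean_sd(a),
            summary_b=_mean_sd(b),
            n_a=a.size,
            n_b=b.size,
        )
    if np.array_equal(np.sort(a), np.sort(b)):
        # identical samples: U test is degenerate but the answer is clear
        stat, p = a.size * b.size / 2.0, 1.0
    else:
        res = mann_whitney(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    return TwoGroupResult(
        variable=variable,
        test="mann_whitney",
        statistic=stat,
        p=min(p, 1.0),
        summary_a=_median_iqr(a),
        summary_b=_median_iqr(b),
        n_a=a.size,
        n_b=b.size,
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Uncorrected chi-square test for the 2x2 table [[a, b], [c, d]].

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with one degree of
    freedom and no continuity correction.  A zero row or column margin makes
    the statistic undefined.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValidationError("counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValidationError("table must contain at least one observation")
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise DegenerateStatisticError("zero margin: chi-square statistic undefined")
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    return ContingencyResult(
        table=((a, b), (c, d)),
        chi_square=chi2,
        p=float(stats.chi2.sf(chi2, df=1)),
    )


def spearman_with_ci(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Spearman rho (mid-ranks), its t-approximation p-value and a Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have the same length")
    if x.size < 4:
        raise ValidationError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("rho undefined for a constant vector")
    res = stats.spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)
    z_crit = stats.norm.ppf(0.5 + confidence / 2.0)
    if abs(rho) >= 1.0:
        ci = (rho, rho)
    else:
        z = np.arctanh(rho)
        half = z_crit / math.sqrt(x.size - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return rho, p, ci


def percent_difference(value: float, reference: float) -> int:
    """``100 * (value - reference) / reference`` rounded to the nearest integer."""
    if reference == 0:
        raise ValidationError("reference must be non-zero")
    return round(100.0 * (value - reference) / reference)


# --------------------------------------------------------------------------
# report assembly

#: Correlation panels: (x column, y column) pairs from the merged per-patient
#: table, covering volume/number, volume/density, size/number, size/density,
#: sclerosis/number and sclerosis/density relationships.
CORRELATION_PANELS = [
    ("glomerular_volume", "podocytes_per_tuft"),
    ("glomerular_volume", "podocyte_density"),
    ("total_podocyte_volume", "podocytes_per_tuft"),
    ("total_podocyte_volume", "podocyte_density"),
    ("gsi", "podocytes_per_tuft"),
    ("gsi", "podocyte_density"),
]

PODOMETRIC_VARIABLES = [
    "mean_apparent_caliper",
    "estimated_true_caliper",
    "podocytes_per_tuft",
    "glomerular_volume",
    "podocyte_density",
    "snp_fraction",
    "nuclear_volume",
    "cytoplasmic_volume",
    "total_podocyte_volume",
    "nc_ratio",
    "vv_pod_glom",
    "gsi",
    "pct_global",
    "pct_fsgs",
]

FLAG_COLUMNS = [
    "flag_low_podocyte",
    "flag_gsi_gt_1",
    "flag_global_gt_20",
    "flag_fsgs_gt_50",
]


def _two_group_frame(
    merged: pd.DataFrame, variables: Sequence[str], labels: pd.Series
) -> pd.DataFrame:
    rows = []
    responders = merged.loc[labels == "responder"]
    non_responders = merged.loc[labels == "non_responder"]
    for var in variables:
        if var not in merged.columns:
            continue
        a = responders[var].dropna().to_numpy()
        b = non_responders[var].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        res = compare_groups(a, b, variable=var)
        rows.append(
            {
                "variable": var,
                "responders": res.summary_a,
                "non_responders": res.summary_b,
                "test": res.test,
                "p": res.p,
                "n_responders": res.n_a,
                "n_non_responders": res.n_b,
            }
        )
    return pd.DataFrame(rows)


def _threshold_frame(merged: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    rows = []
    nr = merged.loc[labels == "non_responder"]
    r = merged.loc[labels == "responder"]
    for flag in FLAG_COLUMNS:
        if flag not in merged.columns:
            continue
        a = int(nr[flag].sum())
        b = int((1 - nr[flag]).sum())
        c = int(r[flag].sum())
        d = int((1 - r[flag]).sum())
        row = {
            "flag": flag.removeprefix("flag_"),
            "nr_flagged": a,
            "nr_total": a + b,
            "r_flagged": c,
            "r_total": c + d,
        }
        try:
            res = chi_square_2x2(a, b, c, d)
            row.update(chi_square=res.chi_square, p=res.p, error="")
        except DegenerateStatisticError as exc:
            row.update(chi_square=float("nan"), p=float("nan"), error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def _correlation_frame(merged: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for xcol, ycol in CORRELATION_PANELS:
        if xcol not in merged.columns or ycol not in merged.columns:
            continue
        sub = merged[[xcol, ycol]].dropna()
        try:
            rho, p, ci = spearman_with_ci(sub[xcol], sub[ycol])
        except ValidationError as exc:
            rows.append(
                {"x": xcol, "y": ycol, "rho": float("nan"), "p": float("nan"),
                 "ci_low": float("nan"), "ci_high": float("nan"), "n": len(sub),
                 "error": str(exc)}
            )
            continue
        rows.append(
            {"x": xcol, "y": ycol, "rho": rho, "p": p,
             "ci_low": ci[0], "ci_high": ci[1], "n": len(sub), "error": ""}
        )
    return pd.DataFrame(rows)


def build_report(
    podometrics: pd.DataFrame,
    sclerosis: pd.DataFrame,
    clinical: pd.DataFrame,
    labels: pd.Series,
) -> dict[str, pd.DataFrame]:
    """Assemble the cohort report tables.

    Parameters
    ----------
    podometrics, sclerosis:
        Per-patient frames keyed by ``patient_id`` (podometric indices; GSI,
        percentages and flags).
    clinical:
        Long-format clinical frame with a ``timepoint`` column plus derived
        ``proteinuria_g_day`` / ``egfr`` columns where computable.
    labels:
        ``patient_id -> "responder" | "non_responder"``.

    Returns a dict of frames: ``demographics`` (biopsy-time variables),
    ``outcomes`` (month-6 variables), ``podometrics`` (podometric and
    sclerosis indices), ``thresholds`` (the four 2x2 analyses) and
    ``correlations`` (six Spearman panels).
    """
    merged = podometrics.merge(sclerosis, on="patient_id", how="inner")
    if set(merged["patient_id"]) - set(labels.index):
        raise ValidationError("every measured patient needs a response label")
    merged = merged.set_index("patient_id")
    lab = labels.loc[merged.index]

    tables: dict[str, pd.DataFrame] = {}

    clin_vars = ["age_years", "scr_umol_l", "proteinuria_g_day", "egfr"]
    for name, timepoint in (("demographics", "biopsy"), ("outcomes", "month6")):
        sub = clinical.loc[clinical["timepoint"] == timepoint].set_index("patient_id")
        sub = sub.loc[sub.index.intersection(labels.index)]
        tables[name] = _two_group_frame(sub, clin_vars, labels.loc[sub.index])

    # sex proportion belongs to demographics; use a contingency row
    biopsy_clin = clinical.loc[clinical["timepoint"] == "biopsy"].set_index("patient_id")
    biopsy_clin = biopsy_clin.loc[biopsy_clin.index.intersection(labels.index)]
    if "sex" in biopsy_clin.columns and len(biopsy_clin):
        is_male = (biopsy_clin["sex"] == "male").astype(int)
        lab_clin = labels.loc[biopsy_clin.index]
        a = int(is_male[lab_clin == "non_responder"].sum())
        b = int((lab_clin == "non_responder").sum()) - a
        c = int(is_male[lab_clin == "responder"].sum())
        d = int((lab_clin == "responder").sum()) - c
        try:
            res = chi_square_2x2(a, b, c, d)
            sex_row = {"variable": "sex_male", "responders": f"{c}/{c + d}",
                       "non_responders": f"{a}/{a + b}", "test": "chi_square",
                       "p": res.p, "n_responders": c + d, "n_non_responders": a + b}
        except DegenerateStatisticError:
            sex_row = {"variable": "sex_male", "responders": f"{c}/{c + d}",
                       "non_responders": f"{a}/{a + b}", "test": "chi_square",
                       "p": float("nan"), "n_responders": c + d,
                       "n_non_responders": a + b}
        tables["demographics"] = pd.concat(
            [tables["demographics"], pd.DataFrame([sex_row])], ignore_index=True
        )

    tables["podometrics"] = _two_group_frame(merged, PODOMETRIC_VARIABLES, lab)
    tables["thresholds"] = _threshold_frame(merged, lab)
    tables["correlations"] = _correlation_frame(merged)
    return tables


def plot_correlations(merged: pd.DataFrame, out_path: str) -> None:
    """Six-panel Spearman correlation figure (presentation only: OLS trend
    line with a pointwise 95% band)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, (xcol, ycol) in zip(axes.ravel(), CORRELATION_PANELS):
        if xcol not in merged.columns or ycol not in merged.columns:
            ax.set_axis_off()
            continue
        sub = merged[[xcol, ycol]].dropna()
        x, y = sub[xcol].to_numpy(), sub[ycol].to_numpy()
        ax.scatter(x, y, s=14, color="k")
        if len(sub) >= 4 and np.ptp(x) > 0:
            res = stats.linregress(x, y)
            grid = np.linspace(x.min(), x.max(), 50)
            yhat = res.intercept + res.slope * grid
            resid = y - (res.intercept + res.slope * x)
            se = np.std(resid, ddof=2)
            mean_x = x.mean()
            band = 1.96 * se * np.sqrt(
                1.0 / len(x) + (grid - mean_x) ** 2 / np.sum((x - mean_x) ** 2)
            )
            ax.plot(grid, yhat, "b-")
            ax.fill_between(grid, yhat - band, yhat + band, alpha=0.2)
        ax.set_xlabel(xcol)
        ax.set_ylabel(ycol)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


__all__ = [
    "ALPHA",
    "CORRELATION_PANELS",
    "ContingencyResult",
    "FLAG_COLUMNS",
    "MIN_N_NORMALITY",
    "PODOMETRIC_VARIABLES",
    "TwoGroupResult",
    "build_report",
    "chi_square_2x2",
    "compare_groups",
    "mann_whitney",
    "normality_gate",
    "percent_difference",
    "plot_correlations",
    "spearman_with_ci",
]
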