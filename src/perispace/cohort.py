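"""Cohort-level statistical battery.

Reproduces the analysis grid used to relate hydrogel placement to rectum
dosimetry across a patient cohort: Pearson correlations and simple linear
regressions of each rectal dose metric on each placement predictor,
pooled-variance t-tests between symmetry groups, a three-variable
regression of rDmax 1 cc on theta, gel volume and their product with
standardized coefficients, and Shapiro-Wilk normality screening.

Missing values are handled complete-case per analysis, so the effective n
varies between analyses exactly as it does in clinical cohorts where not
every patient has every scan.  No multiple-testing correction is applied
by default (raw R-squared / p values are reported); a Benjamini-Hochberg
adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "BatteryReport",
    "pearson_r2",
    "linreg",
    "two_sample_t",
    "shapiro_wilk",
    "benjamini_hochberg",
    "analysis_battery",
    "PREDICTOR_COLUMNS",
    "RESPONSE_COLUMNS",
    "REQUIRED_COLUMNS",
]


class DegenerateDataError(ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


class RankDeficiencyError(ValueError):
    """The regression design matrix is collinear."""


#: Placement predictors regressed against each dose metric, in report order.
PREDICTOR_COLUMNS: tuple[str, ...] = (
    "peri_center_mm",
    "peri_inf1_mm",
    "peri_inf2_mm",
    "gel_volume_cc",
    "theta_deg",
    "norm_theta_vol",
)

#: Rectal dose metrics serving as regression responses, in report order.
RESPONSE_COLUMNS: tuple[str, ...] = (
    "rdmax_1cc_cgy",
    "rdmax_2cc_cgy",
    "rdmax_3cc_cgy",
    "rv95_cc",
    "rv90_cc",
    "rv80_cc",
)

REQUIRED_COLUMNS: tuple[str, ...] = (
    ("patient_id",) + PREDICTOR_COLUMNS + RESPONSE_COLUMNS
    + ("symmetry_category", "toxicity_grade")
)


@dataclass(frozen=True)
class RegressionResult:
    """Least-squares fit summary for one (multiple) linear regression."""

    r2: float
    intercept: float
    slopes: dict[str, float]
    standardized_betas: dict[str, float]
    t_stats: dict[str, float]
    p_values: dict[str, float]
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n: int


@dataclass
class BatteryReport:
    """Output bundle of :func:`analysis_battery`."""

    r2_grid: pd.DataFrame
    p_grid: pd.DataFrame
    n_grid: pd.DataFrame
    symmetry_tests: pd.DataFrame
    multivariable: RegressionResult | None
    toxicity_comparison: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson_r2(x, y) -> tuple[float, float, float]:
    """Product-moment correlation: returns (r, r^2, two-sided p).

    Complete pairs only; the p value uses the t distribution with n-2
    degrees of freedom.
    """
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("cannot standardize a zero-variance column")
    return (a - a.mean()) / sd


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # Name the smallest set of trailing columns whose removal restores
    # full rank — enough to point at the offending predictor(s).
    bad = []
    for j in range(X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
            bad.append(names[j])
    return bad or names


def linreg(
    y,
    X: pd.DataFrame | np.ndarray,
    standardized: bool = False,
) -> RegressionResult:
    """Ordinary least squares of y on one or more predictors.

    With ``standardized=True`` both the predictors *and* the response are
    z-scored (sample SD) before fitting, so the reported coefficients are
    standardized betas in SD units.  R^2, F and t statistics are identical
    between the raw and standardized fits; both sets of coefficients are
    always returned.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    keep = np.isfinite(ya) & np.isfinite(Xa).all(axis=1)
    ya, Xa = ya[keep], Xa[keep]
    n, p = Xa.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(Xa, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankDeficiencyError(
            "collinear design; offending columns: "
            + ", ".join(_collinear_columns(Xa, names))
        )
    fit = sm.OLS(ya, design).fit()
    if standardized:
        Xs = np.column_stack([_zscore(Xa[:, j]) for j in range(p)])
        ys = _zscore(ya)
        std_fit = sm.OLS(ys, sm.add_constant(Xs, has_constant="add")).fit()
        std_betas = dict(zip(names, std_fit.params[1:]))
    else:
        # Closed-form rescaling gives the same betas without a second fit.
        sy = ya.std(ddof=1)
        std_betas = {
            nm: float(fit.params[1 + j] * Xa[:, j].std(ddof=1) / sy)
            for j, nm in enumerate(names)
        }
    return RegressionResult(
        r2=float(fit.rsquared),
        intercept=float(fit.params[0]),
        slopes=dict(zip(names, map(float, fit.params[1:]))),
        standardized_betas={k: float(v) for k, v in std_betas.items()},
        t_stats=dict(zip(names, map(float, fit.tvalues[1:]))),
        p_values=dict(zip(names, map(float, fit.pvalues[1:]))),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n=n,
    )


def two_sample_t(a, b, pooled: bool = True) -> tuple[float, float, float]:
    """Two-sample t test: returns (t, df, two-sided p).

    Pooled-variance Student t by default; ``pooled=False`` gives Welch.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise DegenerateDataError("t statistic undefined: all values identical")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality screen: returns (W, p)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("normality test undefined for constant input")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q values (optional; the battery reports raw p by default)."""
    p = np.asarray(p_values, dtype=float)
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _grid_cell(cohort: pd.DataFrame, pred: str, resp: str):
    x = cohort[pred].to_numpy(dtype=float)
    y = cohort[resp].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < 3 or np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
        return np.nan, np.nan, n
    r, r2, p = pearson_r2(x[keep], y[keep])
    return r2, p, n


def analysis_battery(
    cohort: pd.DataFrame,
    predictors: tuple[str, ...] = PREDICTOR_COLUMNS,
    responses: tuple[str, ...] = RESPONSE_COLUMNS,
    adjust_p: bool = False,
) -> BatteryReport:
    """Run the full placement-vs-dosimetry analysis grid on a cohort table.

    Components:

    a. simple-regression R^2 (= squared Pearson r) and p for every
       (predictor, response) pair;
    b. pooled t tests of rDmax 1 cc between the SYM1 group and every
       other symmetry category with at least two patients;
    c. the three-variable regression of rDmax 1 cc on theta, gel volume
       and normalized theta*volume, with standardized betas;
    d. a descriptive comparison of rDmax 1 cc and theta*volume between
       patients with and without acute rectal toxicity.

    Degenerate analyses (too few patients, zero variance) are reported as
    NaN cells or skipped rows with a note, never as exceptions.
    """
    missing = [c for c in set(predictors) | set(responses) if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks columns: {sorted(missing)}")
    if len(cohort) < 4:
        raise ValueError(f"need >= 4 patients, got {len(cohort)}")
    notes: list[str] = []

    r2 = pd.DataFrame(index=list(predictors), columns=list(responses), dtype=float)
    pv = pd.DataFrame(index=list(predictors), columns=list(responses), dtype=float)
    ng = pd.DataFrame(index=list(predictors), columns=list(responses), dtype=float)
    for pred in predictors:
        for resp in responses:
            r2.loc[pred, resp], pv.loc[pred, resp], ng.loc[pred, resp] = _grid_cell(
                cohort, pred, resp
            )
    if r2.isna().any().any():
        notes.append("some regression cells degenerate (n < 3 or zero variance)")
    if adjust_p:
        flat = pv.to_numpy().ravel()
        ok = np.isfinite(flat)
        adj = flat.copy()
        adj[ok] = benjamini_hochberg(flat[ok])
        pv = pd.DataFrame(adj.reshape(pv.shape), index=pv.index, columns=pv.columns)

    # (b) symmetry-group comparisons on rDmax 1 cc
    sym_rows = []
    if "symmetry_category" in cohort.columns:
        sym1 = cohort.loc[cohort["symmetry_category"] == "SYM1", "rdmax_1cc_cgy"]
        for cat, grp in cohort.groupby("symmetry_category"):
            if cat == "SYM1":
                continue
            other = grp["rdmax_1cc_cgy"].dropna()
            if len(sym1.dropna()) < 2 or len(other) < 2:
                notes.append(f"symmetry group {cat}: too few patients for t test")
                continue
            try:
                t, df, p = two_sample_t(sym1.dropna(), other)
            except DegenerateDataError:
                notes.append(f"symmetry group {cat}: degenerate t test")
                continue
            sym_rows.append(
                {
                    "group": cat,
                    "n_sym1": int(len(sym1.dropna())),
                    "n_group": int(len(other)),
                    "mean_sym1_cgy": float(sym1.mean()),
                    "mean_group_cgy": float(other.mean()),
                    "mean_diff_cgy": float(other.mean() - sym1.mean()),
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
    symmetry_tests = pd.DataFrame(
        sym_rows,
        columns=[
            "group", "n_sym1", "n_group", "mean_sym1_cgy",
            "mean_group_cgy", "mean_diff_cgy", "t", "df", "p",
        ],
    )

    # (c) three-variable regression: theta, volume, theta*volume
    multivariable: RegressionResult | None = None
    tri = cohort[["theta_deg", "gel_volume_cc", "norm_theta_vol", "rdmax_1cc_cgy"]]
    tri = tri.dropna()
    if len(tri) >= 5:
        try:
            multivariable = linreg(
                tri["rdmax_1cc_cgy"],
                tri[["theta_deg", "gel_volume_cc", "norm_theta_vol"]],
                standardized=True,
            )
        except (RankDeficiencyError, DegenerateDataError) as exc:
            notes.append(f"multivariable regression degenerate: {exc}")
    else:
        notes.append("multivariable regression skipped: fewer than 5 complete patients")

    # (d) toxicity group comparison (descriptive at cohort sizes like n=20)
    tox_rows = []
    if "toxicity_grade" in cohort.columns:
        has_tox = cohort["toxicity_grade"].fillna(0) >= 1
        for col in ("rdmax_1cc_cgy", "norm_theta_vol"):
            g1 = cohort.loc[has_tox, col].dropna()
            g0 = cohort.loc[~has_tox, col].dropna()
            row = {
                "metric": col,
                "n_toxicity": int(len(g1)),
                "n_no_toxicity": int(len(g0)),
                "mean_toxicity": float(g1.mean()) if len(g1) else np.nan,
                "mean_no_toxicity": float(g0.mean()) if len(g0) else np.nan,
                "t": np.nan,
                "p": np.nan,
            }
            if len(g1) >= 2 and len(g0) >= 2:
                try:
                    t, _, p = two_sample_t(g1, g0)
                    row["t"], row["p"] = t, p
                except DegenerateDataError:
                    pass
            tox_rows.append(row)
    toxicity_comparison = pd.DataFrame(tox_rows)

    return BatteryReport(
        r2_grid=r2,
        p_grid=pv,
        n_grid=ng,
        symmetry_tests=symmetry_tests,
        multivariable=multivariable,
        toxicity_comparison=toxicity_comparison,
        notes=notes,
    )
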