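"""Association analyses: mixed-effects scale-on-actigraphy models,
Benjamini-Hochberg FDR, covariate-adjusted Spearman correlations, and
ASD-vs-TD group comparisons.

The core repeated-measures model is

    scale ~ (1 | participant) + actigraphy + age + sex + IQ

with all variables standardized on the analysis sample, fit by REML with a
random intercept per participant.  Inference on the actigraphy fixed effect
uses the Wald statistic with a normal approximation (the fitting backend
does not provide Satterthwaite degrees of freedom).  When the random
intercept cannot be estimated (e.g., a single visit per participant), the
model degrades to OLS and the result is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


@dataclass
class AssociationResult:
    scale_name: str
    actigraphy_feature: str
    estimate: float          # standardized fixed-effect coefficient
    p_value: float
    q_value: float | None
    n_obs: int
    n_participants: int
    degenerate: bool = False  # True when the random intercept was dropped


@dataclass
class CorrelationResult:
    scale_x: str
    scale_y: str
    rho: float
    p_value: float
    q_value: float | None
    timepoint: str | None
    n: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - np.mean(x)) / sd


def fit_scale_on_actigraphy(
    df: pd.DataFrame,
    scale: str,
    feature: str,
    covariates: tuple[str, ...] = ("age", "sex", "iq"),
    participant_col: str = "participant_id",
) -> AssociationResult:
    """Fit scale ~ (1|participant) + feature + covariates on standardized data.

    Rows with missing values in any model variable are dropped (complete
    case).  Sex is encoded 0/1 before standardization.  Returns the
    standardized coefficient on the actigraphy feature and its Wald p-value.
    """
    cols = [scale, feature, *covariates, participant_col]
    d = df[cols].dropna().copy()
    if d[participant_col].nunique() < 2:
        raise ValueError("need at least 2 participants")
    for c in (scale, feature, *covariates):
        if d[c].dtype == object or str(d[c].dtype) == "category":
            codes, _ = pd.factorize(d[c], sort=True)
            d[c] = codes
        d[c] = _zscore(d[c].to_numpy(dtype=float))

    endog = d[scale].to_numpy()
    exog = sm.add_constant(d[[feature, *covariates]].to_numpy())
    groups = d[participant_col].to_numpy()
    one_visit_each = d.groupby(participant_col).size().max() == 1

    degenerate = False
    if one_visit_each:
        degenerate = True
        res = sm.OLS(endog, exog).fit()
        est, p = res.params[1], res.pvalues[1]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog, exog, groups=groups)
            try:
                res = model.fit(reml=True)
                est, p = res.fe_params[1], res.pvalues[1]
                if not np.isfinite(p):
                    raise ValueError("non-finite mixed-model p-value")
            except (np.linalg.LinAlgError, ValueError):
                degenerate = True
                res = sm.OLS(endog, exog).fit()
                est, p = res.params[1], res.pvalues[1]
    return AssociationResult(
        scale_name=scale, actigraphy_feature=feature,
        estimate=float(est), p_value=float(p), q_value=None,
        n_obs=len(d), n_participants=int(d[participant_col].nunique()),
        degenerate=degenerate,
    )


def bh_adjust(p_values, family_label: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one explicit family)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError(f"p-values must lie in [0, 1] (family {family_label!r})")
    return multipletests(p, method="fdr_bh")[1]


def partial_spearman(
    x,
    y,
    covariates: np.ndarray | pd.DataFrame | None = None,
    scale_x: str = "x",
    scale_y: str = "y",
    timepoint: str | None = None,
) -> CorrelationResult:
    """Covariate-adjusted Spearman correlation.

    All variables (x, y and every covariate) are rank-transformed, the ranks
    of x and y are residualized on the covariate ranks (plus intercept) by
    least squares, and the Pearson correlation of the residuals is reported
    with a t-based p-value on n - 2 - k degrees of freedom.  With no
    covariates this reduces to the classical Spearman coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[mask], y[mask], Z[mask]
    n, k = len(x), Z.shape[1]
    if n < 4:
        raise ValueError("need at least 4 complete observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: correlation undefined")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rZ = np.column_stack([scipy.stats.rankdata(Z[:, j]) for j in range(k)]) if k else Z
    design = np.column_stack([np.ones(n), rZ])
    rx_res = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ry_res = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt(np.sum(rx_res ** 2) * np.sum(ry_res ** 2))
    if denom == 0:
        raise ValueError("residual ranks are constant: correlation undefined")
    rho = float(np.sum(rx_res * ry_res) / denom)
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough observations for the covariate set")
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * np.sqrt(df / (1 - rho_c ** 2))
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    return CorrelationResult(scale_x, scale_y, rho_c, p, None, timepoint, n)


def compare_groups_linear(
    scale,
    group,
    covariates: pd.DataFrame | np.ndarray,
) -> tuple[float, float]:
    """OLS of a scale on a group indicator plus covariates (sex, age).

    Returns (group coefficient, p-value).  ``group`` may be a binary vector
    or labels; the second sorted label is coded 1.
    """
    scale = np.asarray(scale, dtype=float)
    g = pd.Series(group)
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError("exactly two non-empty groups are required")
    gind = (g == labels[1]).to_numpy(dtype=float)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    X = sm.add_constant(np.column_stack([gind, Z]))
    res = sm.OLS(scale, X).fit()
    return float(res.params[1]), float(res.pvalues[1])


def compare_proportions_chisq(
    flags_group_a,
    flags_group_b,
    correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-squared test comparing proportions of flagged participants.

    ``flags_*`` are boolean vectors (e.g., caregiver sleep item >= 3).
    Continuity correction is off by default.
    """
    a = np.asarray(flags_group_a, dtype=bool)
    b = np.asarray(flags_group_b, dtype=bool)
    table = np.array([[a.sum(), (~a).sum()], [b.sum(), (~b).sum()]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-squared test requires all margins > 0")
    stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def flag_sleep_problems(abi_sleep, threshold: int = 3) -> np.ndarray:
    """More-than-mild sleep problems: caregiver sleep item >= threshold."""
    return np.asarray(abi_sleep, dtype=float) >= threshold


def association_table(
    data: pd.DataFrame,
    scales: tuple[str, ...],
    features: tuple[str, ...],
    covariates: tuple[str, ...] = ("age", "sex", "iq"),
    fdr_family: str = "all",
) -> pd.DataFrame:
    """Fit the mixed model for every scale x actigraphy-feature cell and
    BH-adjust p-values within the table (one family per grid)."""
    results: list[AssociationResult] = []
    for scale in scales:
        for feature in features:
            try:
                results.append(fit_scale_on_actigraphy(data, scale, feature, covariates))
            except ValueError:
                continue
    if not results:
        return pd.DataFrame(columns=["scale", "feature", "estimate", "p_value",
                                     "q_value", "n_obs", "n_participants", "degenerate"])
    q = bh_adjust([r.p_value for r in results], fdr_family)
    rows = []
    for r, qv in zip(results, q):
        rows.append({"scale": r.scale_name, "feature": r.actigraphy_feature,
                     "estimate": r.estimate, "p_value": r.p_value, "q_value": qv,
                     "n_obs": r.n_obs, "n_participants": r.n_participants,
                     "degenerate": r.degenerate})
    return pd.DataFrame(rows)
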