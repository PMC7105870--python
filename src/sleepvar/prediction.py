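"""Anxiety prediction: feature assembly, collinearity preprocessing,
elastic-net fitting, the repeated nested cross-validation protocol, and the
goodness-of-fit-weighted feature-importance score.

The predictor set has p = 17 columns: mean/SD/CV of the four actigraphy
sleep measures (12), the caregiver sleep item, age, sex, IQ and ADOS CSS;
the response is the caregiver anxiety total.  Preprocessing flags near-zero
variance columns, iteratively removes correlated predictors until all
pairwise |r| < 0.7, and checks variance inflation factors against 10.

The elastic net minimizes

    (1/2N) sum_i (y_i - b0 - x_i' b)^2 + lambda * sum_j ((1-a)/2 b_j^2 + a |b_j|)

over a grid of mixing values a in {0, 0.05, ..., 1} and a log-spaced lambda
path.  The protocol repeatedly (default 100x) splits participants 70/30,
selects (a*, lambda*) on the training side by repeated (default 100x)
10-fold cross-validation, refits on the full training side, and scores the
held-out side by MSE, test R^2 and the regression F-test against an
intercept-only model.  Feature importance accumulates, over test sets s,
the selection indicator times w_s = r_s * f_s (test R^2 gated by F-test
significance), and is finally normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import enet_path

ACTIGRAPHY_MEASURES = ("sleep_start", "duration", "awakenings", "efficiency")
ACTIGRAPHY_FEATURES = tuple(f"{m}_{s}" for m in ACTIGRAPHY_MEASURES
                            for s in ("mean", "sd", "cv"))
EXTRA_FEATURES = ("abi_sleep", "age", "sex", "iq", "ados_css")
ALL_FEATURES = ACTIGRAPHY_FEATURES + EXTRA_FEATURES   # p = 17
RESPONSE = "casi_anx"


@dataclass
class ElasticNetConfig:
    """Protocol parameters (defaults follow the published protocol)."""

    alpha_grid: tuple[float, ...] = tuple(float(a) for a in np.round(np.arange(0, 1.0001, 0.05), 2))
    n_inner_folds: int = 10
    n_inner_reps: int = 100
    n_outer_reps: int = 100
    train_fraction: float = 0.70
    lambda_rule: str = "min_mse"          # or "min_mse_plus_1se"
    n_lambda: int = 100
    lambda_decades: float = 4.0
    split_unit: str = "participant"       # or "row"
    importance_denominator: int | None = None   # None -> number of test sets S
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 <= a <= 1 for a in self.alpha_grid):
            raise ValueError("alpha grid values must lie in [0, 1]")
        if self.n_inner_folds < 2:
            raise ValueError("need at least 2 folds")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.lambda_rule not in ("min_mse", "min_mse_plus_1se"):
            raise ValueError(f"unknown lambda rule {self.lambda_rule!r}")


# ---------------------------------------------------------------- preprocessing

def flag_near_zero_variance(column, n_samples: int | None = None) -> bool:
    """Near-zero-variance rule: unique fraction < 10% AND the frequency ratio
    of the two most common values > 19 (strict; a single-valued column has an
    infinite ratio and is always flagged)."""
    col = pd.Series(column).dropna()
    if len(col) == 0:
        raise ValueError("column is empty")
    n = n_samples if n_samples is not None else len(col)
    counts = col.value_counts().to_numpy()
    unique_frac = len(counts) / n
    ratio = np.inf if len(counts) < 2 else counts[0] / counts[1]
    return bool(unique_frac < 0.10 and ratio > 19)


def remove_correlated(features: pd.DataFrame, threshold: float = 0.7) -> list[str]:
    """Iteratively drop predictors until all pairwise |r| < threshold.

    At each step the pair with the largest |correlation| at or above the
    threshold is found and the member with the larger mean absolute
    correlation to all remaining features is dropped (ties: the later
    column).  Returns the retained column names in original order.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        return cols
    corr = features[cols].corr().abs().to_numpy()
    keep = list(range(len(cols)))
    while len(keep) > 1:
        sub = corr[np.ix_(keep, keep)]
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < threshold:
            break
        mean_i = sub[i].sum() / (len(keep) - 1)
        mean_j = sub[j].sum() / (len(keep) - 1)
        drop_local = i if mean_i > mean_j else j if mean_j > mean_i else max(i, j)
        keep.pop(drop_local)
    return [cols[i] for i in keep]


def compute_vif(features: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per feature: VIF_j = 1 / (1 - R^2_j) from an
    intercept-including OLS of feature j on all the others."""
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF requires at least 2 features")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        # name the columns implicated in the exact dependence
        bad = []
        for j, name in enumerate(features.columns):
            others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.sum(resid ** 2) < 1e-10 * max(1.0, np.sum(X[:, j] ** 2)):
                bad.append(name)
        raise ValueError(f"feature matrix is rank deficient; collinear set: {bad}")
    vifs = {}
    for j, name in enumerate(features.columns):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta = np.linalg.lstsq(others, yj, rcond=None)[0]
        resid = yj - others @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / sst
        vifs[name] = 1.0 / max(1.0 - r2, 1e-300)
    return pd.Series(vifs)


@dataclass
class PreprocessResult:
    retained: list[str]
    nzv_flagged: list[str]
    corr_dropped: list[str]
    vif_dropped: list[str]
    vif: pd.Series


def preprocess_features(
    features: pd.DataFrame,
    corr_threshold: float = 0.7,
    vif_threshold: float = 10.0,
) -> PreprocessResult:
    """Full chain: near-zero-variance flagging, iterative decorrelation,
    VIF check (features at or above the threshold are dropped worst-first
    until all retained VIFs are below it)."""
    nzv = [c for c in features.columns if flag_near_zero_variance(features[c])]
    work = features.drop(columns=nzv)
    retained = remove_correlated(work, corr_threshold)
    corr_dropped = [c for c in work.columns if c not in retained]
    vif_dropped: list[str] = []
    vif = compute_vif(features[retained]) if len(retained) >= 2 else pd.Series(dtype=float)
    while len(retained) >= 2:
        vif = compute_vif(features[retained])
        if vif.max() < vif_threshold:
            break
        worst = vif.idxmax()
        vif_dropped.append(worst)
        retained = [c for c in retained if c != worst]
    return PreprocessResult(retained, nzv, corr_dropped, vif_dropped, vif)


# ---------------------------------------------------------------- elastic net

@dataclass
class ElasticNetFit:
    """Coefficients on the standardized-predictor scale plus the transforms
    needed to predict raw inputs."""

    alpha: float
    lam: float
    coef: np.ndarray         # per standardized predictor
    intercept: float         # = mean of y (X standardized to mean zero)
    x_mean: np.ndarray
    x_scale: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return self.intercept + Xs @ self.coef

    @property
    def selected(self) -> np.ndarray:
        return self.coef != 0


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if np.any(scale == 0):
        raise ValueError("cannot standardize constant predictor columns")
    return (X - mean) / scale, mean, scale


def _ridge_path(Xs: np.ndarray, yc: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Closed-form coefficients for the alpha = 0 (pure ridge) grid point:
    minimizes (1/2N)||y - Xb||^2 + (lam/2)||b||^2 for every lam at once."""
    n = len(yc)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    uty = U.T @ yc
    # shape (p, n_lam)
    shrink = s[:, None] / (s[:, None] ** 2 + n * lams[None, :])
    return Vt.T @ (shrink * uty[:, None])


def elastic_net_fit(X, y, alpha: float, lam: float) -> ElasticNetFit:
    """Solve the elastic-net problem at one (alpha, lambda).

    Standardizes predictors and centers the response internally; lambda = 0
    returns the OLS solution, alpha = 0 the closed-form ridge solution, and
    the general case uses coordinate descent at tight tolerance.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, x_mean, x_scale = _standardize(X)
    y_mean = float(y.mean())
    yc = y - y_mean
    if lam == 0:
        coef = np.linalg.lstsq(Xs, yc, rcond=None)[0]
    elif alpha == 0:
        coef = _ridge_path(Xs, yc, np.array([lam]))[:, 0]
    else:
        _, coefs, _ = enet_path(
            np.asfortranarray(Xs), yc, l1_ratio=alpha, alphas=np.array([lam]),
            tol=1e-10, max_iter=100000, check_input=True)
        coef = coefs[:, 0]
    return ElasticNetFit(alpha, lam, np.asarray(coef, dtype=float), y_mean, x_mean, x_scale)


def lambda_path(Xs: np.ndarray, yc: np.ndarray, alpha: float,
                n_lambda: int = 100, decades: float = 4.0) -> np.ndarray:
    """Log-spaced lambda path from lambda_max (all-zero coefficients) down
    ``decades`` decades.  For alpha near 0 the ridge convention caps the
    divisor at 0.001 so the path stays finite."""
    n = len(yc)
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)


# ---------------------------------------------------------------- inner CV

@dataclass
class InnerSelection:
    alpha: float
    lam: float
    cv_table: pd.DataFrame   # per-alpha averaged minimum cross-validated MSE


def _prepare_folds(
    Xs: np.ndarray,
    yc: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> list[tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]]:
    """Standardize each training fold once (shared across the alpha grid)."""
    prep = []
    for tr, va in folds:
        Xtr, x_mean, x_scale = _standardize(Xs[tr])
        icept = yc[tr].mean()
        ytr = yc[tr] - icept
        Xva = (Xs[va] - x_mean) / x_scale
        prep.append((np.asfortranarray(Xtr), ytr, float(icept), Xva, yc[va]))
    return prep


def _cv_mse_for_alpha(
    prep: list[tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]],
    alpha: float,
    lams: np.ndarray,
) -> np.ndarray:
    """Per-(fold, lambda) validation MSE for one alpha along a fixed path."""
    out = np.empty((len(prep), len(lams)))
    for fi, (Xtr, ytr, icept, Xva, yva) in enumerate(prep):
        if alpha == 0:
            coefs = _ridge_path(Xtr, ytr, lams)
        else:
            _, coefs, _ = enet_path(Xtr, ytr, l1_ratio=alpha, alphas=lams,
                                    check_input=False)
        pred = icept + Xva @ coefs
        out[fi] = np.mean((yva[:, None] - pred) ** 2, axis=0)
    return out


def inner_select_alpha(
    X_train,
    y_train,
    config: ElasticNetConfig,
    rng: np.random.Generator | None = None,
) -> InnerSelection:
    """Select (alpha*, lambda*) by repeated k-fold cross-validation.

    For each alpha on the grid, ``n_inner_reps`` repetitions of k-fold CV
    are run along a per-alpha lambda path; each repetition contributes its
    minimum cross-validated MSE, repetitions are averaged, and the alpha
    with the smallest average wins (ties break toward smaller alpha).
    lambda* comes from the pooled MSE curve at alpha*: its minimizer, or the
    largest lambda within one standard error of the minimum.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    n = len(y)
    if n < 2 * config.n_inner_folds:
        raise ValueError("too few training rows for the requested folds")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    Xs, _, _ = _standardize(X)
    yc = y - y.mean()

    # one fold assignment per repetition, shared across the alpha grid so
    # alphas compete on identical resamples
    rep_preps = []
    k = config.n_inner_folds
    for _ in range(config.n_inner_reps):
        perm = rng.permutation(n)
        splits = np.array_split(perm, k)
        folds = [(np.setdiff1d(perm, va, assume_unique=True), va) for va in splits]
        rep_preps.append(_prepare_folds(Xs, yc, folds))

    best = None
    table_rows = []
    for alpha in config.alpha_grid:
        lams = lambda_path(Xs, yc, alpha, config.n_lambda, config.lambda_decades)
        min_mses = np.empty(config.n_inner_reps)
        pooled = np.zeros((0, len(lams)))
        for ri, prep in enumerate(rep_preps):
            fold_mse = _cv_mse_for_alpha(prep, alpha, lams)
            curve = fold_mse.mean(axis=0)
            min_mses[ri] = curve.min()
            pooled = np.vstack([pooled, fold_mse])
        avg_min = float(min_mses.mean())
        table_rows.append({"alpha": alpha, "avg_min_mse": avg_min})
        if best is None or avg_min < best[0]:
            best = (avg_min, alpha, lams, pooled)

    _, alpha_star, lams, pooled = best
    curve = pooled.mean(axis=0)
    j_min = int(np.argmin(curve))
    if config.lambda_rule == "min_mse":
        lam_star = float(lams[j_min])
    else:
        se = float(np.std(pooled[:, j_min], ddof=1) / np.sqrt(config.n_inner_folds))
        within = np.flatnonzero(curve <= curve[j_min] + se)
        lam_star = float(lams[within[0]])    # path is descending: first = largest lambda
    return InnerSelection(float(alpha_star), lam_star, pd.DataFrame(table_rows))


# ---------------------------------------------------------------- outer protocol

@dataclass
class ImportanceResult:
    """Per-split records and aggregated normalized feature importances."""

    feature_names: list[str]
    records: pd.DataFrame        # one row per outer test set
    selections: np.ndarray       # (S, p) selection indicators c_sj
    importance: pd.DataFrame     # feature, raw, normalized
    all_zero: bool = False


def _split_groups(
    groups: np.ndarray,
    train_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    uniq = np.unique(groups)
    perm = rng.permutation(uniq)
    n_train = max(1, int(round(train_fraction * len(uniq))))
    n_train = min(n_train, len(uniq) - 1)
    train_ids = set(perm[:n_train])
    mask = np.array([g in train_ids for g in groups])
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def feature_importance(
    selections: np.ndarray,
    r2: np.ndarray,
    f_sig: np.ndarray,
    feature_names: Sequence[str],
    denominator: int | None = None,
) -> pd.DataFrame:
    """Goodness-of-fit-weighted selection frequency, normalized to [0, 1].

    raw_j = sum_s c_sj * (r_s * f_s) / S; the raw vector is then divided by
    its maximum (all-zero raw vectors stay zero)."""
    S = selections.shape[0]
    denom = denominator if denominator is not None else S
    w = r2 * f_sig
    raw = (selections * w[:, None]).sum(axis=0) / denom
    top = raw.max()
    normalized = raw / top if top > 0 else np.zeros_like(raw)
    return pd.DataFrame({"feature": list(feature_names), "raw": raw,
                         "normalized": normalized})


def outer_protocol(
    features: pd.DataFrame,
    y,
    groups,
    config: ElasticNetConfig | None = None,
) -> ImportanceResult:
    """Repeated 70/30 nested cross-validation with per-split scoring.

    For each outer repetition: split at the participant level (all visits of
    a participant on one side), select (alpha*, lambda*) by the inner CV,
    refit on the full training side, and score the held-out side: MSE, test
    R^2 (1 - SSE/SST about the test mean), and the regression F-test of the
    refit model against an intercept-only model (df1 = number of selected
    features, df2 = n_test - df1 - 1).  Splits leaving a constant predictor
    column in the training side are redrawn.
    """
    config = config or ElasticNetConfig()
    X = features.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups if config.split_unit == "participant"
                        else np.arange(len(y)))
    rng = np.random.default_rng(config.seed)

    names = list(features.columns)
    p = X.shape[1]
    selections = np.zeros((config.n_outer_reps, p), dtype=int)
    rows = []
    for s in range(config.n_outer_reps):
        for _ in range(50):
            tr, te = _split_groups(groups, config.train_fraction, rng)
            if len(te) >= 3 and np.all(X[tr].std(axis=0) > 0):
                break
        else:
            raise RuntimeError("could not find a usable train/test split")
        sel = inner_select_alpha(X[tr], y[tr], config, rng)
        fit = elastic_net_fit(X[tr], y[tr], sel.alpha, sel.lam)
        pred = fit.predict(X[te])
        resid = y[te] - pred
        sse = float(np.sum(resid ** 2))
        sst = float(np.sum((y[te] - y[te].mean()) ** 2))
        mse = sse / len(te)
        r2 = 1.0 - sse / sst if sst > 0 else np.nan
        k = int(np.sum(fit.selected))
        df1 = max(k, 1)
        df2 = len(te) - df1 - 1
        if df2 > 0 and sst > 0 and sse > 0 and r2 > 0:
            fstat = (r2 / df1) / ((1 - r2) / df2)
            f_p = float(scipy.stats.f.sf(fstat, df1, df2))
        else:
            fstat, f_p = np.nan, 1.0
        f_sig = int(f_p < 0.05)
        selections[s] = fit.selected.astype(int)
        rows.append({"split": s, "alpha": sel.alpha, "lambda": sel.lam,
                     "n_train": len(tr), "n_test": len(te), "mse": mse,
                     "r2": r2, "f_stat": fstat, "f_p": f_p, "f_sig": f_sig,
                     "n_selected": k})
    records = pd.DataFrame(rows)
    imp = feature_importance(
        selections, records["r2"].to_numpy(), records["f_sig"].to_numpy(),
        names, config.importance_denominator)
    return ImportanceResult(
        feature_names=names, records=records, selections=selections,
        importance=imp, all_zero=bool(imp["raw"].max() <= 0))


# ---------------------------------------------------------------- assembly

def assemble_features(
    windows: pd.DataFrame,
    scales: pd.DataFrame,
    profiles: pd.DataFrame,
    visits: tuple[str, ...] = ("midpoint", "endpoint"),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build the 17-column feature table with the anxiety response.

    Joins included participant-visit windows with same-visit scale scores and
    participant profiles; ASD rows only (ADOS CSS is an ASD-only feature);
    sex encoded 0/1; complete cases.  Returns (X, y, participant ids).
    """
    w = windows[windows["included"] & windows["visit"].isin(visits)]
    merged = (w.merge(scales, on=["participant_id", "visit"], how="inner")
               .merge(profiles, on="participant_id", how="inner"))
    merged = merged[merged["group"] == "ASD"].copy()
    merged["sex"] = merged["sex"].map({"female": 0, "male": 1})
    cols = list(ALL_FEATURES)
    merged = merged.dropna(subset=cols + [RESPONSE])
    X = merged[cols].reset_index(drop=True)
    y = merged[RESPONSE].to_numpy(dtype=float)
    groups = merged["participant_id"].to_numpy()
    return X, y, groups
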