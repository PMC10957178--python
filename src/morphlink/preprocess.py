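"""Imputation, deconfounding, standardization, harmonization and the
case-control sensitivity machinery (binary risk-composite classification,
matching, group-difference maps).

The ordering convention for the main pipeline is: k-NN imputation of the
clinical block (within variable group), OLS residualization of both blocks
against the confounds, then column z-scoring. All functions accept pandas
DataFrames and preserve index/columns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy import stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

__all__ = [
    "impute_knn",
    "residualize_confounds",
    "zscore_columns",
    "harmonize_across_cohorts",
    "classify_mets",
    "match_cases_controls",
    "group_difference_map",
    "DEFAULT_METS_THRESHOLDS",
]


def impute_knn(
    table: pd.DataFrame,
    groups: dict[str, str] | None = None,
    k: int = 4,
) -> pd.DataFrame:
    """k-nearest-neighbour imputation restricted to each variable group.

    Missing cells are replaced by the unweighted mean of the k nearest
    subjects' observed values, with neighbours found by Euclidean distance
    on the z-scored variables of the *same* group (e.g. a missing lipid
    value is imputed from the other lipid measurements only). If a subject
    is missing an entire group, its values are imputed from all columns
    jointly and a warning is emitted.

    Distances on z-scored columns with mean-of-raw-neighbour imputation are
    affine-equivalent to running ``sklearn.impute.KNNImputer`` on the
    z-scored columns and undoing the scaling, which is how this is backed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if groups is None:
        groups = {c: "all" for c in table.columns}
    missing_cols = set(table.columns) - set(groups)
    if missing_cols:
        raise ValueError(f"columns without group label: {sorted(missing_cols)}")

    out = table.copy()
    group_names = sorted(set(groups.values()))

    def _impute_block(block: pd.DataFrame) -> pd.DataFrame:
        mu = block.mean()
        sd = block.std(ddof=1).replace(0.0, 1.0)
        z = (block - mu) / sd
        imp = KNNImputer(n_neighbors=k, weights="uniform")
        filled = pd.DataFrame(imp.fit_transform(z), index=block.index, columns=block.columns)
        return filled * sd + mu

    for g in group_names:
        cols = [c for c in table.columns if groups[c] == g]
        block = table[cols]
        if not block.isna().any().any():
            continue
        out[cols] = _impute_block(block)

    # subjects missing an entire group: fall back to all clinical columns
    whole_group_missing = False
    for g in group_names:
        cols = [c for c in table.columns if groups[c] == g]
        if table[cols].isna().all(axis=1).any():
            whole_group_missing = True
    if whole_group_missing:
        warnings.warn(
            "at least one subject is missing an entire variable group; "
            "imputing those subjects from all clinical variables",
            RuntimeWarning,
            stacklevel=2,
        )
        full = _impute_block(table)
        for g in group_names:
            cols = [c for c in table.columns if groups[c] == g]
            rows = table[cols].isna().all(axis=1)
            out.loc[rows, cols] = full.loc[rows, cols]

    return out


def _design(confounds: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([np.ones(len(confounds)), confounds.to_numpy(float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by leave-one-out rank
        bad = []
        for j, col in enumerate(confounds.columns):
            Xr = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                bad.append(col)
        raise ValueError(f"confound matrix is rank-deficient; collinear columns: {bad}")
    return X


def residualize_confounds(data, confounds: pd.DataFrame):
    """Replace each column by its OLS residual against [1, confounds].

    The confounds must be complete; residual columns are exactly orthogonal
    to every confound column (and mean zero). Idempotent.
    """
    if confounds.isna().any().any():
        raise ValueError("confounds must be complete")
    is_df = isinstance(data, pd.DataFrame)
    Y = data.to_numpy(float) if is_df else np.asarray(data, float)
    if Y.shape[0] != len(confounds):
        raise ValueError("data and confounds must have the same number of rows")
    if Y.shape[0] <= confounds.shape[1] + 1:
        raise ValueError("need n_subjects > n_confounds + 1")
    X = _design(confounds)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    if is_df:
        return pd.DataFrame(resid, index=data.index, columns=data.columns)
    return resid


def zscore_columns(data, ddof: int = 1):
    """Column-wise z-scoring (sample SD). Constant columns are an error."""
    is_df = isinstance(data, pd.DataFrame)
    X = data.to_numpy(float) if is_df else np.asarray(data, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    const = np.where(sd == 0)[0]
    if const.size:
        names = (
            [data.columns[i] for i in const] if is_df else const.tolist()
        )
        raise ValueError(f"constant columns cannot be z-scored: {names}")
    Z = (X - mu) / sd
    if is_df:
        return pd.DataFrame(Z, index=data.index, columns=data.columns)
    return Z


def harmonize_across_cohorts(values, cohort) -> np.ndarray:
    """Two-stage z-scoring for test scores pooled over cohorts.

    Values are z-scored within each cohort (removing cohort-specific mean
    and scale, e.g. different versions of the same cognitive test), then
    the pooled vector is z-scored once more.
    """
    v = np.asarray(values, float)
    labels = np.asarray(cohort)
    if v.shape != labels.shape:
        raise ValueError("values and cohort labels must align")
    out = np.empty_like(v)
    for lab in np.unique(labels):
        m = labels == lab
        obs = v[m]
        obs = obs[~np.isnan(obs)]
        if obs.size < 3:
            raise ValueError(f"cohort {lab!r} has fewer than 3 observed values")
        sd = obs.std(ddof=1)
        if sd == 0:
            raise ValueError(f"cohort {lab!r} has constant values")
        out[m] = (v[m] - obs.mean()) / sd
    obs = out[~np.isnan(out)]
    return (out - obs.mean()) / obs.std(ddof=1)


# Conventional consensus cut-offs for the binary risk-composite definition;
# all overridable through config.
DEFAULT_METS_THRESHOLDS = {
    "waist_male": 94.0,        # cm
    "waist_female": 80.0,      # cm
    "triglycerides": 150.0,    # mg/dL
    "hdl_male": 40.0,          # mg/dL (below => positive criterion)
    "hdl_female": 50.0,        # mg/dL
    "bp_systolic": 130.0,      # mmHg
    "bp_diastolic": 85.0,      # mmHg
    "glucose": 100.0,          # mg/dL
}


def classify_mets(
    table: pd.DataFrame, thresholds: dict | None = None
) -> pd.Series:
    """Binary metabolic-syndrome classification (IDF-style consensus rule).

    Positive iff the central-obesity criterion (sex-specific waist cut-off)
    holds AND at least two of: elevated triglycerides, low HDL
    (sex-specific), elevated blood pressure or antihypertensive therapy,
    elevated glucose or antidiabetic therapy.

    Required columns: waist, triglycerides, hdl, bp_systolic, bp_diastolic,
    glucose, sex (1=female, 0=male), antihypertensive, antidiabetic
    (treatment flags 0/1; lipid treatment is not part of the rule here).
    """
    thr = dict(DEFAULT_METS_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    required = [
        "waist", "triglycerides", "hdl", "bp_systolic", "bp_diastolic",
        "glucose", "sex", "antihypertensive", "antidiabetic",
    ]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing required variables: {missing}")
    if table[required].isna().any().any():
        raise ValueError("missing values in required variables; impute first")

    female = table["sex"].astype(int) == 1
    waist_cut = np.where(female, thr["waist_female"], thr["waist_male"])
    hdl_cut = np.where(female, thr["hdl_female"], thr["hdl_male"])

    central_obesity = table["waist"].to_numpy() >= waist_cut
    high_tg = table["triglycerides"].to_numpy() >= thr["triglycerides"]
    low_hdl = table["hdl"].to_numpy() < hdl_cut
    high_bp = (
        (table["bp_systolic"].to_numpy() >= thr["bp_systolic"])
        | (table["bp_diastolic"].to_numpy() >= thr["bp_diastolic"])
        | (table["antihypertensive"].astype(int).to_numpy() == 1)
    )
    high_glc = (table["glucose"].to_numpy() >= thr["glucose"]) | (
        table["antidiabetic"].astype(int).to_numpy() == 1
    )
    n_secondary = (
        high_tg.astype(int) + low_hdl.astype(int) + high_bp.astype(int) + high_glc.astype(int)
    )
    label = central_obesity & (n_secondary >= 2)
    return pd.Series(label.astype(int), index=table.index, name="mets")


def match_cases_controls(
    cases: pd.Index | list,
    pool: pd.Index | list,
    covariates: pd.DataFrame,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Distances are Mahalanobis over the covariate columns (typically age,
    sex, education); cases are processed in a seed-fixed random order, each
    taking its nearest remaining control. Returns (pairs, balance) where
    balance holds the standardized mean difference per covariate before
    and after matching.
    """
    cases = pd.Index(cases)
    pool = pd.Index(pool)
    if len(pool) < len(cases):
        raise ValueError("control pool smaller than case list")
    X = covariates.loc[cases].to_numpy(float)
    P = covariates.loc[pool].to_numpy(float)
    cov = np.cov(np.vstack([X, P]).T)
    cov = np.atleast_2d(cov)
    VI = np.linalg.pinv(cov)
    D = cdist(X, P, metric="mahalanobis", VI=VI)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    used = np.zeros(len(pool), dtype=bool)
    pair_rows = []
    for i in order:
        d = np.where(used, np.inf, D[i])
        j = int(np.argmin(d))
        used[j] = True
        pair_rows.append((cases[i], pool[j], float(D[i, j])))
    pairs = pd.DataFrame(pair_rows, columns=["case", "control", "distance"])
    pairs = pairs.sort_values("case").reset_index(drop=True)

    def _smd(a: np.ndarray, b: np.ndarray) -> float:
        s = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        if s == 0:
            return 0.0
        return float((a.mean() - b.mean()) / s)

    matched_controls = covariates.loc[pairs["control"]].to_numpy(float)
    balance = pd.DataFrame(
        {
            "smd_before": [_smd(X[:, j], P[:, j]) for j in range(X.shape[1])],
            "smd_after": [_smd(X[:, j], matched_controls[:, j]) for j in range(X.shape[1])],
        },
        index=covariates.columns,
    )
    return pairs, balance


def group_difference_map(
    morph: pd.DataFrame,
    labels,
    confounds: pd.DataFrame,
) -> pd.DataFrame:
    """Per-parcel GLM group contrast with BH-FDR correction.

    Each parcel's measure is regressed on [intercept, group, confounds];
    the group coefficient's t statistic and its Benjamini-Hochberg q-value
    are returned per parcel. This is the parcel-level analogue of a
    case-control vertex-wise comparison.
    """
    g = np.asarray(labels, float)
    if len(np.unique(g)) < 2:
        raise ValueError("need both groups non-empty")
    X = np.column_stack([np.ones(len(g)), g, confounds.to_numpy(float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "group indicator is collinear with confounds; proceeding",
            RuntimeWarning,
            stacklevel=2,
        )
    Y = morph.to_numpy(float)
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"t": t, "p": p, "q": q}, index=morph.columns)
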