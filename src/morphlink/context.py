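"""Contextualization of parcel effect maps against cell-type expression
and connectome topology.

Two families of analysis consume an effect map (bootstrap ratio or group
t-statistic per parcel):

- virtual histology / ensemble gene-category enrichment (GCEA): per cell
  category, Spearman-correlate the effect map with each member gene's
  expression map, Fisher-z the coefficients and average into Z(rsp); test
  against spatial-lag surrogates of the effect map and BH-FDR across
  categories;
- network topology: weighted degree centrality (hubness ranks),
  neighborhood abnormality A_i = (1/N_i) sum_{j in N_i} C_j w_ij
  (degree-normalized connectivity-weighted mean of the neighbours'
  effects), and diffusion-map connectivity gradients; each related to the
  effect map by Spearman correlation with spin / variogram / rewiring
  nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mediation import fdr_adjust
from .nulls import (
    empirical_pvalue,
    rewire_connectome,
    spatial_lag_surrogates,
    spin_surrogates,
    variogram_surrogates,
)
from .synth import Connectome, ParcelGeometry

__all__ = [
    "ContextResult",
    "degree_centrality_rank",
    "neighborhood_abnormality",
    "connectivity_gradients",
    "spatial_correlation",
    "neighborhood_correlation",
    "cell_density_maps",
    "gcea_cell_types",
]


@dataclass
class ContextResult:
    """Spearman statistic with per-null-method empirical p-values."""

    statistic: float                      # rsp or aggregate Z(rsp)
    p: dict[str, float] = field(default_factory=dict)
    q: dict[str, float] = field(default_factory=dict)
    label: str = ""


def degree_centrality_rank(connectome: Connectome) -> np.ndarray:
    """Weighted degree (strength) per node, returned as ascending ranks.

    Strength is the row sum of connection weights; ties get the average
    rank. Larger rank = stronger hub. Negative weights are an error:
    functional matrices must be preprocessed to non-negative first.
    """
    W = connectome.weights
    if np.any(W < 0):
        raise ValueError("negative weights; threshold or absolutize first")
    return stats.rankdata(W.sum(axis=1))


def neighborhood_abnormality(connectome: Connectome, values) -> np.ndarray:
    """Degree-normalized connectivity-weighted neighbour mean of an effect.

    A_i = (1 / N_i) * sum_{j in N_i} C_j * w_ij, where N_i counts node i's
    nonzero connections. Isolated nodes get NaN and should be excluded
    from downstream correlation.
    """
    C = np.asarray(values, float)
    W = connectome.weights
    if C.size != W.shape[0]:
        raise ValueError("map length must match connectome size")
    N = (W > 0).sum(axis=1).astype(float)
    if np.all(N == 0):
        raise ValueError("all nodes are isolated")
    with np.errstate(invalid="ignore", divide="ignore"):
        A = (W @ C) / N
    A[N == 0] = np.nan
    return A


def connectivity_gradients(
    fc: Connectome, n_components: int = 2, sparsity: float = 0.9, alpha: float = 0.5
) -> np.ndarray:
    """Diffusion-map embedding gradients of a connectivity matrix.

    Rows are sparsified to their top (1 - sparsity) fraction of entries,
    a cosine-similarity affinity is built between sparsified connectivity
    profiles, and anisotropic diffusion-map embedding (alpha = 0.5,
    automatic diffusion time, i.e. eigenvalue scaling lambda/(1-lambda))
    returns the first ``n_components`` gradients ordered by eigenvalue.
    """
    W = np.asarray(fc.weights, float)
    n = W.shape[0]
    if np.all(W.sum(axis=1) == 0):
        raise ValueError("connectivity matrix has only zero rows")
    # row-wise sparsification to top entries
    S = W.copy()
    thresh = np.quantile(S, sparsity, axis=1, keepdims=True)
    S[S < thresh] = 0.0

    norms = np.linalg.norm(S, axis=1)
    if np.any(norms == 0):
        raise ValueError("sparsified profile is all-zero for some rows")
    aff = (S @ S.T) / np.outer(norms, norms)
    aff = np.clip(aff, 0.0, None)
    np.fill_diagonal(aff, 0.0)

    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components((aff > 0).astype(int), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph is disconnected ({n_comp} components, sizes {sizes.tolist()})"
        )

    # anisotropic normalization L = D^-a K D^-a, then Markov P = D_L^-1 L
    d = aff.sum(axis=1)
    La = aff / np.outer(d**alpha, d**alpha)
    dl = La.sum(axis=1)
    # symmetric conjugate of the Markov matrix for a stable eigendecomposition
    M = La / np.outer(np.sqrt(dl), np.sqrt(dl))
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(dl)[:, None]  # right eigenvectors of P
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    lam = np.clip(evals[1 : n_components + 1], None, 1 - 1e-12)
    grads = psi[:, 1 : n_components + 1] * (lam / (1 - lam))
    return grads


def _common_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.isfinite(a) & np.isfinite(b)


def spatial_correlation(
    map_a,
    map_b,
    geometry: ParcelGeometry | None = None,
    distances: np.ndarray | None = None,
    null_methods: tuple[str, ...] = ("spin",),
    n_null: int = 1000,
    seed: int | None = None,
    label: str = "",
) -> ContextResult:
    """Spearman correlation of two parcel maps with spatially constrained p.

    For each requested null method, ``map_a`` is replaced by its surrogate
    ensemble and the empirical two-tailed p-value of the observed rsp is
    computed. 'spin' needs ``geometry``; 'variogram' and 'spatial_lag'
    need ``distances`` (or a geometry to compute centroid distances from).
    A plain parametric p is always reported under key 'parametric'.
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    mask = _common_mask(a, b)
    if mask.sum() < 10:
        raise ValueError("fewer than 10 parcels in common")
    rsp, p_param = stats.spearmanr(a[mask], b[mask])
    res = ContextResult(statistic=float(rsp), label=label)
    res.p["parametric"] = float(p_param)

    if distances is None and geometry is not None:
        distances = geometry.distances()

    for method in null_methods:
        if method == "spin":
            if geometry is None:
                raise ValueError("spin null requires geometry")
            ens = spin_surrogates(a, geometry, n=n_null, seed=seed)
            cort = ens.parcel_mask
            b_sub = b[cort]
            nulls = np.array(
                [
                    stats.spearmanr(row[np.isfinite(b_sub)], b_sub[np.isfinite(b_sub)])[0]
                    for row in ens.values
                ]
            )
            obs = stats.spearmanr(a[cort][np.isfinite(b_sub)], b_sub[np.isfinite(b_sub)])[0]
            res.p["spin"] = empirical_pvalue(obs, nulls)
        elif method in ("variogram", "spatial_lag"):
            if distances is None:
                raise ValueError(f"{method} null requires distances or geometry")
            gen = variogram_surrogates if method == "variogram" else spatial_lag_surrogates
            ens = gen(a, distances, n=n_null, seed=seed)
            nulls = np.array(
                [stats.spearmanr(row[mask], b[mask])[0] for row in ens.values]
            )
            res.p[method] = empirical_pvalue(rsp, nulls)
        else:
            raise ValueError(f"unknown null method {method!r}")
    return res


def neighborhood_correlation(
    connectome: Connectome,
    effect_map,
    n_null: int = 1000,
    seed: int | None = None,
    n_swaps_per_edge: int = 10,
    label: str = "neighborhood_abnormality",
) -> ContextResult:
    """Correlate an effect map with its own neighborhood abnormality,
    tested against a degree-preserving rewiring null.

    The rewiring null recomputes the neighborhood-abnormality map on each
    rewired connectome (the statistic depends on topology, so the null
    must randomize topology, not the map).
    """
    C = np.asarray(effect_map, float)
    A = neighborhood_abnormality(connectome, C)
    mask = _common_mask(A, C)
    rsp, p_param = stats.spearmanr(A[mask], C[mask])
    res = ContextResult(statistic=float(rsp), label=label)
    res.p["parametric"] = float(p_param)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_null)
    for i in range(n_null):
        rw = rewire_connectome(
            connectome, n_swaps_per_edge=n_swaps_per_edge, seed=int(rng.integers(2**31))
        )
        A_null = neighborhood_abnormality(rw, C)
        m = _common_mask(A_null, C)
        nulls[i] = stats.spearmanr(A_null[m], C[m])[0]
    res.p["rewire"] = empirical_pvalue(rsp, nulls)
    return res


def cell_density_maps(
    expression: pd.DataFrame, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Per-category mean expression map (proxy for cell-population density).

    Each gene's parcel map is z-scored across parcels first, then averaged
    within its category. Genes absent from the expression matrix are
    skipped with a warning; categories left without genes are dropped.
    """
    missing = set(catalog["gene"]) - set(expression.columns)
    if missing:
        warnings.warn(
            f"{len(missing)} catalog gene(s) absent from expression matrix; skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    maps = {}
    for cat, sub in catalog.groupby("category"):
        genes = [g for g in sub["gene"] if g in expression.columns]
        if not genes:
            warnings.warn(f"category {cat!r} has no present genes; excluded",
                          RuntimeWarning, stacklevel=2)
            continue
        block = expression[genes].to_numpy(float)
        z = (block - block.mean(axis=0)) / block.std(axis=0, ddof=1)
        maps[cat] = z.mean(axis=1)
    if not maps:
        raise ValueError("no category has any present gene")
    return pd.DataFrame(maps, index=expression.index)


def _fisher_z_mean(effect_ranked: np.ndarray, gene_ranks: np.ndarray) -> float:
    """Aggregate Fisher-z Spearman correlation of one map with many genes.

    ``effect_ranked``: z-scored ranks of the effect map (n_parcels,);
    ``gene_ranks``: z-scored ranks, (n_parcels, n_genes).
    """
    r = effect_ranked @ gene_ranks / (effect_ranked.size - 1)
    r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    return float(np.arctanh(r).mean())


def _zrank(X: np.ndarray) -> np.ndarray:
    """Rank columns and standardize so that u^T v / (n-1) is Spearman r."""
    R = np.apply_along_axis(stats.rankdata, 0, X)
    return (R - R.mean(axis=0)) / R.std(axis=0, ddof=1)


def gcea_cell_types(
    effect_map,
    expression: pd.DataFrame,
    catalog: pd.DataFrame,
    distances: np.ndarray | None = None,
    geometry: ParcelGeometry | None = None,
    n_surrogates: int = 1000,
    seed: int | None = None,
    aggregation: str = "per_gene",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Ensemble gene-category enrichment of an effect map by cell type.

    Per category the aggregate statistic is the mean Fisher-z-transformed
    Spearman correlation between the effect map and each member gene's
    expression map (``aggregation='per_gene'``), or the Spearman
    correlation with the category-mean density map
    (``aggregation='category_mean'``). The null recomputes the statistic
    with spatial-lag surrogates of the effect map (two-tailed empirical
    p), and BH-FDR corrects across categories.

    Returns a DataFrame indexed by category with columns
    [n_genes, z, p, q, significant].
    """
    effect = np.asarray(effect_map, float)
    if distances is None:
        if geometry is None:
            raise ValueError("need distances or geometry for the surrogate null")
        distances = geometry.distances()
    if aggregation not in ("per_gene", "category_mean"):
        raise ValueError("aggregation must be 'per_gene' or 'category_mean'")

    cats, gene_blocks = [], {}
    for cat, sub in catalog.groupby("category"):
        genes = [g for g in sub["gene"] if g in expression.columns]
        if len(genes) < 2:
            warnings.warn(f"category {cat!r} has < 2 genes; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        cats.append(cat)
        gene_blocks[cat] = _zrank(expression[genes].to_numpy(float))

    if aggregation == "category_mean":
        density = cell_density_maps(expression, catalog)
        gene_blocks = {c: _zrank(density[[c]].to_numpy(float)) for c in cats}

    ens = spatial_lag_surrogates(effect, distances, n=n_surrogates, seed=seed)
    all_maps = np.vstack([effect[None, :], ens.values])
    ranked = _zrank(all_maps.T).T  # rank each map across parcels

    rows = []
    for cat in cats:
        G = gene_blocks[cat]
        zs = np.array([_fisher_z_mean(ranked[i], G) for i in range(ranked.shape[0])])
        z_obs, z_null = zs[0], zs[1:]
        p = empirical_pvalue(z_obs, z_null)
        rows.append({"category": cat, "n_genes": G.shape[1], "z": z_obs, "p": p})
    out = pd.DataFrame(rows).set_index("category")
    out["q"] = fdr_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
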