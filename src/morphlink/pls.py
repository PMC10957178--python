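"""Partial least squares correlation (PLSC) between two data blocks.

The model: given an n x p morphometry block X and an n x q clinical block Y
(both deconfounded and column z-scored), the cross-block Pearson
correlation matrix R (p x q) is decomposed by SVD,

    R = U diag(delta) V^T,

yielding min(p, q) mutually orthogonal latent variables. Each latent
variable pairs a brain "covariance profile" (column of U) with a clinical
one (column of V); its explained variance is delta_j^2 / sum_k delta_k^2.
Inference attaches to the decomposition non-parametrically:

- significance per latent variable via subject-order permutation of X with
  Procrustes re-alignment of the permuted decomposition;
- stability per weight via subject-level bootstrap: bootstrap ratios
  (weight / bootstrap SE, z-like, |BR| > 1.96 conventionally significant)
  for the brain side, percentile confidence intervals for the clinical
  side;
- per-subject expression scores X U and Y V, and k-fold cross-validated
  out-of-sample score correlations.

Usage follows the statsmodels convention::

    model = PLSCorrelation(X, Y)
    res = model.fit(n_perm=5000, n_boot=5000, seed=0)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes

__all__ = [
    "PLSCorrelation",
    "PLSResults",
    "cross_correlation",
    "pls_decompose",
]

BR_THRESHOLD = 1.96  # two-sided 95% normal cut for bootstrap ratios


def cross_correlation(X, Y) -> np.ndarray:
    """Cross-block Pearson correlation matrix R (p regions x q variables)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of subjects")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = Xc.std(axis=0, ddof=1)
    sy = Yc.std(axis=0, ddof=1)
    if np.any(sx == 0) or np.any(sy == 0):
        raise ValueError("constant column in X or Y")
    R = (Xc / sx).T @ (Yc / sy) / (n - 1)
    return np.clip(R, -1.0, 1.0)  # numerical safety


def _svd_signed(R: np.ndarray):
    """SVD of R with the deterministic sign convention: per latent variable,
    flip signs so the V element of largest magnitude is positive."""
    U, delta, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    return U, delta, V


def pls_decompose(R: np.ndarray):
    """Decompose a correlation matrix into latent variables.

    Returns (U, delta, V, explained_variance) with U: p x k, V: q x k,
    k = min(p, q), delta descending and explained variance summing to 1.
    """
    R = np.asarray(R, float)
    if not np.all(np.isfinite(R)):
        raise ValueError("R must be finite")
    U, delta, V = _svd_signed(R)
    ev = delta**2 / (delta**2).sum()
    return U, delta, V, ev


def _aligned_singular_values(R_perm: np.ndarray, V_obs: np.ndarray) -> np.ndarray:
    """Singular values of a permuted decomposition expressed in the observed
    latent-variable basis (orthogonal Procrustes on the clinical side)."""
    Up, dp, Vp = _svd_signed(R_perm)
    Q, _ = orthogonal_procrustes(Vp, V_obs)
    A = (Up * dp) @ Q  # rotation applied jointly to U and delta
    return np.linalg.norm(A, axis=0)


@dataclass
class PLSResults:
    """Fitted PLS correlation results.

    Attributes mirror the latent-variable bookkeeping: singular vectors
    ``u`` (regions) / ``v`` (clinical), singular values ``delta``,
    ``explained_variance``, permutation ``perm_p`` per latent variable,
    ``boot_ratio`` (regions x LVs), ``v_ci`` (clinical x LVs x 2), subject
    ``scores_imaging`` / ``scores_clinical``.
    """

    model: "PLSCorrelation"
    R: np.ndarray
    u: np.ndarray
    v: np.ndarray
    delta: np.ndarray
    explained_variance: np.ndarray
    scores_imaging: np.ndarray
    scores_clinical: np.ndarray
    perm_p: np.ndarray | None = None
    boot_ratio: np.ndarray | None = None
    v_ci: np.ndarray | None = None
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_lv(self) -> int:
        return self.delta.size

    def significant_regions(self, lv: int = 0, threshold: float = BR_THRESHOLD):
        """Boolean mask of regions with |bootstrap ratio| above threshold."""
        if self.boot_ratio is None:
            raise ValueError("fit was run without bootstrap")
        return np.abs(self.boot_ratio[:, lv]) > threshold

    def significant_clinical(self, lv: int = 0):
        """Boolean mask of clinical variables whose 95% CI excludes zero."""
        if self.v_ci is None:
            raise ValueError("fit was run without bootstrap")
        lo, hi = self.v_ci[:, lv, 0], self.v_ci[:, lv, 1]
        return (lo > 0) | (hi < 0)

    def score_correlation(self, lv: int = 0) -> float:
        """Spearman correlation between clinical and imaging subject scores."""
        r, _ = stats.spearmanr(self.scores_clinical[:, lv], self.scores_imaging[:, lv])
        return float(r)

    def summary(self) -> str:
        lines = [
            "PLS correlation results",
            "=" * 60,
            f"subjects: {self.scores_imaging.shape[0]}   "
            f"regions: {self.u.shape[0]}   clinical: {self.v.shape[0]}   "
            f"latent variables: {self.n_lv}",
            f"n_perm: {self.n_perm}   n_boot: {self.n_boot}   seed: {self.seed}",
            "",
            f"{'LV':>3} {'delta':>10} {'expl.var %':>11} {'perm p':>10} {'score r_sp':>11}",
        ]
        for j in range(self.n_lv):
            p = f"{self.perm_p[j]:.4f}" if self.perm_p is not None else "--"
            lines.append(
                f"{j + 1:>3} {self.delta[j]:>10.4f} "
                f"{100 * self.explained_variance[j]:>11.2f} {p:>10} "
                f"{self.score_correlation(j):>11.3f}"
            )
        if self.boot_ratio is not None:
            n_sig = int(self.significant_regions(0).sum())
            lines += [
                "",
                f"LV1: {n_sig} region(s) with |bootstrap ratio| > {BR_THRESHOLD}, "
                f"{int(self.significant_clinical(0).sum())} clinical variable(s) "
                "with 95% CI excluding 0",
            ]
        return "\n".join(lines)

    def plot_explained_variance(self, ax=None):
        """Bar plot of explained variance per latent variable, with the
        permutation p-value annotated when available."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(1, self.n_lv + 1)
        ax.bar(x, 100 * self.explained_variance, color="steelblue")
        if self.perm_p is not None:
            for xi, ev, p in zip(x, 100 * self.explained_variance, self.perm_p):
                ax.annotate(f"p={p:.3g}", (xi, ev), ha="center", va="bottom",
                            fontsize=7, rotation=90)
        ax.set_xlabel("latent variable")
        ax.set_ylabel("explained variance (%)")
        return ax

    def plot_clinical_loadings(self, lv: int = 0, ax=None):
        """Horizontal bar plot of clinical loadings with bootstrap 95% CIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = self.model.clinical_names or [
            f"var{j}" for j in range(self.v.shape[0])
        ]
        y = np.arange(len(names))
        vals = self.v[:, lv]
        if self.v_ci is not None:
            lo, hi = self.v_ci[:, lv, 0], self.v_ci[:, lv, 1]
            ax.errorbar(vals, y, xerr=[vals - lo, hi - vals], fmt="o",
                        color="k", ecolor="gray", capsize=2)
        else:
            ax.plot(vals, y, "ko")
        ax.axvline(0, color="0.7", lw=0.8)
        ax.set_yticks(y, names)
        ax.set_xlabel(f"LV{lv + 1} loading")
        return ax

    def to_dict(self) -> dict:
        d = {
            "delta": self.delta.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "n_perm": self.n_perm,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        if self.perm_p is not None:
            d["perm_p"] = self.perm_p.tolist()
        return d


class PLSCorrelation:
    """PLS correlation model between a morphometry and a clinical block.

    Parameters
    ----------
    X : array-like or DataFrame, n_subjects x n_regions
        Deconfounded, z-scored morphometry block.
    Y : array-like or DataFrame, n_subjects x n_clinical
        Deconfounded, z-scored clinical block.
    """

    def __init__(self, X, Y):
        self.region_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        self.clinical_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
        self.X = np.asarray(X, float)
        self.Y = np.asarray(Y, float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must share the subject dimension")

    # -- core ---------------------------------------------------------------

    def fit(
        self,
        n_perm: int = 5000,
        n_boot: int = 5000,
        seed: int | None = None,
    ) -> PLSResults:
        """Decompose, then run permutation and bootstrap inference.

        Set ``n_perm=0`` or ``n_boot=0`` to skip either stage.
        """
        R = cross_correlation(self.X, self.Y)
        U, delta, V, ev = pls_decompose(R)
        res = PLSResults(
            model=self,
            R=R,
            u=U,
            v=V,
            delta=delta,
            explained_variance=ev,
            scores_imaging=self.X @ U,
            scores_clinical=self.Y @ V,
            n_perm=n_perm,
            n_boot=n_boot,
            seed=seed,
        )
        self._check_invariants(res)
        rng = np.random.default_rng(seed)
        if n_perm:
            res.perm_p = self.permutation_pvalues(n_perm, rng=rng, results=res)
        if n_boot:
            res.boot_ratio, res.v_ci = self.bootstrap_stability(
                n_boot, rng=rng, results=res
            )
        return res

    @staticmethod
    def _check_invariants(res: PLSResults):
        k = res.n_lv
        assert np.allclose(res.u.T @ res.u, np.eye(k), atol=1e-8)
        assert np.allclose(res.v.T @ res.v, np.eye(k), atol=1e-8)
        assert np.all(np.diff(res.delta) <= 1e-12) and np.all(res.delta >= 0)
        assert abs(res.explained_variance.sum() - 1) < 1e-10
        assert np.allclose((res.u * res.delta) @ res.v.T, res.R, atol=1e-8)

    # -- inference ----------------------------------------------------------

    def permutation_pvalues(
        self,
        n_perm: int = 5000,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        results: PLSResults | None = None,
        align: str = "sorted",
    ) -> np.ndarray:
        """Permutation p-value per latent variable.

        Rows of X are shuffled (breaking the subject-level coupling while
        preserving each block's internal correlation structure), the
        decomposition is recomputed, and the observed explained variance of
        latent variable j is compared against the permuted explained
        variances: p = (1 + #{perm >= observed}) / (1 + n_perm).

        ``align='sorted'`` (default) compares rank-for-rank against the
        descending permuted explained variances; this is exchangeable
        under the null and therefore calibrated. ``align='procrustes'``
        instead rotates each permuted decomposition onto the observed V
        before reading off per-LV variance; it keeps the identity of the
        latent variables but is strongly anticonservative for LV1 (the
        observed value is an extreme order statistic while the aligned
        null is not), so it is off by default.
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if align not in ("sorted", "procrustes"):
            raise ValueError("align must be 'sorted' or 'procrustes'")
        if rng is None:
            rng = np.random.default_rng(seed)
        if results is None:
            R = cross_correlation(self.X, self.Y)
            U, delta, V, ev = pls_decompose(R)
        else:
            V, ev = results.v, results.explained_variance
        n = self.X.shape[0]
        exceed = np.zeros(ev.size)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Rp = cross_correlation(self.X[perm], self.Y)
            if align == "procrustes":
                dp = _aligned_singular_values(Rp, V)
            else:
                dp = np.linalg.svd(Rp, compute_uv=False)
            ev_p = dp**2 / (dp**2).sum()
            if align == "sorted":
                ev_p = np.sort(ev_p)[::-1]
            exceed += ev_p >= ev
        return (1 + exceed) / (1 + n_perm)

    def bootstrap_stability(
        self,
        n_boot: int = 5000,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        results: PLSResults | None = None,
        max_retries: int = 10,
    ):
        """Subject-level bootstrap of the singular vectors.

        Subjects are resampled with replacement jointly from X and Y; each
        resample's decomposition is aligned to the original via orthogonal
        Procrustes on V (the smaller, stabler side), with the rotation
        applied to both U and V. Returns (boot_ratio, v_ci):
        boot_ratio[i, j] = u[i, j] / SD_boot(aligned u[i, j]);
        v_ci[:, j] = percentile 2.5 / 97.5 of aligned V weights.
        """
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        if results is None:
            R = cross_correlation(self.X, self.Y)
            U, delta, V, _ = pls_decompose(R)
        else:
            U, V = results.u, results.v
        n = self.X.shape[0]
        u_samples = np.empty((n_boot, *U.shape))
        v_samples = np.empty((n_boot, *V.shape))
        for b in range(n_boot):
            for attempt in range(max_retries + 1):
                idx = rng.integers(0, n, n)
                Xb, Yb = self.X[idx], self.Y[idx]
                if Xb.std(axis=0).min() > 0 and Yb.std(axis=0).min() > 0:
                    break
                warnings.warn(
                    "bootstrap resample produced a constant column; redrawing",
                    RuntimeWarning,
                    stacklevel=2,
                )
            else:
                raise RuntimeError("could not draw a non-degenerate bootstrap sample")
            Ub, db, Vb = _svd_signed(cross_correlation(Xb, Yb))
            Q, _ = orthogonal_procrustes(Vb, V)
            u_samples[b] = Ub @ Q
            v_samples[b] = Vb @ Q
        u_sd = u_samples.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot_ratio = np.where(u_sd > 0, U / u_sd, np.inf * np.sign(U))
        v_ci = np.stack(
            [
                np.percentile(v_samples, 2.5, axis=0),
                np.percentile(v_samples, 97.5, axis=0),
            ],
            axis=-1,
        )
        return boot_ratio, v_ci

    def cross_validate(self, k: int = 10, seed: int | None = None) -> pd.DataFrame:
        """k-fold out-of-sample score correlation per latent variable.

        Each fold refits the decomposition on the training subjects and
        projects the held-out subjects with the training U, V; the Spearman
        correlation of the held-out imaging and clinical scores is
        reported per fold, with the across-fold mean in the last row.
        """
        n = self.X.shape[0]
        if n < 2 * k:
            raise ValueError("need n >= 2k subjects")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        if min(len(f) for f in folds) < 3:
            raise ValueError("a fold has fewer than 3 subjects")
        n_lv = min(self.X.shape[1], self.Y.shape[1])
        rows = []
        # each fold uses its own (sorted) latent variables: aligning folds
        # to a reference fold would leak training information, since the
        # reference decomposition saw the other folds' test subjects
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(order, test_idx)
            R = cross_correlation(self.X[train_idx], self.Y[train_idx])
            U, delta, V, _ = pls_decompose(R)
            si = self.X[test_idx] @ U
            sc = self.Y[test_idx] @ V
            rows.append(
                [stats.spearmanr(si[:, j], sc[:, j])[0] for j in range(n_lv)]
            )
        df = pd.DataFrame(
            rows,
            index=[f"fold{fi + 1}" for fi in range(k)],
            columns=[f"LV{j + 1}" for j in range(n_lv)],
        )
        df.loc["mean"] = df.mean(axis=0)
        return df
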