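"""Single-mediator bootstrap mediation with covariate adjustment.

The path model, on z-scored variables (x: predictor, e.g. the clinical
latent score; m: mediator, e.g. the imaging latent score; y: outcome,
e.g. a cognitive test):

    m = a x + covariates            (path a)
    y = c' x + b m + covariates     (paths b, c')
    y = c x + covariates            (total effect c)

The indirect effect is ab = a * b, and on a common complete-case sample
the OLS identity ab + c' = c holds exactly. Significance of ab comes from
a subject-level percentile bootstrap; path p-values come from the OLS
t-tests. A relationship is classified as fully mediated when ab is
significant and c' is not, partially mediated when both are significant
and |c'| < |c|.

Usage::

    res = Mediation(x, m, y, covariates).fit(n_boot=5000, seed=0)
    res.ab, res.ci_ab, res.classify()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = ["Mediation", "MediationResults", "mediate_batch", "fdr_adjust"]


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd < 1e-12 * max(1.0, abs(float(v.mean()))):
        raise ValueError("constant input cannot be z-scored")
    return (v - v.mean()) / sd


def _paths(x, m, y, C):
    """OLS path coefficients and t-test p-values on standardized inputs."""
    Xa = sm.add_constant(np.column_stack([x, C]) if C is not None else x)
    fit_a = sm.OLS(m, Xa).fit()
    a, p_a = fit_a.params[1], fit_a.pvalues[1]

    Xb = sm.add_constant(
        np.column_stack([x, m, C]) if C is not None else np.column_stack([x, m])
    )
    fit_b = sm.OLS(y, Xb).fit()
    c_prime, b = fit_b.params[1], fit_b.params[2]
    p_c_prime, p_b = fit_b.pvalues[1], fit_b.pvalues[2]

    fit_c = sm.OLS(y, Xa).fit()
    c, p_c = fit_c.params[1], fit_c.pvalues[1]
    return a, b, c_prime, c, p_a, p_b, p_c_prime, p_c


@dataclass
class MediationResults:
    """Standardized path estimates with bootstrap CI for the indirect effect."""

    a: float
    b: float
    ab: float
    c_prime: float
    c: float
    ci_ab: tuple[float, float]
    p_a: float
    p_b: float
    p_ab: float
    p_c_prime: float
    p_c: float
    n: int
    n_boot: int
    seed: int | None
    # FDR-adjusted p-values; default to the raw p for a standalone fit and
    # are overwritten by mediate_batch when correcting across tests.
    q_a: float = None
    q_b: float = None
    q_ab: float = None
    q_c_prime: float = None
    q_c: float = None

    def __post_init__(self):
        for raw, adj in (("p_a", "q_a"), ("p_b", "q_b"), ("p_ab", "q_ab"),
                         ("p_c_prime", "q_c_prime"), ("p_c", "q_c")):
            if getattr(self, adj) is None:
                setattr(self, adj, getattr(self, raw))

    def classify(self, alpha: float = 0.05) -> str:
        """Mediation class: 'full', 'partial' or 'none' (FDR-adjusted p)."""
        mediating = self.q_ab < alpha and self.q_a < alpha and self.q_b < alpha
        if not mediating:
            return "none"
        if self.q_c_prime >= alpha:
            return "full"
        if abs(self.c_prime) < abs(self.c):
            return "partial"
        return "none"

    def summary(self) -> str:
        lines = [
            "Mediation analysis (standardized paths)",
            "=" * 52,
            f"n = {self.n}   n_boot = {self.n_boot}   seed = {self.seed}",
            f"{'path':>8} {'estimate':>10} {'p':>10} {'q':>10}",
            f"{'a':>8} {self.a:>10.4f} {self.p_a:>10.4g} {self.q_a:>10.4g}",
            f"{'b':>8} {self.b:>10.4f} {self.p_b:>10.4g} {self.q_b:>10.4g}",
            f"{'ab':>8} {self.ab:>10.4f} {self.p_ab:>10.4g} {self.q_ab:>10.4g}",
            f"{'c_prime':>8} {self.c_prime:>10.4f} {self.p_c_prime:>10.4g} {self.q_c_prime:>10.4g}",
            f"{'c':>8} {self.c:>10.4f} {self.p_c:>10.4g} {self.q_c:>10.4g}",
            f"ab 95% CI: [{self.ci_ab[0]:.4f}, {self.ci_ab[1]:.4f}]",
            f"class: {self.classify()}",
        ]
        return "\n".join(lines)


class Mediation:
    """Single-mediator model x -> m -> y with optional covariates.

    Rows with any missing value among x, m, y or the covariates are
    dropped (listwise deletion); all remaining inputs are z-scored before
    fitting, so estimates are standardized slopes.
    """

    def __init__(self, x, m, y, covariates: pd.DataFrame | None = None):
        x = np.asarray(x, float)
        m = np.asarray(m, float)
        y = np.asarray(y, float)
        C = None if covariates is None else np.asarray(covariates, float)
        keep = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
        if C is not None:
            keep &= ~np.isnan(C).any(axis=1)
        x, m, y = x[keep], m[keep], y[keep]
        C = C[keep] if C is not None else None
        n_cov = 0 if C is None else C.shape[1]
        if x.size <= n_cov + 3:
            raise ValueError("too few complete cases")
        if abs(np.corrcoef(x, m)[0, 1]) > 0.999:
            raise ValueError("mediator is collinear with the predictor")
        self.x, self.m, self.y = _zscore(x), _zscore(m), _zscore(y)
        self.C = None if C is None else (C - C.mean(0)) / np.where(
            C.std(0, ddof=1) == 0, 1.0, C.std(0, ddof=1)
        )
        self.n = x.size

    def fit(self, n_boot: int = 5000, seed: int | None = None) -> MediationResults:
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        a, b, c_prime, c, p_a, p_b, p_c_prime, p_c = _paths(
            self.x, self.m, self.y, self.C
        )
        rng = np.random.default_rng(seed)
        ones = np.ones(self.n)
        base_a = (
            np.column_stack([ones, self.x, self.C])
            if self.C is not None
            else np.column_stack([ones, self.x])
        )
        base_b = np.insert(base_a, 2, self.m, axis=1)
        ab_star = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, self.n, self.n)
            a_i = np.linalg.lstsq(base_a[idx], self.m[idx], rcond=None)[0][1]
            b_i = np.linalg.lstsq(base_b[idx], self.y[idx], rcond=None)[0][2]
            ab_star[i] = a_i * b_i
        ci = (float(np.percentile(ab_star, 2.5)), float(np.percentile(ab_star, 97.5)))
        p_lo = (1 + (ab_star <= 0).sum()) / (1 + n_boot)
        p_hi = (1 + (ab_star >= 0).sum()) / (1 + n_boot)
        p_ab = min(1.0, 2 * min(p_lo, p_hi))
        return MediationResults(
            a=float(a), b=float(b), ab=float(a * b), c_prime=float(c_prime),
            c=float(c), ci_ab=ci, p_a=float(p_a), p_b=float(p_b), p_ab=float(p_ab),
            p_c_prime=float(p_c_prime), p_c=float(p_c), n=self.n,
            n_boot=n_boot, seed=seed,
        )


def mediate_batch(
    x,
    m,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One mediation per outcome column, FDR-corrected within path type.

    Listwise deletion is applied per outcome (individuals missing a given
    test are dropped only from that test's model). Returns a table with
    one row per outcome: paths, CI, q-values and mediation class.
    """
    results: dict[str, MediationResults] = {}
    rng = np.random.default_rng(seed)
    for col in outcomes.columns:
        med = Mediation(x, m, outcomes[col], covariates)
        results[col] = med.fit(n_boot=n_boot, seed=int(rng.integers(2**31)))

    names = list(results)
    for path in ("a", "b", "ab", "c_prime", "c"):
        q = fdr_adjust([getattr(results[t], f"p_{path}") for t in names])
        for t, qi in zip(names, q):
            setattr(results[t], f"q_{path}", float(qi))

    rows = []
    for t in names:
        r = results[t]
        rows.append(
            {
                "test": t, "n": r.n, "a": r.a, "b": r.b, "ab": r.ab,
                "c_prime": r.c_prime, "c": r.c,
                "ab_ci_low": r.ci_ab[0], "ab_ci_high": r.ci_ab[1],
                "q_a": r.q_a, "q_b": r.q_b, "q_ab": r.q_ab,
                "q_c_prime": r.q_c_prime, "q_c": r.q_c,
                "class": r.classify(alpha),
            }
        )
    return pd.DataFrame(rows).set_index("test")
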