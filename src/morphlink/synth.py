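"""Synthetic cohorts, parcellations, connectomes and expression maps.

Everything downstream of this module (imputation, deconfounding, PLS
correlation, mediation, spatial nulls, enrichment) assumes data with a
particular statistical structure: a low-rank latent coupling between a
clinical block and a morphometric block, linear confound contamination,
MCAR missingness, spatially autocorrelated parcel maps, distance-decaying
modular connectomes, and cell-category-structured expression. The
generators here plant exactly that structure and record the ground truth,
so every stage of the pipeline can be validated by recovery tests without
access-restricted cohort data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcelGeometry",
    "Connectome",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "gen_sphere_parcellation",
    "gen_smooth_map",
    "gen_connectome",
    "gen_expression",
    "gen_cohort",
]


@dataclass(frozen=True)
class ParcelGeometry:
    """Parcel labels and coordinates for one whole-brain parcellation.

    ``sphere_xyz`` are unit-sphere coordinates (per hemisphere) used by the
    spin test; ``centroid_xyz`` are volumetric coordinates in mm used for
    distance-based nulls. Subcortical parcels may carry NaN sphere
    coordinates (they have no spherical registration).
    """

    parcel_id: np.ndarray        # (n,) str
    hemisphere: np.ndarray       # (n,) 'L' or 'R'
    sphere_xyz: np.ndarray       # (n, 3) unit norm for cortical parcels
    centroid_xyz: np.ndarray     # (n, 3) mm
    structure_class: np.ndarray  # (n,) 'cortical' or 'subcortical'

    def __post_init__(self):
        n = len(self.parcel_id)
        if len(set(self.parcel_id)) != n:
            raise ValueError("parcel_ids must be unique")
        if not set(np.unique(self.hemisphere)) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        cort = self.structure_class == "cortical"
        norms = np.linalg.norm(self.sphere_xyz[cort], axis=1)
        if cort.any() and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("cortical sphere coordinates must be unit-norm")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_id)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances in mm."""
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.centroid_xyz))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_id,
                "hemisphere": self.hemisphere,
                "sphere_x": self.sphere_xyz[:, 0],
                "sphere_y": self.sphere_xyz[:, 1],
                "sphere_z": self.sphere_xyz[:, 2],
                "centroid_x": self.centroid_xyz[:, 0],
                "centroid_y": self.centroid_xyz[:, 1],
                "centroid_z": self.centroid_xyz[:, 2],
                "structure_class": self.structure_class,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParcelGeometry":
        return cls(
            parcel_id=df["parcel_id"].to_numpy(dtype=str),
            hemisphere=df["hemisphere"].to_numpy(dtype=str),
            sphere_xyz=df[["sphere_x", "sphere_y", "sphere_z"]].to_numpy(float),
            centroid_xyz=df[["centroid_x", "centroid_y", "centroid_z"]].to_numpy(float),
            structure_class=df["structure_class"].to_numpy(dtype=str),
        )


@dataclass
class Connectome:
    """Symmetric weighted adjacency matrix with optional planted modules."""

    weights: np.ndarray            # (n, n) symmetric, zero diagonal, >= 0
    parcel_id: np.ndarray | None = None
    modules: np.ndarray | None = None  # planted module label per node
    connected: bool = True

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def density(self) -> float:
        n = self.n_nodes
        return float((self.weights > 0).sum() / (n * (n - 1)))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the full unit sphere (Fibonacci lattice)."""
    golden = (1 + 5 ** 0.5) / 2
    i = np.arange(n)
    z = 1 - 2 * (i + 0.5) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z**2, 0.0, 1.0))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def gen_sphere_parcellation(n_parcels: int, seed: int = 0) -> ParcelGeometry:
    """Quasi-uniform parcel centroids, split L/R.

    Each hemisphere carries its own full unit sphere (as in surface-based
    registration, where left and right cortices are inflated to separate
    spheres) with n_parcels/2 Fibonacci-lattice points; the right
    hemisphere is the x-mirror of the left. Volumetric centroids are the
    sphere coordinates scaled to a 100 mm radius with the hemispheres
    offset along x so the two spheres do not overlap.
    """
    if n_parcels < 4 or n_parcels % 2 != 0:
        raise ValueError("n_parcels must be an even number >= 4")
    half = n_parcels // 2
    left = _fibonacci_sphere(half)
    right = left * np.array([-1.0, 1.0, 1.0])  # mirror

    sphere = np.vstack([left, right])
    # hemispheres offset so that every interhemispheric distance exceeds
    # the intrahemispheric diameter: maps are generated independently per
    # hemisphere, so distance-based machinery (variograms, lag models)
    # must not see cross-hemisphere pairs as near neighbours — mirroring
    # surface-based conventions where distances are per-hemisphere
    offset = np.array([[-210.0, 0.0, 0.0]] * half + [[210.0, 0.0, 0.0]] * half)
    centroid = 100.0 * sphere + offset

    hemi = np.array(["L"] * half + ["R"] * half)
    ids = np.array(
        [f"L_{i:03d}" for i in range(half)] + [f"R_{i:03d}" for i in range(half)]
    )
    return ParcelGeometry(
        parcel_id=ids,
        hemisphere=hemi,
        sphere_xyz=sphere,
        centroid_xyz=centroid,
        structure_class=np.array(["cortical"] * n_parcels),
    )


def gen_smooth_map(
    geometry: ParcelGeometry, lengthscale: float, seed: int = 0
) -> np.ndarray:
    """Spatially autocorrelated parcel map (zero mean, unit variance).

    A Gaussian-process draw with exponential kernel exp(-d / lengthscale)
    on centroid distances, drawn independently per hemisphere so no
    covariance leaks across the midline. ``lengthscale`` is in mm; small
    values approach white noise.
    """
    if lengthscale <= 0:
        raise ValueError("lengthscale must be positive")
    rng = np.random.default_rng(seed)
    values = np.empty(geometry.n_parcels)
    d = geometry.distances()
    for hemi in ("L", "R"):
        idx = np.where(geometry.hemisphere == hemi)[0]
        if idx.size == 0:
            continue
        K = np.exp(-d[np.ix_(idx, idx)] / lengthscale)
        K[np.diag_indices_from(K)] += 1e-8  # jitter for Cholesky
        L = np.linalg.cholesky(K)
        values[idx] = L @ rng.standard_normal(idx.size)
    values -= values.mean()
    sd = values.std()
    if sd > 0:
        values /= sd
    return values


def gen_connectome(
    geometry: ParcelGeometry,
    decay: float = 60.0,
    density: float = 0.2,
    n_modules: int = 1,
    module_boost: float = 3.0,
    seed: int = 0,
) -> Connectome:
    """Distance-decaying, modular, weighted random connectome.

    Edge existence probability is proportional to exp(-d / decay), scaled
    so the expected density matches ``density``, and multiplied by
    ``module_boost`` for node pairs in the same planted module (modules
    are spatially contiguous: k-means on centroids). Weights are uniform
    in (0, 1]. If the realized graph is disconnected the connectome is
    returned with ``connected=False`` and a warning is emitted.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    if decay <= 0:
        raise ValueError("decay must be positive")
    rng = np.random.default_rng(seed)
    n = geometry.n_parcels
    d = geometry.distances()
    iu = np.triu_indices(n, k=1)

    if n_modules > 1:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_modules, n_init=10, random_state=seed)
        modules = km.fit_predict(geometry.centroid_xyz)
    else:
        modules = np.zeros(n, dtype=int)

    base = np.exp(-d[iu] / decay)
    same = modules[iu[0]] == modules[iu[1]]
    base = np.where(same, base * module_boost, base)
    # scale so the expected density matches after clipping at 1 (bisection
    # over the multiplier; plain proportional scaling undershoots once
    # short-range probabilities saturate)
    lo, hi = 0.0, 1.0
    while np.clip(hi * base, 0, 1).mean() < density and hi < 1e12:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.clip(mid * base, 0, 1).mean() < density:
            lo = mid
        else:
            hi = mid
    p = np.clip(hi * base, 0.0, 1.0)

    exists = rng.random(p.size) < p
    w_upper = np.where(exists, 1.0 - rng.random(p.size), 0.0)  # (0, 1]
    W = np.zeros((n, n))
    W[iu] = w_upper
    W += W.T

    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components((W > 0).astype(int), directed=False)
    connected = n_comp == 1
    if not connected:
        import warnings

        warnings.warn(
            f"generated connectome is disconnected ({n_comp} components)",
            RuntimeWarning,
            stacklevel=2,
        )
    return Connectome(
        weights=W, parcel_id=geometry.parcel_id, modules=modules, connected=connected
    )


def gen_expression(
    geometry: ParcelGeometry,
    n_categories: int,
    genes_per_category: int,
    signal_map: np.ndarray | None = None,
    signal_categories: set | frozenset = frozenset(),
    signal_weight: float = 1.0,
    lengthscale: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parcels x genes expression matrix with planted category signal.

    Every gene map is an independent smooth spatial noise draw; genes whose
    category is in ``signal_categories`` additionally load on ``signal_map``
    with weight ``signal_weight``. Returns (expression, catalog) where the
    catalog maps each gene to exactly one category.
    """
    if n_categories < 1 or genes_per_category < 1:
        raise ValueError("need at least one category and one gene per category")
    categories = [f"cat{c:02d}" for c in range(n_categories)]
    unknown = set(signal_categories) - set(categories)
    if unknown:
        raise ValueError(f"signal_categories not in catalog: {sorted(unknown)}")
    if signal_map is not None and len(signal_map) != geometry.n_parcels:
        raise ValueError("signal_map length must match geometry")

    rng = np.random.default_rng(seed)
    cols, gene_names, gene_cats = [], [], []
    for ci, cat in enumerate(categories):
        for g in range(genes_per_category):
            noise = gen_smooth_map(
                geometry, lengthscale, seed=int(rng.integers(2**31))
            )
            gmap = noise.astype(float)
            if signal_map is not None and cat in signal_categories:
                gmap = gmap + signal_weight * np.asarray(signal_map, float)
            cols.append(gmap)
            gene_names.append(f"{cat}_g{g:03d}")
            gene_cats.append(cat)
    expr = pd.DataFrame(
        np.column_stack(cols), index=geometry.parcel_id, columns=gene_names
    )
    expr.index.name = "parcel_id"
    catalog = pd.DataFrame({"gene": gene_names, "category": gene_cats})
    return expr, catalog


CLINICAL_GROUPS = ("obesity", "blood_pressure", "lipids", "glycemic")


@dataclass
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort draw.

    ``coupling_strength`` scales the shared latent signal in both blocks
    relative to ``noise_sd``; ``mediation_effects`` are the standardized
    planted path coefficients (a: clinical latent -> imaging latent,
    b: imaging latent -> cognition, c_prime: direct clinical -> cognition).
    """

    n_subjects: int = 500
    n_regions: int = 60
    n_clinical: int = 12
    coupling_strength: float = 0.8
    noise_sd: float = 0.5
    missing_rate: float = 0.05
    mediation_effects: tuple[float, float, float] = (1.0, 0.3, 0.1)
    n_cognition: int = 3
    confound_strength: float = 0.3
    seed: int = 0
    latent_loadings_u: np.ndarray | None = None  # regions, unit norm
    latent_loadings_v: np.ndarray | None = None  # clinical, unit norm
    confound_effects: np.ndarray | None = None   # (n_confounds, n_vars slopes)

    def validate(self):
        if not (0 <= self.coupling_strength <= 1):
            raise ValueError("coupling_strength must be in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("latent_loadings_u", "latent_loadings_v"):
            v = getattr(self, name)
            if v is not None and not np.isclose(np.linalg.norm(v), 1.0):
                raise ValueError(f"{name} must be unit-norm")
        if self.latent_loadings_u is not None and len(self.latent_loadings_u) != self.n_regions:
            raise ValueError("latent_loadings_u length must equal n_regions")
        if self.latent_loadings_v is not None and len(self.latent_loadings_v) != self.n_clinical:
            raise ValueError("latent_loadings_v length must equal n_clinical")
        a, b, c = self.mediation_effects
        if b**2 + c**2 + 2 * a * b * c >= 1:
            raise ValueError("mediation_effects imply cognition variance > 1")


@dataclass
class SyntheticCohort:
    """One generated cohort plus its planted ground truth."""

    clinical: pd.DataFrame
    clinical_groups: dict[str, str]
    morph: pd.DataFrame
    confounds: pd.DataFrame
    cognition: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def truth_json(self) -> str:
        ser = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()
        }
        return json.dumps(ser, indent=1)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def gen_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw a cohort with planted latent coupling, confounds and mediation.

    Generative model (all latents standardized):

    - t_clin ~ N(0,1); t_img = a*t_clin + sqrt(1-a^2)*e  (a = planted
      clinical->imaging path; a=1 collapses to a single shared latent).
    - clinical_ij = coupling * t_clin_i * v_j + (confounds @ B_clin)_ij
      + noise_sd * eps; morph analogous with u and t_img.
    - cognition_k = b*t_img + c'*t_clin + residual noise scaled so each
      cognition column has unit variance.
    - An MCAR mask at ``missing_rate`` is applied to the clinical block.

    Morph columns are shifted to a positive baseline (thickness-like) so
    the positivity invariant of raw morphometry holds.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, q = spec.n_subjects, spec.n_regions, spec.n_clinical
    a, b, c_prime = spec.mediation_effects

    u = spec.latent_loadings_u
    v = spec.latent_loadings_v
    if u is None:
        u = _unit(rng.standard_normal(p))
    if v is None:
        v = _unit(rng.standard_normal(q))

    t_clin = rng.standard_normal(n)
    t_img = a * t_clin + np.sqrt(max(0.0, 1 - a**2)) * rng.standard_normal(n)

    # confounds: age (years), sex (binary), education (ordinal), cohort (binary)
    confounds = pd.DataFrame(
        {
            "age": rng.uniform(45, 80, n).round(1),
            "sex": rng.integers(0, 2, n),
            "education": rng.integers(1, 5, n),
            "cohort": rng.integers(0, 2, n),
        },
        index=pd.RangeIndex(n, name="subject_id"),
    )
    conf_z = (confounds - confounds.mean()) / confounds.std(ddof=1)
    n_conf = conf_z.shape[1]

    B = spec.confound_effects
    if B is None:
        B = spec.confound_strength * rng.standard_normal((n_conf, p + q))
    B_morph, B_clin = B[:, :p], B[:, p:]

    coup = spec.coupling_strength
    morph = (
        coup * np.outer(t_img, u)
        + conf_z.to_numpy() @ B_morph
        + spec.noise_sd * rng.standard_normal((n, p))
    )
    clinical = (
        coup * np.outer(t_clin, v)
        + conf_z.to_numpy() @ B_clin
        + spec.noise_sd * rng.standard_normal((n, q))
    )

    # positive thickness-like baseline (mm scale)
    morph = morph + 10.0 + 4.0 * np.abs(morph).max()

    sigma2 = 1 - (b**2 + c_prime**2 + 2 * a * b * c_prime)
    cog = np.empty((n, spec.n_cognition))
    for k in range(spec.n_cognition):
        cog[:, k] = (
            b * t_img + c_prime * t_clin + np.sqrt(max(sigma2, 0.0)) * rng.standard_normal(n)
        )

    mask = rng.random((n, q)) < spec.missing_rate
    clinical = np.where(mask, np.nan, clinical)

    clin_cols = [f"clin{j:02d}" for j in range(q)]
    groups = {
        col: CLINICAL_GROUPS[j % len(CLINICAL_GROUPS)] for j, col in enumerate(clin_cols)
    }
    idx = pd.RangeIndex(n, name="subject_id")
    region_ids = [f"region{j:03d}" for j in range(p)]

    truth = {
        "u": u,
        "v": v,
        "t_clin": t_clin,
        "t_img": t_img,
        "coupling_strength": coup,
        "noise_sd": spec.noise_sd,
        "mediation_effects": list(spec.mediation_effects),
        "seed": spec.seed,
    }
    return SyntheticCohort(
        clinical=pd.DataFrame(clinical, index=idx, columns=clin_cols),
        clinical_groups=groups,
        morph=pd.DataFrame(morph, index=idx, columns=region_ids),
        confounds=confounds,
        cognition=pd.DataFrame(
            cog, index=idx, columns=[f"cognition{k}" for k in range(spec.n_cognition)]
        ),
        truth=truth,
    )
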