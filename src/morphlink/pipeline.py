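"""End-to-end pipeline: I/O, configuration, orchestration and reporting.

All inputs and outputs are delimited text (header row, empty field =
missing) plus JSON for scalar results and provenance. A fixed master seed
fully determines every stochastic stage (per-stage seeds are derived by
hashing the master seed with the stage name), so rerunning a config
reproduces the output tree byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .context import (
    connectivity_gradients,
    degree_centrality_rank,
    gcea_cell_types,
    neighborhood_correlation,
    spatial_correlation,
)
from .mediation import mediate_batch
from .pls import PLSCorrelation
from .preprocess import impute_knn, residualize_confounds, zscore_columns
from .synth import (
    Connectome,
    ParcelGeometry,
    SyntheticCohort,
    SyntheticCohortSpec,
    gen_cohort,
    gen_connectome,
    gen_expression,
    gen_smooth_map,
    gen_sphere_parcellation,
)

__all__ = ["PipelineConfig", "load_inputs", "run_pipeline", "write_report",
           "write_bundle", "simulate_bundle", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


_KNOWN_KEYS = {
    "input_dir", "output_dir", "run_preprocess", "run_pls", "run_mediation",
    "run_context", "impute_k", "n_perm", "n_boot", "n_spin", "n_surrogates",
    "cv_folds", "alpha", "br_threshold", "seed", "mediation_covariates",
}


@dataclass
class PipelineConfig:
    """All pipeline knobs; unknown keys are rejected on load.

    Defaults are the analysis constants of the reference workflow:
    impute_k=4 neighbours, n_perm=5000 permutations, n_boot=5000 bootstrap
    resamples, n_spin=1000 spin permutations, 10 cross-validation folds,
    alpha=0.05, bootstrap-ratio cut 1.96.
    """

    input_dir: str = "."
    output_dir: str = "results"
    run_preprocess: bool = True
    run_pls: bool = True
    run_mediation: bool = True
    run_context: bool = True
    impute_k: int = 4
    n_perm: int = 5000
    n_boot: int = 5000
    n_spin: int = 1000
    n_surrogates: int = 1000
    cv_folds: int = 10
    alpha: float = 0.05
    br_threshold: float = 1.96
    seed: int = 0
    mediation_covariates: list[str] = field(
        default_factory=lambda: ["age", "sex", "education"]
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def params(self) -> dict:
        """Everything that affects results (paths excluded)."""
        d = asdict(self)
        d.pop("input_dir")
        d.pop("output_dir")
        return d

    def hash(self) -> str:
        payload = json.dumps(self.params(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# bundle I/O (delimited text only)

_FILES = {
    "clinical": "clinical.csv",
    "clinical_groups": "clinical_groups.csv",
    "morph": "morph.csv",
    "confounds": "confounds.csv",
    "cognition": "cognition.csv",
    "geometry": "geometry.csv",
    "connectome": "connectome.csv",
    "expression": "expression.csv",
    "catalog": "cell_catalog.csv",
}


def write_bundle(
    path,
    cohort: SyntheticCohort,
    geometry: ParcelGeometry,
    connectome: Connectome,
    expression: pd.DataFrame,
    catalog: pd.DataFrame,
):
    """Write a full input bundle as delimited text; planted truth goes to a
    separate JSON sidecar, never into the data tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(path / _FILES["clinical"])
    pd.Series(cohort.clinical_groups, name="group").rename_axis("variable").to_csv(
        path / _FILES["clinical_groups"]
    )
    cohort.morph.to_csv(path / _FILES["morph"])
    cohort.confounds.to_csv(path / _FILES["confounds"])
    cohort.cognition.to_csv(path / _FILES["cognition"])
    geometry.to_frame().to_csv(path / _FILES["geometry"], index=False)
    pd.DataFrame(
        connectome.weights, index=geometry.parcel_id, columns=geometry.parcel_id
    ).to_csv(path / _FILES["connectome"])
    expression.to_csv(path / _FILES["expression"])
    catalog.to_csv(path / _FILES["catalog"], index=False)
    (path / "truth.json").write_text(cohort.truth_json())


def simulate_bundle(
    out_dir,
    n_subjects: int = 500,
    n_regions: int = 100,
    n_clinical: int = 12,
    seed: int = 0,
    **spec_kwargs,
):
    """Generate and write a complete synthetic input bundle."""
    geometry = gen_sphere_parcellation(n_regions, seed=stage_seed(seed, "geometry"))
    spec = SyntheticCohortSpec(
        n_subjects=n_subjects,
        n_regions=n_regions,
        n_clinical=n_clinical,
        seed=stage_seed(seed, "cohort"),
        **spec_kwargs,
    )
    cohort = gen_cohort(spec)
    connectome = gen_connectome(
        geometry, n_modules=4, seed=stage_seed(seed, "connectome")
    )
    signal = gen_smooth_map(geometry, 50.0, seed=stage_seed(seed, "signal"))
    expression, catalog = gen_expression(
        geometry, n_categories=10, genes_per_category=20,
        signal_map=signal, signal_categories={"cat00", "cat01"},
        seed=stage_seed(seed, "expression"),
    )
    write_bundle(out_dir, cohort, geometry, connectome, expression, catalog)
    return out_dir


def load_inputs(config: PipelineConfig) -> dict:
    """Load and validate a bundle; align subjects and parcels.

    Subject tables are inner-joined on subject_id (counts logged in the
    validation report); morphometry and connectome columns are reordered
    to the geometry's parcel order. Duplicate subject ids and a subject
    overlap below 3 are errors.
    """
    p = Path(config.input_dir)
    tables = {}
    for key in ("clinical", "morph", "confounds", "cognition"):
        df = pd.read_csv(p / _FILES[key], index_col=0)
        dupes = df.index[df.index.duplicated()].unique()
        if len(dupes):
            raise ValueError(f"duplicated subject_id in {key}: {list(dupes)}")
        tables[key] = df.sort_index()
    common = tables["clinical"].index
    for key in ("morph", "confounds", "cognition"):
        common = common.intersection(tables[key].index)
    if len(common) < 3:
        raise ValueError("subject overlap across tables is < 3")
    report = {
        "n_subjects": int(len(common)),
        "dropped": {
            k: int(len(t.index) - len(common)) for k, t in tables.items()
        },
    }
    for k in tables:
        tables[k] = tables[k].loc[common]

    geometry = ParcelGeometry.from_frame(pd.read_csv(p / _FILES["geometry"]))
    morph_cols = list(tables["morph"].columns)
    if len(morph_cols) != geometry.n_parcels:
        raise ValueError(
            f"parcel mismatch: morph has {len(morph_cols)} columns, "
            f"geometry has {geometry.n_parcels} parcels"
        )

    groups = pd.read_csv(p / _FILES["clinical_groups"], index_col=0)["group"].to_dict()
    conn = pd.read_csv(p / _FILES["connectome"], index_col=0)
    connectome = Connectome(weights=conn.to_numpy(float), parcel_id=geometry.parcel_id)
    expression = pd.read_csv(p / _FILES["expression"], index_col=0)
    catalog = pd.read_csv(p / _FILES["catalog"])

    report["missingness"] = {
        c: float(tables["clinical"][c].isna().mean()) for c in tables["clinical"]
    }
    report["constant_columns"] = [
        c for c in tables["clinical"] if tables["clinical"][c].nunique(dropna=True) <= 1
    ]
    return {
        **tables,
        "clinical_groups": groups,
        "geometry": geometry,
        "connectome": connectome,
        "expression": expression,
        "catalog": catalog,
        "validation": report,
    }


# ---------------------------------------------------------------------------
# orchestration


def _json_dump(obj, path: Path):
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order, writing results + provenance.

    Stage order: preprocess (impute -> residualize -> z-score) -> PLS
    (decomposition, permutation, bootstrap, scores, CV) -> mediation (one
    model per cognition column, mediator = imaging score, predictor =
    clinical score) -> contextualization (degree rank, neighborhood
    abnormality with rewiring null, GCEA cell-type enrichment).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_inputs(config)
    _json_dump(bundle["validation"], out / "validation.json")
    _json_dump(
        {"config": config.params(), "config_hash": config.hash(),
         "version": __version__},
        out / "provenance.json",
    )

    stage = "none"
    try:
        if config.run_preprocess:
            stage = "preprocess"
            clin = impute_knn(bundle["clinical"], bundle["clinical_groups"],
                              k=config.impute_k)
            clin = residualize_confounds(clin, bundle["confounds"])
            clin = zscore_columns(clin)
            morph = residualize_confounds(bundle["morph"], bundle["confounds"])
            morph = zscore_columns(morph)
            clin.to_csv(out / "clinical_preprocessed.csv")
            morph.to_csv(out / "morph_preprocessed.csv")
        else:
            clin, morph = bundle["clinical"], bundle["morph"]

        pls_res = None
        if config.run_pls:
            stage = "pls"
            model = PLSCorrelation(morph, clin)
            pls_res = model.fit(
                n_perm=config.n_perm, n_boot=config.n_boot,
                seed=stage_seed(config.seed, "pls"),
            )
            cv = model.cross_validate(k=config.cv_folds,
                                      seed=stage_seed(config.seed, "cv"))
            _json_dump(pls_res.to_dict(), out / "pls.json")
            pd.DataFrame(pls_res.u, index=morph.columns).to_csv(out / "pls_u.csv")
            pd.DataFrame(pls_res.v, index=clin.columns).to_csv(out / "pls_v.csv")
            pd.DataFrame(pls_res.boot_ratio, index=morph.columns).to_csv(
                out / "pls_bootstrap_ratio.csv"
            )
            scores = pd.DataFrame(
                {
                    "clinical_score": pls_res.scores_clinical[:, 0],
                    "imaging_score": pls_res.scores_imaging[:, 0],
                },
                index=clin.index,
            )
            scores.to_csv(out / "pls_scores.csv")
            cv.to_csv(out / "pls_cv.csv")

        if config.run_mediation:
            stage = "mediation"
            if pls_res is None:
                raise RuntimeError("mediation requires the PLS stage")
            covs = bundle["confounds"][config.mediation_covariates]
            med = mediate_batch(
                pls_res.scores_clinical[:, 0],
                pls_res.scores_imaging[:, 0],
                bundle["cognition"],
                covariates=covs,
                n_boot=config.n_boot,
                seed=stage_seed(config.seed, "mediation"),
                alpha=config.alpha,
            )
            med.to_csv(out / "mediation.csv")

        if config.run_context:
            stage = "context"
            if pls_res is None:
                raise RuntimeError("contextualization requires the PLS stage")
            effect = pls_res.boot_ratio[:, 0]
            geometry = bundle["geometry"]
            connectome = bundle["connectome"]
            dist = geometry.distances()
            rows = {}
            deg = degree_centrality_rank(connectome)
            res_deg = spatial_correlation(
                effect, deg, geometry=geometry, distances=dist,
                null_methods=("spin", "variogram"),
                n_null=config.n_spin, seed=stage_seed(config.seed, "context_deg"),
                label="degree_centrality",
            )
            rows["degree_centrality"] = {"rsp": res_deg.statistic, **{
                f"p_{k}": v for k, v in res_deg.p.items()}}
            res_nb = neighborhood_correlation(
                connectome, effect, n_null=min(config.n_surrogates, 200),
                seed=stage_seed(config.seed, "context_nb"),
            )
            rows["neighborhood_abnormality"] = {"rsp": res_nb.statistic, **{
                f"p_{k}": v for k, v in res_nb.p.items()}}
            try:
                grads = connectivity_gradients(connectome, n_components=2)
                for gi in range(grads.shape[1]):
                    res_g = spatial_correlation(
                        effect, grads[:, gi], geometry=geometry, distances=dist,
                        null_methods=("spin",), n_null=config.n_spin,
                        seed=stage_seed(config.seed, f"context_grad{gi}"),
                        label=f"gradient{gi + 1}",
                    )
                    rows[f"gradient{gi + 1}"] = {"rsp": res_g.statistic, **{
                        f"p_{k}": v for k, v in res_g.p.items()}}
            except ValueError as err:
                import warnings

                warnings.warn(f"gradient analysis skipped: {err}", RuntimeWarning)
            pd.DataFrame(rows).T.to_csv(out / "context_network.csv")

            gcea = gcea_cell_types(
                effect, bundle["expression"], bundle["catalog"],
                distances=dist, n_surrogates=config.n_surrogates,
                seed=stage_seed(config.seed, "gcea"), alpha=config.alpha,
            )
            gcea.to_csv(out / "context_gcea.csv")
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        raise

    write_report(out)
    return out


def write_report(results_dir) -> Path:
    """Render a human-readable markdown summary of a results directory.

    Numbers are read back from the result files so the report matches them
    exactly; missing stages are marked 'not run'. Regenerating the report
    is byte-stable.
    """
    out = Path(results_dir)
    lines = ["# Pipeline report", ""]
    prov = out / "provenance.json"
    if prov.exists():
        meta = json.loads(prov.read_text())
        lines += [f"- config hash: `{meta['config_hash']}`",
                  f"- version: {meta['version']}",
                  f"- seed: {meta['config']['seed']}", ""]

    lines.append("## PLS correlation")
    if (out / "pls.json").exists():
        pls = json.loads((out / "pls.json").read_text())
        lines.append("")
        lines.append("| LV | explained variance % | permutation p |")
        lines.append("|---:|---:|---:|")
        ps = pls.get("perm_p") or ["--"] * len(pls["explained_variance"])
        for j, (ev, p) in enumerate(zip(pls["explained_variance"], ps)):
            pstr = f"{p:.4f}" if isinstance(p, float) else p
            lines.append(f"| {j + 1} | {100 * ev:.2f} | {pstr} |")
        total = 100 * sum(pls["explained_variance"])
        lines.append("")
        lines.append(f"Total explained variance: {total:.2f}%")
    else:
        lines.append("not run")
    lines.append("")

    lines.append("## Mediation")
    if (out / "mediation.csv").exists():
        med = pd.read_csv(out / "mediation.csv", index_col=0)
        lines.append("")
        lines.append("| test | a | b | ab | c' | c | q(ab) | class |")
        lines.append("|---|---:|---:|---:|---:|---:|---:|---|")
        for t, r in med.iterrows():
            lines.append(
                f"| {t} | {r['a']:.3f} | {r['b']:.3f} | {r['ab']:.3f} | "
                f"{r['c_prime']:.3f} | {r['c']:.3f} | {r['q_ab']:.4f} | {r['class']} |"
            )
    else:
        lines.append("not run")
    lines.append("")

    lines.append("## Contextualization")
    wrote = False
    if (out / "context_network.csv").exists():
        net = pd.read_csv(out / "context_network.csv", index_col=0)
        lines += ["", "```", net.to_string(float_format=lambda x: f"{x:.4f}"), "```"]
        wrote = True
    if (out / "context_gcea.csv").exists():
        gc = pd.read_csv(out / "context_gcea.csv", index_col=0)
        nsig = int(gc["significant"].sum())
        lines += ["", f"GCEA: {nsig} of {len(gc)} cell categories significant "
                      f"(q < 0.05): {sorted(gc.index[gc['significant']])}"]
        wrote = True
    if not wrote:
        lines.append("not run")
    lines.append("")

    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
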