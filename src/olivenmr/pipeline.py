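"""End-to-end pipeline: simulate/read -> bucket -> normalize -> outlier
screen -> Pareto scale -> PCA -> optional supervised models -> cluster
quality -> paired distances. Every artifact is written under the configured
output directory together with a manifest (package version, seed, config
hash) sufficient to re-run any stage in isolation."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import (
    encode_classes,
    fit_oplsda,
    fit_pca,
    fit_plsda,
    permutation_test,
    q2_crossval,
    select_ncomp_by_cumvar,
)
from .cluster_quality import quality_report, year_contrast
from .config import PipelineConfig
from .io import read_spectrum, write_bucket_table
from .paired import kernel_density, paired_distance_sets, summarize
from .preprocessing import (
    BucketScheme,
    build_bucket_table,
    detect_outliers,
    normalize_total_sum,
    pareto_scale,
)
from .synthetic import generate_cohort

__all__ = ["run_pipeline"]

logger = logging.getLogger("olivenmr")


def _stage(name: str, message: str) -> None:
    logger.info("[%s] %s", name, message)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Returns a report bundle (dict of in-memory artifacts); all tabular
    outputs are written as CSV and all summaries as JSON under
    ``config.output_dir``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # --- acquire spectra ---------------------------------------------------
    try:
        if config.simulation is not None:
            cohort = generate_cohort(config.simulation)
            spectra, metadata = cohort.spectra, cohort.metadata
            bundle["cohort"] = cohort
        else:
            spectra = [read_spectrum(p) for p in config.input_paths]
            metadata = pd.DataFrame(
                {
                    "sample_id": [s.sample_id for s in spectra],
                    "cultivar": "unknown",
                    "harvest": "unknown",
                    "plant_id": [s.sample_id for s in spectra],
                }
            )
        _stage("acquire", f"{len(spectra)} spectra")
    except Exception as exc:
        raise type(exc)(f"acquire: {exc}") from exc

    # --- bucketing ---------------------------------------------------------
    try:
        scheme = BucketScheme(
            region_high=config.region_high,
            region_low=config.region_low,
            width=config.bucket_width,
            exclusions=config.exclusions,
        )
        table = build_bucket_table(spectra, metadata, scheme)
        _stage("bucket", f"{table.n_samples} x {table.n_buckets} bucket matrix")
    except Exception as exc:
        raise type(exc)(f"bucket: {exc}") from exc

    # --- normalization -----------------------------------------------------
    table = normalize_total_sum(table, config.normalization_target)
    _stage("normalize", f"row sum fixed at {config.normalization_target}")

    # --- outlier screen (single pass, before scaling and refit) ------------
    outlier_ids: list[str] = []
    if config.outlier_alpha is not None:
        screen = pareto_scale(table)
        report = detect_outliers(
            screen, alpha=config.outlier_alpha, n_components=config.outlier_components
        )
        outlier_ids = report.flagged_ids
        if outlier_ids:
            keep = ~table.metadata["sample_id"].astype(str).isin(outlier_ids).to_numpy()
            table = table.subset(keep)
        bundle["outliers"] = report
        _stage("outliers", f"{len(outlier_ids)} flagged (alpha={config.outlier_alpha})")

    # --- scaling -----------------------------------------------------------
    scaled = pareto_scale(table)
    bundle["bucket_table"] = scaled
    write_bucket_table(scaled, out / "bucket_table.csv")
    _stage("scale", "Pareto scaling applied")

    # --- PCA ---------------------------------------------------------------
    try:
        k = min(config.pca_components, scaled.n_samples - 1, scaled.n_buckets)
        pca = fit_pca(scaled.values, k)
        bundle["pca"] = pca
        scores_df = pd.DataFrame(
            pca.scores, columns=[f"t{i + 1}" for i in range(pca.n_components)]
        )
        scores_df.insert(0, "sample_id", scaled.metadata["sample_id"].to_numpy())
        scores_df.to_csv(out / "pca_scores.csv", index=False)
        pd.DataFrame(
            pca.loadings,
            index=scaled.labels,
            columns=[f"p{i + 1}" for i in range(pca.n_components)],
        ).to_csv(out / "pca_loadings.csv")
        _stage("pca", f"{pca.n_components} components, R2X={pca.cumulative_R2X[-1]:.3f}")
    except Exception as exc:
        raise type(exc)(f"pca: {exc}") from exc

    # --- supervised model (optional) ----------------------------------------
    model_summary: dict = {}
    if config.model is not None:
        try:
            labels = scaled.metadata[config.model_by].astype(str).tolist()
            response = encode_classes(labels)
            if config.model == "plsda":
                model = fit_plsda(scaled.values, response, config.n_components)
                q2 = q2_crossval(
                    scaled.values,
                    response,
                    n_components=config.n_components,
                    folds=config.cv_folds,
                    seed=config.seed,
                )
                model_summary = {
                    "model": "plsda",
                    "n_components": config.n_components,
                    "R2X": model.R2X,
                    "R2Y": model.R2Y,
                    "Q2": q2,
                }
            elif config.model == "oplsda":
                model = fit_oplsda(scaled.values, response, config.n_ortho)
                q2 = q2_crossval(
                    scaled.values,
                    response,
                    n_ortho=config.n_ortho,
                    folds=config.cv_folds,
                    seed=config.seed,
                )
                model_summary = {
                    "model": "oplsda",
                    "n_ortho": config.n_ortho,
                    "R2X": model.R2X,
                    "R2Y": model.R2Y,
                    "Q2": q2,
                    "predictive_variance_fraction": model.predictive_variance_fraction,
                    "ortho_variance_fractions": model.ortho_variance_fractions.tolist(),
                }
            else:
                raise ValueError(f"unknown model {config.model!r}")
            bundle["model"] = model
            if config.n_permutations > 0:
                perm = permutation_test(
                    scaled.values,
                    response,
                    n_perm=config.n_permutations,
                    seed=config.seed,
                    n_components=config.n_components
                    if config.model == "plsda"
                    else 1,
                    n_ortho=None if config.model == "plsda" else config.n_ortho,
                    folds=config.cv_folds,
                )
                model_summary["permutation_p"] = perm.empirical_p
                bundle["permutation"] = perm
            (out / "model_summary.json").write_text(json.dumps(model_summary, indent=1))
            _stage("fit", f"{config.model}: " + ", ".join(
                f"{k}={v:.3f}" for k, v in model_summary.items()
                if isinstance(v, float)
            ))
        except Exception as exc:
            raise type(exc)(f"fit: {exc}") from exc

    # --- cluster quality ----------------------------------------------------
    try:
        labels = scaled.metadata["cultivar"].astype(str).tolist()
        if len(set(labels)) >= 2:
            report = quality_report(pca, labels, config.quality_configurations)
            report.to_dataframe().to_csv(out / "quality_report.csv", index=False)
            bundle["quality"] = report
            years = scaled.metadata["harvest"].astype(str)
            if years.nunique() == 2:
                k99 = select_ncomp_by_cumvar(pca, 0.99)
                # within-class scatter of a class with n_c members (split in
                # two year groups) has rank at most n_c - 2
                min_class = min(labels.count(c) for c in set(labels))
                k99 = max(1, min(k99, min_class - 2))
                contrast = year_contrast(
                    pca.scores[:, :k99], labels, years.tolist()
                )
                contrast.to_csv(out / "year_contrast.csv", index=False)
                bundle["year_contrast"] = contrast
            _stage("quality", f"{len(report.rows)} report rows")
    except Exception as exc:
        raise type(exc)(f"quality: {exc}") from exc

    # --- paired plant-level analysis ----------------------------------------
    try:
        meta = scaled.metadata
        if meta["harvest"].astype(str).nunique() == 2:
            cultivars = config.paired_cultivars or sorted(
                meta["cultivar"].astype(str).unique()
            )
            k = select_ncomp_by_cumvar(pca, config.paired_cumvar)
            rows = []
            for cultivar in cultivars:
                sets = paired_distance_sets(pca.scores[:, :k], meta, cultivar)
                for name, vals in (
                    ("plant_plant", sets.plant_plant),
                    ("plant_cultivar", sets.plant_cultivar),
                ):
                    s = summarize(vals)
                    rows.append(
                        {
                            "cultivar": cultivar,
                            "set": name,
                            **asdict(s),
                            "k_used": sets.k_used,
                        }
                    )
                if sets.plant_plant.size >= 2 and sets.plant_plant.std() > 0:
                    curve = kernel_density(sets.plant_plant)
                    pd.DataFrame(
                        {"distance": curve.grid, "density": curve.density}
                    ).to_csv(out / f"kde_plant_plant_{cultivar}.csv", index=False)
            paired_df = pd.DataFrame(rows)
            paired_df.to_csv(out / "paired_summary.csv", index=False)
            bundle["paired"] = paired_df
            _stage("paired", f"{len(cultivars)} cultivars, k={k}")
    except Exception as exc:
        raise type(exc)(f"paired: {exc}") from exc

    # --- manifest ------------------------------------------------------------
    manifest = {
        "package": "olivenmr",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_jsonable(),
        "n_spectra": len(spectra),
        "n_samples_retained": scaled.n_samples,
        "n_buckets": scaled.n_buckets,
        "outliers_removed": outlier_ids,
        "model_summary": model_summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    _stage("manifest", f"written to {out / 'manifest.json'}")
    return bundle
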