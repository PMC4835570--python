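"""End-to-end pipeline: fluxes -> classification -> community -> indicators.

`run_pipeline` reads the input tables named in a :class:`PipelineConfig`,
executes the stages in order, writes every report to the output directory and
returns a manifest (also written as JSON) echoing versions, seeds and
parameters. The whole run is a pure function of (inputs, config): repeated
runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import classify, gas_flux, indicators, ordination, otus
from .io import (
    PipelineConfig,
    read_biogeochem_tsv,
    read_gas_csv,
    read_metadata_tsv,
    read_otu_tsv,
    write_newick,
)

__all__ = ["run_pipeline", "fit_fluxes", "classify_stage", "diversity_stage",
           "ordinate_stage", "indicator_stage"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-named rewrap
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


@_stage("fluxes")
def fit_fluxes(gas_df: pd.DataFrame, *, headspace_volume_l: float = 0.48,
               dry_mass_g: float = 20.0) -> pd.DataFrame:
    """Fit every (sample, gas) series: first-order uptake for H2/CO, linear
    production for CO2. Returns a tidy flux table."""
    rows = []
    for (sample, gas), grp in gas_df.groupby(["sample_id", "gas"], sort=True):
        grp = grp.sort_values("time_h")
        ts = gas_flux.GasTimeSeries(
            gas=gas, times=grp["time_h"].to_numpy(),
            mixing_ratio=grp["ppmv"].to_numpy(),
            headspace_volume_l=headspace_volume_l, dry_mass_g=dry_mass_g,
        )
        if gas.upper() == "CO2":
            est = gas_flux.fit_linear_production(ts)
        else:
            est = gas_flux.fit_first_order_uptake(ts)
        rows.append({
            "sample_id": sample, "gas": gas, "mode": est.mode,
            "k_or_slope": est.k_or_slope, "rate": est.rate,
            "fit_r2": est.fit_r2, "n_points": est.n_points,
        })
    return pd.DataFrame(rows)


@_stage("classify")
def classify_stage(biogeochem: pd.DataFrame, meta: pd.DataFrame,
                   config: PipelineConfig):
    """Standardize, cluster, delineate classes and rank them; run the PCA."""
    variables = [v for v in config.variables if v in biogeochem.columns]
    if not variables:
        raise ValueError("no configured variables present in the table")
    data = biogeochem[variables]
    if data.isna().any().any():
        raise ValueError("missing values in biogeochemical table; impute first")
    z = classify.standardize_variables(data)
    dist = classify.euclidean_distances(z)
    tree = classify.upgma(dist)
    dendro = classify.delineate_classes(
        tree, z, alpha=config.alpha, n_perm=config.n_perm_simprof,
        seed=config.seed,
    )
    comp_treat = meta.drop_duplicates("composite_id").set_index("composite_id")[
        "treatment"]
    reference = comp_treat.reindex(z.index) == config.reference_treatment
    ranks = classify.rank_classes(dendro.labels, z, reference.to_numpy())
    pca_res = classify.pca(z)
    return z, dendro, ranks, pca_res


@_stage("diversity")
def diversity_stage(table: otus.OtuTable, labels: pd.Series,
                    config: PipelineConfig):
    """Equalize, filter, and compute alpha/beta diversity on the OTU table."""
    equalized = otus.equalize_libraries(table, depth=config.rarefaction_depth,
                                        seed=config.seed)
    filtered = otus.filter_rare_otus(equalized, config.filter_fraction)
    counts = filtered.counts
    alpha_rows = []
    for sample in counts.index:
        row = counts.loc[sample].to_numpy()
        alpha_rows.append({
            "sample_id": sample,
            "shannon": otus.shannon_index(row),
            "ace": otus.ace_estimator(row),
            "observed_otus": int((row > 0).sum()),
        })
    alpha = pd.DataFrame(alpha_rows).set_index("sample_id")
    hell = otus.hellinger_transform(counts)
    dist = classify.euclidean_distances(hell)
    grp = labels.reindex(counts.index)
    per_sample, group_means = otus.multivariate_dispersion(dist, grp)
    beta = per_sample.to_frame()
    beta["class"] = grp
    return filtered, hell, alpha, beta, group_means


@_stage("ordinate")
def ordinate_stage(hell: pd.DataFrame, z: pd.DataFrame, config: PipelineConfig):
    """Parsimonious RDA of the Hellinger matrix on standardized variables."""
    z_aligned = z.reindex(hell.index)
    return ordination.forward_select(
        hell, z_aligned, alpha=config.alpha, n_perm=config.n_perm_rda,
        seed=config.seed,
    )


@_stage("indicators")
def indicator_stage(filtered: otus.OtuTable, labels: pd.Series,
                    biogeochem: pd.DataFrame, config: PipelineConfig):
    """IndVal against the multifunctional classes, representatives, and
    Spearman validation against the environmental variables."""
    counts = filtered.counts
    results = indicators.indval(
        counts, labels.reindex(counts.index), mode=config.indval_mode,
        n_perm=config.n_perm_indval, alpha=config.alpha, seed=config.seed,
    )
    indicators.select_representatives(results, counts)
    variables = [v for v in config.variables if v in biogeochem.columns]
    corr = indicators.correlate_indicators(
        results, counts, biogeochem[variables], alpha=config.alpha)
    res_df = pd.DataFrame([{
        "otu": r.otu, "class": r.best_class, "A": r.a, "B": r.b,
        "stat": r.stat, "p_value": r.p, "significant": r.significant,
        "testable": r.testable, "representative": r.representative,
        "total_count": r.total_count,
    } for r in results])
    return res_df, corr


def run_pipeline(config: PipelineConfig, base_dir: str | Path = ".") -> dict:
    """Execute every configured stage and write the report bundle."""
    base = Path(base_dir)
    outdir = base / config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mfsoil_version": __version__,
        "schema_version": 1,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "n_perm_simprof": config.n_perm_simprof,
            "n_perm_rda": config.n_perm_rda,
            "n_perm_indval": config.n_perm_indval,
            "filter_fraction": config.filter_fraction,
            "rarefaction_depth": config.rarefaction_depth,
            "indval_mode": config.indval_mode,
            "variables": list(config.variables),
        },
        "stages": [],
        "outputs": {},
    }

    meta = read_metadata_tsv(base / config.metadata)
    biogeochem = read_biogeochem_tsv(base / config.biogeochem)

    if config.gas_series:
        gas_df = read_gas_csv(base / config.gas_series)
        fluxes = fit_fluxes(gas_df)
        fluxes.to_csv(outdir / "fluxes.tsv", sep="\t", index=False)
        manifest["stages"].append("fluxes")
        manifest["outputs"]["fluxes"] = "fluxes.tsv"

    z, dendro, ranks, pca_res = classify_stage(biogeochem, meta, config)
    assignment = dendro.labels.to_frame()
    assignment = assignment.join(
        ranks[["distance_to_reference", "disturbance_rank"]], on="class")
    assignment.to_csv(outdir / "class_assignment.tsv", sep="\t",
                      index_label="composite_id")
    ranks.to_csv(outdir / "class_ranks.tsv", sep="\t")
    write_newick(dendro, outdir / "multifunc_tree.nwk")
    pca_report = pca_res.loadings.copy()
    pca_report["contributing"] = pca_res.contributing
    pca_report.to_csv(outdir / "pca_loadings.tsv", sep="\t",
                      index_label="variable")
    pca_res.scores.to_csv(outdir / "pca_scores.tsv", sep="\t",
                          index_label="composite_id")
    pd.DataFrame({
        "eigenvalue": pca_res.eigenvalues,
        "retained": pca_res.retained,
    }).to_csv(outdir / "pca_eigenvalues.tsv", sep="\t", index_label="axis")
    manifest["stages"].append("classify")
    manifest["outputs"]["classes"] = "class_assignment.tsv"
    manifest["n_classes"] = int(dendro.labels.nunique())
    manifest["class_sizes"] = {
        label: len(members) for label, members in sorted(dendro.classes.items())
    }

    if config.otu_table and not config.classify_only:
        table = read_otu_tsv(base / config.otu_table)
        filtered, hell, alpha_div, beta, group_means = diversity_stage(
            table, dendro.labels, config)
        alpha_div.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        beta.to_csv(outdir / "beta_dispersion.tsv", sep="\t",
                    index_label="sample_id")
        manifest["stages"].append("diversity")

        rda_res = ordinate_stage(hell, z, config)
        rda_report = {
            "r2": rda_res.r2, "adj_r2": rda_res.adj_r2,
            "p_value": rda_res.p_value,
            "selected": rda_res.selected,
            "canonical_eigenvalues": [float(v) for v in
                                      rda_res.canonical_eigenvalues],
        }
        (outdir / "rda_report.json").write_text(
            json.dumps(rda_report, indent=2, sort_keys=True), encoding="utf-8")
        if rda_res.selected:
            rda_res.site_scores.to_csv(outdir / "rda_site_scores.tsv", sep="\t",
                                       index_label="composite_id")
            rda_res.species_scores.to_csv(outdir / "rda_species_scores.tsv",
                                          sep="\t", index_label="otu_id")
        manifest["stages"].append("ordinate")
        manifest["rda_selected"] = rda_res.selected

        ind_df, corr = indicator_stage(filtered, dendro.labels, biogeochem,
                                       config)
        ind_df.to_csv(outdir / "indicators.tsv", sep="\t", index=False)
        corr.to_csv(outdir / "indicator_correlations.tsv", sep="\t",
                    index=False)
        manifest["stages"].append("indicators")
        manifest["n_significant_indicators"] = int(ind_df["significant"].sum())

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest
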