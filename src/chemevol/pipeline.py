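"""End-to-end pipeline: annotate -> assemble -> chemodiversity -> phylogenetic
statistics (-> dose-response when plates are supplied).

Every stage writes its tables under the configured output directory with a
provenance header (seed, tolerances); a run manifest records versions, seeds
and the stages executed. Stage failures abort with the failing stage named.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_cardenolides, quantify_compounds, screen_glucosinolates
from .assemble import (
    extract_species_means,
    fit_combining_model,
    log_transform,
    standardize,
)
from .chemodiv import bray_curtis, mantel_test, multiscale_bootstrap_support, pcoa
from .io import PipelineConfig, read_newick, read_table, write_table
from .library import CompoundLibrary, default_library
from .phylo import phylo_signal_test, tip_rates, trc_test

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a manifest of written outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header_fields()
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__ if k != "extra"},
        "stages": [],
        "outputs": [],
    }

    library = (
        CompoundLibrary.from_yaml(config.library_path)
        if config.library_path
        else default_library()
    )

    if config.features_path is None:
        raise StageError("stage 'annotate' failed: no feature table configured")

    features = _read_features(config.features_path)
    quantities = _annotate_stage(features, library, config, out, header, manifest)
    profiles = _assemble_stage(quantities, config, out, header, manifest)

    tree = None
    if config.tree_path:
        tree = read_newick(config.tree_path)

    chem = _chemodiv_stage(profiles, tree, config, out, header, manifest)
    if tree is not None:
        _phylo_stage(tree, profiles, chem, config, out, header, manifest)
    elif config.traits_path or config.extra.get("require_phylo"):
        raise StageError("stage 'phylo' failed: phylogenetic statistics need a tree")

    if config.plate_path:
        _dose_stage(config, out, header, manifest)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@_stage("annotate")
def _annotate_stage(features, library, config, out, header, manifest):
    pos = features[features["mode"] == "positive"]
    neg = features[features["mode"] == "negative"]
    annotations = []
    if len(pos):
        annotations += annotate_cardenolides(
            pos, library, mz_tol=config.mz_tol, rt_tol=config.rt_tol
        )
    if len(neg):
        annotations += screen_glucosinolates(
            neg, library, mz_tol=config.mz_tol, rt_tol=config.rt_tol
        )
    quantities = quantify_compounds(features, annotations)
    ann_table = pd.DataFrame(
        [
            {
                "compound_id": a.compound_id,
                "class": a.compound_class,
                "genin": a.genin,
                "sugars": "+".join(a.sugars),
                "acetyl": a.acetyl,
                "neutral_mass": a.neutral_mass,
                "rt": a.rt,
                "isomer_index": a.isomer_index,
            }
            for a in annotations
        ]
    )
    write_table(ann_table, out / "annotations.csv", header, index=False)
    write_table(quantities, out / "compound_quantities.csv", header)
    manifest["stages"].append("annotate")
    manifest["outputs"] += ["annotations.csv", "compound_quantities.csv"]
    return quantities


@_stage("assemble")
def _assemble_stage(quantities, config, out, header, manifest):
    meta = None
    if config.sample_metadata_path:
        meta = pd.read_csv(config.sample_metadata_path, comment="#")
    long = quantities.stack().rename("intensity").reset_index()
    long.columns = ["sample_id", "compound", "intensity"]
    if meta is not None:
        long = long.merge(meta, on="sample_id", how="left")
        if {"dry_mass"}.issubset(long.columns):
            long = standardize(long)
    if "species" not in long.columns:
        long["species"] = long["sample_id"].str.split(":").str[0]
    if "experiment" not in long.columns:
        parts = long["sample_id"].str.split(":")
        long["experiment"] = np.where(
            parts.str.len() > 1, parts.str[1], "exp1"
        )
    long["y"] = log_transform(long["intensity"].to_numpy())
    fit = fit_combining_model(long)
    profiles = extract_species_means(fit)
    write_table(profiles.matrix, out / "species_profiles.csv", header)
    summary = pd.DataFrame(
        {
            "total_intensity": profiles.totals,
            "total_log": profiles.totals_log,
            "n_compounds": profiles.counts,
        }
    )
    write_table(summary, out / "species_summaries.csv", header)
    manifest["stages"].append("assemble")
    manifest["outputs"] += ["species_profiles.csv", "species_summaries.csv"]
    return profiles


@_stage("chemodiv")
def _chemodiv_stage(profiles, tree, config, out, header, manifest):
    matrix = profiles.matrix
    # species with empty profiles carry no proportion information
    matrix = matrix[matrix.sum(axis=1) > 0]
    dist = bray_curtis(matrix)
    write_table(
        pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids),
        out / "bray_curtis.csv",
        header,
    )
    supported = multiscale_bootstrap_support(
        matrix, n_boot=max(100, config.n_boot), seed=config.seed,
        variant=config.ward_variant,
    )
    support = pd.DataFrame(
        {
            "cluster": [";".join(sorted(c)) for c in supported.clusters],
            "au": supported.au,
            "bp": supported.bp,
        }
    )
    write_table(support, out / "cluster_support.csv", header, index=False)
    (out / "chemogram.nwk").write_text(supported.to_newick() + "\n")
    ordination = pcoa(dist)
    write_table(ordination.coordinates, out / "pcoa_coordinates.csv", header)

    results = {"pcoa_percent_variance": list(ordination.percent_variance[:2])}
    if tree is not None:
        from .chemodiv import DistanceMatrix

        shared = [t for t in dist.ids if t in
                  {l.taxon.label for l in tree.leaf_node_iter()}]
        if len(shared) >= 4:
            from .phylo import brownian_cov

            V = brownian_cov(tree).loc[shared, shared].to_numpy()
            coph_data = np.add.outer(np.diag(V), np.diag(V)) - 2 * V
            np.fill_diagonal(coph_data, 0.0)
            coph = DistanceMatrix(coph_data, ids=shared)
            r, p = mantel_test(
                dist.filter(shared), coph, n_perm=config.n_perm_mantel,
                seed=config.seed,
            )
            results["mantel_chem_vs_phylo"] = {"r": r, "p": p}
    (out / "chemodiv_stats.json").write_text(json.dumps(results, indent=2))
    manifest["stages"].append("chemodiv")
    manifest["outputs"] += [
        "bray_curtis.csv", "cluster_support.csv", "chemogram.nwk",
        "pcoa_coordinates.csv", "chemodiv_stats.json",
    ]
    return {"dist": dist, "pcoa": ordination}


@_stage("phylo")
def _phylo_stage(tree, profiles, chem, config, out, header, manifest):
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    traits = pd.DataFrame(
        {
            "total_intensity": profiles.totals,
            "n_compounds": profiles.counts.astype(float),
        }
    )
    coords = chem["pcoa"].coordinates
    for col in coords.columns[:2]:
        traits[f"chem_{col}"] = coords[col]
    if config.traits_path:
        extra = read_table(config.traits_path)
        traits = traits.join(extra, how="left")
    traits = traits.loc[[t for t in traits.index if t in tips]]

    rows = []
    rates = tip_rates(tree)
    for col in traits.columns:
        x = traits[col].dropna()
        if x.nunique() < 3 or len(x) < len(tips):
            continue
        k = phylo_signal_test(tree, x, n_sim=config.n_sim_k, seed=config.seed)
        rows.append({"trait": col, "statistic": "blomberg_k", "value": k.k, "p": k.p})
        for measure in ("nd", "es_rate"):
            f, p = trc_test(tree, rates[measure], x, method="pgls")
            rows.append(
                {"trait": col, "statistic": f"trc_{measure}_pgls", "value": f, "p": p}
            )
            r, p = trc_test(
                tree, rates[measure], x, method="sim",
                n_sim=max(100, config.n_sim_k // 10), seed=config.seed,
            )
            rows.append(
                {"trait": col, "statistic": f"trc_{measure}_sim", "value": r, "p": p}
            )
    write_table(pd.DataFrame(rows), out / "phylo_stats.csv", header, index=False)
    write_table(rates, out / "tip_rates.csv", header)
    manifest["stages"].append("phylo")
    manifest["outputs"] += ["phylo_stats.csv", "tip_rates.csv"]


@_stage("doseresponse")
def _dose_stage(config, out, header, manifest):
    from .doseresponse import calibrate_ouabain, fit_4pl_mixed, ouabain_equivalents

    plate = pd.read_csv(config.plate_path, comment="#")
    fit = fit_4pl_mixed(plate)
    calib = calibrate_ouabain(plate)
    equiv = ouabain_equivalents(fit, calib)
    table = pd.DataFrame(
        {
            "x_mid": fit.x_mid,
            "molar_well": equiv.molar_well,
            "ug_per_mg": equiv.ug_per_mg,
            "extrapolated": equiv.extrapolated,
        }
    )
    write_table(table, out / "ouabain_equivalents.csv", header)
    manifest["stages"].append("doseresponse")
    manifest["outputs"].append("ouabain_equivalents.csv")
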