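"""End-to-end runner: simulate or load data, compute every analysis table.

Stage order mirrors the analysis workflow: data -> richness & island
groups -> functional-type classification -> beta metrics (whole
community and per type) -> pair tables -> GLMs -> variation
partitioning -> group summaries.  Every intermediate is written as CSV
and a JSON manifest records the configuration hash, the seed, derived
per-stage seeds, and dropped-pair counts, so an identical configuration
reproduces every output byte for byte.

Per-stage seeds are derived by hashing the global seed together with
the stage name; adding a stage therefore never perturbs the randomness
of earlier stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .beta import beta_summary, jaccard, pairwise_to_long, raup_crick
from .community import (
    build_pair_table,
    classify_islands,
    group_summary,
    pair_classes,
    read_attributes,
    read_community,
    richness,
    validate_community,
    write_community,
)
from .config import RunConfig
from .models import RESPONSES, backward_stepwise, deviance_by_term
from .pft import classification_report, kmeans_partition, standardize_traits
from .simulate import (
    assemble_communities,
    generate_island_attributes,
    generate_species_pool,
    generate_traits,
)
from .varpart import pft_pair_table, varpart_by_stratum

logger = logging.getLogger(__name__)

STAGES = ("data", "alpha", "pft", "beta", "pairs", "glm", "varpart", "summary")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write(df: pd.DataFrame, path: Path, **kw) -> str:
    df.to_csv(path, **kw)
    return path.name


def run_pipeline(config: RunConfig, output_dir) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages": [],
        "outputs": [],
        "notes": [
            "pairwise observations are not independent; GLM and varpart "
            "inference ignores this by design"
        ],
    }
    files = manifest["outputs"]

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    # ---- data ---------------------------------------------------------
    stage("data")
    traits = latent = None
    if config.synthetic is not None:
        syn = config.synthetic
        seed = stage_seed(config.seed, "data")
        attrs = generate_island_attributes(
            syn.assembly.n_islands, syn.area_range_ha, syn.dni_range_m, syn.dm_range_m, seed=seed
        )
        pool = generate_species_pool(
            syn.assembly.n_species, syn.assembly.sad_shape, syn.assembly.sad_param, seed=seed + 1
        )
        assembly = dataclasses.replace(syn.assembly, seed=seed + 2)
        matrix = assemble_communities(pool, attrs, assembly)
        traits, latent = generate_traits(
            syn.assembly.n_species, syn.trait_clusters, syn.trait_separation, seed=seed + 3
        )
        files.append(_write(latent.to_frame(), out / "latent_pft.csv"))
    else:
        matrix = read_community(config.inputs.community)
        attrs = read_attributes(config.inputs.attributes)
        if set(attrs.index) != set(matrix.index):
            raise RuntimeError("stage data: attribute islands do not match community matrix")
        if config.inputs.traits:
            traits = pd.read_csv(config.inputs.traits, index_col=0)
        matrix = validate_community(matrix)
    write_community(matrix, out / "community.csv")
    files.append("community.csv")
    files.append(_write(attrs, out / "island_attributes.csv"))
    if traits is not None:
        files.append(_write(traits, out / "traits.csv"))

    # ---- alpha --------------------------------------------------------
    stage("alpha")
    s = richness(matrix)
    groups = classify_islands(attrs, config.area_cut_ha, config.dni_cut_m, config.dm_cut_m)
    files.append(_write(s.to_frame(), out / "richness.csv"))
    files.append(_write(groups, out / "island_groups.csv"))

    # ---- pft ----------------------------------------------------------
    stage("pft")
    assignment = None
    if traits is not None:
        z = standardize_traits(traits)
        assignment = kmeans_partition(
            z, k=config.pft_k, n_init=config.pft_n_init, seed=stage_seed(config.seed, "pft")
        )
        files.append(_write(assignment.to_frame(), out / "pft_assignment.csv"))
        files.append(_write(classification_report(assignment, traits), out / "pft_report.csv"))

    # ---- beta ---------------------------------------------------------
    stage("beta")
    null_cfg = dataclasses.replace(config.null_model, seed=stage_seed(config.seed, "beta"))
    bj = jaccard(matrix)
    brc = raup_crick(matrix, null_cfg)
    files.append(_write(bj, out / "beta_j_matrix.csv"))
    files.append(_write(brc, out / "beta_rc_matrix.csv"))
    files.append(_write(pairwise_to_long(bj, "beta_j"), out / "beta_j_long.csv", index=False))
    files.append(_write(pairwise_to_long(brc, "beta_rc"), out / "beta_rc_long.csv", index=False))

    # ---- pairs --------------------------------------------------------
    stage("pairs")
    pairs = build_pair_table(matrix, attrs, bj, brc, reduction=config.reduction)
    files.append(_write(pairs, out / "pair_table.csv", index=False))
    pft_pairs: dict = {}
    if assignment is not None:
        for pft in sorted(set(assignment.values)):
            pcfg = dataclasses.replace(
                config.null_model, seed=stage_seed(config.seed, f"beta:pft{pft}")
            )
            ptab = pft_pair_table(matrix, attrs, assignment, pft, pcfg)
            pft_pairs[pft] = ptab
            files.append(_write(ptab, out / f"pair_table_pft{pft}.csv", index=False))

    # ---- glm ----------------------------------------------------------
    stage("glm")
    taxa = {"all_plants": pairs, **{f"PFT{k}": v for k, v in pft_pairs.items()}}
    table1, dropped = make_table1(taxa, hierarchy=config.hierarchy)
    manifest["dropped_pairs"] = dropped
    files.append(_write(table1, out / "table1.csv", index=False))

    # ---- varpart ------------------------------------------------------
    stage("varpart")
    vp_cfg = dataclasses.replace(config.null_model, seed=stage_seed(config.seed, "varpart"))
    vp = varpart_by_stratum(pairs, groups, matrix, attrs, assignment, vp_cfg)
    vp_table = pd.DataFrame([r.as_row() for r in vp])
    files.append(_write(vp_table, out / "varpart.csv", index=False))

    # ---- summary ------------------------------------------------------
    stage("summary")
    summaries = []
    for column in groups.columns:
        alpha = group_summary(s.astype(float), groups[column]).assign(
            metric="richness", grouping=column
        )
        summaries.append(alpha)
        for metric, pm in (("beta_j", bj), ("beta_rc", brc)):
            summaries.append(beta_summary(pm, groups, column).assign(metric=metric, grouping=column))
    fig2 = pd.concat(summaries).reset_index()
    files.append(_write(fig2, out / "group_summaries.csv", index=False))

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def make_table1(taxa: dict[str, pd.DataFrame], hierarchy: bool = True) -> tuple[pd.DataFrame, dict]:
    """Stepwise-GLM results for every response x taxa block, long-form CSV.

    Rows carry estimate, SE, p-value and the sequential percentage of
    deviance explained for each retained term, mirroring the layout of a
    stepwise-GLM results table (three response blocks by taxa set).
    """
    rows = []
    dropped: dict[str, int] = {}
    for taxa_name, pairs in taxa.items():
        for response in RESPONSES:
            try:
                res = backward_stepwise(pairs, response, hierarchy=hierarchy)
            except ValueError as exc:
                logger.warning("GLM block %s/%s skipped: %s", taxa_name, response, exc)
                continue
            dropped[f"{taxa_name}:{response}"] = res.n_dropped
            shares = deviance_by_term(res, pairs)
            for term in shares.index:
                rows.append(
                    {
                        "response": response,
                        "taxa": taxa_name,
                        "term": term,
                        "estimate": res.params[term],
                        "se": res.bse[term],
                        "p_value": res.pvalues[term],
                        "deviance_explained_pct": shares.at[term, "sequential_pct"],
                        "drop_one_pct": shares.at[term, "drop_one_pct"],
                        "model_aic": res.aic,
                        "model_deviance_explained_pct": res.deviance_explained_pct,
                        "n_pairs": res.n_obs,
                    }
                )
            if not len(shares):
                rows.append(
                    {
                        "response": response,
                        "taxa": taxa_name,
                        "term": "(intercept only)",
                        "estimate": res.params["intercept"],
                        "se": res.bse["intercept"],
                        "p_value": res.pvalues["intercept"],
                        "deviance_explained_pct": 0.0,
                        "drop_one_pct": 0.0,
                        "model_aic": res.aic,
                        "model_deviance_explained_pct": res.deviance_explained_pct,
                        "n_pairs": res.n_obs,
                    }
                )
    return pd.DataFrame(rows), dropped


def make_fig_tables(vp_table: pd.DataFrame, summaries: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Machine-readable twins of the figure panels: varpart fractions and group means."""
    return {"varpart_fractions": vp_table, "group_summaries": summaries}
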