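"""End-to-end pipeline wiring the stages together with full provenance.

Order: simulate (or load) -> QC artifact injection -> QC filtering ->
normalization/HVGs -> type trees -> MIOG feature alignment -> cross-species
classifier mapping -> conserved markers -> ROSA protein activity ->
permutation-GSEA conservation. Every written artifact is listed in a
manifest carrying the stage parameters, per-stage seeds, the config hash
and SHA-256 digests of the files, so identical configs are verifiably
identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gsea as gsea_mod
from . import io_formats, markers, miog, qc_cluster, rosa, simulate, xmap
from .config import PipelineConfig

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a simulated two-species pair; return the results.

    Artifacts land under ``config.outdir``; the returned dict holds the
    in-memory objects (datasets, mapping result, marker tables, activity
    matrices, conservation scores) for programmatic use.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "files": {},
    }
    results: dict = {}

    # -- simulate ---------------------------------------------------------
    sim_cfg = dataclasses.replace(config.sim, seed=config.stage_seed("simulate"))
    ds_A, ds_B, orthogroups, regulons, truth = simulate.simulate_pair(sim_cfg)
    ds_A = simulate.inject_qc_artifacts(
        ds_A, sim_cfg, truth, seed=config.stage_seed("artifacts_A")
    )
    ds_B = simulate.inject_qc_artifacts(
        ds_B, sim_cfg, truth, seed=config.stage_seed("artifacts_B")
    )
    for tag, ds in (("A", ds_A), ("B", ds_B)):
        io_formats.write_expression(
            ds,
            out / f"species{tag}.mtx",
            out / f"species{tag}.cells.tsv",
            out / f"species{tag}.genes.tsv",
        )
    io_formats.write_orthogroups(orthogroups, out / "orthogroups.tsv")
    io_formats.write_regulons(regulons, out / "regulons.json")
    truth.to_json(out / "ground_truth.json")
    _record(manifest, "simulate", dataclasses.asdict(sim_cfg))
    results.update(truth=truth, orthogroups=orthogroups, regulons=regulons)

    # -- qc ---------------------------------------------------------------
    datasets, lognorm, hvgs = {}, {}, {}
    for tag, ds in (("speciesA", ds_A), ("speciesB", ds_B)):
        report = qc_cluster.qc_report(
            ds,
            min_counts=config.qc.min_counts,
            min_features=config.qc.min_features,
            max_features=_max_features(config, ds),
        )
        report.to_csv(out / f"qc_report_{tag}.tsv", sep="\t")
        filtered = qc_cluster.qc_filter(
            ds,
            min_counts=config.qc.min_counts,
            min_features=config.qc.min_features,
            max_features=_max_features(config, ds),
            low_quality_rule=config.qc.low_quality_rule,
        )
        datasets[tag] = filtered
        lognorm[tag] = qc_cluster.normalize_log_cpm(filtered)
        hvgs[tag] = qc_cluster.select_hvgs(
            lognorm[tag], filtered.gene_ids, min(config.miog.n_hvgs, filtered.n_genes)
        )
    _record(manifest, "qc", dataclasses.asdict(config.qc))
    results["datasets"] = datasets

    # -- trees ------------------------------------------------------------
    for tag in datasets:
        profiles = qc_cluster.type_mean_profiles(
            lognorm[tag],
            datasets[tag].cell_meta["cell_type"],
            datasets[tag].gene_ids,
        )
        D = qc_cluster.correlation_distance(profiles)
        dendro = qc_cluster.hclust_centroid(D)
        njt = qc_cluster.nj_tree(
            D,
            profiles=profiles,
            n_bootstrap=config.trees.n_bootstrap,
            seed=config.stage_seed(f"trees_{tag}"),
        )
        (out / f"dendrogram_{tag}.nwk").write_text(dendro.to_newick() + "\n")
        (out / f"nj_{tag}.nwk").write_text(njt.to_newick() + "\n")
    _record(manifest, "trees", dataclasses.asdict(config.trees))

    # -- miog -------------------------------------------------------------
    miog_table = miog.miog_select(datasets, orthogroups, lognorm=lognorm)
    miog_table.to_tsv(out / "miog.tsv")
    features = miog.build_feature_table(
        miog_table,
        mode=config.miog.mode,
        hvgs_per_species=hvgs if config.miog.mode == "intersection" else None,
    )
    _record(manifest, "miog", dataclasses.asdict(config.miog))
    results["miog"] = miog_table
    results["features"] = features

    # -- xmap: train on species A types, map species B cells --------------
    mapping = xmap.map_types(
        datasets["speciesA"],
        datasets["speciesB"],
        features,
        train_fraction=config.xmap.train_fraction,
        cap=config.xmap.cap,
        threshold=config.xmap.threshold,
        seed=config.stage_seed("xmap"),
        n_estimators=config.xmap.n_estimators,
        max_depth=config.xmap.max_depth,
        learning_rate=config.xmap.learning_rate,
    )
    io_formats.write_matrix_csv(mapping.confusion.to_frame(), out / "confusion.csv")
    mapping.best_match.to_csv(out / "best_match.tsv", sep="\t")
    with open(out / "mapping.json", "w") as fh:
        json.dump(
            {
                "holdout_accuracy": mapping.holdout_accuracy,
                "h_norm": mapping.h_norm,
                "threshold": mapping.threshold,
            },
            fh,
            indent=1,
        )
    _record(manifest, "xmap", dataclasses.asdict(config.xmap))
    results["mapping"] = mapping

    # -- markers ----------------------------------------------------------
    marker_tables = {}
    for tag in datasets:
        tables = markers.conserved_markers(
            datasets[tag], group_label="cell_type", lognorm=lognorm[tag]
        )
        marker_tables[tag] = tables
        combined = pd.concat(
            [t.assign(group=g) for g, t in tables.items()]
        )
        combined.to_csv(out / f"markers_{tag}.tsv", sep="\t")
    _record(manifest, "markers", {})
    results["markers"] = marker_tables

    # -- rosa -------------------------------------------------------------
    pruned = rosa.prune_regulons(
        regulons, max_size=config.rosa.max_size, min_size=config.rosa.min_size
    )
    grid = rosa.QuantileGrid(q=config.rosa.q)
    activities = {}
    rep_B = miog_table.representative("speciesB")
    regulons_by_species = {
        "speciesA": pruned,
        "speciesB": miog.translate_regulons(
            pruned, orthogroups, "speciesA", "speciesB", rep_B
        ),
    }
    for tag, ds in datasets.items():
        Z = rosa.expression_zscores(lognorm[tag], mode=config.rosa.zmode)
        Z = grid.adjust(Z)
        act = rosa.rosa_nes(
            Z,
            ds.gene_ids,
            regulons_by_species[tag],
            cell_ids=ds.cell_ids,
            cell_classes=ds.cell_meta["cell_class"],
        )
        activities[tag] = act
        io_formats.write_matrix_csv(act.to_frame(), out / f"activity_{tag}.csv")
        diff = rosa.differential_activity(act)
        diff.to_csv(out / f"differential_activity_{tag}.tsv", sep="\t", index=False)
        results.setdefault("differential_activity", {})[tag] = diff
    _record(manifest, "rosa", dataclasses.asdict(config.rosa))
    results["activities"] = activities

    # -- gsea: query species-B class programs against species A -----------
    scores = []
    act_A, act_B = activities["speciesA"], activities["speciesB"]
    shared_classes = sorted(
        set(act_A.cell_classes) & set(act_B.cell_classes)
    )
    for cls in shared_classes:
        sig_B = gsea_mod.class_signature(act_B, cls)
        # the query is the activated program: cap at positively scored
        # regulators, and below the full regulator count (the KS statistic
        # is undefined when the query covers every regulator)
        k = min(
            config.gsea.k,
            int((sig_B.scores > 0).sum()),
            len(sig_B.scores) - 1,
        )
        query = gsea_mod.top_query_set(sig_B, k=max(k, 1))
        score = gsea_mod.gsea_conservation(
            query,
            act_A,
            cls,
            n_perm=config.gsea.n_perm,
            seed=config.stage_seed(f"gsea_{cls}"),
            weight_exponent=config.gsea.weight_exponent,
            perm_unit=config.gsea.perm_unit,
        )
        scores.append(score)
    conservation = pd.DataFrame(
        [
            {
                "class": s.target_class,
                "es": s.es,
                "nes": s.nes,
                "p": s.p,
                "n_permutations": s.n_permutations,
            }
            for s in scores
        ]
    )
    conservation.to_csv(out / "conservation.csv", index=False)
    _record(manifest, "gsea", dataclasses.asdict(config.gsea))
    results["conservation"] = conservation

    # -- manifest ---------------------------------------------------------
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    results["manifest"] = manifest
    return results


def _max_features(config: PipelineConfig, ds) -> int:
    """Doublet feature threshold, scaled to the simulated gene universe.

    The real-data default (8,950 detected features) exceeds the number of
    simulated genes, so on simulated inputs the simulator's own threshold
    applies; a config max_features below the gene count wins if the user
    set one.
    """
    if config.qc.max_features <= ds.n_genes:
        return config.qc.max_features
    if config.sim.doublet_feature_threshold < ds.n_genes:
        return config.sim.doublet_feature_threshold
    return config.qc.max_features


def _record(manifest: dict, stage: str, params: dict) -> None:
    manifest["stages"][stage] = {"params": params}
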