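"""Two-species synthetic single-cell data with known ground truth.

The generator emulates the statistical structure the downstream stages
assume: two "species" whose cell types are linked by a partial homology map,
orthogroups that may carry a duplicated copy in one species (only one copy
carries the type signal), negative-binomial counts with log-normal library
sizes, per-sample batch wobble, regulators whose signed weighted targets are
shifted in the classes where the regulator is active, and injectable QC
artifacts (low-depth cells, doublets). Every draw flows from one
``numpy.random.default_rng`` seed, so identical configs give bit-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    ExpressionDataset,
    OrthoGroupTable,
    Regulon,
    RegulonSet,
    ValidationError,
)


@dataclass
class SimConfig:
    """Parameters of the two-species simulation.

    Defaults are sized for desk scale: roughly 2,000 cells and 2,000 genes
    per species, 20 regulators. ``homology_map`` maps species-B type index
    to species-A type index and must be injective; types absent from it are
    species-specific (they get their own marker program). ``None`` means the
    identity map on the first ``min(n_types_A, n_types_B) - 1`` types,
    leaving the last type of each species unmatched.
    """

    seed: int = 0
    n_types_A: int = 6
    n_types_B: int = 6
    homology_map: dict[int, int] | None = None
    cells_per_type: int = 330
    n_samples: int = 2
    n_genes: int = 2000
    markers_per_type: int = 40
    nb_dispersion: float = 2.0
    fold_change: float = 4.0
    depth: float = 2000.0
    library_sd: float = 0.3
    sample_effect_sd: float = 0.1
    species_effect_sd: float = 0.3
    dup_fraction: float = 0.2
    n_classes: int = 3
    n_regulators: int = 20
    targets_per_regulator: int = 40
    activity_effect: float = 1.0
    # qc artifact injection
    low_depth_rate: float = 0.02
    doublet_rate: float = 0.02
    # feature-count doublet threshold scaled to the simulated gene universe
    # (singlets at the default depth detect ~850 +- 120 of 2,000 genes)
    doublet_feature_threshold: int = 1450

    def __post_init__(self) -> None:
        for name in (
            "n_types_A",
            "n_types_B",
            "cells_per_type",
            "n_samples",
            "n_genes",
            "markers_per_type",
            "n_classes",
            "n_regulators",
            "targets_per_regulator",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("low_depth_rate", "doublet_rate", "dup_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} not in [0, 1]")
        if self.nb_dispersion <= 0 or self.fold_change <= 0:
            raise ValidationError("nb_dispersion and fold_change must be positive")
        if self.homology_map is None:
            k = min(self.n_types_A, self.n_types_B) - 1
            self.homology_map = {i: i for i in range(max(k, 1))}
        vals = list(self.homology_map.values())
        if len(set(vals)) != len(vals):
            raise ValidationError("homology_map must be injective")
        for b, a in self.homology_map.items():
            if not (0 <= b < self.n_types_B and 0 <= a < self.n_types_A):
                raise ValidationError(f"homology_map entry {b}->{a} out of range")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    # species-B type label -> homologous species-A type label
    type_map: dict[str, str]
    # orthogroup -> {species: gene_id carrying the programmed type signal}
    informative_copy: dict[str, dict[str, str]]
    # type label -> marker gene ids, per species
    marker_genes: dict[str, dict[str, list[str]]]
    # regulator -> class label in which it is programmed active
    regulator_classes: dict[str, str]
    activity_effect: float
    # species -> {cell_id: "low_depth" | "doublet"} (filled by injection)
    artifacts: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _type_label(species: str, t: int) -> str:
    return f"{species}_t{t:02d}"


def _class_label(t: int, n_classes: int) -> str:
    return f"class{t % n_classes}"


def simulate_pair(
    config: SimConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, OrthoGroupTable, RegulonSet, GroundTruth]:
    """Simulate a two-species dataset pair with shared cell-type programs.

    Returns the species-A and species-B datasets, the orthogroup table
    linking their genes, a regulon set (targets in species-A gene ids;
    translate through the orthogroup table for species B), and the ground
    truth used to program the data.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_unmatched_B = cfg.n_types_B - len(cfg.homology_map)
    n_marker_sets = cfg.n_types_A + n_unmatched_B
    if n_marker_sets * cfg.markers_per_type > cfg.n_genes:
        raise ValidationError(
            f"{n_marker_sets} marker programs x {cfg.markers_per_type} genes "
            f"exceed n_genes={cfg.n_genes}"
        )

    # --- orthogroup scaffold: one orthogroup per simulated ancestral gene.
    og_ids = [f"OG{g:05d}" for g in range(cfg.n_genes)]
    genes_A = [f"A_g{g:05d}" for g in range(cfg.n_genes)]
    dup_mask = rng.random(cfg.n_genes) < cfg.dup_fraction
    records: dict[str, dict[str, list[str]]] = {}
    genes_B: list[str] = []
    informative_B_idx = np.zeros(cfg.n_genes, dtype=int)  # column index in B
    dup_B_idx = np.full(cfg.n_genes, -1, dtype=int)
    informative_copy: dict[str, dict[str, str]] = {}
    for g in range(cfg.n_genes):
        primary = f"B_g{g:05d}"
        members = [primary]
        if dup_mask[g]:
            members.append(f"B_g{g:05d}dup")
        # the signal-carrying copy is drawn at random among the B members
        signal = int(rng.integers(len(members)))
        informative_B_idx[g] = len(genes_B) + signal
        if len(members) == 2:
            dup_B_idx[g] = len(genes_B) + (1 - signal)
        records[og_ids[g]] = {"speciesA": [genes_A[g]], "speciesB": list(members)}
        informative_copy[og_ids[g]] = {
            "speciesA": genes_A[g],
            "speciesB": members[signal],
        }
        genes_B.extend(members)
    orthogroups = OrthoGroupTable(records=records, species=("speciesA", "speciesB"))

    # --- marker programs on orthogroup indices (disjoint across programs).
    perm = rng.permutation(cfg.n_genes)
    marker_ogs: list[np.ndarray] = [
        perm[i * cfg.markers_per_type : (i + 1) * cfg.markers_per_type]
        for i in range(n_marker_sets)
    ]
    # programs 0..n_types_A-1 belong to A types; the rest to unmatched B types
    unmatched_B = [b for b in range(cfg.n_types_B) if b not in cfg.homology_map]
    program_of_B = {b: cfg.homology_map.get(b) for b in range(cfg.n_types_B)}
    for j, b in enumerate(unmatched_B):
        program_of_B[b] = cfg.n_types_A + j

    # --- regulators: signed weighted targets drawn over all orthogroups.
    regulons = []
    regulator_classes: dict[str, str] = {}
    target_pool = rng.permutation(cfg.n_genes)
    for r in range(cfg.n_regulators):
        idx = rng.choice(target_pool, size=cfg.targets_per_regulator, replace=False)
        modes = rng.choice([-1, 1], size=cfg.targets_per_regulator)
        weights = rng.uniform(0.25, 1.0, size=cfg.targets_per_regulator)
        name = f"R{r:03d}"
        regulons.append(
            Regulon(
                regulator=name,
                targets=tuple(genes_A[g] for g in idx),
                modes=tuple(int(m) for m in modes),
                weights=tuple(float(w) for w in np.round(weights, 6)),
            )
        )
        regulator_classes[name] = _class_label(r, cfg.n_classes)
    regulon_set = RegulonSet(regulons)

    # --- per-orthogroup base rates, normalized to the target depth.
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    base *= cfg.depth / base.sum()
    species_scale_B = rng.lognormal(0.0, cfg.species_effect_sd, size=cfg.n_genes)

    # per-type rate matrices at orthogroup resolution
    def type_rates(program: int | None, species: str, class_of_type: str) -> np.ndarray:
        rates = base.copy()
        if species == "speciesB":
            rates = rates * species_scale_B
        if program is not None:
            rates[marker_ogs[program]] *= cfg.fold_change
        for reg in regulon_set:
            if regulator_classes[reg.regulator] != class_of_type:
                continue
            for t, m, w in zip(reg.targets, reg.modes, reg.weights):
                g = int(t[3:8])  # A_g%05d -> orthogroup index
                rates[g] *= np.exp(cfg.activity_effect * m * w)
        return rates

    def expand_to_B(og_rates: np.ndarray) -> np.ndarray:
        """Place orthogroup rates on species-B gene columns.

        The informative copy carries the full rate; a duplicated copy gets
        flat low-level noise (5% of the orthogroup base), independent of
        type, so it is uninformative by construction.
        """
        out = np.empty(len(genes_B))
        out[informative_B_idx] = og_rates
        has_dup = dup_B_idx >= 0
        out[dup_B_idx[has_dup]] = 0.05 * base[has_dup] * species_scale_B[has_dup]
        return out

    def sample_species(
        species: str, n_types: int, program_of: dict[int, int | None] | None
    ) -> ExpressionDataset:
        gene_ids = genes_A if species == "speciesA" else genes_B
        n_g = len(gene_ids)
        sample_scale = rng.lognormal(
            0.0, cfg.sample_effect_sd, size=(cfg.n_samples, n_g)
        )
        blocks, meta_rows = [], []
        for t in range(n_types):
            program = t if program_of is None else program_of[t]
            cls = _class_label(t, cfg.n_classes)
            og_rates = type_rates(program, species, cls)
            rates = og_rates if species == "speciesA" else expand_to_B(og_rates)
            rates = rates * (cfg.depth / rates.sum())
            for s in range(cfg.n_samples):
                n_c = cfg.cells_per_type // cfg.n_samples + (
                    1 if s < cfg.cells_per_type % cfg.n_samples else 0
                )
                lib = rng.lognormal(0.0, cfg.library_sd, size=n_c)
                mu = lib[:, None] * (rates * sample_scale[s])[None, :]
                lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
                counts = rng.poisson(lam)
                blocks.append(sp.csr_matrix(counts))
                for c in range(n_c):
                    meta_rows.append(
                        {
                            "species": species,
                            "sample": f"{species}_s{s}",
                            "cell_class": cls,
                            "cell_type": _type_label(species, t),
                            "artifact": "",
                        }
                    )
        counts = sp.vstack(blocks).tocsr()
        cell_meta = pd.DataFrame(meta_rows)
        cell_meta.index = pd.Index(
            [f"{species}_c{i:05d}" for i in range(len(cell_meta))], name="cell_id"
        )
        gene_meta = pd.DataFrame(
            {"symbol": gene_ids},
            index=pd.Index(gene_ids, name="gene_id"),
        )
        return ExpressionDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)

    ds_A = sample_species("speciesA", cfg.n_types_A, None)
    ds_B = sample_species("speciesB", cfg.n_types_B, program_of_B)

    marker_genes: dict[str, dict[str, list[str]]] = {"speciesA": {}, "speciesB": {}}
    for t in range(cfg.n_types_A):
        marker_genes["speciesA"][_type_label("speciesA", t)] = [
            genes_A[g] for g in marker_ogs[t]
        ]
    for b in range(cfg.n_types_B):
        marker_genes["speciesB"][_type_label("speciesB", b)] = [
            informative_copy[og_ids[g]]["speciesB"] for g in marker_ogs[program_of_B[b]]
        ]

    truth = GroundTruth(
        type_map={
            _type_label("speciesB", b): _type_label("speciesA", a)
            for b, a in cfg.homology_map.items()
        },
        informative_copy=informative_copy,
        marker_genes=marker_genes,
        regulator_classes=regulator_classes,
        activity_effect=cfg.activity_effect,
    )
    return ds_A, ds_B, orthogroups, regulon_set, truth


def inject_qc_artifacts(
    dataset: ExpressionDataset,
    config: SimConfig,
    truth: GroundTruth | None = None,
    seed: int | None = None,
) -> ExpressionDataset:
    """Append labeled low-depth cells and doublets to a simulated dataset.

    Low-depth cells are binomially thinned copies of real cells whose totals
    fall below the low-quality thresholds (total counts < 500, detected
    features < 330). Doublets are sums of two random cells, scaled up until
    their detected-feature count exceeds ``config.doublet_feature_threshold``.
    Artifact labels land in the ``artifact`` metadata column (and in
    ``truth.artifacts`` when a GroundTruth is passed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n = dataset.n_cells
    n_low = int(round(cfg.low_depth_rate * n))
    n_dbl = int(round(cfg.doublet_rate * n))
    if n_low == 0 and n_dbl == 0:
        return dataset

    counts = dataset.counts.tocsr()
    new_rows: list[sp.csr_matrix] = []
    new_meta: list[dict] = []
    species = str(dataset.cell_meta["species"].iloc[0])

    low_src = rng.integers(0, n, size=n_low)
    for k, i in enumerate(low_src):
        row = counts[int(i)].toarray().ravel()
        total = row.sum()
        # thin to ~200 expected counts: far below both minimum thresholds
        p = min(1.0, 200.0 / max(total, 1))
        thin = rng.binomial(row.astype(int), p)
        new_rows.append(sp.csr_matrix(thin))
        new_meta.append(_artifact_meta(dataset, int(i), "low_depth"))

    dbl_src = rng.integers(0, n, size=(n_dbl, 2))
    for k, (i, j) in enumerate(dbl_src):
        row = (counts[int(i)] + counts[int(j)]).toarray().ravel().astype(int)
        scale = 1
        while (row > 0).sum() <= cfg.doublet_feature_threshold and scale < 64:
            # amplify by resampling: doubling counts cannot add features, so
            # add a second independent draw of the same doublet profile
            row = row + rng.poisson(np.maximum(row, 1))
            scale *= 2
        new_rows.append(sp.csr_matrix(row))
        new_meta.append(_artifact_meta(dataset, int(i), "doublet"))

    meta = pd.DataFrame(new_meta)
    meta.index = pd.Index(
        [f"{species}_art{i:04d}" for i in range(len(meta))], name="cell_id"
    )
    out = ExpressionDataset(
        counts=sp.vstack([counts] + new_rows).tocsr(),
        cell_meta=pd.concat([dataset.cell_meta, meta]),
        gene_meta=dataset.gene_meta,
    )
    if truth is not None:
        truth.artifacts.setdefault(species, {}).update(
            {cid: m["artifact"] for cid, m in zip(meta.index, new_meta)}
        )
    return out


def _artifact_meta(dataset: ExpressionDataset, src: int, kind: str) -> dict:
    base = dataset.cell_meta.iloc[src]
    return {
        "species": base["species"],
        "sample": base["sample"],
        "cell_class": "",
        "cell_type": "",
        "artifact": kind,
    }
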