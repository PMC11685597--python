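"""Most Informative Orthologous Gene (MIOG) selection.

Gene duplication makes many orthology relations one-to-many or
many-to-many, so a cross-species feature space needs one representative
gene per species per orthogroup. The MIOG rule picks, within each
orthogroup and species, the member gene with the highest standard deviation
of log-normalized expression across that species' cells — the copy carrying
the most information about cell identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ExpressionDataset,
    OrthoGroupTable,
    Regulon,
    RegulonSet,
    ValidationError,
)
from .qc_cluster import normalize_log_cpm

logger = logging.getLogger(__name__)


@dataclass
class MiogTable:
    """Per-orthogroup, per-species representative genes and their scores.

    Backed by a long-format frame with columns ``orthogroup_id``,
    ``species``, ``gene_id``, ``sd`` (selection score: standard deviation of
    log-normalized expression, always >= 0; at most one row per orthogroup
    and species).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"orthogroup_id", "species", "gene_id", "sd"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(f"MiogTable needs columns {sorted(required)}")
        if self.frame.duplicated(["orthogroup_id", "species"]).any():
            raise ValidationError("multiple representatives for one orthogroup/species")
        if (self.frame["sd"] < 0).any():
            raise ValidationError("negative selection score")

    def representative(self, species: str) -> dict[str, str]:
        """orthogroup_id -> chosen gene_id for one species."""
        sub = self.frame[self.frame["species"] == species]
        return dict(zip(sub["orthogroup_id"], sub["gene_id"]))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MiogTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"orthogroup_id": str}))


def miog_select(
    datasets: Mapping[str, ExpressionDataset],
    orthogroups: OrthoGroupTable,
    lognorm: Mapping[str, np.ndarray] | None = None,
) -> MiogTable:
    """Choose the most informative orthogroup member per species.

    For each orthogroup and species, members present in the expression
    matrix compete by standard deviation (ddof=1) of log2(1+CPM) across all
    of that species' cells; the highest wins, ties broken by gene id.
    Members listed in the orthogroup table but absent from the matrix score
    0 and are skipped with a warning; orthogroups with no expressed member
    in a species get no entry for that species.
    """
    if len(orthogroups) == 0:
        raise ValidationError("empty orthogroup table")
    rows = []
    for species, ds in datasets.items():
        X = (
            lognorm[species]
            if lognorm is not None and species in lognorm
            else normalize_log_cpm(ds)
        )
        sd = np.std(np.asarray(X), axis=0, ddof=1)
        sd_of = dict(zip(ds.gene_ids, sd))
        n_missing = 0
        for og_id in orthogroups:
            members = orthogroups.members(og_id, species)
            present = [g for g in members if g in sd_of]
            n_missing += len(members) - len(present)
            if not present:
                continue
            # highest SD wins; SD ties break toward the smallest gene id
            best = min(present, key=lambda g: (-sd_of[g], g))
            rows.append(
                {
                    "orthogroup_id": og_id,
                    "species": species,
                    "gene_id": best,
                    "sd": float(sd_of[best]),
                }
            )
        if n_missing:
            logger.warning(
                "miog_select: %d orthogroup members absent from %s matrix "
                "(treated as SD 0)",
                n_missing,
                species,
            )
    return MiogTable(pd.DataFrame(rows, columns=["orthogroup_id", "species", "gene_id", "sd"]))


def build_feature_table(
    miog: MiogTable,
    mode: str = "miog",
    hvgs_per_species: Mapping[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Aligned cross-species feature pairs, one row per orthogroup.

    ``miog`` mode keeps every orthogroup with a representative in both
    species. ``intersection`` mode additionally requires the representative
    to be a highly variable gene in both species (``hvgs_per_species``
    keyed by species tag), mirroring per-species HVG-list intersection.
    """
    if mode not in ("miog", "intersection"):
        raise ValidationError(f"unknown mode {mode!r}")
    species = sorted(miog.frame["species"].unique())
    if len(species) != 2:
        raise ValidationError(f"feature table needs exactly 2 species, got {species}")
    wide = miog.frame.pivot(index="orthogroup_id", columns="species", values="gene_id")
    wide = wide.dropna()
    if mode == "intersection":
        if hvgs_per_species is None:
            raise ValidationError("intersection mode requires hvgs_per_species")
        for s in species:
            hv = set(hvgs_per_species[s])
            wide = wide[wide[s].isin(hv)]
    if len(wide) == 0:
        raise ValidationError(
            "no shared features between species"
            + (" — try a larger HVG list" if mode == "intersection" else "")
        )
    wide = wide.sort_index()
    wide.columns.name = None
    return wide.reset_index()


def translate_regulons(
    regulon_set: RegulonSet,
    orthogroups: OrthoGroupTable,
    src_species: str,
    dst_species: str,
    representative: Mapping[str, str],
) -> RegulonSet:
    """Carry regulon targets from one species' namespace into another.

    Each target maps through its orthogroup to the destination species'
    representative gene (e.g. the MIOG); targets without an orthogroup or
    without a destination representative are dropped with a warning.
    """
    src_og = orthogroups.gene_to_orthogroup(src_species)
    out = []
    n_dropped = 0
    for reg in regulon_set:
        targets, modes, weights, seen = [], [], [], set()
        for t, m, w in zip(reg.targets, reg.modes, reg.weights):
            og = src_og.get(t)
            dst = representative.get(og) if og is not None else None
            if dst is None or dst in seen:
                n_dropped += 1
                continue
            seen.add(dst)
            targets.append(dst)
            modes.append(m)
            weights.append(w)
        if targets:
            out.append(
                Regulon(
                    regulator=reg.regulator,
                    targets=tuple(targets),
                    modes=tuple(modes),
                    weights=tuple(weights),
                )
            )
    if n_dropped:
        logger.warning(
            "translate_regulons: dropped %d targets without a %s representative",
            n_dropped,
            dst_species,
        )
    return RegulonSet(out)
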