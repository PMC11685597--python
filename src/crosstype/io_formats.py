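"""Readers and writers for the external formats the pipeline touches.

Expression data travels as MatrixMarket coordinate files with TSV sidecars
(the 10x-style triplet); orthogroups use the OrthoFinder ``Orthogroups.tsv``
dialect (one row per orthogroup, one column per species, comma-separated
gene lists); regulons use a JSON list (canonical) or a 4-column TSV.
All readers validate on load and never silently drop records.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    CELL_META_COLUMNS,
    ExpressionDataset,
    OrthoGroupTable,
    Regulon,
    RegulonSet,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Expression matrices: MTX + cells.tsv / genes.tsv sidecars
# ---------------------------------------------------------------------------


def read_expression(
    mtx_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
    orientation: str = "auto",
) -> ExpressionDataset:
    """Load a sparse count matrix with its cell and gene sidecars.

    On-disk matrices circulate in both orientations; the 10x convention is
    genes x cells. With ``orientation="auto"`` the sidecar lengths decide:
    if the matrix is (n_genes, n_cells) it is transposed to cells x genes.
    Pass ``"cells_by_genes"`` or ``"genes_by_cells"`` to override (required
    for square matrices, where the sidecars cannot disambiguate).
    """
    if orientation not in ("auto", "cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    cell_meta = _read_sidecar(cells_path, "cell_id")
    gene_meta = _read_sidecar(genes_path, "gene_id")
    n_cells, n_genes = len(cell_meta), len(gene_meta)

    if orientation == "genes_by_cells":
        mat = mat.T.tocsr()
    elif orientation == "auto":
        if mat.shape == (n_cells, n_genes) and n_cells != n_genes:
            pass
        elif mat.shape == (n_genes, n_cells) and n_cells != n_genes:
            mat = mat.T.tocsr()
        elif mat.shape == (n_cells, n_genes):  # square: assume cells x genes
            pass
        else:
            raise ValidationError(
                f"matrix shape {mat.shape} matches neither "
                f"{n_cells} cells x {n_genes} genes nor its transpose "
                f"({mtx_path})"
            )
    if mat.shape != (n_cells, n_genes):
        raise ValidationError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({n_cells} cells, {n_genes} genes)"
        )
    for col in CELL_META_COLUMNS:
        if col not in cell_meta.columns:
            cell_meta[col] = ""
    if mat.nnz:
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValidationError(f"{mtx_path}: non-integer count entries")
        mat.data = np.round(mat.data)
    return ExpressionDataset(counts=mat, cell_meta=cell_meta, gene_meta=gene_meta)


def write_expression(
    dataset: ExpressionDataset,
    mtx_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
) -> None:
    """Write a dataset as cells x genes MTX plus TSV sidecars."""
    scipy.io.mmwrite(str(mtx_path), dataset.counts.tocoo(), field="integer")
    dataset.cell_meta.to_csv(cells_path, sep="\t", index_label="cell_id")
    dataset.gene_meta.to_csv(genes_path, sep="\t", index_label="gene_id")


def _read_sidecar(path: str | Path, id_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if id_name not in df.columns:
        # headerless single-column sidecar (bare barcodes/features)
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, keep_default_na=False)
        df.columns = [id_name] + [f"col{i}" for i in range(1, df.shape[1])]
    if df[id_name].duplicated().any():
        dup = df[id_name][df[id_name].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate {id_name} {dup!r}")
    return df.set_index(id_name)


# ---------------------------------------------------------------------------
# Orthogroups: OrthoFinder Orthogroups.tsv dialect
# ---------------------------------------------------------------------------


def read_orthogroups(
    tsv_path: str | Path, species_tags: Sequence[str]
) -> OrthoGroupTable:
    """Parse an ``Orthogroups.tsv``-style table for the requested species.

    The first column is the orthogroup id; remaining columns are named for
    species and hold comma-separated gene lists (possibly empty). Gene ids
    are whitespace-trimmed; rows are never dropped.
    """
    species_tags = list(species_tags)
    with open(tsv_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        unknown = [s for s in species_tags if s not in header[1:]]
        if unknown:
            raise ValidationError(
                f"{tsv_path}: requested species {unknown} not in header "
                f"{header[1:]}"
            )
        col_of = {s: header.index(s) for s in species_tags}
        records: dict[str, dict[str, list[str]]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            og_id = row[0].strip()
            if og_id in records:
                raise ValidationError(
                    f"{tsv_path}:{lineno}: duplicate orthogroup id {og_id!r}"
                )
            records[og_id] = {
                s: [g.strip() for g in row[c].split(",") if g.strip()]
                if c < len(row)
                else []
                for s, c in col_of.items()
            }
    return OrthoGroupTable(records=records, species=tuple(species_tags))


def write_orthogroups(table: OrthoGroupTable, tsv_path: str | Path) -> None:
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["Orthogroup", *table.species])
        for og_id in table:
            writer.writerow(
                [og_id]
                + [", ".join(table.members(og_id, s)) for s in table.species]
            )


# ---------------------------------------------------------------------------
# Regulons: JSON (canonical) and 4-column TSV
# ---------------------------------------------------------------------------


def read_regulons(path: str | Path) -> RegulonSet:
    """Read a regulon set from JSON or TSV (decided by file suffix).

    JSON: list of ``{"regulator": str, "targets": [[target, mode, weight],
    ...]}``. TSV: columns regulator, target, mode, weight with a header row;
    rows for one regulator must be contiguous ("." marks a missing optional
    field and is rejected for mode/weight, which are required).
    """
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        regulons = [
            _make_regulon(
                rec["regulator"],
                [(t, m, w) for t, m, w in rec["targets"]],
                src=str(path),
            )
            for rec in raw
        ]
        return RegulonSet(regulons)
    rows = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    required = {"regulator", "target", "mode", "weight"}
    if not required.issubset(rows.columns):
        raise ValidationError(
            f"{path}: regulon TSV needs columns {sorted(required)}"
        )
    regulons = []
    for reg, grp in rows.groupby("regulator", sort=False):
        triples = list(zip(grp["target"], grp["mode"], grp["weight"]))
        regulons.append(_make_regulon(str(reg), triples, src=str(path)))
    return RegulonSet(regulons)


def _make_regulon(regulator: str, triples: list, src: str) -> Regulon:
    targets, modes, weights = [], [], []
    for t, m, w in triples:
        if m in (".", None) or w in (".", None):
            raise ValidationError(
                f"{src}: regulon {regulator!r} target {t!r} has missing "
                "mode/weight"
            )
        m = int(m)
        w = float(w)
        targets.append(str(t))
        modes.append(m)
        weights.append(w)
    return Regulon(
        regulator=regulator,
        targets=tuple(targets),
        modes=tuple(modes),
        weights=tuple(weights),
    )


def write_regulons(regulon_set: RegulonSet, path: str | Path) -> None:
    """Write regulons as JSON (``.json`` suffix) or TSV (anything else)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = [
            {
                "regulator": r.regulator,
                "targets": [
                    [t, int(m), float(w)]
                    for t, m, w in zip(r.targets, r.modes, r.weights)
                ],
            }
            for r in regulon_set
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["regulator", "target", "mode", "weight"])
            for r in regulon_set:
                for t, m, w in zip(r.targets, r.modes, r.weights):
                    writer.writerow([r.regulator, t, int(m), repr(float(w))])


# ---------------------------------------------------------------------------
# Derived matrices
# ---------------------------------------------------------------------------


def write_matrix_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index_label="")


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
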