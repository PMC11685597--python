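"""Core in-memory containers shared by every pipeline stage.

The pipeline moves four kinds of object between stages: sparse cell-by-gene
count matrices with cell/gene metadata, orthogroup tables mapping ancestral
genes to per-species gene lists, regulon sets (a regulator plus its signed,
weighted targets), and the derived matrices (type-type distances, classifier
confusion matrices, regulator-by-cell activities). Each container validates
its own invariants on construction so format errors surface at the boundary
rather than deep inside a stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


# Metadata columns every ExpressionDataset carries per cell.
CELL_META_COLUMNS = ("species", "sample", "cell_class", "cell_type")


@dataclass
class ExpressionDataset:
    """Sparse cell x gene count matrix with per-cell and per-gene metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells in rows and genes in columns.
        Stored as CSR.
    cell_meta
        One row per cell, indexed by unique ``cell_id``. Must contain the
        columns ``species``, ``sample``, ``cell_class`` and ``cell_type``
        (values may be empty strings when unknown).
    gene_meta
        One row per gene, indexed by unique ``gene_id``.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise ValidationError(
                f"cell_meta has {len(self.cell_meta)} rows but counts has "
                f"{n_cells} cells"
            )
        if len(self.gene_meta) != n_genes:
            raise ValidationError(
                f"gene_meta has {len(self.gene_meta)} rows but counts has "
                f"{n_genes} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            i = int(np.argmax(self.counts.data < 0))
            raise ValidationError(
                f"counts contains negative entries (first stored value "
                f"{self.counts.data[i]})"
            )
        for name, meta in (("cell", self.cell_meta), ("gene", self.gene_meta)):
            if meta.index.has_duplicates:
                dup = meta.index[meta.index.duplicated()][0]
                raise ValidationError(f"duplicate {name}_id {dup!r}")
        missing = [c for c in CELL_META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValidationError(f"cell_meta missing columns {missing}")

    # -- conveniences -----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_meta.index

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        """Restrict to the cells selected by a boolean mask or index array."""
        mask = np.asarray(mask)
        return ExpressionDataset(
            counts=self.counts[mask],
            cell_meta=self.cell_meta.iloc[mask]
            if mask.dtype.kind in "iu"
            else self.cell_meta.loc[mask],
            gene_meta=self.gene_meta,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the given genes, in the given order."""
        idx = self.gene_meta.index.get_indexer(list(gene_ids))
        if (idx < 0).any():
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise ValidationError(f"unknown gene ids {missing[:5]}")
        return ExpressionDataset(
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta,
            gene_meta=self.gene_meta.iloc[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and self.cell_meta.index.equals(other.cell_meta.index)
            and self.gene_meta.index.equals(other.gene_meta.index)
        )


@dataclass
class OrthoGroupTable:
    """Orthogroup id -> {species tag -> list of member gene ids}.

    A gene may belong to at most one orthogroup within its species; empty
    per-species lists are allowed (the orthogroup has no member there).
    """

    records: dict[str, dict[str, list[str]]]
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        seen: dict[str, dict[str, str]] = {s: {} for s in self.species}
        for og_id, per_species in self.records.items():
            for s in per_species:
                if s not in seen:
                    raise ValidationError(
                        f"orthogroup {og_id!r} names unknown species {s!r}"
                    )
            for s, genes in per_species.items():
                for g in genes:
                    if g in seen[s]:
                        raise ValidationError(
                            f"gene {g!r} ({s}) appears in orthogroups "
                            f"{seen[s][g]!r} and {og_id!r}"
                        )
                    seen[s][g] = og_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def members(self, og_id: str, species: str) -> list[str]:
        return list(self.records[og_id].get(species, []))

    def gene_to_orthogroup(self, species: str) -> dict[str, str]:
        """Invert the table for one species: gene_id -> orthogroup_id."""
        out: dict[str, str] = {}
        for og_id, per_species in self.records.items():
            for g in per_species.get(species, []):
                out[g] = og_id
        return out


@dataclass(frozen=True)
class Regulon:
    """A regulator with signed, weighted targets.

    ``modes`` are the regulation modes (+1 activating, -1 repressing) and
    ``weights`` the regulatory strengths in (0, 1].
    """

    regulator: str
    targets: tuple[str, ...]
    modes: tuple[int, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.targets) == len(self.modes) == len(self.weights)):
            raise ValidationError(
                f"regulon {self.regulator!r}: targets/modes/weights lengths differ"
            )
        if len(set(self.targets)) != len(self.targets):
            dup = next(t for t in self.targets if self.targets.count(t) > 1)
            raise ValidationError(
                f"regulon {self.regulator!r}: duplicate target {dup!r}"
            )
        for t, m in zip(self.targets, self.modes):
            if m not in (-1, 1):
                raise ValidationError(
                    f"regulon {self.regulator!r} target {t!r}: mode {m} not in {{-1,+1}}"
                )
        for t, w in zip(self.targets, self.weights):
            if not (0.0 < w <= 1.0):
                raise ValidationError(
                    f"regulon {self.regulator!r} target {t!r}: weight {w} not in (0,1]"
                )

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def mode_array(self) -> np.ndarray:
        return np.asarray(self.modes, dtype=float)

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass
class RegulonSet:
    """Ordered collection of regulons with unique regulator ids."""

    regulons: list[Regulon]

    def __post_init__(self) -> None:
        names = [r.regulator for r in self.regulons]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValidationError(f"duplicate regulator {dup!r}")

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self) -> Iterator[Regulon]:
        return iter(self.regulons)

    def __getitem__(self, regulator: str) -> Regulon:
        for r in self.regulons:
            if r.regulator == regulator:
                return r
        raise KeyError(regulator)

    @property
    def regulators(self) -> list[str]:
        return [r.regulator for r in self.regulons]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulonSet):
            return NotImplemented
        if self.regulators != other.regulators:
            return False
        for a, b in zip(self.regulons, other.regulons):
            if a.targets != b.targets or a.modes != b.modes:
                return False
            if not np.allclose(a.weights, b.weights, rtol=0, atol=1e-12):
                return False
        return True


@dataclass
class DistanceMatrix:
    """Symmetric matrix of correlation distances between type profiles.

    Entries lie in [0, 1]: 0 for perfectly correlated profiles, 1 for
    perfectly anti-correlated ones.
    """

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.D.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.D, self.D.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-9):
            raise ValidationError("distance matrix has nonzero diagonal")
        if self.D.min() < -1e-9 or self.D.max() > 1 + 1e-9:
            raise ValidationError("distance entries outside [0, 1]")
        # enforce exact symmetry/bounds after the tolerance checks
        self.D = np.clip((self.D + self.D.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.D, 0.0)


@dataclass
class ConfusionMatrix:
    """Matched-percentage matrix of a cross-species type mapping.

    ``P[j, i]`` is the fraction of test-type-``j`` cells the classifier
    assigned to train type ``i``; every row sums to one.
    """

    train_labels: list[str]
    test_labels: list[str]
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        m, n = len(self.test_labels), len(self.train_labels)
        if self.P.shape != (m, n):
            raise ValidationError(
                f"P shape {self.P.shape} does not match {m} test x {n} train types"
            )
        if self.P.min() < -1e-12 or self.P.max() > 1 + 1e-9:
            raise ValidationError("confusion entries outside [0, 1]")
        rows = self.P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            j = int(np.argmax(np.abs(rows - 1.0)))
            raise ValidationError(
                f"row {self.test_labels[j]!r} sums to {rows[j]:.6g}, not 1"
            )

    @property
    def n_train(self) -> int:
        return len(self.train_labels)

    @property
    def n_test(self) -> int:
        return len(self.test_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.test_labels, columns=self.train_labels)


@dataclass
class ActivityMatrix:
    """Regulator x cell normalized enrichment scores (protein activities)."""

    regulators: list[str]
    cell_ids: list[str]
    nes: np.ndarray
    cell_classes: list[str] | None = None
    sd_es: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nes = np.asarray(self.nes, dtype=float)
        if self.nes.shape != (len(self.regulators), len(self.cell_ids)):
            raise ValidationError(
                f"nes shape {self.nes.shape} does not match "
                f"{len(self.regulators)} regulators x {len(self.cell_ids)} cells"
            )
        if not np.isfinite(self.nes).all():
            raise ValidationError("non-finite NES values")
        if self.cell_classes is not None and len(self.cell_classes) != len(
            self.cell_ids
        ):
            raise ValidationError("cell_classes length does not match cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.nes, index=self.regulators, columns=self.cell_ids)
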