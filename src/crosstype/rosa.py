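"""Regulon-structure-based protein-activity inference (ROSA).

A regulator's activity in a cell is read off the expression of its regulon:
the enrichment score is the mode- and weight-weighted sum of the targets'
(coarse-grained) expression Z scores,

    ES = sum_i mod_i * w_i * Z_i,

and the normalized score divides by the analytic null standard deviation,

    NES = ES / sqrt(sum_i (mod_i * w_i)^2),

so that independent standard-normal target Zs give NES ~ N(0, 1). Extreme
Z values are tamed beforehand by snapping each Z toward zero onto a fixed
grid of standard-normal q-quantiles (the coarse-grained adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as stats

from .containers import ActivityMatrix, Regulon, RegulonSet, ValidationError

logger = logging.getLogger(__name__)


def prune_regulons(
    regulon_set: RegulonSet, max_size: int = 50, min_size: int = 20
) -> RegulonSet:
    """Cap regulons at ``max_size`` targets and drop undersized ones.

    Regulons above the cap keep their ``max_size`` largest-weight targets
    (weight ties broken by target id); regulons with fewer than ``min_size``
    targets are removed entirely.
    """
    if max_size < min_size:
        raise ValidationError(f"max_size {max_size} < min_size {min_size}")
    kept = []
    n_removed = n_trimmed = 0
    for reg in regulon_set:
        if len(reg) < min_size:
            n_removed += 1
            continue
        if len(reg) > max_size:
            order = sorted(
                range(len(reg)),
                key=lambda i: (-reg.weights[i], reg.targets[i]),
            )[:max_size]
            order = sorted(order)  # preserve original target order
            reg = Regulon(
                regulator=reg.regulator,
                targets=tuple(reg.targets[i] for i in order),
                modes=tuple(reg.modes[i] for i in order),
                weights=tuple(reg.weights[i] for i in order),
            )
            n_trimmed += 1
        kept.append(reg)
    logger.info(
        "prune_regulons: %d removed (<%d targets), %d trimmed to %d",
        n_removed,
        min_size,
        n_trimmed,
        max_size,
    )
    return RegulonSet(kept)


def expression_zscores(
    matrix: np.ndarray, mode: str = "scaled_log_cpm"
) -> np.ndarray:
    """Per-gene standardization of a cells x genes matrix.

    ``scaled_log_cpm`` standardizes log2(1+CPM) values; ``residuals_input``
    accepts an externally computed residual matrix and standardizes it the
    same way. Constant genes get Z = 0 everywhere.
    """
    if mode not in ("scaled_log_cpm", "residuals_input"):
        raise ValidationError(f"unknown mode {mode!r}")
    X = np.asarray(matrix, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - mu) / sd
    Z[:, sd == 0] = 0.0
    return Z


@dataclass
class QuantileGrid:
    """The q-quantile points of the standard normal used for coarse-graining.

    ``grid[i] = Phi^-1((i+1)/q)`` for i = 0..q-2: strictly increasing,
    symmetric about zero, with ``Pr[Z < grid[i]] = (i+1)/q``. Larger q means
    a finer grid and milder shrinkage; the extreme grid points bound the
    adjusted |Z| at ``Phi^-1(1 - 1/q)`` (about 2.33 for the default q=100).
    """

    q: int = 100

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ValidationError("q must be >= 2")
        self.grid = stats.norm.ppf(np.arange(1, self.q) / self.q)

    def adjust(self, Z: np.ndarray) -> np.ndarray:
        """Snap Z scores toward zero onto the grid.

        Negative Z maps to ``min{Z_i | Z_i >= Z}``; non-negative Z maps to
        ``max{Z_i | Z_i <= Z}``. Values beyond the grid therefore clamp to
        the extreme grid point, and a non-negative Z below every
        non-negative grid point (possible for odd q, which has no zero
        point) takes the largest negative grid point. Grid points are fixed
        points, so the adjustment is idempotent.
        """
        Z = np.asarray(Z, dtype=float)
        g = self.grid
        neg = Z < 0
        # min{Z_i >= Z}: first grid index with g[k] >= Z
        up = np.searchsorted(g, Z, side="left").clip(max=len(g) - 1)
        # max{Z_i <= Z}: last grid index with g[k] <= Z
        down = (np.searchsorted(g, Z, side="right") - 1).clip(min=0)
        return np.where(neg, g[up], g[down])


def coarse_grain(Z: np.ndarray, grid: QuantileGrid | int = 100) -> np.ndarray:
    """Coarse-grained Z adjustment (see :meth:`QuantileGrid.adjust`)."""
    if isinstance(grid, int):
        grid = QuantileGrid(q=grid)
    return grid.adjust(Z)


def rosa_nes(
    Z: np.ndarray,
    gene_ids,
    regulon_set: RegulonSet,
    cell_ids=None,
    cell_classes=None,
) -> ActivityMatrix:
    """Per-cell NES for every regulon, from (adjusted) expression Z scores.

    ``Z`` is cells x genes, columns named by ``gene_ids``. Targets absent
    from the matrix are dropped and the null SD recomputed over the targets
    actually used, keeping the analytic null exact; regulons left with zero
    present targets are removed with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    col = {g: i for i, g in enumerate(gene_ids)}
    regs, rows, sds = [], [], []
    for reg in regulon_set:
        present = [
            (col[t], m, w)
            for t, m, w in zip(reg.targets, reg.modes, reg.weights)
            if t in col
        ]
        if not present:
            logger.warning(
                "regulon %r has no targets in the matrix; removed", reg.regulator
            )
            continue
        if len(present) < len(reg):
            logger.warning(
                "regulon %r: %d of %d targets absent from matrix",
                reg.regulator,
                len(reg) - len(present),
                len(reg),
            )
        idx = np.array([i for i, _, _ in present])
        mw = np.array([m * w for _, m, w in present], dtype=float)
        es = Z[:, idx] @ mw
        sd_es = float(np.sqrt((mw**2).sum()))
        regs.append(reg.regulator)
        rows.append(es / sd_es)
        sds.append(sd_es)
    if not regs:
        raise ValidationError("no regulon has targets in the matrix")
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(Z.shape[0])]
    return ActivityMatrix(
        regulators=regs,
        cell_ids=list(cell_ids),
        nes=np.vstack(rows),
        cell_classes=list(cell_classes) if cell_classes is not None else None,
        sd_es=np.array(sds),
    )


def top_sd_regulators(activity: ActivityMatrix, k: int = 700) -> list[str]:
    """Top-k regulators by NES standard deviation across cells.

    k is capped at the number of available regulators; ties break by
    regulator id.
    """
    sd = activity.nes.std(axis=1, ddof=1)
    order = sorted(
        range(len(activity.regulators)),
        key=lambda i: (-sd[i], activity.regulators[i]),
    )
    return [activity.regulators[i] for i in order[: min(k, len(order))]]


def differential_activity(
    activity: ActivityMatrix, class_labels=None
) -> pd.DataFrame:
    """One-vs-rest Student's t-tests of NES per regulator per class.

    Returns a long frame (class, regulator, t, p, mean_in, mean_rest)
    sorted within each class by descending t, for reading off
    class-specific regulators.
    """
    labels = np.asarray(
        class_labels if class_labels is not None else activity.cell_classes
    )
    if labels is None or len(labels) != len(activity.cell_ids):
        raise ValidationError("class labels missing or wrong length")
    classes = sorted(pd.unique(labels))
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    frames = []
    for c in classes:
        mask = labels == c
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValidationError(f"class {c!r} has a degenerate size")
        a = activity.nes[:, mask]
        b = activity.nes[:, ~mask]
        t, p = stats.ttest_ind(a, b, axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "class": c,
                    "regulator": activity.regulators,
                    "t": t,
                    "p": p,
                    "mean_in": a.mean(axis=1),
                    "mean_rest": b.mean(axis=1),
                }
            ).sort_values("t", ascending=False)
        )
    return pd.concat(frames, ignore_index=True)
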