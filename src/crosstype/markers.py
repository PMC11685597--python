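"""Conserved marker detection: per-sample Wilcoxon tests + Stouffer's Z.

Markers are tested one-vs-rest within each sample (or species) with the
two-sided Wilcoxon rank-sum test, so batch structure never mixes across
samples. Per-sample evidence is then combined by Stouffer's method,
``Z = sum_i Z_i / sqrt(n)``, where each ``Z_i`` is the signed normal
transform of that sample's p-value, and the combined p-values are
Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats as stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionDataset, ValidationError
from .qc_cluster import normalize_log_cpm

logger = logging.getLogger(__name__)

# R's .Machine$double.xmin — smallest positive normalized double — replaces
# p = 0 before the normal transform so Z scores stay finite.
SMALLEST_NORMALIZED = float(np.finfo(np.float64).tiny)
SMALLEST_SUBNORMAL = float(np.nextafter(0.0, 1.0))


def per_sample_markers(
    dataset: ExpressionDataset,
    group_label: str = "cell_type",
    lognorm: np.ndarray | None = None,
    min_group_cells: int = 2,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum tests per gene, per group, per sample.

    Returns a long frame with columns ``sample``, ``group``, ``gene_id``,
    ``p`` (two-sided) and ``direction`` (sign of the in-group minus
    rest mean of log-normalized expression; 0 for exact ties). Groups
    absent from a sample, or with fewer than ``min_group_cells`` cells on
    either side, are skipped with a warning.
    """
    groups = pd.unique(dataset.cell_meta[group_label])
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups for one-vs-rest testing")
    X = lognorm if lognorm is not None else normalize_log_cpm(dataset)
    X = np.asarray(X)
    gene_ids = list(dataset.gene_ids)
    samples = dataset.cell_meta["sample"].to_numpy()
    labels = dataset.cell_meta[group_label].to_numpy()
    frames = []
    for s in sorted(pd.unique(samples)):
        in_sample = samples == s
        Xs = X[in_sample]
        ls = labels[in_sample]
        for g in sorted(pd.unique(labels)):
            a = Xs[ls == g]
            b = Xs[ls != g]
            if len(a) < min_group_cells or len(b) < min_group_cells:
                logger.warning(
                    "sample %r group %r skipped (%d vs %d cells)",
                    s,
                    g,
                    len(a),
                    len(b),
                )
                continue
            res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
            diff = a.mean(axis=0) - b.mean(axis=0)
            frames.append(
                pd.DataFrame(
                    {
                        "sample": s,
                        "group": g,
                        "gene_id": gene_ids,
                        "p": np.asarray(res.pvalue, dtype=float),
                        "direction": np.sign(diff).astype(int),
                    }
                )
            )
    if not frames:
        raise ValidationError("no testable sample/group combination")
    return pd.concat(frames, ignore_index=True)


def stouffer_z(
    p_values: np.ndarray,
    directions: np.ndarray,
    zero_replacement: str = "normalized",
) -> tuple[np.ndarray, float, float]:
    """Combine one gene's per-sample evidence by Stouffer's method.

    Each two-sided p becomes a signed Z, ``Z_i = sign_i * Phi^-1(1 - p_i/2)``,
    and the combined score is ``Z = sum Z_i / sqrt(n)`` with a two-sided
    combined p from the standard normal. Zero p-values are replaced by the
    smallest positive normalized double (or the subnormal minimum with
    ``zero_replacement="subnormal"``), bounding |Z_i| at ~38.

    Returns ``(per-sample Z_i, Z_Stouffer, combined p)``.
    """
    p = np.asarray(p_values, dtype=float)
    d = np.asarray(directions, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values to combine")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values outside [0, 1]")
    if zero_replacement == "normalized":
        floor = SMALLEST_NORMALIZED
    elif zero_replacement == "subnormal":
        floor = SMALLEST_SUBNORMAL
    else:
        raise ValueError(f"unknown zero_replacement {zero_replacement!r}")
    p = np.where(p == 0.0, floor, p)
    # halving the subnormal minimum would underflow back to zero
    z_i = np.sign(d) * stats.norm.isf(np.maximum(p / 2.0, SMALLEST_SUBNORMAL))
    z = float(z_i.sum() / np.sqrt(len(z_i)))
    combined_p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    return z_i, z, combined_p


def stouffer_combine(
    per_sample: pd.DataFrame,
    group: str,
    fdr_alpha: float = 0.05,
    zero_replacement: str = "normalized",
) -> pd.DataFrame:
    """Meta-analytic marker table for one group.

    Takes the long frame from :func:`per_sample_markers`, combines each
    gene's per-sample Z scores, and BH-adjusts the combined p-values across
    genes. Output (sorted by descending Z) has one per-sample Z column
    (``z_<sample>``), ``n_samples``, ``z_stouffer``, ``p``, ``q`` and
    ``significant`` (q < alpha).
    """
    sub = per_sample[per_sample["group"] == group]
    if len(sub) == 0:
        raise ValidationError(f"group {group!r} absent from marker table")
    sample_ids = sorted(sub["sample"].unique())
    P = sub.pivot(index="gene_id", columns="sample", values="p")
    D = sub.pivot(index="gene_id", columns="sample", values="direction")
    if (P.to_numpy() < 0).any() or (P.to_numpy() > 1).any():
        raise ValidationError("p-values outside [0, 1]")
    floor = {
        "normalized": SMALLEST_NORMALIZED,
        "subnormal": SMALLEST_SUBNORMAL,
    }[zero_replacement]
    p_mat = np.where(P.to_numpy() == 0.0, floor, P.to_numpy())
    z_mat = np.sign(D.to_numpy()) * stats.norm.isf(
        np.maximum(p_mat / 2.0, SMALLEST_SUBNORMAL)
    )
    n_i = np.isfinite(z_mat).sum(axis=1)
    z = np.nansum(np.where(np.isfinite(z_mat), z_mat, 0.0), axis=1) / np.sqrt(n_i)
    p_comb = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    out = pd.DataFrame(
        {"n_samples": n_i, "z_stouffer": z, "p": p_comb}, index=P.index
    )
    for k, s in enumerate(P.columns):
        out[f"z_{s}"] = z_mat[:, k]
    reject, q, _, _ = multipletests(out["p"], alpha=fdr_alpha, method="fdr_bh")
    out["q"] = q
    out["significant"] = reject
    cols = ["n_samples"] + [f"z_{s}" for s in sample_ids if f"z_{s}" in out] + [
        "z_stouffer",
        "p",
        "q",
        "significant",
    ]
    return out[cols].sort_values("z_stouffer", ascending=False)


def conserved_markers(
    dataset: ExpressionDataset,
    group_label: str = "cell_type",
    lognorm: np.ndarray | None = None,
    fdr_alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-group ranked marker tables, Stouffer-combined across samples."""
    per_sample = per_sample_markers(dataset, group_label=group_label, lognorm=lognorm)
    return {
        g: stouffer_combine(per_sample, g, fdr_alpha=fdr_alpha)
        for g in sorted(per_sample["group"].unique())
    }
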