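"""Cross-species conservation of class-specific regulator programs.

For each cell class, a one-vs-rest differential activity signature (mean
NES in the class minus mean NES elsewhere) ranks all regulators. The top
regulators of the same class in another species — translated through
orthology — form a query set, and a weighted Kolmogorov-Smirnov running-sum
enrichment score measures how near the top of the reference ranking the
query regulators sit. Significance comes from a permutation null: cell
class labels are permuted uniformly at random, the signature and enrichment
score recomputed each time; NES = ES / mean|ES_null| and the two-sided p is
the fraction of null |ES| at least as large as the observed one (with the
usual +1 guard, so p is never below 1/(n_perm + 1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as stats

from .containers import ActivityMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClassSignature:
    """One-vs-rest differential activity signature for one class.

    ``scores`` is the per-regulator mean difference; ``ranks`` its rank
    transform (ascending, average ranks on ties — the top activator has
    rank n_regulators).
    """

    target_class: str
    scores: pd.Series
    ranks: pd.Series


def class_signature(
    activity: ActivityMatrix, target_class: str, class_labels=None
) -> ClassSignature:
    """Differential signature: mean NES in the class minus mean elsewhere."""
    labels = np.asarray(
        class_labels if class_labels is not None else activity.cell_classes
    )
    if labels is None or len(labels) != len(activity.cell_ids):
        raise ValidationError("class labels missing or wrong length")
    mask = labels == target_class
    if not mask.any():
        raise ValidationError(f"class {target_class!r} absent")
    if mask.all():
        raise ValidationError(f"class {target_class!r} is the only class")
    scores = pd.Series(
        activity.nes[:, mask].mean(axis=1) - activity.nes[:, ~mask].mean(axis=1),
        index=activity.regulators,
    )
    ranks = pd.Series(
        stats.rankdata(scores.to_numpy(), method="average"),
        index=scores.index,
    )
    return ClassSignature(target_class=target_class, scores=scores, ranks=ranks)


def top_query_set(
    signature: ClassSignature,
    k: int = 50,
    ortholog_map: dict[str, str] | None = None,
) -> list[str]:
    """Top-k most activated regulators, translated into another namespace.

    Regulators are ordered by descending differential score (ties by
    regulator id); ``ortholog_map`` carries each into the reference
    species' regulator namespace (``None`` = identity). Regulators without
    an ortholog are dropped with a warning; if fewer than k remain, all are
    used.
    """
    order = sorted(
        signature.scores.index, key=lambda r: (-signature.scores[r], r)
    )
    out: list[str] = []
    n_dropped = 0
    for r in order:
        if ortholog_map is None:
            mapped = r
        else:
            mapped = ortholog_map.get(r)
            if mapped is None:
                n_dropped += 1
                continue
        if mapped not in out:
            out.append(mapped)
        if len(out) == k:
            break
    if n_dropped:
        logger.warning("top_query_set: %d regulators had no ortholog", n_dropped)
    if len(out) < k:
        logger.warning("top_query_set: only %d mappable regulators (< k=%d)", len(out), k)
    return out


@dataclass
class ConservationScore:
    """Permutation-GSEA conservation of a query program in a reference class."""

    target_class: str
    es: float
    nes: float
    p: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.nes):
            raise ValidationError("non-finite NES")
        if not (1.0 / (self.n_permutations + 1) <= self.p <= 1.0):
            raise ValidationError(f"p={self.p} outside permutation bounds")


def enrichment_score(
    scores: np.ndarray, is_query: np.ndarray, weight_exponent: float = 1.0
) -> float:
    """Weighted KS running-sum enrichment score of a query set.

    Regulators are walked in descending score order; query hits push the
    running sum up by |score|^exponent (normalized over hits), misses pull
    it down by 1/(n - n_hits). The ES is the running-sum value of maximal
    magnitude (signed).
    """
    scores = np.asarray(scores, dtype=float)
    is_query = np.asarray(is_query, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    return float(_es_from_sorted(scores[order], is_query[order], weight_exponent))


def _es_from_sorted(
    s_sorted: np.ndarray, hit_sorted: np.ndarray, weight_exponent: float
) -> float:
    n = len(s_sorted)
    n_hit = int(hit_sorted.sum())
    if n_hit == 0 or n_hit == n:
        raise ValidationError("query set is empty or covers every regulator")
    w = np.abs(s_sorted) ** weight_exponent * hit_sorted
    denom = w.sum()
    if denom == 0:
        return 0.0
    running = np.cumsum(w / denom - (~hit_sorted) / (n - n_hit))
    return running[int(np.argmax(np.abs(running)))]


def gsea_conservation(
    query_set,
    activity: ActivityMatrix,
    target_class: str,
    class_labels=None,
    n_perm: int = 100_000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    perm_unit: str = "cells",
    block: int = 2000,
) -> ConservationScore:
    """Permutation-GSEA conservation score of a query regulator set.

    The observed ES tests the query set against the target class's
    one-vs-rest signature. The null permutes cell class labels uniformly at
    random (``perm_unit="cells"``), recomputing the signature and ES each
    time; ``perm_unit="regulators"`` instead shuffles the signature across
    regulators (gene-set-style permutation). NES = ES / mean|ES_null|;
    two-sided p = (1 + #{|ES_null| >= |ES|}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValidationError("n_perm < 100 gives meaningless p-values")
    if perm_unit not in ("cells", "regulators"):
        raise ValidationError(f"unknown perm_unit {perm_unit!r}")
    labels = np.asarray(
        class_labels if class_labels is not None else activity.cell_classes
    )
    query = [q for q in query_set if q in activity.regulators]
    if not query:
        raise ValidationError("query set empty after mapping to the reference")
    if len(query) < len(list(query_set)):
        logger.warning(
            "gsea_conservation: %d query regulators absent from the reference",
            len(list(query_set)) - len(query),
        )
    is_query = np.isin(np.array(activity.regulators), query)

    sig = class_signature(activity, target_class, labels)
    es = enrichment_score(sig.scores.to_numpy(), is_query, weight_exponent)

    rng = np.random.default_rng(seed)
    A = activity.nes
    n_cells = A.shape[1]
    n_in = int((labels == target_class).sum())
    tot = A.sum(axis=1)
    null_es = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        if perm_unit == "cells":
            # permuting all labels uniformly = drawing the in-class subset
            # uniformly; realized as random permutation column indicators
            ind = np.zeros((n_cells, b))
            for col in range(b):
                ind[rng.choice(n_cells, size=n_in, replace=False), col] = 1.0
            sums = A @ ind
            s_null = sums / n_in - (tot[:, None] - sums) / (n_cells - n_in)
        else:
            s_null = np.empty((A.shape[0], b))
            base = sig.scores.to_numpy()
            for col in range(b):
                s_null[:, col] = base[rng.permutation(len(base))]
        for col in range(b):
            null_es[done + col] = enrichment_score(
                s_null[:, col], is_query, weight_exponent
            )
        done += b
    scale = float(np.mean(np.abs(null_es)))
    nes = es / scale if scale > 0 else 0.0
    p = (1.0 + int((np.abs(null_es) >= abs(es)).sum())) / (1.0 + n_perm)
    return ConservationScore(
        target_class=target_class,
        es=float(es),
        nes=float(nes),
        p=float(p),
        n_permutations=n_perm,
    )
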