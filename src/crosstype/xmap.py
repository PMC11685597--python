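"""Cross-species cell-type mapping with a gradient-boosted classifier.

A multiclass gradient-boosted decision-tree model (XGBoost) is trained on
one species' cell types over the ortholog-aligned feature space, evaluated
on held-out cells of the same species, and then applied to the other
species. The resulting confusion matrix of matched percentages — the
fraction of each test type's cells assigned to each training type — is
summarized per test type (best match, conserved if matched percentage
>= 50%) and globally by the normalized entropy, a [0, 1] score of mapping
confidence (0 = every test type maps confidently to one training type,
1 = assignments are uniformly random).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .containers import ConfusionMatrix, ExpressionDataset, ValidationError
from .qc_cluster import normalize_log_cpm

logger = logging.getLogger(__name__)

CONSERVED_THRESHOLD = 0.5  # matched percentage below 50% = no reliable match


def split_train_eval(
    dataset: ExpressionDataset,
    train_fraction: float = 0.67,
    cap: int = 300,
    seed: int = 0,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Per-type train/evaluation split with a per-type training cap.

    Each type contributes ``min(floor(train_fraction * n), cap)`` training
    cells sampled without replacement; the remainder evaluate the model.
    Types with fewer than 3 cells go entirely to training (with a warning).
    """
    rng = np.random.default_rng(seed)
    labels = dataset.cell_meta["cell_type"].to_numpy()
    train_mask = np.zeros(dataset.n_cells, dtype=bool)
    for t in sorted(pd.unique(labels)):
        idx = np.flatnonzero(labels == t)
        if len(idx) < 3:
            logger.warning("type %r has %d cells; all sent to training", t, len(idx))
            train_mask[idx] = True
            continue
        n_train = min(int(np.floor(train_fraction * len(idx))), cap)
        chosen = rng.choice(idx, size=n_train, replace=False)
        train_mask[chosen] = True
    return dataset.subset_cells(train_mask), dataset.subset_cells(~train_mask)


@dataclass
class MappingResult:
    """Outcome of mapping one test species onto one training species."""

    confusion: ConfusionMatrix
    best_match: pd.DataFrame  # index test_type; best_train_type, matched_pct, conserved
    holdout_accuracy: float
    h_norm: float
    threshold: float = CONSERVED_THRESHOLD

    def __post_init__(self) -> None:
        want = (self.best_match["matched_pct"] >= self.threshold).to_numpy()
        if not (self.best_match["conserved"].to_numpy() == want).all():
            raise ValidationError("conserved flags inconsistent with threshold")
        if not (0.0 <= self.h_norm <= 1.0):
            raise ValidationError(f"h_norm {self.h_norm} outside [0, 1]")


def map_types(
    train_dataset: ExpressionDataset,
    test_dataset: ExpressionDataset,
    features: pd.DataFrame,
    train_fraction: float = 0.67,
    cap: int = 300,
    threshold: float = CONSERVED_THRESHOLD,
    seed: int = 0,
    n_estimators: int = 80,
    max_depth: int = 4,
    learning_rate: float = 0.3,
) -> MappingResult:
    """Train on one species' types, predict the other species' cells.

    ``features`` is the aligned feature table from
    :func:`crosstype.miog.build_feature_table`: one column per species tag
    holding that species' gene id for each orthogroup-aligned feature.
    Cells are assigned by hard argmax of the class scores, and
    ``P[j, i]`` is the fraction of test-type-j cells assigned train type i.
    """
    train_species = str(train_dataset.cell_meta["species"].iloc[0])
    test_species = str(test_dataset.cell_meta["species"].iloc[0])
    for s in (train_species, test_species):
        if s not in features.columns:
            raise ValidationError(f"feature table has no column for species {s!r}")

    X_train_full = _feature_matrix(train_dataset, features[train_species])
    X_test = _feature_matrix(test_dataset, features[test_species])

    tr, ev = split_train_eval(
        train_dataset, train_fraction=train_fraction, cap=cap, seed=seed
    )
    tr_pos = train_dataset.cell_ids.get_indexer(tr.cell_ids)
    ev_pos = train_dataset.cell_ids.get_indexer(ev.cell_ids)

    classes = sorted(pd.unique(train_dataset.cell_meta["cell_type"]))
    class_idx = {c: i for i, c in enumerate(classes)}
    y_tr = np.array([class_idx[c] for c in tr.cell_meta["cell_type"]])
    if len(np.unique(y_tr)) < len(classes):
        missing = [c for c in classes if class_idx[c] not in set(y_tr)]
        raise ValidationError(f"training classes with zero cells: {missing}")

    if len(classes) == 1:
        # degenerate: every cell is forced into the only training class
        test_types = sorted(pd.unique(test_dataset.cell_meta["cell_type"]))
        P = np.ones((len(test_types), 1))
        confusion = ConfusionMatrix(
            train_labels=classes, test_labels=test_types, P=P
        )
        best_match = pd.DataFrame(
            {
                "best_train_type": classes * len(test_types),
                "matched_pct": np.ones(len(test_types)),
                "conserved": np.ones(len(test_types), dtype=bool),
            },
            index=pd.Index(test_types, name="test_type"),
        )
        return MappingResult(
            confusion=confusion,
            best_match=best_match,
            holdout_accuracy=1.0,
            h_norm=0.0,
            threshold=threshold,
        )

    model = xgb.XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        objective="multi:softprob",
        tree_method="hist",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    model.fit(X_train_full[tr_pos], y_tr)

    if len(ev_pos):
        y_ev = np.array([class_idx[c] for c in ev.cell_meta["cell_type"]])
        holdout_accuracy = float(
            (model.predict(X_train_full[ev_pos]) == y_ev).mean()
        )
    else:
        holdout_accuracy = float("nan")

    pred = model.predict(X_test)
    test_types = sorted(pd.unique(test_dataset.cell_meta["cell_type"]))
    P = np.zeros((len(test_types), len(classes)))
    test_labels = test_dataset.cell_meta["cell_type"].to_numpy()
    for j, t in enumerate(test_types):
        sel = pred[test_labels == t]
        for i in sel:
            P[j, int(i)] += 1
        P[j] /= max(len(sel), 1)
    confusion = ConfusionMatrix(train_labels=classes, test_labels=test_types, P=P)

    # best match per test type; score ties go to the lexicographically
    # first training label (np.argmax returns the first maximum and
    # `classes` is sorted)
    best_i = P.argmax(axis=1)
    best_pct = P[np.arange(len(test_types)), best_i]
    best_match = pd.DataFrame(
        {
            "best_train_type": [classes[i] for i in best_i],
            "matched_pct": best_pct,
            "conserved": best_pct >= threshold,
        },
        index=pd.Index(test_types, name="test_type"),
    )
    return MappingResult(
        confusion=confusion,
        best_match=best_match,
        holdout_accuracy=holdout_accuracy,
        h_norm=normalized_entropy(confusion),
        threshold=threshold,
    )


def _feature_matrix(dataset: ExpressionDataset, gene_ids: pd.Series) -> np.ndarray:
    # normalize against full cell depth first, then select feature columns
    X = normalize_log_cpm(dataset)
    idx = dataset.gene_ids.get_indexer(list(gene_ids))
    if (idx < 0).any():
        missing = [g for g, i in zip(gene_ids, idx) if i < 0]
        raise ValidationError(f"feature genes absent from dataset: {missing[:5]}")
    return np.asarray(X[:, idx])


def normalized_entropy(C: ConfusionMatrix) -> float:
    """Normalized entropy of a confusion matrix, base e.

    ``H_norm = -sum_j sum_i p_ij ln p_ij / (m ln n)`` with the convention
    ``0 ln 0 = 0``; n and m are the numbers of training and test types.
    Ranges from 0 (every row one-hot) to 1 (every row uniform).
    """
    n = C.n_train
    m = C.n_test
    if n < 2:
        raise ValidationError("normalized entropy undefined for n < 2 training types")
    P = C.P
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return float(-terms.sum() / (m * np.log(n)) + 0.0)  # +0.0 avoids -0.0


def call_conserved(
    results: dict[str, MappingResult],
    threshold: float = CONSERVED_THRESHOLD,
) -> pd.DataFrame:
    """Partition test types into conserved / non-conserved across references.

    A test type is conserved if its best matched percentage reaches the
    threshold against ANY reference species. The output records, per test
    type, the set of supporting references and whether the match is unique
    to one reference or shared by several.
    """
    rows: dict[str, dict] = {}
    for ref, res in results.items():
        for t, r in res.best_match.iterrows():
            rec = rows.setdefault(
                t, {"conserved": False, "supporting_refs": [], "best_pct": 0.0}
            )
            if r["matched_pct"] >= threshold:
                rec["conserved"] = True
                rec["supporting_refs"].append(ref)
            rec["best_pct"] = max(rec["best_pct"], float(r["matched_pct"]))
    out = pd.DataFrame.from_dict(rows, orient="index")
    if len(out) == 0:
        return pd.DataFrame(
            columns=["conserved", "supporting_refs", "best_pct", "n_refs", "sharing"]
        )
    out["n_refs"] = out["supporting_refs"].map(len)
    out["sharing"] = np.select(
        [out["n_refs"] == 0, out["n_refs"] == 1],
        ["none", "unique"],
        default="shared",
    )
    out.index.name = "test_type"
    return out.sort_index()
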