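"""Spotwise cross-validation, imputation metrics, and region/segmentation
concordance metrics.

Cross-validation is spotwise: whole spots (all genes at a grid position)
are held out, their mask entries zeroed during training, and imputed
values scored at the entries that were observed in the truth.  R² is
computed per held-out spot across genes and averaged over spots, so it
measures how well the imputed expression profile of a spot correlates
with the original one.  Region concordance uses AUC (ranking quality of a
component map against the binarized region) and the Euclidean distance
between the two maps after normalizing each to unit length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from .containers import ExpressionTensor, MaskTensor

__all__ = [
    "SpotFolds",
    "make_spot_folds",
    "holdout_mask",
    "imputation_metrics",
    "auc",
    "euclidean_distance",
    "cluster_spots",
    "ari",
]


@dataclass
class SpotFolds:
    """Disjoint folds of eligible (y, x) spot indices."""

    folds: list[np.ndarray]  # each (n_i, 2) int array of (y, x)
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def all_spots(self) -> np.ndarray:
        return np.concatenate(self.folds, axis=0)


def _eligible_spots(t) -> np.ndarray:
    values = t.values if hasattr(t, "values") else np.asarray(t)
    nonzero = values.sum(axis=2) > 0
    if hasattr(t, "in_tissue") and t.in_tissue is not None:
        nonzero &= t.in_tissue
    return np.argwhere(nonzero)


def make_spot_folds(t, k: int, seed: int = 0) -> SpotFolds:
    """Random partition of eligible spots into ``k`` near-equal folds.

    Eligible spots are in-tissue spots with nonzero total expression;
    all-zero spots are never held out.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    spots = _eligible_spots(t)
    if len(spots) < k:
        raise ValueError(f"only {len(spots)} eligible spots for {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(spots))
    folds = [spots[idx] for idx in np.array_split(perm, k)]
    return SpotFolds(folds=folds, seed=seed)


def holdout_mask(m, test_spots: np.ndarray) -> MaskTensor:
    """Copy of the mask with every gene entry at the test spots zeroed."""
    values = (m.values if hasattr(m, "values") else np.asarray(m)).copy()
    test_spots = np.asarray(test_spots)
    if len(test_spots):
        values[test_spots[:, 0], test_spots[:, 1], :] = 0.0
    return MaskTensor(values)


def imputation_metrics(
    truth: np.ndarray,
    predicted: np.ndarray,
    eval_entries: np.ndarray,
) -> tuple[float, float, float]:
    """(MAE, MAPE, R²) over the evaluation entries.

    ``eval_entries`` is a boolean tensor marking scored entries (typically
    the observed entries at held-out spots).  MAE averages |truth − pred|
    over all scored entries; MAPE averages |truth − pred| / truth over the
    scored entries with positive truth; R² measures within-spot profile
    agreement: residuals and totals are centered per spot across its
    scored genes and pooled, R² = 1 − Σ_s SSres_s / Σ_s SStot_s, over
    spots with nonzero truth variance.  Pooling weights each spot by its
    truth variance, which keeps the score finite when sparse spots happen
    to have nearly constant truth values.
    """
    truth = np.asarray(truth, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ev = np.asarray(eval_entries, dtype=bool)
    if not ev.any():
        raise ValueError("no evaluation entries")
    diff = np.abs(truth - predicted)
    mae = float(diff[ev].mean())

    pos = ev & (truth > 0)
    if not pos.any():
        raise ValueError("MAPE undefined: no nonzero-truth evaluation entries")
    mape = float((diff[pos] / truth[pos]).mean())

    ssres_total = sstot_total = 0.0
    for y, x in np.unique(np.argwhere(ev)[:, :2], axis=0):
        sel = ev[y, x, :]
        tt, pp = truth[y, x, sel], predicted[y, x, sel]
        sstot = float(np.sum((tt - tt.mean()) ** 2))
        if sstot == 0:
            continue
        ssres_total += float(np.sum((tt - pp) ** 2))
        sstot_total += sstot
    r2 = 1.0 - ssres_total / sstot_total if sstot_total > 0 else float("nan")
    return (mae, mape, r2)


def auc(component_map: np.ndarray, region_binary: np.ndarray) -> float:
    """ROC AUC of a component map against a binary region labeling.

    Equivalent to the Mann–Whitney rank statistic with ties counted ½;
    requires at least one positive and one negative spot.
    """
    scores = np.asarray(component_map, dtype=float).ravel()
    labels = np.asarray(region_binary).ravel().astype(int)
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: labels are all one class")
    return float(roc_auc_score(labels, scores))


def euclidean_distance(component_map: np.ndarray, region_binary: np.ndarray) -> float:
    """‖a/‖a‖ − b/‖b‖‖₂ between the component map and the binary region
    map; 0 for identical shapes, √2 for disjoint-support nonnegative maps."""
    a = np.asarray(component_map, dtype=float).ravel()
    b = np.asarray(region_binary, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("both maps need positive norm")
    return float(np.linalg.norm(a / na - b / nb))


def cluster_spots(
    comps: np.ndarray,
    k: int,
    seed: int = 0,
    in_tissue: np.ndarray | None = None,
    n_init: int = 10,
) -> np.ndarray:
    """k-means over the per-spot component-coefficient vectors.

    Each in-tissue spot contributes its rg-vector ``comps[y, x, :]``;
    returns one integer label per in-tissue spot in row-major spot order.
    """
    comps = np.asarray(comps)
    if in_tissue is None:
        in_tissue = np.ones(comps.shape[:2], dtype=bool)
    feats = comps[in_tissue]
    if len(feats) < k:
        raise ValueError(f"only {len(feats)} spots for k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(feats)


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand Index between two spot partitions (1 = identical,
    ≈0 for independent clusterings)."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have the same length")
    return float(adjusted_rand_score(labels_a, labels_b))
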