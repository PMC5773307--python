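"""Ordinal habitat-suitability classification from EVI phenology.

A bagged tree ensemble (scikit-learn random forest) maps the 23-value
phenology of a location to the expert's ordinal category
(poor < acceptable < good < excellent). Ordinality enters through two
bespoke steps: an ordered-weight correction of the out-of-bag confusion
matrix, and a vote-weighted continuous suitability index in [0, 3].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .grid import GridLayer

CATEGORIES = ("poor", "acceptable", "good", "excellent")
CATEGORY_CODES = {c: i for i, c in enumerate(CATEGORIES)}
INDEX_WEIGHTS = (0.0, 1.0, 2.0, 3.0)


@dataclass
class ForestParams:
    n_trees: int = 50_000
    predictors_per_split: int = 5
    bootstrap_fraction: float = 0.63


def encode_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US" or arr.dtype == object:
        return np.array([CATEGORY_CODES[str(l)] for l in arr])
    codes = arr.astype(int)
    if ((codes < 0) | (codes >= len(CATEGORIES))).any():
        raise ValueError("label codes must be in 0..3")
    return codes


@dataclass
class OrdinalForestModel:
    params: ForestParams
    estimator: RandomForestClassifier
    classes_present: np.ndarray
    oob_votes: np.ndarray          # (n_train, 4), rows sum to 1
    oob_confusion: np.ndarray      # 4x4 true x predicted counts
    seed: int = 0

    def vote_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-record vote shares over the full 4-category order."""
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        out = np.zeros((len(proba), len(CATEGORIES)))
        out[:, self.classes_present] = proba
        return out


def fit_forest(
    phenologies: np.ndarray,
    labels,
    params: ForestParams | None = None,
    seed: int = 0,
) -> OrdinalForestModel:
    """Train the ensemble and retain out-of-bag votes per training record.

    Bootstrap samples draw ``bootstrap_fraction`` of the records with
    replacement; each split considers ``predictors_per_split`` predictors.
    Deterministic for a fixed seed.
    """
    params = params or ForestParams()
    X = np.asarray(phenologies, dtype=float)
    y = encode_labels(labels)
    if X.ndim != 2:
        raise ValueError("phenology matrix must be 2-D")
    if len(X) != len(y):
        raise ValueError("phenologies and labels must align")
    if len(X) < 20:
        raise ValueError("need at least 20 training records")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must cover at least 2 classes")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError("all predictor columns are constant")

    est = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=min(params.predictors_per_split, X.shape[1]),
        bootstrap=True,
        max_samples=params.bootstrap_fraction,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(X, y)

    classes_present = est.classes_.astype(int)
    oob = est.oob_decision_function_
    votes = np.zeros((len(X), len(CATEGORIES)))
    votes[:, classes_present] = oob
    never_oob = np.isnan(votes).any(axis=1) | (votes.sum(axis=1) == 0)

    confusion = np.zeros((len(CATEGORIES), len(CATEGORIES)))
    pred = np.argmax(votes, axis=1)
    for t, p, skip in zip(y, pred, never_oob):
        if not skip:
            confusion[t, p] += 1
    return OrdinalForestModel(params, est, classes_present, votes,
                              confusion, seed)


# ---------------------------------------------------------------------------
# ordered-weight OOB correction

@dataclass
class WeightedConfusion:
    counts: np.ndarray
    weights: np.ndarray
    raw_error: float
    weighted_error: float


def linear_weights(k: int = 4) -> np.ndarray:
    """Single-step ordered penalties ``w_ij = |i - j| / (k - 1)``."""
    idx = np.arange(k)
    return np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def weighted_oob(counts: np.ndarray,
                 penalty: np.ndarray | str = "linear") -> WeightedConfusion:
    """Recompute the OOB error with ordered penalties so that confusion
    between contiguous categories counts less than distant confusion."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (4, 4):
        raise ValueError("confusion matrix must be 4x4")
    if (counts < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix has zero total")
    if isinstance(penalty, str):
        if penalty != "linear":
            raise ValueError(f"unknown penalty {penalty!r}")
        weights = linear_weights(4)
    else:
        weights = np.asarray(penalty, dtype=float)
        if weights.shape != (4, 4):
            raise ValueError("penalty matrix must be 4x4")
        if np.diag(weights).any():
            raise ValueError("penalty diagonal must be zero")
        if not np.allclose(weights, weights.T):
            raise ValueError("penalty matrix must be symmetric")
    raw = (total - np.trace(counts)) / total
    weighted = float((weights * counts).sum() / total)
    return WeightedConfusion(counts, weights, float(raw), weighted)


# ---------------------------------------------------------------------------
# suitability index

@dataclass
class SuitabilityIndexSurface:
    layer: GridLayer
    weights: tuple[float, ...] = INDEX_WEIGHTS


def votes_to_index(votes: np.ndarray,
                   weights: tuple[float, ...] = INDEX_WEIGHTS) -> np.ndarray:
    """Weighted-average suitability per vote vector; votes must be a
    probability simplex over the 4 ordered categories."""
    votes = np.asarray(votes, dtype=float)
    if votes.shape[-1] != len(weights):
        raise ValueError("vote vectors must have one share per category")
    if (votes < 0).any():
        raise ValueError("votes must be nonnegative")
    sums = votes.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("vote vectors must sum to 1")
    return votes @ np.asarray(weights)


def predict_surface(
    model: OrdinalForestModel,
    evi_layers: list[GridLayer],
) -> tuple[GridLayer, SuitabilityIndexSurface]:
    """Predict the modal category and vote-weighted index per cell from a
    23-layer EVI phenology stack; nodata propagates."""
    if len(evi_layers) != 23:
        raise ValueError(f"expected 23 EVI layers, got {len(evi_layers)}")
    base = evi_layers[0]
    for lyr in evi_layers[1:]:
        base.require_same_geometry(lyr)
    mask = np.ones(base.shape, dtype=bool)
    for lyr in evi_layers:
        mask &= lyr.mask
    X = np.column_stack([lyr.values[mask] for lyr in evi_layers])
    cat = np.full(base.shape, base.nodata)
    idx = np.full(base.shape, base.nodata)
    if mask.any():
        votes = model.vote_proba(X)
        cat[mask] = np.argmax(votes, axis=1)
        idx[mask] = votes_to_index(votes)
    cat_layer = GridLayer(cat, base.cell_size, base.origin, base.nodata)
    idx_layer = GridLayer(idx, base.cell_size, base.origin, base.nodata)
    return cat_layer, SuitabilityIndexSurface(idx_layer)
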