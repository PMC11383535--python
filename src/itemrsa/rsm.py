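"""Model representational similarity matrices (RSMs) from feature norms.

A feature-norm matrix records, for every concept, the normalized frequency
with which raters ascribed each feature to it.  Features carry a category
label (visual or semantic/taxonomic); correlating two concepts' vectors over
the features of one category yields that category's model RSM.  Because the
visual and semantic RSMs share variance, this module also quantifies their
overlap (Spearman rho, globally and item-wise) and removes it by mutual
residualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

VALID_CATEGORIES = ("visual", "semantic")


@dataclass
class FeatureNorms:
    """Nonnegative concept-by-feature normalized frequency matrix."""

    concept_ids: list[str]
    feature_ids: list[str]
    categories: np.ndarray  # per-feature, "visual" | "semantic"
    values: np.ndarray      # concepts x features, >= 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.categories = np.asarray(self.categories)
        if self.values.shape != (len(self.concept_ids), len(self.feature_ids)):
            raise ValueError("norms matrix shape does not match id lists")
        if np.any(self.values < 0):
            raise ValueError("feature norms must be nonnegative")
        bad = set(self.categories) - set(VALID_CATEGORIES)
        if bad:
            raise ValueError(f"unknown feature categories: {sorted(bad)}")
        shared = (self.values > 0).sum(axis=0)
        if np.any(shared < 2):
            raise ValueError(
                "every feature must be reported for at least 2 concepts"
            )

    def category_block(self, category: str) -> np.ndarray:
        if category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        mask = self.categories == category
        if mask.sum() < 2:
            raise ValueError(f"fewer than 2 features in category {category!r}")
        return self.values[:, mask]


@dataclass
class ModelRSM:
    """Item-by-item similarity matrix (Pearson r for non-residual kinds)."""

    item_ids: list[str]
    values: np.ndarray
    category: str  # visual | semantic | residual-visual | residual-semantic

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if self.values.shape != (n, n):
            raise ValueError("RSM must be square over item_ids")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


@dataclass
class RSMComparison:
    global_rho: float
    itemwise_rho: np.ndarray = field(repr=False)


def tril_vec(m: np.ndarray) -> np.ndarray:
    """Strict lower triangle, row-major."""
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def fold_sym(vec: np.ndarray, n: int, diag: float = np.nan) -> np.ndarray:
    """Refold a strict-lower-triangle vector into a symmetric matrix."""
    out = np.full((n, n), diag, dtype=float)
    i, j = np.tril_indices(n, k=-1)
    out[i, j] = vec
    out[j, i] = vec
    return out


def build_model_rsm(norms: FeatureNorms, category: str) -> ModelRSM:
    """Pearson-correlate concepts over the features of one category."""
    block = norms.category_block(category)
    if block.shape[0] < 3:
        raise ValueError("need at least 3 concepts to build an RSM")
    sd = block.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [norms.concept_ids[k] for k in flat[:5]]
        raise ValueError(
            f"concepts with zero variance over {category} features: {names}"
        )
    values = np.corrcoef(block)
    np.fill_diagonal(values, 1.0)
    return ModelRSM(list(norms.concept_ids), values, category)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan  # undefined for a constant vector
    return float(sps.spearmanr(x, y).statistic)


def compare_rsms(a: ModelRSM, b: ModelRSM) -> RSMComparison:
    """Global and item-wise Spearman rho between two RSMs.

    The global value uses the vectorized strict lower triangle; the item-wise
    values correlate matching rows with the self-similarity cell removed.
    Constant rows yield NaN rather than a silent zero.
    """
    if a.item_ids != b.item_ids:
        raise ValueError("RSMs must share the same item ordering")
    n = a.n_items
    global_rho = _spearman(tril_vec(a.values), tril_vec(b.values))
    itemwise = np.empty(n)
    keep = ~np.eye(n, dtype=bool)
    for i in range(n):
        itemwise[i] = _spearman(a.values[i, keep[i]], b.values[i, keep[i]])
    return RSMComparison(global_rho, itemwise)


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def residualize_rsms(
    a: ModelRSM, b: ModelRSM, per_row: bool = False
) -> tuple[ModelRSM, ModelRSM]:
    """Mutually residualize two RSMs (each regressed on the other).

    Whole-matrix mode (default) regresses the vectorized strict lower
    triangles on each other with an intercept and refolds the residuals;
    per-row mode repeats the regression within each item's row (self cell
    excluded) and averages the two copies of each pair on refolding.
    Residual matrices have an undefined (NaN) diagonal.
    """
    if a.item_ids != b.item_ids:
        raise ValueError("RSMs must share the same item ordering")
    n = a.n_items
    if per_row:
        ra = np.full((n, n), np.nan)
        rb = np.full((n, n), np.nan)
        keep = ~np.eye(n, dtype=bool)
        for i in range(n):
            av, bv = a.values[i, keep[i]], b.values[i, keep[i]]
            if np.ptp(bv) == 0 or np.ptp(av) == 0:
                raise ValueError(f"constant row for item {a.item_ids[i]!r}")
            ra[i, keep[i]] = _ols_residuals(av, bv)
            rb[i, keep[i]] = _ols_residuals(bv, av)
        va = (ra + ra.T) / 2.0
        vb = (rb + rb.T) / 2.0
        np.fill_diagonal(va, np.nan)
        np.fill_diagonal(vb, np.nan)
    else:
        av, bv = tril_vec(a.values), tril_vec(b.values)
        if np.ptp(bv) == 0 or np.ptp(av) == 0:
            raise ValueError("zero-variance predictor RSM")
        va = fold_sym(_ols_residuals(av, bv), n)
        vb = fold_sym(_ols_residuals(bv, av), n)
    return (
        ModelRSM(list(a.item_ids), va, f"residual-{a.category}"),
        ModelRSM(list(b.item_ids), vb, f"residual-{b.category}"),
    )
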