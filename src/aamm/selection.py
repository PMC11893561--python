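"""Reconstruction-error-driven top-k instance selection.

Given per-instance anomaly scores (squared reconstruction errors), a bag
keeps only a fraction ``k`` of its instances before multimodal fusion:

* **Maximum selection** keeps the ``ceil(k*m)`` instances with the largest
  errors — those the normal-tissue autoencoder reconstructs worst, i.e.
  the likeliest tumor patches.
* **MinMax selection** splits the same budget between the largest- and
  smallest-error instances, anchoring the representation with confidently
  normal patches as well.

Ordering is by descending error with a stable tie rule (lower original
index first), so selection is deterministic.  With ``n_sel = ceil(k*m)``,
MinMax uses ``h_max = ceil(n_sel/2)`` from the top and
``h_min = n_sel - h_max`` from the bottom; the two halves are merged as a
set, so the result can be smaller than ``n_sel`` only when they overlap
(possible only when ``n_sel >= m``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bags import EmbeddingBag

STRATEGIES = ("max", "minmax", "none")


@dataclass
class SelectionConfig:
    """Fraction ``k`` of instances to keep and the strategy used."""

    k: float = 0.3
    strategy: str = "max"

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.strategy != "none" and not (0.0 < self.k <= 1.0):
            raise ValueError("k must be in (0, 1]")


@dataclass
class SelectionResult:
    """Selected index set, the scores, and the descending-error permutation."""

    indices: np.ndarray          # ascending original positions
    errors: np.ndarray           # all m scores
    sort_permutation: np.ndarray  # positions ordered by descending error

    @property
    def n_selected(self) -> int:
        return len(self.indices)


def reconstruction_errors(F_p: np.ndarray, F_r: np.ndarray) -> np.ndarray:
    """Per-instance squared Euclidean error ``r_i = ||f_p,i - f_r,i||^2``."""
    F_p = np.asarray(F_p, dtype=float)
    F_r = np.asarray(F_r, dtype=float)
    if F_p.shape != F_r.shape:
        raise ValueError(f"shape mismatch: {F_p.shape} vs {F_r.shape}")
    return np.sum((F_p - F_r) ** 2, axis=1)


def _descending_permutation(r: np.ndarray) -> np.ndarray:
    # stable: among equal errors the lower original index comes first
    return np.argsort(-r, kind="stable")


def _validate(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("errors must be a non-empty vector")
    return r


def n_selected(m: int, k: float) -> int:
    """Selection budget ``ceil(k*m)`` for a bag of ``m`` instances."""
    if not (0.0 < k <= 1.0):
        raise ValueError("k must be in (0, 1]")
    return math.ceil(k * m)


def select_max(r, k: float) -> SelectionResult:
    """Keep the ``ceil(k*m)`` instances with the largest reconstruction errors."""
    r = _validate(r)
    perm = _descending_permutation(r)
    n_sel = n_selected(len(r), k)
    chosen = np.sort(perm[:n_sel])
    return SelectionResult(indices=chosen, errors=r, sort_permutation=perm)


def select_minmax(r, k: float) -> SelectionResult:
    """Split the budget between the largest- and smallest-error instances."""
    r = _validate(r)
    perm = _descending_permutation(r)
    m = len(r)
    n_sel = n_selected(m, k)
    h_max = math.ceil(n_sel / 2)
    h_min = n_sel - h_max
    top = perm[:h_max]
    bottom = perm[m - h_min:] if h_min > 0 else perm[:0]
    chosen = np.unique(np.concatenate([top, bottom]))
    return SelectionResult(indices=chosen, errors=r, sort_permutation=perm)


def select(r, config: SelectionConfig) -> SelectionResult:
    """Dispatch on strategy; ``none`` keeps every instance (the no-top-k variant)."""
    r = _validate(r)
    if config.strategy == "none":
        perm = _descending_permutation(r)
        return SelectionResult(indices=np.arange(len(r)), errors=r,
                               sort_permutation=perm)
    if config.strategy == "max":
        return select_max(r, config.k)
    return select_minmax(r, config.k)


def apply_selection(bag: EmbeddingBag, result: SelectionResult) -> EmbeddingBag:
    """Row-subset every present modality by the selected indices.

    Order is preserved (ascending original index); the index set is recorded
    in the bag's provenance.
    """
    idx = np.asarray(result.indices)
    m = bag.n_instances
    if idx.size == 0:
        raise ValueError("empty selection")
    if idx.min() < 0 or idx.max() >= m:
        raise IndexError(f"selection index out of range for bag of size {m}")
    changes = {"selected_indices": idx}
    for key in ("F_p", "F_c", "F_t", "F_r"):
        mat = getattr(bag, key)
        if mat is not None:
            changes[key] = mat[idx]
    for key in ("errors", "instance_labels"):
        vec = getattr(bag, key)
        if vec is not None:
            changes[key] = np.asarray(vec)[idx]
    return bag.with_(**changes)
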