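"""Representational dissimilarity matrices (RDMs).

An RDM is a square symmetric matrix of pairwise dissimilarities between
labeled conditions, with an exactly-zero diagonal.  All second-level
comparisons in this package operate on the lower triangle (excluding the
diagonal) in a fixed row-major pair order, so that vectors extracted from
different RDMs over the same labels are always comparable element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Valid dissimilarity measure tags and their admissible value ranges.
MEASURE_RANGES = {
    "one_minus_normalized_rating": (0.0, 1.0),
    # [0, 1] for nonnegative vectors (production counts); up to 2 in general
    "one_minus_cosine": (0.0, 2.0),
    "one_minus_pearson": (0.0, 2.0),
    "unknown": (-np.inf, np.inf),
}

_SYM_TOL = 1e-9


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix with condition labels.

    Parameters
    ----------
    values : (n, n) array_like
        Dissimilarity matrix.  Symmetrized copies are not made silently:
        asymmetry beyond tolerance raises ``ValueError``.
    labels : sequence of str
        Condition labels, one per row/column.
    measure : str
        One of :data:`MEASURE_RANGES`.
    note : str
        Free-text provenance note.
    """

    values: np.ndarray
    labels: list[str]
    measure: str = "unknown"
    note: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(l) for l in self.labels]
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"RDM values must be square, got shape {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {v.shape[0]}x{v.shape[1]} matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate condition labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite values in RDM")
        asym = np.max(np.abs(v - v.T)) if v.size else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"RDM asymmetric beyond tolerance ({asym:.3g})")
        # exact symmetry + exact-zero diagonal are part of the invariant
        self.values = (v + v.T) / 2.0
        if np.max(np.abs(np.diag(self.values))) > _SYM_TOL:
            raise ValueError("RDM diagonal not zero")
        np.fill_diagonal(self.values, 0.0)
        if self.measure not in MEASURE_RANGES:
            raise ValueError(f"unknown measure tag {self.measure!r}")
        lo, hi = MEASURE_RANGES[self.measure]
        tol = 1e-8
        if self.values.min() < lo - tol or self.values.max() > hi + tol:
            raise ValueError(
                f"values outside [{lo}, {hi}] for measure {self.measure!r}"
            )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    def vector(self) -> np.ndarray:
        """Lower-triangle values (excluding diagonal), row-major pair order."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def pair_labels(self) -> list[tuple[str, str]]:
        i, j = np.tril_indices(self.n, k=-1)
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]

    def cell(self, a: str, b: str) -> float:
        """Dissimilarity between two labeled conditions."""
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels: Sequence[str]) -> "RDM":
        """Return a copy with rows/columns in the given label order."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels not in RDM: {missing}")
        if len(labels) != self.n:
            raise ValueError("reorder must use all labels exactly once")
        idx = [self.labels.index(l) for l in labels]
        return RDM(
            self.values[np.ix_(idx, idx)],
            list(labels),
            measure=self.measure,
            note=self.note,
            meta=dict(self.meta),
        )

    def permute(self, perm: Sequence[int]) -> np.ndarray:
        """Lower-triangle vector after simultaneous row+column permutation."""
        perm = np.asarray(perm)
        sub = self.values[np.ix_(perm, perm)]
        i, j = np.tril_indices(self.n, k=-1)
        return sub[i, j]


def aligned_vectors(a: RDM, b: RDM) -> tuple[np.ndarray, np.ndarray]:
    """Lower-triangle vectors of two RDMs in a shared label order."""
    if set(a.labels) != set(b.labels):
        raise ValueError("RDMs do not share condition labels")
    return a.vector(), b.reorder(a.labels).vector()


def squareform_from_vector(vec: np.ndarray, labels: Sequence[str], **kw) -> RDM:
    """Build an RDM from a lower-triangle vector in row-major pair order."""
    n = len(labels)
    vec = np.asarray(vec, dtype=float)
    if vec.size != n * (n - 1) // 2:
        raise ValueError("vector length does not match label count")
    m = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    m[i, j] = vec
    m[j, i] = vec
    return RDM(m, list(labels), **kw)
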