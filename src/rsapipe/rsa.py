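"""First-level RSA: correlation-distance RDMs and within-object similarity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import PatternSet
from .rdm import RDM


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of two (objects x voxels) matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    if (den == 0).any():
        raise ValueError("zero-variance pattern encountered")
    return num / den


def pattern_rdm(patterns: PatternSet) -> RDM:
    """Correlation-distance RDM: ``1 - Pearson r`` between object patterns."""
    x = patterns.data
    if x.shape[1] < 2:
        raise ValueError("need >= 2 voxels for correlation distance")
    sd = x.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        names = [patterns.object_labels[i] for i in flat]
        raise ValueError(f"zero-variance pattern for object(s) {names}")
    r = np.clip(np.corrcoef(x), -1.0, 1.0)
    m = 1.0 - r
    np.fill_diagonal(m, 0.0)
    rdm = RDM(m, list(patterns.object_labels), measure="one_minus_pearson",
              note="pattern correlation distance")
    rdm.meta.update(subject=patterns.subject, context=patterns.context,
                    roi=patterns.roi)
    return rdm


@dataclass
class WithinObjectResult:
    """Per-object cross-context pattern correlations and their mean."""

    r: np.ndarray
    object_labels: list[str]
    subject: str = ""
    roi: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.r))


def within_object_similarity(a: PatternSet, b: PatternSet) -> WithinObjectResult:
    """Correlate each object's pattern across two task contexts.

    Returns per-object Pearson r between matching rows of ``a`` and ``b``
    (similarity, not dissimilarity) plus their mean as the subject summary.
    """
    if a.object_labels != b.object_labels:
        raise ValueError("pattern sets do not share object labels")
    if a.data.shape != b.data.shape:
        raise ValueError("pattern sets do not share voxel space")
    if a.context == b.context and a.context:
        raise ValueError("within-object similarity requires two distinct contexts")
    r = _row_corr(a.data, b.data)
    return WithinObjectResult(r=r, object_labels=list(a.object_labels),
                              subject=a.subject, roi=a.roi)
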