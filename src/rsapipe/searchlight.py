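"""Searchlight RSA: local-neighborhood model fits mapped to center voxels.

Neighborhoods are k-nearest mask voxels, by Euclidean distance in world
coordinates by default, or by geodesic distance along a supplied surface
mesh.  Within each neighborhood, a correlation-distance RDM is computed
from the local patterns, compared with a model RDM via Kendall tau-a,
converted to a Pearson-scale r (``sin(pi/2 * tau)``), Fisher-z transformed
and assigned to the center voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .glm import PatternSet
from .inference import kendall_tau_a_batch
from .rdm import RDM

log = logging.getLogger(__name__)

DEFAULT_K = 100
#: |r| clamp before Fisher-z, so a perfect local rank order stays finite.
R_CLAMP = 1.0 - 1e-6


def mask_coordinates(mask: np.ndarray) -> np.ndarray:
    """Voxel (i, j, k) indices of in-mask voxels in canonical (C) order."""
    return np.argwhere(np.asarray(mask, dtype=bool))


def voxel_to_world(ijk: np.ndarray, affine: np.ndarray) -> np.ndarray:
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


@dataclass
class Neighborhoods:
    """Per-center member voxel indices (into the canonical mask order)."""

    members: list[np.ndarray]
    mask: np.ndarray
    affine: np.ndarray
    k: int
    metric: str = "euclidean_knn"

    @property
    def n_centers(self) -> int:
        return len(self.members)


def build_neighborhoods(
    mask: np.ndarray,
    affine: np.ndarray,
    k: int = DEFAULT_K,
    mesh: tuple[np.ndarray, np.ndarray] | None = None,
    chunk: int = 256,
) -> Neighborhoods:
    """k-nearest-voxel neighborhoods for every in-mask voxel.

    Ties in distance are broken deterministically by voxel index.  With a
    ``mesh`` (world-coordinate vertices, triangle faces), distances are
    geodesic along the mesh between each voxel's nearest vertex.
    """
    mask = np.asarray(mask, dtype=bool)
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = mask_coordinates(mask)
    n = len(coords)
    if n == 0:
        raise ValueError("empty mask")
    if n < k:
        log.warning("mask smaller than k (%d < %d); using full-mask neighborhoods",
                    n, k)
        k = n
    world = voxel_to_world(coords, affine)

    if mesh is None:
        dist_to_all = None
        metric = "euclidean_knn"
    else:
        vertices, faces = mesh
        vert_of_voxel = _nearest_vertices(world, vertices)
        geo = _geodesic_distances(vertices, faces, np.unique(vert_of_voxel))
        row_of_vert = {v: i for i, v in enumerate(np.unique(vert_of_voxel))}
        rows = np.array([row_of_vert[v] for v in vert_of_voxel])
        dist_to_all = geo[rows][:, vert_of_voxel]
        metric = "geodesic_surface"

    members: list[np.ndarray] = []
    order_key = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        if dist_to_all is None:
            d = np.linalg.norm(world[start:stop, None, :] - world[None, :, :],
                               axis=2)
        else:
            d = dist_to_all[start:stop]
        for row in d:
            idx = np.lexsort((order_key, row))[:k]
            members.append(idx)
    return Neighborhoods(members=members, mask=mask, affine=np.asarray(affine),
                         k=k, metric=metric)


def _nearest_vertices(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    out = np.empty(len(points), dtype=int)
    for i, p in enumerate(points):
        out[i] = int(np.argmin(np.linalg.norm(vertices - p, axis=1)))
    return out


def _geodesic_distances(vertices: np.ndarray, faces: np.ndarray,
                        sources: np.ndarray) -> np.ndarray:
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
    lengths = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]],
                             axis=1)
    nv = len(vertices)
    g = coo_matrix((np.r_[lengths, lengths],
                    (np.r_[edges[:, 0], edges[:, 1]],
                     np.r_[edges[:, 1], edges[:, 0]])), shape=(nv, nv)).tocsr()
    return dijkstra(g, directed=False, indices=sources)


@dataclass
class SimilarityMap:
    """Per-voxel Fisher-z model-fit values over a mask.

    ``values`` follows the canonical mask-voxel order; NaN marks centers
    skipped for degenerate (zero-variance) local patterns.
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject: str = ""
    context: str = ""
    model_id: str = ""
    meta: dict = field(default_factory=dict)

    def volume(self, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = np.where(np.isfinite(self.values), self.values, fill)
        return vol

    @property
    def n_missing(self) -> int:
        return int((~np.isfinite(self.values)).sum())


def local_rdm_vectors(patterns: PatternSet, nb: Neighborhoods) -> np.ndarray:
    """Correlation-distance RDM vectors per searchlight center.

    Returns a (centers, n_pairs) array; rows are NaN where any local
    object pattern has zero variance.
    """
    x = patterns.data
    n_obj = x.shape[0]
    if x.shape[1] != nb.n_centers:
        raise ValueError("patterns do not cover all mask voxels")
    il, jl = np.tril_indices(n_obj, k=-1)
    out = np.empty((nb.n_centers, len(il)))
    n_bad = 0
    for c, idx in enumerate(nb.members):
        local = x[:, idx]
        if (local.std(axis=1) == 0).any():
            out[c] = np.nan
            n_bad += 1
            continue
        r = np.clip(np.corrcoef(local), -1.0, 1.0)
        out[c] = 1.0 - r[il, jl]
    if n_bad:
        log.warning("%d searchlight center(s) skipped (zero-variance patterns)",
                    n_bad)
    return out


def fit_from_vectors(vectors: np.ndarray, model_vector: np.ndarray) -> np.ndarray:
    """Tau-a -> sine transform -> Fisher-z for each local RDM vector."""
    tau = kendall_tau_a_batch(vectors, model_vector)
    with np.errstate(invalid="ignore"):
        r = np.clip(np.sin(0.5 * np.pi * tau), -R_CLAMP, R_CLAMP)
        return np.arctanh(r)


def searchlight_fit(
    patterns: PatternSet,
    model: RDM,
    nb: Neighborhoods,
) -> SimilarityMap:
    """Whole-volume searchlight model fit for one subject/context."""
    if list(model.labels) != list(patterns.object_labels):
        model = model.reorder(list(patterns.object_labels))
    vectors = local_rdm_vectors(patterns, nb)
    z = fit_from_vectors(vectors, model.vector())
    return SimilarityMap(values=z, mask=nb.mask, affine=nb.affine,
                         subject=patterns.subject, context=patterns.context,
                         model_id=model.note or "model",
                         meta={"k": nb.k, "metric": nb.metric,
                               "n_missing": int((~np.isfinite(z)).sum())})
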