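"""Group-level statistics on searchlight similarity maps.

Subject maps are z-scored within the mask, combined with a one-sample
t-test per voxel (converted to z), enhanced with TFCE, and thresholded
against a max-TFCE Monte Carlo permutation null for family-wise error
control.  Thresholded maps are summarized as cluster tables and combined
with voxel-overlap analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import PatternSet
from .rdm import RDM
from .searchlight import (Neighborhoods, SimilarityMap, fit_from_vectors,
                          local_rdm_vectors, voxel_to_world)

log = logging.getLogger(__name__)

TFCE_E = 0.5
TFCE_H = 2.0
DEFAULT_ALPHA = 0.05


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class GroupStatMap:
    """Per-voxel group z statistic over a mask."""

    values: np.ndarray  # 1-D, canonical mask order
    mask: np.ndarray
    affine: np.ndarray
    n_subjects: int

    def volume(self, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.values
        return vol


def group_stat(subject_maps: list[SimilarityMap]) -> GroupStatMap:
    """Standardize subject maps within-mask and t-test across subjects.

    Each subject map is z-scored within the mask (mean 0, sd 1); the
    per-voxel one-sample t across subjects is converted to a z statistic.
    """
    if len(subject_maps) < 3:
        raise ValueError("need >= 3 subjects")
    mask = subject_maps[0].mask
    for m in subject_maps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("subject maps do not share a mask")
    if mask.sum() < 2:
        raise ValueError("mask too small to standardize (need >= 2 voxels)")
    stack = []
    for m in subject_maps:
        v = np.where(np.isfinite(m.values), m.values, 0.0)
        sd = v.std()
        if sd == 0:
            raise ValueError(
                f"zero within-mask variance for subject {m.subject!r}")
        stack.append((v - v.mean()) / sd)
    x = np.asarray(stack)
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    z = stats.norm.isf(stats.t.sf(t, df=n - 1))
    z = np.clip(z, -40, 40)  # guard infinities from extreme t
    return GroupStatMap(values=z, mask=mask,
                        affine=subject_maps[0].affine, n_subjects=n)


def tfce(
    stat: GroupStatMap | np.ndarray,
    E: float = TFCE_E,
    H: float = TFCE_H,
    dh: float | None = None,
    n_steps: int = 100,
    connectivity: int = 26,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a (one-sided) statistic map.

    ``TFCE(v) = sum_h extent_h(v)^E * h^H * dh`` over thresholds
    ``h = dh, 2dh, ... <= max``; negative values contribute nothing.
    Returns a 3-D volume (zero outside the mask).  ``dh`` defaults to
    ``max / n_steps``.
    """
    if isinstance(stat, GroupStatMap):
        vol = stat.volume(fill=0.0)
    else:
        vol = np.asarray(stat, dtype=float)
    if E < 0 or H < 0:
        raise ValueError("E and H must be >= 0")
    pos = np.clip(vol, 0.0, None)
    top = pos.max()
    out = np.zeros_like(pos)
    if top <= 0:
        return out
    if dh is None:
        dh = top / n_steps
    if dh <= 0:
        raise ValueError("dh must be > 0")
    struct = _structure(connectivity)
    # midpoint rule over the threshold integral: O(dh^2) accuracy
    h = dh / 2
    while h <= top:
        labels, n_lab = ndimage.label(pos >= h, structure=struct)
        if n_lab == 0:
            break
        extents = np.bincount(labels.ravel())
        extents[0] = 0
        out += np.where(labels > 0, extents[labels] ** E * h**H * dh, 0.0)
        h += dh
    return out


@dataclass
class NullDistribution:
    """Sorted max-TFCE permutation null."""

    values: np.ndarray
    seed: int | None
    recipe: str

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))

    @property
    def size(self) -> int:
        return self.values.size

    def corrected_p(self, observed: np.ndarray) -> np.ndarray:
        """``p = (1 + #{null >= obs}) / (1 + N)`` per voxel."""
        n_ge = self.size - np.searchsorted(self.values, observed, side="left")
        return (1 + n_ge) / (1 + self.size)


@dataclass
class PermutationResult:
    observed_tfce: np.ndarray  # 3-D volume
    null: NullDistribution
    p_map: np.ndarray  # 3-D volume of corrected p (1 outside mask)
    threshold_mask: np.ndarray  # 3-D bool, p < alpha
    group_z: GroupStatMap
    alpha: float


def permutation_null(
    subject_patterns: list[PatternSet],
    model: RDM,
    nb: Neighborhoods,
    n_subject_null: int = 100,
    n_group: int = 10_000,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    E: float = TFCE_E,
    H: float = TFCE_H,
    n_steps: int = 100,
    connectivity: int = 26,
) -> PermutationResult:
    """Monte Carlo max-TFCE FWE inference for a searchlight model fit.

    Per subject, ``n_subject_null`` null similarity maps are built by
    permuting object labels of the local RDMs (implemented as permuting
    the model RDM labels, one permutation per null map) before model
    comparison.  ``n_group`` group null assemblies each sample one null
    map per subject with replacement, pass through group standardization
    + t + TFCE, and record the map maximum.
    """
    if n_subject_null < 1:
        raise ValueError("n_subject_null must be >= 1")
    if n_group < 100:
        raise ValueError("n_group must be >= 100")
    n_sub = len(subject_patterns)
    if n_subject_null**n_sub < n_group:
        log.warning("n_group=%d exceeds distinct assemblies (%d^%d); "
                    "sampling with replacement continues",
                    n_group, n_subject_null, n_sub)
    rng = np.random.default_rng(seed)
    labels = list(subject_patterns[0].object_labels)
    model = model.reorder(labels)
    model_vec = model.vector()

    n_vox = nb.n_centers
    observed_maps: list[SimilarityMap] = []
    null_std = np.empty((n_sub, n_subject_null, n_vox))
    for s, ps in enumerate(subject_patterns):
        if list(ps.object_labels) != labels:
            raise ValueError("subjects do not share object labels")
        vecs = local_rdm_vectors(ps, nb)
        observed_maps.append(SimilarityMap(
            values=fit_from_vectors(vecs, model_vec), mask=nb.mask,
            affine=nb.affine, subject=ps.subject, context=ps.context))
        for j in range(n_subject_null):
            perm = rng.permutation(model.n)
            v = fit_from_vectors(vecs, model.permute(perm))
            v = np.where(np.isfinite(v), v, 0.0)
            sd = v.std()
            if sd == 0:
                raise ValueError(
                    f"zero within-mask variance in null map for {ps.subject!r}")
            null_std[s, j] = (v - v.mean()) / sd

    group_z = group_stat(observed_maps)
    tfce_kw = dict(E=E, H=H, n_steps=n_steps, connectivity=connectivity)
    observed_tfce = tfce(group_z, **tfce_kw)

    # sample one (pre-standardized) null map per subject per assembly and
    # run the identical group t -> z -> TFCE chain, recording the max
    picks = rng.integers(n_subject_null, size=(n_group, n_sub))
    null_max = np.empty(n_group)
    vol = np.zeros(nb.mask.shape)
    for g in range(n_group):
        data = null_std[np.arange(n_sub), picks[g]]
        mean = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / (sd / np.sqrt(n_sub)), 0.0)
        z = np.clip(stats.norm.isf(stats.t.sf(t, df=n_sub - 1)), -40, 40)
        vol[nb.mask] = z
        null_max[g] = tfce(vol, **tfce_kw).max()
    null = NullDistribution(null_max, seed=seed,
                            recipe=f"max-tfce;n_subject_null={n_subject_null};"
                                   f"n_group={n_group}")

    p_map = np.ones(nb.mask.shape)
    p_map[nb.mask] = null.corrected_p(observed_tfce[nb.mask])
    return PermutationResult(
        observed_tfce=observed_tfce, null=null, p_map=p_map,
        threshold_mask=(p_map < alpha) & nb.mask, group_z=group_z, alpha=alpha,
    )


def cluster_report(
    thresholded: np.ndarray,
    affine: np.ndarray,
    stat: np.ndarray | None = None,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Connected-component summary of a thresholded map.

    Columns: label, extent (voxels), peak statistic and its world-mm
    coordinates (when ``stat`` is given), and center of mass in world mm.
    """
    binary = np.asarray(thresholded) > 0
    labels, n_lab = ndimage.label(binary, structure=_structure(connectivity))
    rows = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        extent = int(sel.sum())
        com_ijk = ndimage.center_of_mass(sel)
        com = voxel_to_world(np.array(com_ijk), affine)
        row = {"label": lab, "extent": extent,
               "com_x": com[0], "com_y": com[1], "com_z": com[2]}
        if stat is not None:
            vals = np.where(sel, stat, -np.inf)
            peak_ijk = np.unravel_index(np.argmax(vals), vals.shape)
            peak = voxel_to_world(np.array(peak_ijk), affine)
            row.update(peak_stat=float(stat[peak_ijk]),
                       peak_x=peak[0], peak_y=peak[1], peak_z=peak[2])
        rows.append(row)
    cols = ["label", "extent", "peak_stat", "peak_x", "peak_y", "peak_z",
            "com_x", "com_y", "com_z"] if stat is not None else \
           ["label", "extent", "com_x", "com_y", "com_z"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("extent", ascending=False).reset_index(drop=True)


def overlap(
    maps: list[np.ndarray],
    affine: np.ndarray,
    connectivity: int = 26,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Voxelwise intersection of thresholded maps plus its cluster table."""
    if not maps:
        raise ValueError("no maps to overlap")
    shape = np.asarray(maps[0]).shape
    inter = np.ones(shape, dtype=bool)
    for m in maps:
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError("maps do not share a space")
        inter &= m > 0
    return inter, cluster_report(inter, affine, connectivity=connectivity)
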