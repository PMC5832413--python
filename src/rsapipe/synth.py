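"""Synthetic fixtures with known representational structure.

Generates every input the pipeline consumes: two near-orthogonal model
RDMs built by chained pairing (each object gets one low-dissimilarity
partner per model, different partners across models), Likert rating
tables with catch trials, feature norms whose cosine geometry tracks the
conceptual model, embedding vectors with a configurable visual "leak",
event-related BOLD series, and multi-subject multi-voxel patterns whose
expected pairwise geometry is a weighted mixture of the two model RDMs
plus noise, organized in runs and two task contexts over a voxel grid
with region-specific mixture regimes.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .glm import CONTEXTS, PatternSet, build_design
from .inference import kendall_tau_a
from .rdm import RDM, aligned_vectors

__all__ = [
    "RegionSpec",
    "SyntheticConfig",
    "GroundTruth",
    "make_model_rdms",
    "SimulatedPatterns",
    "simulate_patterns",
    "simulate_ratings",
    "simulate_norms",
    "simulate_embeddings",
    "simulate_bold",
    "default_regions",
]


# ----------------------------------------------------------------------
# Configuration


@dataclass
class RegionSpec:
    """Cubic region with per-context (w_visual, w_conceptual) mixture weights.

    ``share_profiles`` reuses the same voxel response profiles in both
    task contexts (context-invariant coding); ``None`` auto-shares when
    the weights are identical across contexts.
    """

    slices: tuple[slice, slice, slice]
    weights: dict[str, tuple[float, float]]
    share_profiles: bool | None = None

    def __post_init__(self) -> None:
        for ctx, (wv, wc) in self.weights.items():
            if ctx not in CONTEXTS:
                raise ValueError(f"unknown context {ctx!r}")
            if wv < 0 or wc < 0 or wv + wc > 1 + 1e-12:
                raise ValueError("weights must be >= 0 with w_v + w_c <= 1")

    @property
    def shares(self) -> bool:
        if self.share_profiles is not None:
            return self.share_profiles
        ws = [self.weights.get(c, (0.0, 0.0)) for c in CONTEXTS]
        return ws[0] == ws[1]

    def mask(self, grid: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(grid, dtype=bool)
        m[self.slices] = True
        return m


def default_regions(grid: tuple[int, int, int] = (12, 12, 12)
                    ) -> dict[str, RegionSpec]:
    """Four cubic regions mirroring the qualitative ROI regimes.

    * ``loc_like``  — visual code, visual context only (task-dependent)
    * ``phc_like``  — conceptual code, conceptual context only
    * ``tp_like``   — conceptual code, both contexts (task-invariant)
    * ``prc_like``  — both codes, both contexts (integrative)

    Cube positions scale with the grid; on the default 12^3 grid each
    region is a 4^3 corner cube.
    """
    def lo(g):
        return slice(round(g / 12), round(5 * g / 12))

    def hi(g):
        return slice(round(7 * g / 12), round(11 * g / 12))

    gx, gy, gz = grid
    return {
        "loc_like": RegionSpec((lo(gx), lo(gy), lo(gz)),
                               {"visual": (0.8, 0.0), "conceptual": (0.0, 0.0)},
                               share_profiles=False),
        "phc_like": RegionSpec((hi(gx), lo(gy), lo(gz)),
                               {"visual": (0.0, 0.0), "conceptual": (0.0, 0.8)},
                               share_profiles=False),
        "tp_like": RegionSpec((lo(gx), hi(gy), hi(gz)),
                              {"visual": (0.0, 0.8), "conceptual": (0.0, 0.8)},
                              share_profiles=True),
        "prc_like": RegionSpec((hi(gx), hi(gy), hi(gz)),
                               {"visual": (0.45, 0.45), "conceptual": (0.45, 0.45)},
                               share_profiles=True),
    }


@dataclass
class SyntheticConfig:
    n_objects: int = 40
    n_subjects: int = 16
    n_runs: int = 8
    grid: tuple[int, int, int] = (12, 12, 12)
    regions: dict[str, RegionSpec] = field(default_factory=default_regions)
    noise_sd: float = 1.0
    #: plant the object geometry exactly (orthonormal, mean-centered voxel
    #: profiles): local Pearson equals the target similarity at zero noise
    exact_geometry: bool = False
    rating_noise_sd: float = 0.0
    n_raters: int = 15
    n_producers: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_objects, self.n_subjects, self.n_runs,
               self.n_raters, self.n_producers) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd < 0 or self.rating_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        shape = np.zeros(self.grid, dtype=bool)
        for name, spec in self.regions.items():
            m = spec.mask(self.grid)
            if not m.any():
                raise ValueError(f"region {name!r} outside grid")

    @property
    def affine(self) -> np.ndarray:
        return np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm isotropic grid


@dataclass
class GroundTruth:
    visual: RDM
    conceptual: RDM
    regions: dict[str, RegionSpec]
    tau_vc: float


# ----------------------------------------------------------------------
# Model RDMs


def _chained_pair_rdm(n: int, pairs: list[tuple[int, int]], labels: list[str],
                      rng: np.random.Generator) -> RDM:
    m = rng.uniform(0.7, 1.0, size=(n, n))
    m = np.triu(m, 1)
    m = m + m.T
    for i, j in pairs:
        low = rng.uniform(0.05, 0.3)
        m[i, j] = m[j, i] = low
    np.fill_diagonal(m, 0.0)
    # make 1 - m a valid correlation matrix, so the model geometry is
    # exactly realizable by voxel patterns (any mixture with the identity
    # stays PSD); the projection shifts cells only slightly
    s = _nearest_psd(1.0 - m)
    m = np.clip(1.0 - s, 0.0, 1.0)
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2
    return RDM(m, labels, measure="one_minus_normalized_rating",
               note="synthetic chained-pair model")


def make_model_rdms(
    n_objects: int = 40,
    tol: float = 0.02,
    seed: int | None = 0,
    max_tries: int = 500,
) -> tuple[RDM, RDM]:
    """Near-orthogonal visual and conceptual model RDMs by chained pairing.

    Objects sit on a ring; the visual model pairs (0,1), (2,3), ... and
    the conceptual model pairs (1,2), (3,4), ..., (n-1,0), so every
    object has one low-dissimilarity partner per model and the partners
    differ.  Matrices are regenerated until ``|tau_a(V, C)| < tol``.
    """
    if n_objects < 8 or n_objects % 2:
        raise ValueError("n_objects must be even and >= 8")
    labels = [f"obj{i:03d}" for i in range(n_objects)]
    v_pairs = [(i, i + 1) for i in range(0, n_objects, 2)]
    c_pairs = [(i, (i + 1) % n_objects) for i in range(1, n_objects, 2)]
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(max_tries):
        v = _chained_pair_rdm(n_objects, v_pairs, labels, rng)
        c = _chained_pair_rdm(n_objects, c_pairs, labels, rng)
        tau = kendall_tau_a(v.vector(), c.vector())
        if abs(tau) < tol:
            v.meta["tau_vc"] = c.meta["tau_vc"] = tau
            return v, c
        best = min(best, abs(tau))
    raise RuntimeError(
        f"could not reach |tau| < {tol} in {max_tries} tries (best {best:.4f})")


# ----------------------------------------------------------------------
# Multi-voxel patterns


def _nearest_psd(s: np.ndarray, floor: float = 1e-9) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    w, u = np.linalg.eigh((s + s.T) / 2)
    w = np.clip(w, floor, None)
    out = (u * w) @ u.T
    # keep unit diagonal so voxelwise profiles stay unit-variance
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    return (out + out.T) / 2


def _mixture_cov(v: RDM, c: RDM, wv: float, wc: float) -> np.ndarray:
    n = v.n
    s = wv * (1.0 - v.values) + wc * (1.0 - c.values) + (1 - wv - wc) * np.eye(n)
    np.fill_diagonal(s, 1.0)
    return _nearest_psd(s)


def _cov_factor(s: np.ndarray) -> np.ndarray:
    w, u = np.linalg.eigh(s)
    w = np.clip(w, 0.0, None)
    return u * np.sqrt(w)


def _orthonormal_rows(k: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """(k, n) rows that are orthonormal and orthogonal to the ones vector.

    Scaled by sqrt(n) so row variance is ~1.  Used for exact-geometry
    profiles: with these as latent draws, the sample Gram (and Pearson)
    of the mixed profiles equals the target similarity matrix exactly.
    """
    if n < k + 1:
        raise ValueError(
            f"exact geometry needs >= n_objects+1 voxels per region "
            f"({k + 1} > {n})")
    m = rng.standard_normal((n, k + 1))
    m[:, 0] = 1.0
    q, _ = np.linalg.qr(m)
    return np.sqrt(n) * q[:, 1:k + 1].T


class SimulatedPatterns:
    """Lazy per-subject whole-volume pattern generator.

    Patterns for subject ``s`` are regenerated deterministically from
    ``(config.seed, s)`` on each call, so large cohorts never need to be
    held in memory at once.
    """

    def __init__(self, visual: RDM, conceptual: RDM, config: SyntheticConfig):
        if list(visual.labels) != list(conceptual.labels):
            raise ValueError("model RDMs do not share labels")
        if visual.n != config.n_objects:
            raise ValueError("model RDM size does not match config.n_objects")
        self.visual = visual
        self.conceptual = conceptual
        self.config = config
        self.ground_truth = GroundTruth(
            visual=visual, conceptual=conceptual, regions=dict(config.regions),
            tau_vc=kendall_tau_a(*aligned_vectors(visual, conceptual)),
        )
        grid = config.grid
        self.region_masks = {name: spec.mask(grid)
                             for name, spec in config.regions.items()}
        self.volume_mask = np.ones(grid, dtype=bool)
        self._flat = {name: m.ravel().nonzero()[0]
                      for name, m in self.region_masks.items()}
        self._factors = {
            name: {ctx: _cov_factor(_mixture_cov(
                visual, conceptual, *spec.weights.get(ctx, (0.0, 0.0))))
                for ctx in CONTEXTS}
            for name, spec in config.regions.items()
        }

    @property
    def object_labels(self) -> list[str]:
        return list(self.visual.labels)

    def _profiles(self, subject: int) -> dict[str, dict[str, np.ndarray]]:
        """Noise-free expected (objects x voxels) profile per context."""
        cfg = self.config
        n_obj = cfg.n_objects
        n_vox = int(np.prod(cfg.grid))
        rng = np.random.default_rng([cfg.seed, 1000 + subject])
        out = {ctx: rng.standard_normal((n_obj, n_vox)) for ctx in CONTEXTS}
        # background voxels keep iid profiles (no model structure)
        def draw(size: int) -> np.ndarray:
            if cfg.exact_geometry:
                return _orthonormal_rows(n_obj, size, rng)
            return rng.standard_normal((n_obj, size))

        for name, spec in cfg.regions.items():
            flat = self._flat[name]
            if spec.shares:
                z = draw(flat.size)
                for ctx in CONTEXTS:
                    out[ctx][:, flat] = self._factors[name][ctx] @ z
            else:
                for ctx in CONTEXTS:
                    out[ctx][:, flat] = self._factors[name][ctx] @ draw(flat.size)
        return out

    def run_patterns(self, subject: int) -> dict[str, list[np.ndarray]]:
        """Per-run (objects x voxels) pattern matrices for one subject."""
        cfg = self.config
        profiles = self._profiles(subject)
        rng = np.random.default_rng([cfg.seed, 2000 + subject])
        out: dict[str, list[np.ndarray]] = {}
        for ctx in CONTEXTS:
            out[ctx] = [profiles[ctx] +
                        cfg.noise_sd * rng.standard_normal(profiles[ctx].shape)
                        for _ in range(cfg.n_runs)]
        return out

    def averaged(self, subject: int, context: str,
                 region: str | None = None) -> PatternSet:
        """Run-averaged PatternSet, whole volume or restricted to a region."""
        runs = self.run_patterns(subject)[context]
        data = np.mean(runs, axis=0)
        roi = "volume"
        if region is not None:
            data = data[:, self._flat[region]]
            roi = region
        return PatternSet(data, self.object_labels,
                          subject=f"sub{subject:02d}", context=context, roi=roi,
                          meta={"n_runs": self.config.n_runs})


def simulate_patterns(
    visual: RDM, conceptual: RDM, config: SyntheticConfig
) -> SimulatedPatterns:
    """Simulated multi-subject whole-volume patterns (lazy container)."""
    return SimulatedPatterns(visual, conceptual, config)


# ----------------------------------------------------------------------
# Behavioral tables


def simulate_ratings(
    visual: RDM,
    config: SyntheticConfig,
    n_failing_raters: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Likert rating table whose pair means track ``1 - V``.

    Each of ``n_raters`` raters rates every pair; integer ratings are
    split between adjacent Likert levels so the noise-free pair mean
    approximates ``1 + 4 (1 - V)`` to within ``1 / n_raters``.  Every
    rater receives four catch trials (concept paired with itself, rated
    "very similar").  ``n_failing_raters`` extra raters give junk ratings
    and fail one catch trial, exercising rater exclusion.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labels = visual.labels
    n = visual.n
    rows = []
    raters = [f"r{k:03d}" for k in range(cfg.n_raters)]
    for i in range(n):
        for j in range(i):
            target = 1.0 + 4.0 * (1.0 - visual.values[i, j])
            base = int(np.floor(target))
            n_high = int(np.rint((target - base) * cfg.n_raters))
            for k, rater in enumerate(raters):
                val = min(base + 1, 5) if k < n_high else base
                if cfg.rating_noise_sd > 0:
                    val = int(np.clip(np.rint(
                        val + rng.normal(0, cfg.rating_noise_sd)), 1, 5))
                rows.append((rater, labels[j], labels[i], val, False))
    catch_concepts = rng.choice(labels, size=4, replace=False)
    for rater in raters:
        for c in catch_concepts:
            rows.append((rater, c, c, 5, True))
    for f in range(n_failing_raters):
        rater = f"fail{f:03d}"
        for i in range(n):
            for j in range(i):
                rows.append((rater, labels[j], labels[i],
                             int(rng.integers(1, 6)), False))
        for q, c in enumerate(catch_concepts):
            rows.append((rater, c, c, 3 if q == 0 else 5, True))
    return pd.DataFrame(rows, columns=["rater_id", "concept_a", "concept_b",
                                       "likert", "is_catch"])


def _square_decompose(target: int, lo: int, hi: int) -> list[int]:
    """Greedy decomposition of ``target`` into squares of ints in [lo, hi]."""
    out = []
    rem = target
    while rem >= lo * lo:
        c = min(hi, int(np.floor(np.sqrt(rem))))
        out.append(c)
        rem -= c * c
    return out


def simulate_norms(
    conceptual: RDM,
    config: SyntheticConfig,
    visual: RDM | None = None,
    min_count: int = 4,
    tagged_pairs: int = 6,
    n_unreliable: int = 20,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Feature norms whose cosine geometry approximates ``1 - C``.

    Concept pairs share features with production counts chosen so the
    pairwise dot products are proportional to the target similarities and
    concept norms are equal; unique filler features pad each concept to a
    common squared norm.  Adds ``n_unreliable`` sub-threshold features
    (count < ``min_count``) and, when ``visual`` is given, visually shared
    features tagged ``visual_form``/``color`` for the most visually
    similar pairs — both are removed by the standard filtering chain.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = conceptual.labels
    n = conceptual.n
    hi = config.n_producers
    sim = np.clip(1.0 - conceptual.values, 0.0, 1.0)
    np.fill_diagonal(sim, 0.0)
    rowsum = sim.sum(axis=1).max()
    alpha = 0.8 / rowsum if rowsum > 0 else 1.0
    T = (4 * hi) ** 2  # common squared norm target

    rows = []
    sq_norm = np.zeros(n)
    for i in range(n):
        for j in range(i):
            target = T * alpha * sim[i, j]
            if noise_sd > 0:
                target *= max(0.0, 1.0 + rng.normal(0, noise_sd))
            d = int(np.rint(target))
            for k, cnt in enumerate(_square_decompose(d, min_count, hi)):
                feat = f"shared {labels[j]} {labels[i]} {k}"
                rows.append((labels[i], feat, cnt, "none"))
                rows.append((labels[j], feat, cnt, "none"))
                sq_norm[i] += cnt * cnt
                sq_norm[j] += cnt * cnt
    for i in range(n):
        pad = int(np.rint(T - sq_norm[i]))
        for k, cnt in enumerate(_square_decompose(pad, min_count, hi)):
            rows.append((labels[i], f"unique {labels[i]} {k}", cnt, "none"))

    if visual is not None and tagged_pairs > 0:
        vv = visual.reorder(list(labels)).values
        iu, ju = np.tril_indices(n, k=-1)
        order = np.argsort(vv[iu, ju])[:tagged_pairs]  # most visually similar
        for rank, q in enumerate(order):
            i, j = int(iu[q]), int(ju[q])
            tag = "visual_form" if rank % 2 == 0 else "color"
            feat = f"{tag} shared {labels[j]} {labels[i]}"
            cnt = int(rng.integers(min_count, hi + 1))
            rows.append((labels[i], feat, cnt, tag))
            rows.append((labels[j], feat, cnt, tag))
    for k in range(n_unreliable):
        concept = labels[int(rng.integers(n))]
        cnt = int(rng.integers(1, min_count))
        rows.append((concept, f"unreliable {k}", cnt, "none"))

    return pd.DataFrame(rows, columns=["concept", "feature",
                                       "producer_count", "tags"])


def simulate_embeddings(
    conceptual: RDM,
    visual: RDM,
    leak: float = 0.0,
    dim: int = 300,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Embedding vectors with cosine ~ ``(1-leak)(1-C) + leak(1-V)``.

    The target similarity matrix is factored spectrally so the vector
    Gram matrix matches it, then rotated into ``dim`` dimensions with a
    random orthogonal map (cosines preserved).
    """
    if not 0 <= leak <= 1:
        raise ValueError("leak must be in [0, 1]")
    labels = list(conceptual.labels)
    v = visual.reorder(labels)
    n = conceptual.n
    if dim < n:
        raise ValueError(f"dim must be >= n_concepts ({n})")
    target = (1 - leak) * (1 - conceptual.values) + leak * (1 - v.values)
    np.fill_diagonal(target, 1.0)
    if target.max() > 1 + 1e-9:
        raise ValueError("infeasible cosine targets > 1")
    x = _cov_factor(_nearest_psd(target))  # (n, n), Gram ~ target
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    full = np.zeros((n, dim))
    full[:, :n] = x
    vecs = full @ q.T
    if noise_sd > 0:
        vecs = vecs + rng.normal(0, noise_sd, size=vecs.shape)
    return pd.DataFrame(vecs, index=labels,
                        columns=[f"d{k:03d}" for k in range(dim)])


# ----------------------------------------------------------------------
# BOLD time series


@dataclass
class BoldSim:
    data: np.ndarray  # volumes x voxels
    tr: float
    design: np.ndarray
    design_columns: list[str]
    amplitudes: np.ndarray  # objects x voxels ground truth
    nuisance: np.ndarray | None


def simulate_bold(
    events: pd.DataFrame,
    amplitudes: np.ndarray,
    tr: float = 2.0,
    n_volumes: int | None = None,
    noise_sd: float = 1.0,
    drift: bool = False,
    seed: int | None = 0,
) -> BoldSim:
    """Event-related series ``y = design @ amplitudes + noise (+ drift)``.

    ``amplitudes`` is objects x voxels (rows follow the sorted object
    labels of ``events``).  With ``drift``, a linear trend is added and
    returned as a nuisance covariate.
    """
    if noise_sd < 0:
        raise ValueError("negative noise sd")
    if n_volumes is None:
        n_volumes = int(np.ceil((events["onset"].max() + 24.0) / tr))
    design, names = build_design(events, tr=tr, n_volumes=n_volumes)
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    n_obj = len(names) - 1
    if amplitudes.shape[0] != n_obj:
        raise ValueError(f"amplitudes rows ({amplitudes.shape[0]}) != "
                         f"objects in events ({n_obj})")
    rng = np.random.default_rng(seed)
    y = design[:, :n_obj] @ amplitudes
    y = y + noise_sd * rng.standard_normal(y.shape)
    nuisance = None
    if drift:
        trend = np.linspace(-1, 1, n_volumes)[:, None]
        y = y + 5.0 * trend
        nuisance = trend
    return BoldSim(data=y, tr=tr, design=design, design_columns=names,
                   amplitudes=amplitudes, nuisance=nuisance)
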