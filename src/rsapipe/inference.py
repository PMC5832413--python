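"""Second-level RSA statistics.

Kendall tau-a model comparison with stimulus-label randomization nulls,
one-sided Wilcoxon signed-rank group tests, the tau -> Pearson-r sine
transform and Fisher-z, a 2x2 repeated-measures ANOVA, and Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rdm import RDM, aligned_vectors

__all__ = [
    "kendall_tau_a",
    "kendall_tau_a_batch",
    "randomization_test",
    "wilcoxon_signed_rank_one_sided",
    "tau_to_r",
    "fisher_z",
    "rm_anova_2x2",
    "bonferroni",
    "critical_alpha",
    "group_model_fit",
    "ModelComparisonResult",
]


def _tie_term(v: np.ndarray) -> int:
    _, counts = np.unique(v, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-aware Kendall tau-a: ``(C - D) / (m(m-1)/2)``.

    Pairs tied in either vector count as neither concordant nor
    discordant, so tau-a is penalized (never inflated) by ties — the
    appropriate behavior when model RDMs predict many tied dissimilarities.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    m = x.size
    if m < 2:
        raise ValueError("need at least 2 values")
    n0 = m * (m - 1) // 2
    tx, ty = _tie_term(x), _tie_term(y)
    if tx == n0 or ty == n0:
        return 0.0  # constant vector: no concordant or discordant pairs
    # scipy's tau-b = (C - D) / sqrt((n0 - tx)(n0 - ty)); recover the
    # integer C - D and renormalize by all pairs.
    tau_b = stats.kendalltau(x, y).statistic
    cd = round(tau_b * np.sqrt(float(n0 - tx) * float(n0 - ty)))
    return cd / n0


def kendall_tau_a_batch(x: np.ndarray, y: np.ndarray,
                        chunk: int = 64) -> np.ndarray:
    """Tau-a of each row of ``x`` against ``y`` via explicit pair signs.

    Exact O(m^2) evaluation (ties count as neither concordant nor
    discordant), vectorized over rows; rows containing non-finite values
    yield NaN.  Used by the searchlight, where many short RDM vectors are
    compared against one model vector.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    m = y.size
    if x.shape[1] != m:
        raise ValueError("row length mismatch")
    iu, ju = np.triu_indices(m, k=1)
    sy = np.sign(y[iu] - y[ju])
    n0 = m * (m - 1) // 2
    out = np.empty(x.shape[0])
    for start in range(0, x.shape[0], chunk):
        block = x[start:start + chunk]
        sx = np.sign(block[:, iu] - block[:, ju])
        out[start:start + chunk] = sx @ sy
    out /= n0
    out[~np.isfinite(x).all(axis=1)] = np.nan
    return out


@dataclass
class ModelComparisonResult:
    """Observed tau-a and its stimulus-label randomization null."""

    tau_a: float
    p: float
    n_null: int
    null_mean: float
    null_sd: float
    seed: int | None = None


def randomization_test(
    a: RDM,
    b: RDM,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> ModelComparisonResult:
    """One-sided stimulus-label randomization test for RDM relatedness.

    The null permutes the object labels of one RDM (simultaneous
    row+column permutation) and recomputes tau-a on the lower triangles;
    ``p = (1 + #{null >= observed}) / (1 + n_iter)``.
    """
    if a.n < 4:
        raise ValueError("need at least 4 conditions")
    # canonical (sorted) label order makes the test numerically invariant
    # to any relabeling applied consistently to both RDMs
    a = a.reorder(sorted(a.labels))
    xa, xb = aligned_vectors(a, b)
    if np.unique(xa).size < 2 or np.unique(xb).size < 2:
        raise ValueError("tau undefined: constant lower triangle")
    obs = kendall_tau_a(xa, xb)
    rng = np.random.default_rng(seed)
    b_aligned = b.reorder(a.labels)
    if xa.size <= 2000:
        # small RDMs: one vectorized O(m^2) pass over all permutations
        permuted = np.empty((n_iter, xa.size))
        for i in range(n_iter):
            permuted[i] = b_aligned.permute(rng.permutation(a.n))
        null = kendall_tau_a_batch(permuted, xa)
    else:
        null = np.empty(n_iter)
        for i in range(n_iter):
            perm = rng.permutation(a.n)
            null[i] = kendall_tau_a(xa, b_aligned.permute(perm))
    p = (1 + int((null >= obs - 1e-12).sum())) / (1 + n_iter)
    return ModelComparisonResult(
        tau_a=obs, p=p, n_null=n_iter,
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)),
        seed=seed,
    )


def wilcoxon_signed_rank_one_sided(values: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank p for median > 0.

    Zeros are dropped before ranking.  For n <= 25 the exact sign-flip
    permutation distribution over midranks is enumerated (tie-exact);
    above that a normal approximation with tie and continuity corrections
    is used.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0 or (v == 0).all():
        raise ValueError("all values zero")
    v = v[v != 0]
    n = v.size
    if n < 5:
        raise ValueError(f"need >= 5 nonzero values, got {n}")
    ranks = stats.rankdata(np.abs(v))
    w_pos = ranks[v > 0].sum()
    if n <= 25:
        # exact null: W+ over all 2^n sign assignments, DP on doubled
        # midranks (integers since midranks are multiples of 1/2)
        dr = np.rint(2 * ranks).astype(int)
        counts = np.zeros(dr.sum() + 1, dtype=float)
        counts[0] = 1.0
        top = 0
        for r in dr:
            counts[r : top + r + 1] += counts[: top + 1].copy()
            top += r
        w2 = int(np.rint(2 * w_pos))
        return float(counts[w2:].sum() / 2.0**n)
    mu = n * (n + 1) / 4.0
    tie_adj = sum(c**3 - c for c in
                  np.unique(np.abs(v), return_counts=True)[1]) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_adj)
    z = (w_pos - mu - 0.5) / sigma
    return float(stats.norm.sf(z))


def tau_to_r(tau: float) -> float:
    """Convert Kendall tau-a to a Pearson-scale r: ``r = sin(pi/2 * tau)``."""
    tau = np.asarray(tau, dtype=float)
    if np.any(np.abs(tau) > 1):
        raise ValueError("|tau| must be <= 1")
    out = np.sin(0.5 * np.pi * tau)
    return float(out) if out.ndim == 0 else out


def fisher_z(r: float) -> float:
    """Fisher z transform ``atanh(r)``; errors at |r| = 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for Fisher z")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


@dataclass
class AnovaEffect:
    F: float
    df: tuple[int, int]
    p: float


def rm_anova_2x2(table: np.ndarray) -> dict[str, AnovaEffect]:
    """2x2 fully repeated-measures ANOVA from a subjects x 4 table.

    Column order: (model A, context 1), (model B, context 1),
    (model A, context 2), (model B, context 2).  For this design every
    effect has df (1, n-1) and equals the squared paired t of the
    corresponding within-subject contrast; the interaction contrast is the
    difference of model differences across contexts.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError("expected a subjects x 4 table")
    if not np.isfinite(x).all():
        raise ValueError("missing cells in ANOVA table")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need >= 3 subjects")

    def paired_f(contrast: np.ndarray) -> AnovaEffect:
        t = stats.ttest_1samp(contrast, 0.0)
        F = float(t.statistic**2)
        p = float(stats.f.sf(F, 1, n - 1))
        return AnovaEffect(F=F, df=(1, n - 1), p=p)

    a1, b1, a2, b2 = x.T
    return {
        "model": paired_f((a1 + a2) / 2 - (b1 + b2) / 2),
        "context": paired_f((a1 + b1) / 2 - (a2 + b2) / 2),
        "interaction": paired_f((a1 - b1) - (a2 - b2)),
    }


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values: ``min(1, p * m)``."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values outside [0, 1]")
    if m is None:
        m = p.size
    if m < 1 or m < p.size:
        raise ValueError("m must be >= number of p values")
    return np.minimum(1.0, p * m)


def critical_alpha(m: int, alpha: float = 0.05) -> float:
    """Bonferroni critical alpha ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class GroupFitResult:
    """Per-subject model fits and their group summary."""

    tau_per_subject: np.ndarray
    mean_tau: float
    p: float
    p_adjusted: float
    significant: bool
    comparison: str = ""


def group_model_fit(
    subject_rdms: list[RDM],
    model: RDM,
    m_comparisons: int = 1,
    alpha: float = 0.05,
    comparison: str = "",
) -> GroupFitResult:
    """Per-subject tau-a against a model RDM plus the group Wilcoxon test."""
    taus = np.array([kendall_tau_a(*aligned_vectors(s, model))
                     for s in subject_rdms])
    p = wilcoxon_signed_rank_one_sided(taus)
    p_adj = float(bonferroni([p], m_comparisons)[0])
    return GroupFitResult(
        tau_per_subject=taus,
        mean_tau=float(taus.mean()),
        p=p,
        p_adjusted=p_adj,
        significant=bool(p < critical_alpha(m_comparisons, alpha)),
        comparison=comparison,
    )
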