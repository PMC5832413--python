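"""Object-pattern estimation with per-run GLMs.

Each run is modeled with one regressor per object: a delta function at
stimulus onset convolved with a double-gamma hemodynamic response, plus an
intercept and any nuisance covariates.  Ordinary least squares yields per
voxel betas and t-statistics (``t = beta / SE``); t-patterns are averaged
across runs into a :class:`PatternSet` per task context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EVENT_COLUMNS = ["run", "context", "object", "onset", "duration"]
CONTEXTS = ("visual", "conceptual")

# canonical double-gamma shape (SPM-style): 6 s peak, 16 s undershoot, 1:6
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 1.0 / 6.0


def hrf_double_gamma(
    time_grid: np.ndarray,
    peak_delay: float = HRF_PEAK_DELAY,
    undershoot_delay: float = HRF_UNDERSHOOT_DELAY,
    peak_disp: float = HRF_PEAK_DISP,
    undershoot_disp: float = HRF_UNDERSHOOT_DISP,
    ratio: float = HRF_RATIO,
) -> np.ndarray:
    """Sample a double-gamma HRF on a uniform time grid starting at 0.

    The response is the difference of two gamma densities (peak minus a
    scaled undershoot), normalized to peak amplitude 1.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with >= 2 samples")
    steps = np.diff(t)
    if t[0] != 0 or not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
        raise ValueError("time grid must be uniform and start at 0")
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp,
                            scale=undershoot_disp)
    h = peak - ratio * under
    top = h.max()
    if top <= 0:
        raise ValueError("degenerate HRF: nonpositive peak")
    return h / top


def check_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    if (events["onset"] < 0).any():
        raise ValueError("negative onsets")
    bad_ctx = set(events["context"]) - set(CONTEXTS)
    if bad_ctx:
        raise ValueError(f"unknown contexts {sorted(bad_ctx)}")
    for run, grp in events.groupby("run"):
        onsets = grp["onset"].to_numpy()
        if not (np.diff(np.sort(onsets)) > 0).all():
            raise ValueError(f"onsets not strictly increasing in run {run}")
    return events


def build_design(
    events: pd.DataFrame,
    tr: float,
    n_volumes: int,
    oversample: int = 16,
    hrf_length: float = 32.0,
    hrf_kwargs: dict | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (volumes x regressors) for one run's events.

    One column per object (delta at onset convolved with the HRF on an
    oversampled grid, sampled at volume acquisition times) plus a trailing
    intercept column.  Returns ``(matrix, column_names)``.
    """
    if len(events) and events["run"].nunique() > 1:
        raise ValueError("build_design expects events from a single run")
    if len(events):
        check_events(events.assign(context=events.get("context", "visual")))
        if (events["onset"] >= n_volumes * tr).any():
            raise ValueError("event onset beyond scan end")
        dup = events.duplicated(subset=["object", "onset"])
        if dup.any():
            raise ValueError("overlapping identical-object events in one run")

    objects = sorted(events["object"].astype(str).unique()) if len(events) else []
    dt = tr / oversample
    n_fine = n_volumes * oversample + int(round(hrf_length / dt))
    hrf_grid = np.arange(0, hrf_length + dt / 2, dt)
    hrf = hrf_double_gamma(hrf_grid, **(hrf_kwargs or {}))

    cols = np.empty((n_volumes, len(objects) + 1))
    vol_idx = np.arange(n_volumes) * oversample
    for k, obj in enumerate(objects):
        stick = np.zeros(n_fine)
        for onset in events.loc[events["object"].astype(str) == obj, "onset"]:
            stick[int(round(onset / dt))] = 1.0
        conv = np.convolve(stick, hrf)[:n_fine]
        cols[:, k] = conv[vol_idx]
    cols[:, -1] = 1.0
    return cols, objects + ["intercept"]


@dataclass
class GLMResult:
    beta: np.ndarray  # (regressors, voxels)
    t: np.ndarray  # (regressors, voxels)
    dof: int
    column_names: list[str]

    def object_t(self, objects: list[str]) -> np.ndarray:
        idx = [self.column_names.index(o) for o in objects]
        return self.t[idx]

    def object_beta(self, objects: list[str]) -> np.ndarray:
        idx = [self.column_names.index(o) for o in objects]
        return self.beta[idx]


def estimate_patterns(
    data: np.ndarray,
    design: np.ndarray,
    column_names: list[str] | None = None,
    nuisance: np.ndarray | None = None,
) -> GLMResult:
    """Voxel-wise OLS: betas and t-statistics for every design column.

    ``data`` is volumes x voxels.  Nuisance covariates are appended to the
    design before fitting; their betas are estimated but typically ignored.
    Residual degrees of freedom are ``volumes - rank(design)``.
    """
    data = np.asarray(data, dtype=float)
    X = np.asarray(design, dtype=float)
    if column_names is None:
        column_names = [f"col{i}" for i in range(X.shape[1])]
    column_names = list(column_names)
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if not np.isfinite(nuisance).all():
            raise ValueError("non-finite nuisance covariates")
        if nuisance.shape[0] != X.shape[0]:
            raise ValueError("nuisance covariates do not match volume count")
        X = np.hstack([X, nuisance])
        column_names += [f"nuisance{i}" for i in range(nuisance.shape[1])]
    if data.shape[0] != X.shape[0]:
        raise ValueError("data volumes do not match design rows")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns for the error message
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep):
                bad.append(column_names[j])
            else:
                keep.append(j)
        raise ValueError(f"design rank deficient; collinear columns: {bad}")
    dof = X.shape[0] - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ data
    resid = data - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    return GLMResult(beta=beta, t=t, dof=dof, column_names=column_names)


@dataclass
class PatternSet:
    """Objects x voxels matrix of run-averaged t-values."""

    data: np.ndarray
    object_labels: list[str]
    subject: str = ""
    context: str = ""
    roi: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("pattern data must be objects x voxels")
        if self.data.shape[0] != len(self.object_labels):
            raise ValueError("object labels do not match pattern rows")
        if len(set(self.object_labels)) != len(self.object_labels):
            raise ValueError("duplicate object labels")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite pattern values")

    @property
    def n_objects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def subset(self, voxel_idx: np.ndarray) -> "PatternSet":
        return PatternSet(self.data[:, voxel_idx], list(self.object_labels),
                          self.subject, self.context, self.roi, dict(self.meta))


def average_runs(
    per_run: list[np.ndarray],
    object_labels: list[str],
    subject: str = "",
    context: str = "",
    roi: str = "",
) -> PatternSet:
    """Element-wise mean of per-run object x voxel t matrices."""
    if not per_run:
        raise ValueError("no runs to average")
    mats = [np.asarray(m, dtype=float) for m in per_run]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("mismatched pattern shapes across runs")
    if shape[0] != len(object_labels):
        raise ValueError("object labels do not match pattern rows")
    return PatternSet(np.mean(mats, axis=0), list(object_labels),
                      subject=subject, context=context, roi=roi,
                      meta={"n_runs": len(mats)})
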