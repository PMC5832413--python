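"""Loaders and recomputations for deposited supplementary source data.

The published study deposited small source-data files alongside its
figures: the three 40x40 model RDMs (behavior-based visual, behavior-based
conceptual, and word2vec), and per-participant coefficient tables.  None of
these ship with this package; when a copy is available, place it under a
directory (default ``data/supplementary`` at the repository root) using
the canonical file names below and every acceptance target becomes
recomputable:

* ``fig1_visual_rdm.csv``      — labeled 40x40 matrix (similarity or
  dissimilarity convention auto-detected from the diagonal)
* ``fig1_conceptual_rdm.csv``
* ``fig1_word2vec_rdm.csv``
* ``fig6_prc.tsv``             — 16 rows x 4 columns of tau-a:
  ``visual_task_visual_model``, ``visual_task_conceptual_model``,
  ``conceptual_task_visual_model``, ``conceptual_task_conceptual_model``
* ``fig7.tsv``                 — per-participant cross-context tau-a,
  one column per ROI (needs ``prc``)
* ``fig8.tsv``                 — per-participant within-object r, one
  column per ROI (needs ``prc`` and ``temporal_pole``)

Excel originals can be converted with any spreadsheet tool; only the
labeled-matrix / labeled-column structure matters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .inference import (fisher_z, kendall_tau_a, rm_anova_2x2, tau_to_r,
                        wilcoxon_signed_rank_one_sided)
from .io import read_rdm_csv, read_stat_table_tsv
from .rdm import RDM, aligned_vectors

DEFAULT_DIR = Path("data/supplementary")

FIG6_COLUMNS = ["visual_task_visual_model", "visual_task_conceptual_model",
                "conceptual_task_visual_model",
                "conceptual_task_conceptual_model"]


class SupplementaryDataMissing(FileNotFoundError):
    pass


def _require(path: Path) -> Path:
    if not path.exists():
        raise SupplementaryDataMissing(
            f"deposited supplementary file not available: {path}")
    return path


def load_model_rdm(data_dir: str | Path, which: str) -> RDM:
    """Load one of the deposited model RDMs (visual/conceptual/word2vec)."""
    path = _require(Path(data_dir) / f"fig1_{which}_rdm.csv")
    return read_rdm_csv(path)


def _find_label(rdm: RDM, token: str) -> str:
    hits = [l for l in rdm.labels if token.lower() in l.lower()]
    if len(hits) != 1:
        raise KeyError(f"could not uniquely match {token!r} in RDM labels")
    return hits[0]


def model_rdm_tau(data_dir: str | Path, a: str, b: str) -> float:
    """Tau-a between two deposited model RDMs on matched lower triangles."""
    ra = load_model_rdm(data_dir, a)
    rb = load_model_rdm(data_dir, b)
    return kendall_tau_a(*aligned_vectors(ra, rb))


def stored_similarity(data_dir: str | Path, which: str,
                      concept_a: str = "gun",
                      concept_b: str = "hairdryer") -> float:
    """Similarity between two concepts recovered from a stored RDM cell.

    The RDM reader already converts similarity-convention files; the cell
    holds ``1 - similarity``, so the similarity is ``1 - cell``.
    """
    rdm = load_model_rdm(data_dir, which)
    la = _find_label(rdm, concept_a)
    lb = _find_label(rdm, concept_b)
    return 1.0 - rdm.cell(la, lb)


def load_fig6_prc(data_dir: str | Path) -> pd.DataFrame:
    df = read_stat_table_tsv(_require(Path(data_dir) / "fig6_prc.tsv"))
    missing = [c for c in FIG6_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"fig6_prc.tsv missing columns {missing}")
    return df


def load_roi_column(data_dir: str | Path, filename: str, roi: str) -> np.ndarray:
    df = read_stat_table_tsv(_require(Path(data_dir) / filename))
    hits = [c for c in df.columns if roi.lower() in c.lower()]
    if len(hits) != 1:
        raise KeyError(f"could not uniquely match ROI {roi!r} in {filename}")
    return df[hits[0]].to_numpy(dtype=float)


def prc_group_mean_tau(data_dir: str | Path) -> tuple[float, float]:
    """Mean and Wilcoxon p for PRC visual-task RDMs vs the visual model."""
    col = load_fig6_prc(data_dir)["visual_task_visual_model"].to_numpy()
    return float(col.mean()), wilcoxon_signed_rank_one_sided(col)


def prc_cross_context_mean(data_dir: str | Path) -> float:
    return float(load_roi_column(data_dir, "fig7.tsv", "prc").mean())


def within_object_mean(data_dir: str | Path, roi: str) -> float:
    return float(load_roi_column(data_dir, "fig8.tsv", roi).mean())


def prc_interaction_f(data_dir: str | Path) -> float:
    """Interaction F of the 2x2 RM-ANOVA on transformed PRC coefficients.

    Each tau-a is converted via ``r = sin(pi/2 tau)`` then Fisher-z before
    the ANOVA, matching the reported analysis chain.
    """
    df = load_fig6_prc(data_dir)
    table = np.column_stack([
        fisher_z(tau_to_r(df[c].to_numpy(dtype=float))) for c in FIG6_COLUMNS])
    return rm_anova_2x2(table)["interaction"].F


def compute_targets(data_dir: str | Path) -> dict[str, dict]:
    """Recompute every supplementary acceptance target from the files.

    Raises :class:`SupplementaryDataMissing` per-target; callers decide
    whether to skip or fail.
    """
    d = Path(data_dir)
    out: dict[str, dict] = {}
    out["t1"] = {"value": model_rdm_tau(d, "visual", "conceptual"), "n": 780}
    out["t2"] = {"value": model_rdm_tau(d, "word2vec", "conceptual"), "n": 780}
    out["t3"] = {"value": model_rdm_tau(d, "word2vec", "visual"), "n": 780}
    out["t4"] = {"value": stored_similarity(d, "word2vec"), "n": 1}
    out["t5"] = {"value": stored_similarity(d, "conceptual"), "n": 1}
    out["t6"] = {"value": stored_similarity(d, "visual"), "n": 1}
    mean, _ = prc_group_mean_tau(d)
    out["t7"] = {"value": mean, "n": 16}
    out["t8"] = {"value": prc_cross_context_mean(d), "n": 16}
    out["t9"] = {"value": within_object_mean(d, "prc"), "n": 16}
    out["t10"] = {"value": within_object_mean(d, "temporal_pole"), "n": 16}
    out["t11"] = {"value": prc_interaction_f(d), "n": 16}
    return out
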