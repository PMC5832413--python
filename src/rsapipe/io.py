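"""Readers and writers for all pipeline formats.

Tabular data are TSV (long-format ratings and norms, wide embeddings,
BIDS-style events); RDMs are labeled CSV matrices; volumes are NIfTI via
nibabel with a JSON sidecar carrying object labels for 4-D pattern
stacks.  RDM files deposited as *similarity* matrices (unit diagonal) are
auto-detected and converted with ``1 - value``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import PatternSet
from .rdm import RDM

_ASYM_TOL = 1e-6


# ----------------------------------------------------------------------
# RDM CSV


def read_rdm_csv(
    path: str | Path,
    similarity: bool | None = None,
    measure: str = "unknown",
) -> RDM:
    """Load a labeled square matrix as an RDM.

    ``similarity=None`` auto-detects the convention from the diagonal: a
    unit diagonal means the file stores similarities and is converted via
    ``1 - value``; a zero diagonal is taken as dissimilarities.
    """
    df = pd.read_csv(path, index_col=0)
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix not square {m.shape}")
    labels = [str(x).strip() for x in df.index]
    col_labels = [str(x).strip() for x in df.columns]
    if labels != col_labels:
        raise ValueError(f"{path}: row and column labels differ")
    if np.max(np.abs(m - m.T)) > _ASYM_TOL:
        raise ValueError(f"{path}: asymmetric beyond {_ASYM_TOL}")
    diag = np.diag(m)
    if similarity is None:
        if np.allclose(diag, 1.0, atol=1e-6):
            similarity = True
        elif np.allclose(diag, 0.0, atol=1e-6):
            similarity = False
        else:
            raise ValueError(
                f"{path}: cannot auto-detect convention (diagonal neither 0 nor 1)")
    if similarity:
        m = 1.0 - m
    if np.max(np.abs(np.diag(m))) > _ASYM_TOL:
        raise ValueError(f"{path}: nonzero diagonal after conversion")
    np.fill_diagonal(m, 0.0)
    return RDM((m + m.T) / 2, labels, measure=measure,
               note=f"loaded from {Path(path).name}"
                    f"{' (similarity converted)' if similarity else ''}")


def write_rdm_csv(rdm: RDM, path: str | Path) -> None:
    df = pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels)
    df.to_csv(path, float_format="%.12g")


# ----------------------------------------------------------------------
# Tables


def read_ratings_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_catch"] = df["is_catch"].astype(bool)
    return df


def write_ratings_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_norms_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tags": str}).fillna({"tags": "none"})


def write_norms_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_embeddings_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_embeddings_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    """BIDS-style events (onset, duration, trial_type, run, context)."""
    df = pd.read_csv(path, sep="\t")
    if "trial_type" in df.columns and "object" not in df.columns:
        df = df.rename(columns={"trial_type": "object"})
    return df


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    out = events.rename(columns={"object": "trial_type"})
    cols = ["onset", "duration", "trial_type", "run", "context"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_stat_table_tsv(path: str | Path) -> pd.DataFrame:
    """Subjects-as-rows, comparisons-as-columns coefficient table."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_stat_table_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.12g")


# ----------------------------------------------------------------------
# Volumes


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data, affine = load_volume(path)
    return data > 0, affine


def save_patterns(ps: PatternSet, mask: np.ndarray, affine: np.ndarray,
                  path: str | Path) -> None:
    """Write a PatternSet as a 4-D stack (x, y, z, object) + JSON sidecar."""
    path = Path(path)
    vol = np.zeros(mask.shape + (ps.n_objects,))
    vol[mask] = ps.data.T
    save_volume(vol, affine, path)
    sidecar = {"object_labels": ps.object_labels, "subject": ps.subject,
               "context": ps.context, "roi": ps.roi}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_patterns(path: str | Path, mask: np.ndarray | None = None
                  ) -> tuple[PatternSet, np.ndarray]:
    path = Path(path)
    vol, affine = load_volume(path)
    side = json.loads(path.with_suffix(".json").read_text())
    if mask is None:
        mask = np.ones(vol.shape[:3], dtype=bool)
    data = vol[mask].T
    ps = PatternSet(data, side["object_labels"], subject=side.get("subject", ""),
                    context=side.get("context", ""), roi=side.get("roi", ""))
    return ps, affine
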