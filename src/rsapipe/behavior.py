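"""Behavior-based similarity models.

Builds three model RDMs from behavioral data tables:

* a visual RDM from pairwise Likert similarity ratings
  (``1 - min-max-normalized mean rating``),
* a conceptual RDM from feature-generation norms
  (``1 - cosine`` over production-count vectors after reliability and
  tag-based filtering),
* an embedding RDM from a table of precomputed word vectors
  (``1 - cosine``).

Rating and norm tables are long-format :class:`pandas.DataFrame` objects;
see :mod:`rsapipe.io` for the TSV layouts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rdm import RDM

log = logging.getLogger(__name__)

RATING_COLUMNS = ["rater_id", "concept_a", "concept_b", "likert", "is_catch"]
NORM_COLUMNS = ["concept", "feature", "producer_count", "tags"]

#: Likert scale: 1 = very dissimilar ... 5 = very similar.
LIKERT_MIN, LIKERT_MAX = 1, 5
#: "somewhat similar" on the 5-point scale.
DEFAULT_CATCH_THRESHOLD = 4

FEATURE_TAGS = {"visual_form", "color", "none"}


def _check_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATING_COLUMNS if c not in ratings.columns]
    if missing:
        raise ValueError(f"rating table missing columns {missing}")
    if len(ratings) == 0:
        raise ValueError("no ratings")
    likert = ratings["likert"].to_numpy()
    if not np.isin(likert, np.arange(LIKERT_MIN, LIKERT_MAX + 1)).all():
        raise ValueError("likert values outside 1..5")
    catch = ratings["is_catch"].astype(bool)
    same = ratings["concept_a"] == ratings["concept_b"]
    if (catch != same).any():
        raise ValueError("is_catch flag inconsistent with concept_a == concept_b")
    return ratings


def filter_raters(
    ratings: pd.DataFrame, min_catch_likert: int = DEFAULT_CATCH_THRESHOLD
) -> pd.DataFrame:
    """Drop all records of raters who under-rated any catch trial.

    A catch trial pairs a concept with itself; raters must rate every
    catch trial at or above ``min_catch_likert`` (default 4, "somewhat
    similar") to be retained.  Raters without catch records are retained
    and logged.
    """
    ratings = _check_ratings(ratings)
    catch = ratings[ratings["is_catch"].astype(bool)]
    no_catch = set(ratings["rater_id"]) - set(catch["rater_id"])
    if no_catch:
        log.warning("%d rater(s) have no catch trials; retained", len(no_catch))
    bad = set(catch.loc[catch["likert"] < min_catch_likert, "rater_id"])
    if bad:
        log.info("excluding %d rater(s) for failed catch trials", len(bad))
    return ratings[~ratings["rater_id"].isin(bad)].reset_index(drop=True)


def _canonical_pairs(ratings: pd.DataFrame) -> pd.DataFrame:
    a = ratings["concept_a"].astype(str)
    b = ratings["concept_b"].astype(str)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    out = ratings.copy()
    out["concept_a"] = lo
    out["concept_b"] = hi
    return out


def visual_rdm(ratings: pd.DataFrame) -> RDM:
    """Visual model RDM: ``1 - min-max-normalized mean rating`` per pair.

    Pair means are taken over raters (after :func:`filter_raters`), then
    min-max normalized to [0, 1] across the ``n(n-1)/2`` pair means, and
    converted to dissimilarity.
    """
    ratings = _check_ratings(ratings)
    ratings = ratings[~ratings["is_catch"].astype(bool)]
    if len(ratings) == 0:
        raise ValueError("no ratings")
    ratings = _canonical_pairs(ratings)
    means = ratings.groupby(["concept_a", "concept_b"])["likert"].mean()
    concepts = sorted(set(ratings["concept_a"]) | set(ratings["concept_b"]))
    n = len(concepts)
    expected = n * (n - 1) // 2
    if len(means) != expected:
        raise ValueError(
            f"expected all {expected} unordered pairs, found {len(means)}"
        )
    lo, hi = means.min(), means.max()
    if hi == lo:
        raise ValueError("degenerate normalization: all pair means identical")
    norm = (means - lo) / (hi - lo)
    idx = {c: k for k, c in enumerate(concepts)}
    m = np.zeros((n, n))
    for (ca, cb), v in norm.items():
        m[idx[ca], idx[cb]] = m[idx[cb], idx[ca]] = 1.0 - v
    return RDM(m, concepts, measure="one_minus_normalized_rating",
               note="visual similarity ratings, 1 - min-max normalized mean")


# ----------------------------------------------------------------------
# Feature norms


def canonicalize_feature(feature: str) -> str:
    """Case-fold, trim, and collapse internal whitespace (no stemming)."""
    return re.sub(r"\s+", " ", str(feature).strip()).casefold()


@dataclass
class ConceptFeatureMatrix:
    """Concepts x retained-features matrix of production counts."""

    counts: np.ndarray  # (n_concepts, n_features) nonnegative ints
    concepts: list[str]
    features: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.concepts), len(self.features)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative production counts")

    def vector(self, concept: str) -> np.ndarray:
        return self.counts[self.concepts.index(concept)]


def _check_norms(norms: pd.DataFrame, n_producers: int | None) -> pd.DataFrame:
    missing = [c for c in NORM_COLUMNS if c not in norms.columns]
    if missing:
        raise ValueError(f"feature norms missing columns {missing}")
    norms = norms.copy()
    norms["feature"] = norms["feature"].map(canonicalize_feature)
    counts = norms["producer_count"].to_numpy()
    if (counts <= 0).any():
        raise ValueError("producer_count must be positive")
    if n_producers is not None and (counts > n_producers).any():
        raise ValueError(f"producer_count exceeds n_producers={n_producers}")
    # canonicalization may merge spelling variants of the same feature
    merged = (
        norms.groupby(["concept", "feature"], sort=False)
        .agg(producer_count=("producer_count", "max"), tags=("tags", "first"))
        .reset_index()
    )
    if len(merged) != len(norms):
        log.info("canonicalization merged %d duplicate (concept, feature) rows",
                 len(norms) - len(merged))
    return merged


def _parse_tags(tags) -> set[str]:
    if isinstance(tags, str):
        parsed = {t.strip() for t in tags.split(",") if t.strip()}
    elif tags is None or (isinstance(tags, float) and np.isnan(tags)):
        parsed = set()
    else:
        parsed = set(tags)
    parsed.discard("none")
    unknown = parsed - FEATURE_TAGS
    if unknown:
        raise ValueError(f"unknown feature tags {sorted(unknown)}")
    return parsed


def filter_features(
    norms: pd.DataFrame,
    min_count: int = 4,
    exclude_tags: set[str] = frozenset({"visual_form", "color"}),
    n_producers: int | None = 20,
) -> ConceptFeatureMatrix:
    """Reliability- and tag-filter feature norms into a count matrix.

    Drops (concept, feature) entries produced by fewer than ``min_count``
    participants, then drops every feature carrying a tag in
    ``exclude_tags``.  Errors if any concept loses all its features.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    exclude_tags = set(exclude_tags)
    norms = _check_norms(norms, n_producers)
    concepts = sorted(norms["concept"].astype(str).unique())

    kept = norms[norms["producer_count"] >= min_count]
    if exclude_tags:
        tag_sets = kept["tags"].map(_parse_tags)
        excluded_features = set(kept.loc[
            tag_sets.map(lambda s: bool(s & exclude_tags)), "feature"])
        if excluded_features:
            log.info("excluding %d tagged feature(s)", len(excluded_features))
        kept = kept[~kept["feature"].isin(excluded_features)]

    surviving = set(kept["concept"])
    dead = [c for c in concepts if c not in surviving]
    if dead:
        raise ValueError(f"concept(s) with zero surviving features: {dead}")

    features = sorted(kept["feature"].unique())
    fidx = {f: k for k, f in enumerate(features)}
    cidx = {c: k for k, c in enumerate(concepts)}
    counts = np.zeros((len(concepts), len(features)), dtype=int)
    for row in kept.itertuples(index=False):
        counts[cidx[str(row.concept)], fidx[row.feature]] = row.producer_count
    return ConceptFeatureMatrix(counts, concepts, features)


def _cosine_rdm(vectors: np.ndarray, labels: list[str], note: str) -> RDM:
    norms = np.linalg.norm(vectors, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(f"zero-norm vector(s) for {[labels[i] for i in zero]}")
    unit = vectors / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    m = 1.0 - cos
    np.fill_diagonal(m, 0.0)
    return RDM(m, labels, measure="one_minus_cosine", note=note)


def conceptual_rdm(matrix: ConceptFeatureMatrix) -> RDM:
    """Conceptual model RDM: ``1 - cosine`` over production-count vectors."""
    return _cosine_rdm(matrix.counts.astype(float), list(matrix.concepts),
                       "feature norms, 1 - cosine of production counts")


def embedding_rdm(table: pd.DataFrame, concepts: list[str] | None = None) -> RDM:
    """Embedding model RDM: ``1 - cosine`` between word vectors.

    ``table`` maps concept labels (index) to fixed-length vectors (columns).
    """
    if concepts is None:
        concepts = [str(c) for c in table.index]
    missing = [c for c in concepts if c not in table.index]
    if missing:
        raise KeyError(f"concepts missing from embedding table: {missing}")
    vectors = table.loc[concepts].to_numpy(dtype=float)
    if not np.isfinite(vectors).all():
        raise ValueError("non-finite embedding components")
    return _cosine_rdm(vectors, list(concepts), "word embeddings, 1 - cosine")
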