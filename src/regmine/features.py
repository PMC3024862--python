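"""Per-pair features relating a TF profile to a candidate target profile.

Five feature groups are computed for each directed TF->TG pair:

* PCC — Pearson correlation of the two profiles.
* ELD — "expression level differences" distance: each profile is mapped to
  the point (lower quartile, upper quartile) and the Euclidean distance
  between the two points is taken. It captures how differently the two
  genes' expression ranges are placed, independent of their correlation.
* dmean / dsd — absolute differences of profile means and sample standard
  deviations.
* Quadrant vector analysis — each measurement t yields the sub-vector
  (tf[t], tg[t]) in the TF-TG expression plane; sub-vectors are summed per
  quadrant and the per-quadrant sum with the largest modulus is the pair's
  main vector, reported as (modulus |x|, angle theta in degrees). Summing
  per quadrant keeps time-shifted or inverted patterns from cancelling the
  way a single global sum would.
* GO co-annotation score — depth-weighted credit for GO terms shared by the
  two genes, with a correction removing duplicated credit below divergent
  shared ancestors.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import DataError, ExpressionMatrix, GenePair, GOAnnotationSet

#: column order of the tabular feature representation
FEATURE_COLUMNS = [
    "tf",
    "tg",
    "pcc",
    "pcc_defined",
    "eld",
    "dmean",
    "dsd",
    "modulus",
    "angle",
    "vector_defined",
    "go_score",
    "go_available",
]


@dataclass(frozen=True)
class FeatureVector:
    """All per-pair feature values plus definedness flags.

    ``pcc`` is 0 with ``pcc_defined`` False when either profile is constant;
    ``angle`` is the sentinel 0 with ``vector_defined`` False when every
    sub-vector is zero; ``go_score`` is 0 with ``go_available`` False when
    either gene carries no GO annotation.
    """

    pcc: float
    pcc_defined: bool
    eld: float
    dmean: float
    dsd: float
    modulus: float
    angle: float
    vector_defined: bool
    go_score: float = 0.0
    go_available: bool = False


@dataclass(frozen=True)
class QuadrantVector:
    """A per-quadrant sum vector in the TF-TG expression plane."""

    quadrant: int
    components: tuple[float, float]

    @property
    def modulus(self) -> float:
        return math.hypot(*self.components)


def _as_profiles(x, y, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("profiles must be equal-length 1-D vectors")
    if x.size < min_len:
        raise ValueError(f"profiles need at least {min_len} measurements")
    return x, y


def pcc(tf_profile, tg_profile) -> float:
    """Pearson correlation; NaN (undefined) when a profile is constant."""
    x, y = _as_profiles(tf_profile, tg_profile, 3)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return math.nan
    return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))


def eld(tf_profile, tg_profile) -> float:
    """Distance between the (Q1, Q3) quartile points of the two profiles.

    Quartiles use linear interpolation (numpy's default, "type 7").
    """
    x, y = _as_profiles(tf_profile, tg_profile, 4)
    qx = np.quantile(x, [0.25, 0.75])
    qy = np.quantile(y, [0.25, 0.75])
    return float(math.hypot(qx[0] - qy[0], qx[1] - qy[1]))


def mean_sd_diff(tf_profile, tg_profile) -> tuple[float, float]:
    """(|mean(tf)-mean(tg)|, |sd(tf)-sd(tg)|) with sample (n-1) sd."""
    x, y = _as_profiles(tf_profile, tg_profile, 2)
    dmean = abs(float(np.mean(x)) - float(np.mean(y)))
    dsd = abs(float(np.std(x, ddof=1)) - float(np.std(y, ddof=1)))
    return dmean, dsd


def quadrant_of(x: float, y: float) -> int:
    """Quadrant of a point; axis points go to the lower-indexed neighbour.

    Positive x-axis and positive y-axis -> Q1, negative x-axis -> Q2,
    negative y-axis -> Q3, the origin -> Q1.
    """
    if x > 0 and y > 0:
        return 1
    if x < 0 and y > 0:
        return 2
    if x < 0 and y < 0:
        return 3
    if x > 0 and y < 0:
        return 4
    if y == 0 and x > 0:
        return 1
    if x == 0 and y > 0:
        return 1
    if y == 0 and x < 0:
        return 2
    if x == 0 and y < 0:
        return 3
    return 1  # origin


def quadrant_sum_vectors(tf_profile, tg_profile) -> list[QuadrantVector]:
    """Per-quadrant sums of the measurement sub-vectors (tf[t], tg[t])."""
    x, y = _as_profiles(tf_profile, tg_profile, 1)
    sums = {q: np.zeros(2) for q in (1, 2, 3, 4)}
    for xt, yt in zip(x, y):
        sums[quadrant_of(xt, yt)] += (xt, yt)
    return [
        QuadrantVector(q, (float(v[0]), float(v[1]))) for q, v in sums.items()
    ]


def quadrant_main_vector(tf_profile, tg_profile) -> tuple[float, float, bool]:
    """Main representative vector of a pair: (modulus, angle_deg, defined).

    The per-quadrant sum with the largest modulus wins; modulus ties break
    toward the lowest quadrant index. The angle is in degrees in [0, 360).
    When every sub-vector is zero the result is (0, 0, False).
    """
    best = max(
        quadrant_sum_vectors(tf_profile, tg_profile),
        key=lambda v: (v.modulus, -v.quadrant),
    )
    if best.modulus == 0.0:
        return 0.0, 0.0, False
    angle = math.degrees(math.atan2(best.components[1], best.components[0])) % 360.0
    return best.modulus, angle, True


def go_coannotation_score(
    tf_id: str, tg_id: str, go: GOAnnotationSet
) -> tuple[float, bool]:
    """Depth-weighted shared-annotation score of a gene pair.

    Annotations are propagated to all ancestors, the shared term set C is
    intersected, and within the sub-DAG induced by C each leaf contributes
    its grade while every divergent node d with k >= 2 children in C is
    penalised by (k-1)*grade(d), removing the credit duplicated below a
    common parent. The score is floored at 0. ``available`` is False when
    either gene carries no annotation at all.
    """
    tf_terms = go.annotation_closure(tf_id)
    tg_terms = go.annotation_closure(tg_id)
    if not tf_terms or not tg_terms:
        return 0.0, False
    shared = tf_terms & tg_terms
    if not shared:
        return 0.0, True
    n_children = dict.fromkeys(shared, 0)
    for term in shared:
        for parent in go.term_parents.get(term, ()):
            if parent in shared:
                n_children[parent] += 1
    score = 0.0
    for term in shared:
        k = n_children[term]
        if k == 0:
            score += go.term_grade[term]
        elif k >= 2:
            score -= (k - 1) * go.term_grade[term]
    return max(score, 0.0), True


def pair_features(
    matrix: ExpressionMatrix,
    pair: GenePair,
    go: Optional[GOAnnotationSet] = None,
) -> FeatureVector:
    """Compute the full feature vector for one pair."""
    x = matrix.profile(pair.tf_id)
    y = matrix.profile(pair.tg_id)
    r = pcc(x, y)
    pcc_defined = math.isfinite(r)
    dmean, dsd = mean_sd_diff(x, y)
    modulus, angle, vector_defined = quadrant_main_vector(x, y)
    if go is not None:
        go_score, go_available = go_coannotation_score(pair.tf_id, pair.tg_id, go)
    else:
        go_score, go_available = 0.0, False
    return FeatureVector(
        pcc=r if pcc_defined else 0.0,
        pcc_defined=pcc_defined,
        eld=eld(x, y),
        dmean=dmean,
        dsd=dsd,
        modulus=modulus,
        angle=angle,
        vector_defined=vector_defined,
        go_score=go_score,
        go_available=go_available,
    )


def feature_table(
    matrix: ExpressionMatrix,
    pairs: Sequence[GenePair],
    go: Optional[GOAnnotationSet] = None,
) -> list[tuple[GenePair, FeatureVector]]:
    """One FeatureVector per pair; pairs with unknown genes are skipped.

    Skipped pairs are reported through a warning; if every pair is skipped a
    DataError is raised.
    """
    rows: list[tuple[GenePair, FeatureVector]] = []
    skipped: list[GenePair] = []
    for pair in pairs:
        if pair.tf_id not in matrix or pair.tg_id not in matrix:
            skipped.append(pair)
            continue
        rows.append((pair, pair_features(matrix, pair, go)))
    if skipped:
        names = ", ".join(f"{p.tf_id}->{p.tg_id}" for p in skipped[:5])
        warnings.warn(
            f"skipped {len(skipped)} pair(s) with genes absent from the "
            f"matrix (e.g. {names})",
            stacklevel=2,
        )
    if not rows:
        raise DataError("all pairs were skipped: no genes found in the matrix")
    return rows


def feature_frame(
    matrix: ExpressionMatrix,
    pairs: Sequence[GenePair],
    go: Optional[GOAnnotationSet] = None,
) -> pd.DataFrame:
    """Tabular form of :func:`feature_table` with a ``label`` column.

    ``label`` is 1 for positive pairs, 0 for negative pairs and NaN for
    unlabeled pairs.
    """
    rows = feature_table(matrix, pairs, go)
    label_map = {"positive": 1.0, "negative": 0.0, None: math.nan}
    data = {
        "tf": [p.tf_id for p, _ in rows],
        "tg": [p.tg_id for p, _ in rows],
        "pcc": [fv.pcc for _, fv in rows],
        "pcc_defined": [fv.pcc_defined for _, fv in rows],
        "eld": [fv.eld for _, fv in rows],
        "dmean": [fv.dmean for _, fv in rows],
        "dsd": [fv.dsd for _, fv in rows],
        "modulus": [fv.modulus for _, fv in rows],
        "angle": [fv.angle for _, fv in rows],
        "vector_defined": [fv.vector_defined for _, fv in rows],
        "go_score": [fv.go_score for _, fv in rows],
        "go_available": [fv.go_available for _, fv in rows],
        "label": [label_map[p.label] for p, _ in rows],
    }
    return pd.DataFrame(data)


def frame_row_to_vector(row: pd.Series) -> FeatureVector:
    """Rebuild a FeatureVector from one feature-frame row."""
    return FeatureVector(
        pcc=float(row["pcc"]),
        pcc_defined=bool(row["pcc_defined"]),
        eld=float(row["eld"]),
        dmean=float(row["dmean"]),
        dsd=float(row["dsd"]),
        modulus=float(row["modulus"]),
        angle=float(row["angle"]),
        vector_defined=bool(row["vector_defined"]),
        go_score=float(row["go_score"]),
        go_available=bool(row["go_available"]),
    )
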