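"""Multi-rater annotation fusion: the evaluator weighted estimator (EWE).

Raters of heterogeneous reliability each assign arousal and valence values
per instance, either on a continuous [-1, 1] slider or on a discrete
five-point {-2, -1, 0, 1, 2} scale.  The fused gold standard is a weighted
mean rating, the weight of rater k being their confidence r_k — the Pearson
correlation of rater k's ratings with the across-rater mean rating — with
the weights normalized to sum to one:

    y_EWE,n = (1 / sum_k r_k) * sum_k r_k * y_{n,k}

Negative confidences are clamped to zero before normalization so the EWE
stays inside the convex hull of the ratings.  Missing ratings exclude the
rater instance-wise, with per-instance weight renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FIVE_POINT = "five_point"
CONTINUOUS = "continuous"

DIMENSIONS = ("arousal", "valence")


@dataclass
class RatingMatrix:
    """Instances x raters ratings for one affect dimension."""

    values: np.ndarray          # NaN marks a missing rating
    scale: str = CONTINUOUS
    rater_ids: list[str] | None = None
    instance_ids: list[str] | None = None
    dimension: str = "arousal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("ratings must be instances x raters with K >= 1")
        if self.rater_ids is None:
            self.rater_ids = [f"rater_{k}" for k in range(self.values.shape[1])]
        if self.instance_ids is None:
            self.instance_ids = [f"inst_{n}" for n in range(self.values.shape[0])]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


@dataclass
class GoldStandard:
    ewe: np.ndarray
    rater_confidence: np.ndarray
    instance_ids: list[str]
    rater_ids: list[str]
    dimension: str = "arousal"

    @property
    def mean_agreement(self) -> float:
        return float(np.mean(self.rater_confidence))


def map_scale(matrix: RatingMatrix) -> RatingMatrix:
    """Map ratings onto [-1, 1]; five-point {-2..2} maps linearly to
    {-1, -0.5, 0, 0.5, 1}, continuous values pass through."""
    v = matrix.values
    if matrix.scale == CONTINUOUS:
        bad = np.abs(v) > 1.0 + 1e-9
    elif matrix.scale == FIVE_POINT:
        bad = ~(np.isin(v, [-2, -1, 0, 1, 2]) | np.isnan(v))
    else:
        raise ValueError(f"unknown scale {matrix.scale!r}")
    if np.any(bad & ~np.isnan(v)):
        n, k = np.argwhere(bad & ~np.isnan(v))[0]
        raise ValueError(
            f"out-of-scale rating {v[n, k]!r} (instance "
            f"{matrix.instance_ids[n]!r}, rater {matrix.rater_ids[k]!r})")
    mapped = v / 2.0 if matrix.scale == FIVE_POINT else v
    return RatingMatrix(mapped, CONTINUOUS, matrix.rater_ids,
                        matrix.instance_ids, matrix.dimension)


def rater_confidence(matrix: RatingMatrix) -> np.ndarray:
    """Pearson correlation of each rater's column with the across-rater
    mean column.  Degenerate raters (zero variance, or a constant mean
    column) get confidence 0 with a warning."""
    v = matrix.values
    if matrix.n_raters < 2:
        return np.ones(1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_col = np.nanmean(v, axis=1)
    conf = np.zeros(matrix.n_raters)
    for k in range(matrix.n_raters):
        col = v[:, k]
        ok = np.isfinite(col) & np.isfinite(mean_col)
        if ok.sum() < 2 or np.std(col[ok]) == 0 or np.std(mean_col[ok]) == 0:
            warnings.warn(
                f"rater {matrix.rater_ids[k]!r}: degenerate ratings, "
                "confidence set to 0")
            continue
        conf[k] = np.corrcoef(col[ok], mean_col[ok])[0, 1]
    return conf


def ewe(matrix: RatingMatrix, confidence: np.ndarray | None = None
        ) -> GoldStandard:
    """Confidence-weighted mean rating per instance."""
    if confidence is None:
        confidence = rater_confidence(matrix)
    conf = np.maximum(np.asarray(confidence, dtype=float), 0.0)
    if conf.sum() <= 0:
        raise ValueError("no rater with positive confidence")
    v = matrix.values
    w = np.where(np.isfinite(v), conf[None, :], 0.0)
    wsum = w.sum(axis=1)
    if np.any(wsum <= 0):
        raise ValueError("instance with no usable rating")
    fused = np.nansum(np.where(np.isfinite(v), v, 0.0) * w, axis=1) / wsum
    return GoldStandard(fused, conf, list(matrix.instance_ids),
                        list(matrix.rater_ids), matrix.dimension)


def bin_2d(valence: np.ndarray, arousal: np.ndarray, bins: int = 5
           ) -> np.ndarray:
    """Instance counts over the valence-arousal plane, equal-width bins on
    [-1, 1]; the boundary value +1 falls in the top bin."""
    edges = np.linspace(-1.0, 1.0, bins + 1)
    counts, _, _ = np.histogram2d(valence, arousal, bins=(edges, edges))
    return counts.astype(int)


# ---------------------------------------------------------------------------
# CSV interface: long table (instance_id, rater_id, arousal, valence)

def ratings_from_frame(df: pd.DataFrame, dimension: str,
                       scale: str = CONTINUOUS) -> RatingMatrix:
    if dimension not in DIMENSIONS:
        raise ValueError(f"dimension must be one of {DIMENSIONS}")
    wide = df.pivot_table(index="instance_id", columns="rater_id",
                          values=dimension, aggfunc="first", sort=True)
    return RatingMatrix(wide.to_numpy(dtype=float), scale,
                        [str(c) for c in wide.columns],
                        [str(i) for i in wide.index], dimension)


def load_ratings_csv(path, dimension: str, scale: str = CONTINUOUS
                     ) -> RatingMatrix:
    return ratings_from_frame(pd.read_csv(path), dimension, scale)


def gold_to_frame(arousal: GoldStandard, valence: GoldStandard) -> pd.DataFrame:
    if arousal.instance_ids != valence.instance_ids:
        raise ValueError("arousal/valence instance ids differ")
    return pd.DataFrame({
        "instance_id": arousal.instance_ids,
        "arousal_ewe": arousal.ewe,
        "valence_ewe": valence.ewe,
    })


def agreement_report(golds: dict[str, GoldStandard]) -> dict:
    """Per-dimension per-rater confidences and their mean."""
    return {
        dim: {
            "rater_confidence": dict(zip(g.rater_ids,
                                         np.round(g.rater_confidence, 4))),
            "mean_agreement": round(g.mean_agreement, 4),
        }
        for dim, g in golds.items()
    }
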