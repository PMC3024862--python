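"""Likelihood-ratio tables and their naive-Bayes integration.

For each feature group the values observed on gold-standard positive
(known regulatory) and negative (non-regulatory) pairs are binned on
equal-frequency (quantile) edges of the pooled data, and each bin's
likelihood ratio is the smoothed relative frequency among positives over
that among negatives:

    lr[b] = ((pos[b] + c) / (sum(pos) + B*c)) / ((neg[b] + c) / (sum(neg) + B*c))

with B bins and additive pseudocount c. Paired features use a 2-D joint
table, which sidesteps any independence argument within a pair. The four
groups {PCC, ELD}, {dmean, dsd}, {|x|, theta} and {GO score} are combined
under the naive-Bayes rule

    O_post = O_prior * prod_g LR_g

where O_prior is the prior odds of a candidate pair being regulatory
(#positives / #negatives of the training universe by default).
"""
from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .features import FeatureVector

MODEL_FORMAT = "regmine-bayes-1"

#: feature groups: name -> (feature columns, definedness flag column or None)
FEATURE_GROUPS: dict[str, tuple[tuple[str, ...], Optional[str]]] = {
    "pcc_eld": (("pcc", "eld"), "pcc_defined"),
    "dmean_dsd": (("dmean", "dsd"), None),
    "modulus_angle": (("modulus", "angle"), "vector_defined"),
    "go": (("go_score",), "go_available"),
}


@dataclass
class LRTable:
    """A 1-D binned likelihood-ratio table."""

    feature_name: str
    bin_edges: np.ndarray  # length B+1, sorted
    pos_counts: np.ndarray  # length B
    neg_counts: np.ndarray
    lr: np.ndarray
    pseudocount: float

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


@dataclass
class JointLRTable:
    """A 2-D joint likelihood-ratio table for a paired feature group."""

    feature_names: tuple[str, str]
    edges_x: np.ndarray
    edges_y: np.ndarray
    pos_counts: np.ndarray  # (Bx, By)
    neg_counts: np.ndarray
    lr: np.ndarray
    pseudocount: float


@dataclass
class BayesModel:
    """Prior odds plus the fitted LR tables of the feature groups."""

    prior_odds: float
    tables: dict[str, Union[LRTable, JointLRTable]]
    lr_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.prior_odds <= 0:
            raise ValueError("prior_odds must be positive")
        if self.lr_cutoff <= 0:
            raise ValueError("lr_cutoff must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Binning, smoothing and prior settings for model training."""

    n_bins_1d: int = 10
    n_bins_2d: int = 6
    pseudocount: float = 1.0
    prior_odds: Optional[float] = None  # default #pos/#neg of the universe
    lr_cutoff: float = 1.0


def _quantile_edges(values: np.ndarray, n_bins: int, what: str) -> np.ndarray:
    """Equal-frequency edges of the pooled values; duplicates collapse bins."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(values, qs))
    if len(edges) < 3:
        # a single bin carries no information; callers treat this as constant
        raise ValueError(f"{what}: too few distinct values to form 2 bins")
    if len(edges) < n_bins + 1:
        warnings.warn(
            f"{what}: only {len(edges) - 1} distinct bins available "
            f"(requested {n_bins})",
            stacklevel=3,
        )
    return edges


def _bin_index(edges: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Half-open [lo, hi) bins, last bin closed, out-of-range clamped."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def _smoothed_lr(
    pos: np.ndarray, neg: np.ndarray, pseudocount: float
) -> np.ndarray:
    b = pos.size
    p = (pos + pseudocount) / (pos.sum() + b * pseudocount)
    q = (neg + pseudocount) / (neg.sum() + b * pseudocount)
    return p / q


def fit_lr_table_1d(
    pos_values,
    neg_values,
    n_bins: int = 10,
    pseudocount: float = 1.0,
    feature_name: str = "",
) -> LRTable:
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("positive and negative value vectors must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    edges = _quantile_edges(
        np.concatenate([pos, neg]), n_bins, feature_name or "feature"
    )
    b = len(edges) - 1
    pos_counts = np.bincount(_bin_index(edges, pos), minlength=b)
    neg_counts = np.bincount(_bin_index(edges, neg), minlength=b)
    return LRTable(
        feature_name=feature_name,
        bin_edges=edges,
        pos_counts=pos_counts,
        neg_counts=neg_counts,
        lr=_smoothed_lr(pos_counts, neg_counts, pseudocount),
        pseudocount=pseudocount,
    )


def fit_lr_table_2d(
    pos_xy,
    neg_xy,
    n_bins_x: int = 6,
    n_bins_y: int = 6,
    pseudocount: float = 1.0,
    feature_names: tuple[str, str] = ("x", "y"),
) -> JointLRTable:
    pos = np.asarray(pos_xy, dtype=float).reshape(-1, 2)
    neg = np.asarray(neg_xy, dtype=float).reshape(-1, 2)
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValueError("positive and negative samples must be non-empty")
    if n_bins_x < 2 or n_bins_y < 2:
        raise ValueError("per-axis bin counts must be >= 2")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    pooled = np.concatenate([pos, neg])
    edges_x = _quantile_edges(pooled[:, 0], n_bins_x, feature_names[0])
    edges_y = _quantile_edges(pooled[:, 1], n_bins_y, feature_names[1])
    bx, by = len(edges_x) - 1, len(edges_y) - 1

    def _counts(samples: np.ndarray) -> np.ndarray:
        ix = _bin_index(edges_x, samples[:, 0])
        iy = _bin_index(edges_y, samples[:, 1])
        flat = np.bincount(ix * by + iy, minlength=bx * by)
        return flat.reshape(bx, by)

    pos_counts = _counts(pos)
    neg_counts = _counts(neg)
    return JointLRTable(
        feature_names=feature_names,
        edges_x=edges_x,
        edges_y=edges_y,
        pos_counts=pos_counts,
        neg_counts=neg_counts,
        lr=_smoothed_lr(pos_counts, neg_counts, pseudocount),
        pseudocount=pseudocount,
    )


def lookup_lr(table: Union[LRTable, JointLRTable], value) -> float:
    """LR of the bin containing ``value``; flagged-undefined values give 1.

    A value of None, or containing NaN, is treated as an undefined feature
    and returns the non-informative ratio 1.0.
    """
    if value is None:
        return 1.0
    if isinstance(table, LRTable):
        v = float(value)
        if math.isnan(v):
            return 1.0
        return float(table.lr[_bin_index(table.bin_edges, np.array([v]))[0]])
    x, y = (float(value[0]), float(value[1]))
    if math.isnan(x) or math.isnan(y):
        return 1.0
    ix = _bin_index(table.edges_x, np.array([x]))[0]
    iy = _bin_index(table.edges_y, np.array([y]))[0]
    return float(table.lr[ix, iy])


def _group_mask(frame: pd.DataFrame, group: str) -> np.ndarray:
    flag = FEATURE_GROUPS[group][1]
    if flag is None:
        return np.ones(len(frame), dtype=bool)
    return frame[flag].to_numpy(dtype=bool)


def train_model(
    features: pd.DataFrame,
    config: TrainConfig = TrainConfig(),
    go_present: bool = True,
) -> BayesModel:
    """Fit the feature-group LR tables from a labeled feature frame.

    ``features`` must carry the columns of features.FEATURE_COLUMNS plus a
    binary ``label`` column (1 = positive, 0 = negative). Groups whose
    feature is constant across all training pairs are skipped with a
    warning; the GO table is omitted when ``go_present`` is False.
    """
    labels = features["label"].to_numpy(dtype=float)
    if np.isnan(labels).any():
        raise ValueError("training requires a fully labeled feature frame")
    pos_mask = labels == 1.0
    neg_mask = labels == 0.0
    n_pos, n_neg = int(pos_mask.sum()), int(neg_mask.sum())
    if n_pos < 10 or n_neg < 10:
        raise ValueError(
            f"need >= 10 positives and >= 10 negatives (got {n_pos}/{n_neg})"
        )
    tables: dict[str, Union[LRTable, JointLRTable]] = {}
    for group, (cols, _flag) in FEATURE_GROUPS.items():
        if group == "go" and not go_present:
            continue
        defined = _group_mask(features, group)
        pos_rows = features.loc[pos_mask & defined, list(cols)].to_numpy(float)
        neg_rows = features.loc[neg_mask & defined, list(cols)].to_numpy(float)
        if pos_rows.shape[0] == 0 or neg_rows.shape[0] == 0:
            warnings.warn(
                f"group {group}: no defined training values; table skipped",
                stacklevel=2,
            )
            continue
        try:
            if len(cols) == 1:
                tables[group] = fit_lr_table_1d(
                    pos_rows[:, 0],
                    neg_rows[:, 0],
                    n_bins=config.n_bins_1d,
                    pseudocount=config.pseudocount,
                    feature_name=cols[0],
                )
            else:
                tables[group] = fit_lr_table_2d(
                    pos_rows,
                    neg_rows,
                    n_bins_x=config.n_bins_2d,
                    n_bins_y=config.n_bins_2d,
                    pseudocount=config.pseudocount,
                    feature_names=(cols[0], cols[1]),
                )
        except ValueError as exc:
            warnings.warn(f"group {group}: {exc}; table skipped", stacklevel=2)
    if not tables:
        raise ValueError("no feature group could be fitted")
    prior = config.prior_odds if config.prior_odds is not None else n_pos / n_neg
    return BayesModel(prior_odds=prior, tables=tables, lr_cutoff=config.lr_cutoff)


def _group_value(fv: FeatureVector, group: str):
    """Feature-group value of a vector, or None when flagged undefined."""
    if group == "pcc_eld":
        return (fv.pcc, fv.eld) if fv.pcc_defined else None
    if group == "dmean_dsd":
        return (fv.dmean, fv.dsd)
    if group == "modulus_angle":
        return (fv.modulus, fv.angle) if fv.vector_defined else None
    if group == "go":
        return fv.go_score if fv.go_available else None
    raise KeyError(group)


def group_lrs(model: BayesModel, fv: FeatureVector) -> dict[str, float]:
    """Per-group likelihood ratios for one feature vector."""
    return {
        group: lookup_lr(table, _group_value(fv, group))
        for group, table in model.tables.items()
    }


def total_lr(model: BayesModel, fv: FeatureVector) -> float:
    """Product of the group LRs (the posterior/prior odds ratio)."""
    out = 1.0
    for lr in group_lrs(model, fv).values():
        out *= lr
    return out


def posterior_odds(model: BayesModel, fv: FeatureVector) -> float:
    """O_post = O_prior * prod_g LR_g."""
    return model.prior_odds * total_lr(model, fv)


def classify(model: BayesModel, fv: FeatureVector) -> tuple[float, bool]:
    """(total LR score, positive call at score >= lr_cutoff)."""
    score = total_lr(model, fv)
    return score, score >= model.lr_cutoff


def score_frame(
    model: BayesModel, features: pd.DataFrame, groups: Optional[list[str]] = None
) -> np.ndarray:
    """Vectorized total LR over a feature frame (optionally a group subset)."""
    selected = groups if groups is not None else list(model.tables)
    out = np.ones(len(features))
    for group in selected:
        table = model.tables[group]
        cols = FEATURE_GROUPS[group][0]
        defined = _group_mask(features, group)
        vals = features[list(cols)].to_numpy(float)
        lr = np.ones(len(features))
        if isinstance(table, LRTable):
            lr[defined] = table.lr[_bin_index(table.bin_edges, vals[defined, 0])]
        else:
            ix = _bin_index(table.edges_x, vals[defined, 0])
            iy = _bin_index(table.edges_y, vals[defined, 1])
            lr[defined] = table.lr[ix, iy]
        out *= lr
    return out


# ---------------------------------------------------------------------------
# serialization

def _table_to_json(table: Union[LRTable, JointLRTable]) -> dict:
    if isinstance(table, LRTable):
        return {
            "kind": "1d",
            "feature_name": table.feature_name,
            "bin_edges": table.bin_edges.tolist(),
            "pos_counts": table.pos_counts.tolist(),
            "neg_counts": table.neg_counts.tolist(),
            "lr": table.lr.tolist(),
            "pseudocount": table.pseudocount,
        }
    return {
        "kind": "2d",
        "feature_names": list(table.feature_names),
        "edges_x": table.edges_x.tolist(),
        "edges_y": table.edges_y.tolist(),
        "pos_counts": table.pos_counts.tolist(),
        "neg_counts": table.neg_counts.tolist(),
        "lr": table.lr.tolist(),
        "pseudocount": table.pseudocount,
    }


def _table_from_json(obj: dict) -> Union[LRTable, JointLRTable]:
    if obj["kind"] == "1d":
        return LRTable(
            feature_name=obj["feature_name"],
            bin_edges=np.asarray(obj["bin_edges"], float),
            pos_counts=np.asarray(obj["pos_counts"], int),
            neg_counts=np.asarray(obj["neg_counts"], int),
            lr=np.asarray(obj["lr"], float),
            pseudocount=float(obj["pseudocount"]),
        )
    return JointLRTable(
        feature_names=tuple(obj["feature_names"]),
        edges_x=np.asarray(obj["edges_x"], float),
        edges_y=np.asarray(obj["edges_y"], float),
        pos_counts=np.asarray(obj["pos_counts"], int),
        neg_counts=np.asarray(obj["neg_counts"], int),
        lr=np.asarray(obj["lr"], float),
        pseudocount=float(obj["pseudocount"]),
    )


def save_model(model: BayesModel, path: str | os.PathLike) -> None:
    obj = {
        "format": MODEL_FORMAT,
        "prior_odds": model.prior_odds,
        "lr_cutoff": model.lr_cutoff,
        "tables": {name: _table_to_json(t) for name, t in model.tables.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: str | os.PathLike) -> BayesModel:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: not a {MODEL_FORMAT} model file")
    return BayesModel(
        prior_odds=float(obj["prior_odds"]),
        tables={n: _table_from_json(t) for n, t in obj["tables"].items()},
        lr_cutoff=float(obj["lr_cutoff"]),
    )
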