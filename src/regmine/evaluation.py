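"""ROC analysis, cross-validated benchmarking and operating-point selection.

Scores are total likelihood ratios; a pair is called regulatory when its
score clears an LR cutoff. ROC curves sweep that cutoff over every unique
score (ties grouped), the AUC is the trapezoidal area (equivalently the
Mann-Whitney U statistic scaled by 1/(n1*n2)), and operating points pick
the cutoff by sensitivity priority, PPV priority, or a balance of both.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .bayes import TrainConfig, score_frame, train_model
from .io import DataError

OPERATING_MODES = ("se_priority", "balanced", "ppv_priority")

#: score columns reported alongside the integrated model, as single-group
#: comparators (the paired groups plus plain PCC)
COMPARATOR_GROUPS = ("pcc_eld", "dmean_dsd", "modulus_angle", "go", "pcc")


@dataclass
class ROCResult:
    """An ROC curve: descending cutoffs with Se/Sp per cutoff and the AUC."""

    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def ppv(self) -> np.ndarray:
        """Positive predictive value per cutoff; 1.0 when nothing is called."""
        tp = self.sensitivity * self.n_pos
        fp = (1.0 - self.specificity) * self.n_neg
        called = tp + fp
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(called > 0, tp / np.where(called > 0, called, 1.0), 1.0)
        return out


@dataclass(frozen=True)
class OperatingPoint:
    mode: str
    lr_cutoff: float
    ppv: float
    se: float
    sp: float
    attainable: bool = True


def roc(scores, labels) -> ROCResult:
    """ROC over every unique score as a cutoff (ties move together)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def select_operating_point(
    roc_result: ROCResult, mode: str, anchor: float = 0.8
) -> OperatingPoint:
    """Pick an LR cutoff from an ROC curve.

    ``se_priority`` takes the largest cutoff whose sensitivity reaches the
    anchor (maximal specificity subject to Se >= anchor); ``ppv_priority``
    takes the smallest cutoff whose PPV still reaches the anchor (maximal
    sensitivity subject to PPV >= anchor); ``balanced`` maximizes
    min(PPV, Se) and ignores the anchor. An unattainable anchor returns the
    closest boundary cutoff flagged ``attainable=False``.
    """
    if mode not in OPERATING_MODES:
        raise ValueError(f"mode must be one of {OPERATING_MODES}")
    se = roc_result.sensitivity
    sp = roc_result.specificity
    ppv = roc_result.ppv
    thr = roc_result.thresholds

    def _point(i: int, attainable: bool = True) -> OperatingPoint:
        return OperatingPoint(
            mode=mode,
            lr_cutoff=float(thr[i]),
            ppv=float(ppv[i]),
            se=float(se[i]),
            sp=float(sp[i]),
            attainable=attainable,
        )

    if mode == "se_priority":
        idx = np.nonzero(se >= anchor)[0]
        if idx.size == 0:
            return _point(len(thr) - 1, attainable=False)
        return _point(int(idx[0]))  # thresholds descend: first hit = largest
    if mode == "ppv_priority":
        idx = np.nonzero(ppv >= anchor)[0]
        if idx.size == 0:
            return _point(0, attainable=False)
        return _point(int(idx[-1]))  # last hit = smallest cutoff
    objective = np.minimum(ppv, se)
    return _point(int(np.argmax(objective)))


def _fold_indices(
    labels: np.ndarray, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    n = len(labels)
    minority = int(min((labels == 1).sum(), (labels == 0).sum()))
    if folds < 2 or folds > n:
        raise ValueError("folds must be in [2, n]")
    dummy = np.zeros(n)
    if folds <= minority:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(splitter.split(dummy, labels))
    # leave-one-out style folds exceed the minority class: plain shuffled folds
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(splitter.split(dummy))


def cross_validate(
    features: pd.DataFrame,
    folds: int = 5,
    seed: int = 42,
    config: TrainConfig = TrainConfig(),
    go_present: Optional[bool] = None,
) -> tuple[ROCResult, dict[str, ROCResult]]:
    """k-fold CV of the integrated model with per-group comparator curves.

    LR tables are refit on each training fold; held-out total-LR scores are
    pooled into one ROC. Single-group curves (each paired group, the GO
    score, and plain 1-D PCC) are computed from the same folds. A fold whose
    training part is single-class triggers a reseeded refold (max 5 tries).
    """
    labels = features["label"].to_numpy(dtype=float)
    if np.isnan(labels).any():
        raise ValueError("cross-validation requires labeled features")
    labels = labels.astype(int)
    if go_present is None:
        go_present = bool(features["go_available"].any())

    split = None
    for attempt in range(5):
        candidate = _fold_indices(labels, folds, seed + attempt)
        if all(len(np.unique(labels[tr])) == 2 for tr, _ in candidate):
            split = candidate
            break
    if split is None:
        raise DataError("could not build folds with both classes in training")

    n = len(features)
    pooled = np.empty(n)
    group_scores: dict[str, np.ndarray] = {}
    available_groups: Optional[list[str]] = None
    for train_idx, test_idx in split:
        train_df = features.iloc[train_idx]
        test_df = features.iloc[test_idx]
        model = train_model(train_df, config=config, go_present=go_present)
        pooled[test_idx] = score_frame(model, test_df)
        if available_groups is None:
            available_groups = [
                g for g in COMPARATOR_GROUPS if g in model.tables or g == "pcc"
            ]
            for g in available_groups:
                group_scores[g] = np.empty(n)
        for g in available_groups:
            if g == "pcc":
                group_scores[g][test_idx] = _pcc_only_scores(train_df, test_df, config)
            else:
                group_scores[g][test_idx] = score_frame(model, test_df, groups=[g])
    pooled_roc = roc(pooled, labels)
    group_rocs = {g: roc(s, labels) for g, s in group_scores.items()}
    return pooled_roc, group_rocs


def _pcc_only_scores(
    train_df: pd.DataFrame, test_df: pd.DataFrame, config: TrainConfig
) -> np.ndarray:
    """Held-out LR scores from a 1-D PCC table fit on the training fold."""
    from .bayes import fit_lr_table_1d, lookup_lr

    tr_def = train_df["pcc_defined"].to_numpy(bool)
    tr_lab = train_df["label"].to_numpy(float)
    pos = train_df.loc[(tr_lab == 1.0) & tr_def, "pcc"].to_numpy(float)
    neg = train_df.loc[(tr_lab == 0.0) & tr_def, "pcc"].to_numpy(float)
    out = np.ones(len(test_df))
    if pos.size == 0 or neg.size == 0:
        return out
    try:
        table = fit_lr_table_1d(
            pos, neg, n_bins=config.n_bins_1d, pseudocount=config.pseudocount,
            feature_name="pcc",
        )
    except ValueError:
        return out
    te_def = test_df["pcc_defined"].to_numpy(bool)
    vals = test_df["pcc"].to_numpy(float)
    for i in np.nonzero(te_def)[0]:
        out[i] = lookup_lr(table, vals[i])
    return out


def ratio_sweep(
    features: pd.DataFrame,
    ratios=(1, 2, 3, 4, 5, 6, 7),
    se_anchor: float = 0.8,
    folds: int = 5,
    seed: int = 42,
    config: TrainConfig = TrainConfig(),
) -> list[tuple[int, float]]:
    """PPV at fixed sensitivity as the negative:positive ratio grows.

    For each ratio r, the training universe keeps every positive and a
    seeded subsample of r * n_pos negatives; pooled k-fold CV scores give
    the PPV at the Se-priority operating point. As negatives accumulate,
    PPV at fixed sensitivity declines.
    """
    labels = features["label"].to_numpy(dtype=float)
    pos_df = features[labels == 1.0]
    neg_df = features[labels == 0.0]
    n_pos = len(pos_df)
    rng = np.random.default_rng(seed)
    neg_order = rng.permutation(len(neg_df))
    out: list[tuple[int, float]] = []
    for r in ratios:
        need = r * n_pos
        if need > len(neg_df):
            raise ValueError(
                f"ratio 1:{r} needs {need} negatives, only {len(neg_df)} available"
            )
        subset = pd.concat(
            [pos_df, neg_df.iloc[neg_order[:need]]], ignore_index=True
        )
        pooled, _ = cross_validate(subset, folds=folds, seed=seed, config=config)
        point = select_operating_point(pooled, "se_priority", anchor=se_anchor)
        out.append((int(r), float(point.ppv)))
    return out
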