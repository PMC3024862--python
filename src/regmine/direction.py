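"""Regulatory direction from the time delay between expression peaks.

A perturbation propagating from a TF to its target shows up as a lag
between the two expression profiles. Peaks (extrema) of each profile are
detected where consecutive first differences change sign strictly,
Delta_y(t-1) * Delta_y(t) < 0, their amplitude measured against a mean or
median baseline; the k strongest peaks of each profile are then matched by
sign and proximity, and the signed offset between matched TF and TG peaks
sets the direction: target lagging (positive delay) means TF -> TG.
"""
from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

BASELINES = ("mean", "median")


@dataclass(frozen=True)
class Peak:
    """An interior extremum: time index, amplitude vs baseline, and type."""

    index: int
    amplitude: float
    sign: str  # "max" or "min"


@dataclass(frozen=True)
class DirectionConfig:
    """Peak-detection and matching settings.

    The defaults (2 peaks, mean baseline, amount-of-delay aggregation) are
    the best-performing variant of the four peak-count x baseline x
    existence/amount combinations; ``max_delay`` defaults to ceil(T/3) to
    keep matches from wrapping around in cyclic data.
    """

    baseline: str = "mean"
    k: int = 2
    use_amount: bool = True
    max_delay: Optional[int] = None

    def resolved_max_delay(self, length: int) -> int:
        return self.max_delay if self.max_delay is not None else math.ceil(length / 3)


@dataclass(frozen=True)
class DirectionCall:
    """forward (TF->TG) / reverse / undetermined, with the estimated delay."""

    direction: str
    delay: Optional[int]  # None iff undetermined
    matched: int
    config: DirectionConfig


def detect_peaks(profile, baseline: str = "mean", k: int = 2) -> list[Peak]:
    """The k strongest interior extrema of a profile, in time order.

    Runs of equal consecutive values are collapsed to their first index
    before differencing, so only strict sign changes count. Amplitude is
    value minus the baseline statistic of the whole profile; an extremum
    whose amplitude contradicts its type (a local max at or below baseline,
    or vice versa) is not a peak. A monotone profile yields no peaks.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("profile must be a 1-D vector of length >= 3")
    if baseline not in BASELINES:
        raise ValueError(f"baseline must be one of {BASELINES}")
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    base = float(np.mean(y)) if baseline == "mean" else float(np.median(y))
    # collapse plateaus: keep the first index of each run of equal values
    reps = [0] + [i for i in range(1, y.size) if y[i] != y[i - 1]]
    cy = y[reps]
    candidates: list[Peak] = []
    for j in range(1, len(reps) - 1):
        d_prev = cy[j] - cy[j - 1]
        d_next = cy[j + 1] - cy[j]
        if d_prev * d_next >= 0:
            continue
        sign = "max" if d_prev > 0 else "min"
        amplitude = float(cy[j] - base)
        if (sign == "max" and amplitude <= 0) or (sign == "min" and amplitude >= 0):
            continue
        candidates.append(Peak(index=reps[j], amplitude=amplitude, sign=sign))
    top = sorted(candidates, key=lambda p: (-abs(p.amplitude), p.index))[:k]
    return sorted(top, key=lambda p: p.index)


def match_delay(
    tf_peaks: Sequence[Peak],
    tg_peaks: Sequence[Peak],
    use_amount: bool = True,
    max_delay: int = 6,
) -> tuple[int, int]:
    """Match TF and TG peaks of the same sign and aggregate their delays.

    Candidate matches (one TF peak, one TG peak, same sign, offset within
    ``max_delay``) are accepted greedily in order of |delay|, breaking ties
    by the earlier and then the later of the two time indices; this ordering
    is symmetric under swapping the two profiles, so the aggregate delay
    exactly negates when the arguments swap. Per-match delay is
    tg.index - tf.index. With ``use_amount`` the reported delay is the
    median of the matched delays truncated toward 0; otherwise only the sign
    consensus (+1/-1/0) of the matched delays is reported.

    Returns (delay, number of matched peak pairs); (0, 0) when nothing
    matches.
    """
    candidates = []
    for a in tf_peaks:
        for b in tg_peaks:
            if a.sign != b.sign:
                continue
            d = b.index - a.index
            if abs(d) > max_delay:
                continue
            lo, hi = min(a.index, b.index), max(a.index, b.index)
            candidates.append((abs(d), lo, hi, d, a, b))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_tf: set[int] = set()
    used_tg: set[int] = set()
    delays: list[int] = []
    for _, _, _, d, a, b in candidates:
        if id(a) in used_tf or id(b) in used_tg:
            continue
        used_tf.add(id(a))
        used_tg.add(id(b))
        delays.append(d)
    if not delays:
        return 0, 0
    if use_amount:
        delay = math.trunc(statistics.median(delays))
    else:
        s = sum((d > 0) - (d < 0) for d in delays)
        delay = (s > 0) - (s < 0)
    return delay, len(delays)


def infer_direction(
    tf_profile,
    tg_profile,
    config: DirectionConfig = DirectionConfig(),
) -> DirectionCall:
    """Direction call for one pair from matched peak delays.

    Positive aggregate delay (target lags) -> forward; negative -> reverse;
    zero delay or no matched peaks -> undetermined.
    """
    x = np.asarray(tf_profile, dtype=float)
    y = np.asarray(tg_profile, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("profiles must be equal-length 1-D vectors, length >= 3")
    tf_peaks = detect_peaks(x, baseline=config.baseline, k=config.k)
    tg_peaks = detect_peaks(y, baseline=config.baseline, k=config.k)
    delay, matched = match_delay(
        tf_peaks,
        tg_peaks,
        use_amount=config.use_amount,
        max_delay=config.resolved_max_delay(x.size),
    )
    if matched == 0 or delay == 0:
        return DirectionCall("undetermined", None, matched, config)
    direction = "forward" if delay > 0 else "reverse"
    return DirectionCall(direction, delay, matched, config)
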