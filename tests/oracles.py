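"""Independent brute-force reference implementations used as test oracles.

Each function here re-derives a quantity from first principles with plain
loops, deliberately sharing no code with the package implementation.
"""
from __future__ import annotations

import math


def quartile_type7(values, q):
    """Linear-interpolation (type 7) quantile computed by hand."""
    xs = sorted(float(v) for v in values)
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def eld_oracle(tf, tg):
    ax, ay = quartile_type7(tf, 0.25), quartile_type7(tf, 0.75)
    bx, by = quartile_type7(tg, 0.25), quartile_type7(tg, 0.75)
    return math.sqrt((ax - bx) ** 2 + (ay - by) ** 2)


def mean_sd_oracle(tf, tg):
    import statistics

    return (
        abs(statistics.fmean(tf) - statistics.fmean(tg)),
        abs(statistics.stdev(tf) - statistics.stdev(tg)),
    )


def quadrant_oracle(tf, tg):
    """Explicit per-quadrant summation; returns (modulus, angle_deg, defined)."""
    sums = {1: [0.0, 0.0], 2: [0.0, 0.0], 3: [0.0, 0.0], 4: [0.0, 0.0]}
    for x, y in zip(tf, tg):
        if x > 0 and y > 0:
            q = 1
        elif x < 0 and y > 0:
            q = 2
        elif x < 0 and y < 0:
            q = 3
        elif x > 0 and y < 0:
            q = 4
        elif y == 0 and x > 0:
            q = 1
        elif x == 0 and y > 0:
            q = 1
        elif y == 0 and x < 0:
            q = 2
        elif x == 0 and y < 0:
            q = 3
        else:
            q = 1
        sums[q][0] += x
        sums[q][1] += y
    best_q, best_mod = None, -1.0
    for q in (1, 2, 3, 4):  # ascending: first strict max wins ties
        mod = math.hypot(*sums[q])
        if mod > best_mod + 1e-15:
            best_q, best_mod = q, mod
    if best_mod <= 0.0:
        return 0.0, 0.0, False
    angle = math.degrees(math.atan2(sums[best_q][1], sums[best_q][0])) % 360.0
    return best_mod, angle, True


def go_score_oracle(tf_terms, tg_terms, parents, grades):
    """GO co-annotation score by explicit closure/leaf/divergence loops.

    ``tf_terms``/``tg_terms`` are the direct annotation sets; ``parents``
    maps term -> iterable of parents; ``grades`` maps term -> grade.
    Returns (score, available).
    """

    def closure(terms):
        out = set(terms)
        changed = True
        while changed:
            changed = False
            for t in list(out):
                for p in parents.get(t, ()):
                    if p not in out:
                        out.add(p)
                        changed = True
        return out

    if not tf_terms or not tg_terms:
        return 0.0, False
    shared = closure(tf_terms) & closure(tg_terms)
    if not shared:
        return 0.0, True
    score = 0.0
    for t in shared:
        children_in = [c for c in shared if t in parents.get(c, ())]
        if len(children_in) == 0:
            score += grades[t]
        elif len(children_in) >= 2:
            score -= (len(children_in) - 1) * grades[t]
    return max(score, 0.0), True


def peaks_oracle(profile, baseline, k):
    """Extremum scan with plateau collapse, written independently."""
    y = [float(v) for v in profile]
    if baseline == "mean":
        base = sum(y) / len(y)
    else:
        ys = sorted(y)
        n = len(ys)
        base = ys[n // 2] if n % 2 else 0.5 * (ys[n // 2 - 1] + ys[n // 2])
    idxs = [0]
    for i in range(1, len(y)):
        if y[i] != y[idxs[-1]]:
            idxs.append(i)
    found = []
    for j in range(1, len(idxs) - 1):
        a, b, c = y[idxs[j - 1]], y[idxs[j]], y[idxs[j + 1]]
        amp = b - base
        if a < b and b > c and amp > 0:
            found.append((idxs[j], amp, "max"))
        elif a > b and b < c and amp < 0:
            found.append((idxs[j], amp, "min"))
    found.sort(key=lambda p: (-abs(p[1]), p[0]))
    return sorted(found[:k])


def auc_mann_whitney(scores, labels):
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
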