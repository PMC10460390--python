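"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plainly as possible (explicit loops, full
covariance matrices) and shares no code with the package's estimators.
"""
from __future__ import annotations

import math

import numpy as np


def icc_trace_oracle_balanced(Y: np.ndarray, subject_index: np.ndarray) -> float:
    """Trace-ratio ICC for a *balanced* panel via empirical moment estimators
    of the between- and within-subject covariance operators.

    K_W is the pooled within-subject covariance of day curves around each
    subject's mean; K_B is the covariance of subject means minus K_W / J.
    """
    subjects = np.unique(subject_index)
    n = len(subjects)
    J = None
    groups = []
    for s in subjects:
        block = Y[subject_index == s]
        if J is None:
            J = block.shape[0]
        assert block.shape[0] == J, "oracle requires a balanced panel"
        groups.append(block)
    p = Y.shape[1]

    K_w = np.zeros((p, p))
    means = np.zeros((n, p))
    for i, block in enumerate(groups):
        mean_i = block.mean(axis=0)
        means[i] = mean_i
        for j in range(J):
            d = block[j] - mean_i
            K_w += np.outer(d, d)
    K_w /= n * (J - 1)

    grand = means.mean(axis=0)
    S_means = np.zeros((p, p))
    for i in range(n):
        d = means[i] - grand
        S_means += np.outer(d, d)
    S_means /= n - 1

    K_b = S_means - K_w / J
    tr_b = max(0.0, float(np.trace(K_b)))
    tr_w = float(np.trace(K_w))
    total = tr_b + tr_w
    return math.nan if total == 0 else tr_b / total


def cv_oracle(values) -> float:
    values = list(values)
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return 100.0 * math.sqrt(var) / mean


def modd_oracle(days: dict[int, tuple[list[float], list[bool]]]):
    """(modd, k) from {calendar_day: (values, observed_mask)} by literal
    application of the 1440-min-lag definition."""
    total = 0.0
    k = 0
    for day, (vals, mask) in days.items():
        if day - 1 not in days:
            continue
        pvals, pmask = days[day - 1]
        for t in range(len(vals)):
            if mask[t] and pmask[t]:
                total += abs(vals[t] - pvals[t])
                k += 1
    return (total / k if k else None), k


def mard_oracle(pairs):
    """Dict of accuracy summaries from (sensor, capillary, day) triples."""
    ards = []
    by_range = {"<70": [], "70-180": [], ">180": []}
    by_day: dict[int, list[float]] = {}
    low_hits = low_n = high_hits = high_n = 0
    for sensor, cap, day in pairs:
        ard = 100.0 * abs(sensor - cap) / cap
        ards.append(ard)
        if cap < 70:
            by_range["<70"].append(ard)
        elif cap <= 180:
            by_range["70-180"].append(ard)
        else:
            by_range[">180"].append(ard)
        by_day.setdefault(day, []).append(ard)
        if cap < 100:
            low_n += 1
            low_hits += abs(sensor - cap) <= 15.0
        else:
            high_n += 1
            high_hits += ard <= 15.0
    return {
        "overall": sum(ards) / len(ards),
        "by_range": {k: (sum(v) / len(v) if v else None) for k, v in by_range.items()},
        "by_day": {d: sum(v) / len(v) for d, v in by_day.items()},
        "pct_low": 100.0 * low_hits / low_n if low_n else None,
        "pct_high": 100.0 * high_hits / high_n if high_n else None,
    }
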