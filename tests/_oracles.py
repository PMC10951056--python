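"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation code paths they are checking.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def mann_whitney_exact_p(sample_a, sample_b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of rank assignments."""
    a = list(sample_a)
    b = list(sample_b)
    pooled = a + b
    n_a = len(a)

    def u_stat(indices_a) -> float:
        set_a = set(indices_a)
        va = [pooled[i] for i in indices_a]
        vb = [pooled[i] for i in range(len(pooled)) if i not in set_a]
        u = 0.0
        for x in va:
            for y in vb:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    observed = u_stat(tuple(range(n_a)))
    mean_u = n_a * (len(pooled) - n_a) / 2.0
    observed_dev = abs(observed - mean_u)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(combo) - mean_u) >= observed_dev - 1e-9:
            count += 1
    return count / total


def isodata_partition(values, threshold) -> np.ndarray:
    return np.asarray(values, dtype=float) > threshold


def isodata_fixed_points(values) -> list[float]:
    """Exhaustive search for all self-consistent class-mean midpoint thresholds.

    Scans every split between consecutive sorted unique values; a candidate
    threshold is the midpoint of the two class means, accepted when it falls
    inside the split interval it defines.  There can be more than one fixed
    point; any of them is a valid IsoData threshold.
    """
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(vals)
    if uniq.size < 2:
        raise ValueError("constant input")
    points = []
    for i in range(uniq.size - 1):
        low = vals[vals <= uniq[i]]
        high = vals[vals > uniq[i]]
        mid = (low.mean() + high.mean()) / 2.0
        if uniq[i] <= mid < uniq[i + 1]:
            points.append(float(mid))
    return points


def isodata_brute_force(values) -> float:
    """First (lowest) self-consistent threshold from :func:`isodata_fixed_points`."""
    points = isodata_fixed_points(values)
    if not points:
        raise ValueError("no self-consistent threshold found")
    return points[0]


def chi_square_p_from_normal(chi2: float) -> float:
    """P(X > chi2) for chi-square df=1 via the standard normal survival
    function, independent of scipy's chi-square distribution."""
    return float(2.0 * (1.0 - 0.5 * (1.0 + math.erf(math.sqrt(chi2) / math.sqrt(2.0)))))
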