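"""Independent brute-force oracles for the numerical operations.

Everything here is written as plain double loops / direct formula
evaluation, deliberately sharing no code with the package implementations
they are used to check.
"""

from __future__ import annotations

import math

import numpy as np


def erode_bruteforce(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion by definition: a pixel survives iff every disk offset lands on
    a true pixel; out-of-bounds counts as false."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    out = np.zeros_like(mask)
    for r in range(rows):
        for c in range(cols):
            ok = True
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols) or not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def disk_offsets(radius: int) -> set[tuple[int, int]]:
    return {
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    }


def glcm_bruteforce(
    levels: np.ndarray,
    n_levels: int,
    distance: int,
    angles,
    symmetric: bool,
) -> np.ndarray:
    """Pair counting by explicit loops; level 0 marks non-ROI pixels."""
    rows, cols = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for ar, ac in angles:
        dr, dc = ar * distance, ac * distance
        for r in range(rows):
            for c in range(cols):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                a, b = levels[r, c], levels[rr, cc]
                if a == 0 or b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                if symmetric:
                    counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def glcm_stats_bruteforce(p: np.ndarray, log: float = math.e) -> dict[str, float]:
    """The 22 second-order statistics by direct scalar summation."""
    ng = p.shape[0]

    def ln(x):
        return math.log(x) / math.log(log) if x > 0 else 0.0

    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))
    psum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    pdiff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]

    s: dict[str, float] = {}
    s["Autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
    )
    s["Contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    if sx * sy == 0:
        s["Correlation_m"] = 0.0
        s["Correlation_p"] = 0.0
    else:
        s["Correlation_m"] = (s["Autocorrelation"] - mux * muy) / (sx * sy)
        s["Correlation_p"] = sum(
            (i + 1 - mux) * (j + 1 - muy) / (sx * sy) * p[i][j]
            for i in range(ng)
            for j in range(ng)
        )
    s["Cluster_prominence"] = sum(
        (i + j + 2 - mux - muy) ** 4 * p[i][j] for i in range(ng) for j in range(ng)
    )
    s["Cluster_shade"] = sum(
        (i + j + 2 - mux - muy) ** 3 * p[i][j] for i in range(ng) for j in range(ng)
    )
    s["Dissimilarity"] = sum(
        abs(i - j) * p[i][j] for i in range(ng) for j in range(ng)
    )
    s["Energy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    s["Entropy"] = -sum(
        p[i][j] * ln(p[i][j]) for i in range(ng) for j in range(ng)
    )
    s["Homogeneity_m"] = sum(
        p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    s["Homogeneity"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    s["Maximum_probability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    s["Sum_of_squares_variance"] = sum(
        (i + 1 - mux) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
    )
    sa = sum(k * psum[k] for k in psum)
    s["Sum_average"] = sa
    s["Sum_variance"] = sum((k - sa) ** 2 * psum[k] for k in psum)
    s["Sum_entropy"] = -sum(psum[k] * ln(psum[k]) for k in psum)
    da = sum(k * pdiff[k] for k in pdiff)
    s["Difference_variance"] = sum((k - da) ** 2 * pdiff[k] for k in pdiff)
    s["Difference_entropy"] = -sum(pdiff[k] * ln(pdiff[k]) for k in pdiff)
    hx = -sum(px[i] * ln(px[i]) for i in range(ng))
    hy = -sum(py[j] * ln(py[j]) for j in range(ng))
    hxy = s["Entropy"]
    hxy1 = -sum(
        p[i][j] * ln(px[i] * py[j]) for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * py[j] * ln(px[i] * py[j]) for i in range(ng) for j in range(ng)
    )
    s["Information_measure_of_correlation1"] = (
        (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    )
    s["Information_measure_of_correlation2"] = math.sqrt(
        max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))
    )
    s["Inverse_difference_normalized"] = sum(
        p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    s["Inverse_difference_moment_normalized"] = sum(
        p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
    )
    return s


def percentile_linear(sorted_vals, q: float) -> float:
    """Linear interpolation between order statistics (inclusive method)."""
    n = len(sorted_vals)
    if n == 1:
        return float(sorted_vals[0])
    h = (n - 1) * q / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    frac = h - lo
    return float(sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac)


def fos_bruteforce(values) -> dict[str, float]:
    """The 20 first-order statistics by direct formula evaluation."""
    v = sorted(float(x) for x in np.ravel(values))
    n = len(v)
    mean = sum(v) / n
    var1 = sum((x - mean) ** 2 for x in v) / (n - 1) if n > 1 else 0.0
    sd = math.sqrt(var1)
    m2 = sum((x - mean) ** 2 for x in v) / n
    if m2 == 0:
        skew, kurt = 0.0, 0.0
    else:
        skew = (sum((x - mean) ** 3 for x in v) / n) / m2**1.5
        kurt = (sum((x - mean) ** 4 for x in v) / n) / m2**2
    pct = {q: percentile_linear(v, q) for q in (1, 5, 10, 15, 20, 25, 50, 75, 80, 85, 90, 95, 99)}
    return {
        "Mean": mean,
        "Standard_deviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Minimum": v[0],
        "5th_percentile": pct[5],
        "10th_percentile": pct[10],
        "15th_percentile": pct[15],
        "20th_percentile": pct[20],
        "25th_percentile": pct[25],
        "Median": pct[50],
        "75th_percentile": pct[75],
        "80th_percentile": pct[80],
        "85th_percentile": pct[85],
        "90th_percentile": pct[90],
        "95th_percentile": pct[95],
        "Maximum": v[-1],
        "Range_all": v[-1] - v[0],
        "Range5": pct[95] - pct[5],
        "Range2": pct[99] - pct[1],
    }


def auc_pairwise(scores, labels, positive="high") -> float:
    """AUC as the fraction of (positive, negative) pairs ordered correctly,
    ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
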