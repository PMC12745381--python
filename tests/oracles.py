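"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive every quantity from first principles with plain
Python loops; they must stay independent of the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_spikes(x: np.ndarray) -> list[dict]:
    """Enumerate strict local maxima and compute topographic prominence and
    half-prominence widths by scanning to the nearest higher flanks.

    Prominence of a peak: scan left/right until a strictly higher sample (or
    the signal border); the contour base is the higher of the two interval
    minima.  Width: at half the prominence below the peak, with linear
    interpolation of the crossings, clipped to the contour bases.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    peaks = [i for i in range(1, n - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
    out = []
    for p in peaks:
        left_min, left_base = x[p], p
        i = p
        while i >= 0 and x[i] <= x[p]:
            if x[i] < left_min:
                left_min, left_base = x[i], i
            i -= 1
        right_min, right_base = x[p], p
        i = p
        while i < n and x[i] <= x[p]:
            if x[i] < right_min:
                right_min, right_base = x[i], i
            i += 1
        prom = x[p] - max(left_min, right_min)
        height = x[p] - 0.5 * prom
        # left crossing
        i = p
        while i > left_base and x[i] > height:
            i -= 1
        left_ip = float(i)
        if x[i] < height:
            left_ip += (height - x[i]) / (x[i + 1] - x[i])
        # right crossing
        i = p
        while i < right_base and x[i] > height:
            i += 1
        right_ip = float(i)
        if x[i] < height:
            right_ip -= (height - x[i]) / (x[i - 1] - x[i])
        out.append(
            {
                "index": p,
                "value": x[p],
                "prominence": prom,
                "left_ip": left_ip,
                "right_ip": right_ip,
                "width": right_ip - left_ip,
            }
        )
    return out


def jensen_shannon_direct(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2) by direct summation."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    p = p / p.sum()
    q = q / q.sum()
    m = (p + q) / 2.0
    total = 0.0
    for pi, qi, mi in zip(p, q, m):
        if pi > 0:
            total += 0.5 * pi * math.log2(pi / mi)
        if qi > 0:
            total += 0.5 * qi * math.log2(qi / mi)
    return total


def hill_response(dose, top, bottom, ic50, slope):
    """Closed-form four-parameter Hill curve."""
    if dose == 0:
        return top
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** slope)


def anova_ss_balanced_2x2(values: np.ndarray) -> dict:
    """Hand-computed sums of squares for a balanced 2x2 design.

    ``values`` has shape (2, 2, r): factor A level x factor B level x
    replicate.  Returns SS for A, B, interaction, residual.
    """
    v = np.asarray(values, dtype=np.float64)
    a_levels, b_levels, r = v.shape
    grand = v.mean()
    n = v.size
    ss_a = sum(
        b_levels * r * (v[i].mean() - grand) ** 2 for i in range(a_levels)
    )
    ss_b = sum(
        a_levels * r * (v[:, j].mean() - grand) ** 2 for j in range(b_levels)
    )
    ss_cells = sum(
        r * (v[i, j].mean() - grand) ** 2
        for i in range(a_levels)
        for j in range(b_levels)
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_res = sum(
        ((v[i, j] - v[i, j].mean()) ** 2).sum()
        for i in range(a_levels)
        for j in range(b_levels)
    )
    return {"A": ss_a, "B": ss_b, "AB": ss_ab, "residual": ss_res}
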