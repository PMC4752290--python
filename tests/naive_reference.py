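"""Intentionally naive triple-loop Higuchi implementation.

Independent oracle for the vectorised estimator: literal 1-based loops
over k, m and i, and an explicit closed-form OLS slope.  Kept free of any
import from the package's estimator internals.
"""

import math


def naive_curve_length(y, k, m):
    n = len(y)
    n_i = (n - m) // k
    total = 0.0
    for i in range(1, n_i + 1):
        total += abs(y[m + i * k - 1] - y[m + (i - 1) * k - 1])
    return total * (n - 1) / (n_i * k) / k


def naive_mean_curve_length(y, k):
    return sum(naive_curve_length(y, k, m) for m in range(1, k + 1)) / k


def naive_higuchi_fd(y, k_max, fit_k_min=1):
    ks = list(range(fit_k_min, k_max + 1))
    xs = [math.log(k) for k in ks]
    ys = [math.log(naive_mean_curve_length(y, k)) for k in ks]
    n = len(ks)
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    sxy = sum((x - xbar) * (v - ybar) for x, v in zip(xs, ys))
    sxx = sum((x - xbar) ** 2 for x in xs)
    return -sxy / sxx
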