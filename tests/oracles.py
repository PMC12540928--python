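"""Independent brute-force oracles used by the test suite.

Everything here is written directly from first-principles definitions
(plain loops, exhaustive enumeration) and never calls the package code it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def viterbi_bruteforce(log_init, log_trans, log_emis):
    """Exhaustive argmax over all state paths; ties broken lexicographically
    (lowest state indices first)."""
    T, n = np.asarray(log_emis).shape
    best_path, best_score = None, -math.inf
    for path in itertools.product(range(n), repeat=T):
        s = log_init[path[0]] + log_emis[0][path[0]]
        for t in range(1, T):
            s += log_trans[path[t - 1]][path[t]] + log_emis[t][path[t]]
        if s > best_score + 1e-15:
            best_score, best_path = s, path
    return list(best_path), best_score


def time_domain_stats_bruteforce(x):
    """Direct-formula waveform shape statistics."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    energy = sum(v * v for v in x)
    abs_mean = sum(abs(v) for v in x) / n
    rms = math.sqrt(energy / n)
    peak = max(abs(v) for v in x)
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    sqrt_mean = sum(math.sqrt(abs(v)) for v in x) / n
    return {
        "energy": energy,
        "abs_mean": abs_mean,
        "peak2valley": max(x) - min(x),
        "crest_factor": peak / rms,
        "shape_factor": rms / abs_mean,
        "margin_factor": peak / sqrt_mean**2,
        "skewness": m3 / m2**1.5,
        "kurtosis": m4 / m2**2,
    }


def group_summary_bruteforce(values, confidence=0.95):
    """Mean/SE/SD/t-CI from raw moment formulas (SD with n-1 denominator).

    The t quantile comes from numerically inverting the incomplete-beta CDF
    by bisection, independent of scipy.stats.
    """
    vals = list(map(float, values))
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    sd = math.sqrt(var)
    se = sd / math.sqrt(n)
    t = _t_quantile(1 - (1 - confidence) / 2, n - 1)
    return {"mean": mean, "std_err": se, "std_dev": sd,
            "ci_low": mean - t * se, "ci_high": mean + t * se}


def _t_cdf(x, df):
    # CDF via the regularized incomplete beta function, computed by
    # continued fraction (Lentz algorithm)
    if x == 0:
        return 0.5
    ib = _reg_inc_beta(df / 2.0, 0.5, df / (df + x * x))
    return 1.0 - 0.5 * ib if x > 0 else 0.5 * ib


def _reg_inc_beta(a, b, x):
    if x <= 0:
        return 0.0
    if x >= 1:
        return 1.0
    ln_front = (
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + a * math.log(x) + b * math.log(1 - x)
    )
    if x < (a + 1) / (a + b + 2):
        return math.exp(ln_front) * _beta_cf(a, b, x) / a
    return 1.0 - math.exp(
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + b * math.log(1 - x) + a * math.log(x)
    ) * _beta_cf(b, a, 1 - x) / b


def _beta_cf(a, b, x, max_iter=300, eps=1e-14):
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c, d = 1.0, 1.0 - qab * x / qap
    if abs(d) < 1e-300:
        d = 1e-300
    d = 1.0 / d
    h = d
    for m in range(1, max_iter + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        c = 1.0 + aa / c
        if abs(d) < 1e-300:
            d = 1e-300
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        c = 1.0 + aa / c
        if abs(d) < 1e-300:
            d = 1e-300
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            break
    return h


def _t_quantile(p, df):
    lo, hi = 0.0, 1e3
    for _ in range(200):
        mid = (lo + hi) / 2
        if _t_cdf(mid, df) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
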