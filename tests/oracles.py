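"""Independent brute-force oracles used to cross-check the implementations.

Deliberately naive (loops, O(N²) scans) so they share no code path with the
package.
"""

from __future__ import annotations

import numpy as np


def sampen_bruteforce(x, m: int, r: float):
    """Triple-loop SampEn match probabilities over the common template range.

    Templates of length m and m+1 both start at i = 0..N-m-1; b and a are
    ordered-pair match fractions with Z = T(T-1).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    t = n - m
    b_count = a_count = 0
    for i in range(t):
        for j in range(t):
            if i == j:
                continue
            ok_m = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok_m = False
                    break
            if ok_m:
                b_count += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a_count += 1
    z = t * (t - 1)
    return b_count / z, a_count / z


def sampen_value_bruteforce(x, m: int, r: float):
    """SampEn value/status from the brute-force probabilities."""
    b, a = sampen_bruteforce(x, m, r)
    if b == 0:
        return float("nan"), "undefined"
    if a == 0:
        return float("inf"), "infinite"
    return -np.log(a / b), "defined"


def changepoint_bruteforce(x, min_size: int = 10, coefficients: str = "as-printed"):
    """Exhaustive evaluation of the two-segment log-variance objective."""
    x = np.asarray(x, dtype=float)
    n = x.size
    floor = 1e-12
    best_k, best_obj = None, np.inf
    for k in range(min_size, n - min_size + 1):
        v0 = max(float(np.var(x[:k])), floor)
        v1 = max(float(np.var(x[k:])), floor)
        if coefficients == "as-printed":
            obj = (k - 1) * np.log(v0) + (n - k + 1) * np.log(v1)
        else:
            obj = k * np.log(v0) + (n - k) * np.log(v1)
        if obj < best_obj:
            best_obj, best_k = obj, k
    return best_k, best_obj


def peak_vo2_grid(time, vo2, window_s=20.0, tail_s=60.0, step=0.01):
    """Dense grid scan over candidate window starts in the final minute."""
    end = time[-1]
    best = -np.inf
    for t0 in np.arange(end - tail_s, end - window_s + step / 2, step):
        sel = (time >= t0) & (time < t0 + window_s)
        if sel.any():
            best = max(best, vo2[sel].mean())
    return best


def holm_sidak_bruteforce(pvals, alpha=0.05):
    """Direct step-down evaluation of the Holm-Sidak adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        candidate = 1.0 - (1.0 - p[idx]) ** (n - rank)
        running = max(running, candidate)
        adj[idx] = min(running, 1.0)
    return adj, adj < alpha
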