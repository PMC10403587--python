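"""Compiled kernels for the quadratic-time complexity estimators.

Template matching for the approximate/sample/fuzzy entropies and the
correlation sum are O(N^2) in the series length. One fused numba kernel
makes a single pass over all template pairs, accumulating every statistic
the embedded markers need; the Chebyshev (maximum-coordinate) distance on
delay embeddings with a shared delay ``tau`` is used throughout.

Template-count conventions (documented; the brute-force oracles in the
test-suite implement them independently):

* ApEn (Pincus): Phi_m over N-(m-1)*tau templates, Phi_{m+1} over N-m*tau,
  self-matches included.
* SampEn (Richman-Moorman): both dimensions over the same N-m*tau
  templates, no self-matches.
* FuzzEn: as SampEn, on baseline-removed templates with membership
  exp(-(d/r)^n).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def embedded_stats(x: np.ndarray, m: int, tau: int, r: float):
    """One pass over template pairs; returns every embedded-marker statistic.

    Returns ``(dists, apen_cm, apen_cm1, sampen_a, sampen_b, fuzz_dm,
    fuzz_dm1)`` where ``dists`` holds all pairwise Chebyshev distances at
    dimension m (feeding the correlation sum), ``apen_cm``/``apen_cm1`` are
    per-template neighbour counts (self included) at dimensions m and m+1,
    ``sampen_a``/``sampen_b`` the matching-pair counts at m+1 and m, and
    ``fuzz_dm``/``fuzz_dm1`` the baseline-removed pair distances over the
    shared N - m*tau template range (memberships are exponentiated outside
    the kernel, vectorized).
    """
    n = x.shape[0]
    n_m = n - (m - 1) * tau  # templates at dimension m
    n_m1 = n - m * tau  # templates at dimension m+1 (and SampEn/FuzzEn range)
    dists = np.empty(n_m * (n_m - 1) // 2)
    n_pairs1 = max(n_m1 * (n_m1 - 1) // 2, 0)
    fuzz_dm = np.empty(n_pairs1)
    fuzz_dm1 = np.empty(n_pairs1)
    apen_cm = np.ones(max(n_m, 0), dtype=np.int64)  # self-match
    apen_cm1 = np.ones(max(n_m1, 0), dtype=np.int64)
    sampen_a = 0
    sampen_b = 0

    mean_m = np.empty(max(n_m, 0))
    for i in range(n_m):
        s = 0.0
        for k in range(m):
            s += x[i + k * tau]
        mean_m[i] = s / m
    mean_m1 = np.empty(max(n_m1, 0))
    for i in range(n_m1):
        s = 0.0
        for k in range(m + 1):
            s += x[i + k * tau]
        mean_m1[i] = s / (m + 1)

    idx = 0
    fidx = 0
    for i in range(n_m - 1):
        for j in range(i + 1, n_m):
            d_m = 0.0
            for k in range(m):
                t = abs(x[i + k * tau] - x[j + k * tau])
                if t > d_m:
                    d_m = t
            dists[idx] = d_m
            idx += 1
            if d_m <= r:
                apen_cm[i] += 1
                apen_cm[j] += 1
            if j < n_m1:
                # dimension m+1 statistics live on the restricted range
                t = abs(x[i + m * tau] - x[j + m * tau])
                d_m1 = d_m if d_m >= t else t
                if d_m <= r:
                    sampen_b += 1
                    if d_m1 <= r:
                        sampen_a += 1
                if d_m1 <= r:
                    apen_cm1[i] += 1
                    apen_cm1[j] += 1
                # fuzzy: baseline-removed Chebyshev distances
                off_m = mean_m[i] - mean_m[j]
                df_m = 0.0
                off_m1 = mean_m1[i] - mean_m1[j]
                df_m1 = 0.0
                for k in range(m + 1):
                    diff = x[i + k * tau] - x[j + k * tau]
                    if k < m:
                        t = abs(diff - off_m)
                        if t > df_m:
                            df_m = t
                    t = abs(diff - off_m1)
                    if t > df_m1:
                        df_m1 = t
                fuzz_dm[fidx] = df_m
                fuzz_dm1[fidx] = df_m1
                fidx += 1
    return dists, apen_cm, apen_cm1, sampen_a, sampen_b, fuzz_dm, fuzz_dm1


@njit(cache=True, fastmath=True)
def apen_phi(x: np.ndarray, m: int, tau: int, r: float) -> float:
    """Pincus Phi_m alone (used when only ApEn at one dimension is needed)."""
    n = x.shape[0] - (m - 1) * tau
    if n < 1:
        return np.nan
    total = 0.0
    for i in range(n):
        count = 0
        for j in range(n):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k * tau] - x[j + k * tau])
                if t > d:
                    d = t
            if d <= r:
                count += 1
        total += np.log(count / n)
    return total / n


@njit(cache=True)
def permutation_counts(x: np.ndarray, k: int, tau: int) -> np.ndarray:
    """Histogram of ordinal patterns of order ``k`` with delay ``tau``.

    Patterns are encoded by the Lehmer code of the sample ranks; ties are
    broken by order of occurrence (earlier sample ranks lower).
    """
    n = x.shape[0] - (k - 1) * tau
    nfact = 1
    for i in range(2, k + 1):
        nfact *= i
    counts = np.zeros(nfact, dtype=np.int64)
    ranks = np.empty(k, dtype=np.int64)
    for i in range(n):
        for a in range(k):
            rk = 0
            va = x[i + a * tau]
            for b in range(k):
                vb = x[i + b * tau]
                if vb < va or (vb == va and b < a):
                    rk += 1
            ranks[a] = rk
        code = 0
        for a in range(k):
            smaller = 0
            for b in range(a + 1, k):
                if ranks[b] < ranks[a]:
                    smaller += 1
            fact = 1
            for c in range(2, k - a):
                fact *= c
            code += smaller * fact
        counts[code] += 1
    return counts


@njit(cache=True, fastmath=True)
def pairwise_chebyshev(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """All pairwise Chebyshev distances between delay-embedded points."""
    n = x.shape[0] - (m - 1) * tau
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k * tau] - x[j + k * tau])
                if t > d:
                    d = t
            out[idx] = d
            idx += 1
    return out
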