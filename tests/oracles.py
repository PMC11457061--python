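"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit Python loops over genotypes, with
no shared code or vectorization from the package, so agreement with the
package is a genuine cross-check of the statistic definitions.
"""

from __future__ import annotations

import math


def _genotypes(matrix):
    """calls as nested lists [[(a, b), ...], ...]."""
    return [[tuple(int(c) for c in cell) for cell in row] for row in matrix.calls]


def oracle_expected_heterozygosity(matrix):
    calls = _genotypes(matrix)
    n_loci = len(calls[0])
    total = 0.0
    for j in range(n_loci):
        ones = 0
        alleles = 0
        for row in calls:
            a, b = row[j]
            if a != 0:
                ones += (a == 1) + (b == 1)
                alleles += 2
        p = ones / alleles
        total += 2.0 * p * (1.0 - p)
    return total / n_loci


def oracle_fixation_index(matrix, skip_monomorphic=False):
    calls = _genotypes(matrix)
    n_loci = len(calls[0])
    ratios = []
    for j in range(n_loci):
        ones = alleles = het = called = 0
        for row in calls:
            a, b = row[j]
            if a != 0:
                ones += (a == 1) + (b == 1)
                alleles += 2
                het += a != b
                called += 1
        p = ones / alleles
        he = 2.0 * p * (1.0 - p)
        if he <= 1e-12:
            if skip_monomorphic:
                continue
            raise ValueError("monomorphic locus")
        ratios.append((het / called) / he)
    return 1.0 - sum(ratios) / len(ratios)


def oracle_multilocus_homozygosity(matrix):
    calls = _genotypes(matrix)
    h = []
    for row in calls:
        h.append(sum(1 for (a, b) in row if a != 0 and a == b))
    s = len(h)
    mean = sum(h) / s
    var = sum((v - mean) ** 2 for v in h) / (s - 1)
    return mean, var


def oracle_burrows_r(matrix, i, j):
    """Clamped Burrows correlation for one pair, or None if unusable."""
    calls = _genotypes(matrix)
    xs, ys = [], []
    for row in calls:
        a1, b1 = row[i]
        a2, b2 = row[j]
        if a1 != 0 and a2 != 0:
            xs.append((a1 == 1) + (b1 == 1))
            ys.append((a2 == 1) + (b2 == 1))
    n = len(xs)
    if n < 2:
        return None
    p = sum(xs) / (2 * n)
    q = sum(ys) / (2 * n)
    if min(p, 1 - p) < 1e-12 or min(q, 1 - q) < 1e-12:
        return None
    delta = sum(x * y for x, y in zip(xs, ys)) / (2 * n) - 2 * p * q
    dx = sum(1 for x in xs if x == 2) / n - p * p
    dy = sum(1 for y in ys if y == 2) / n - q * q
    vx = p * (1 - p) + dx
    vy = q * (1 - q) + dy
    if vx < 1e-12 or vy < 1e-12:
        return None
    r = delta / math.sqrt(vx * vy)
    return max(-1.0, min(1.0, r))


def oracle_mean_r2(matrix):
    n_loci = matrix.calls.shape[1]
    r2s = []
    for i in range(n_loci):
        for j in range(i + 1, n_loci):
            r = oracle_burrows_r(matrix, i, j)
            if r is not None:
                r2s.append(r * r)
    if not r2s:
        return None
    return sum(r2s) / len(r2s)


def oracle_weighted_quantile(values, weights, q):
    """Sort-and-accumulate weighted quantile (inverted CDF)."""
    pairs = sorted(zip(values, weights), key=lambda vw: vw[0])
    total = sum(w for _, w in pairs)
    acc = 0.0
    for v, w in pairs:
        acc += w
        if acc / total >= q - 1e-15:
            return v
    return pairs[-1][0]
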