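"""Independent brute-force oracles used to validate the fast implementations.

Each oracle takes a computation path deliberately different from the library:
exhaustive enumeration over latent configurations, exact integer arithmetic,
or direct double loops. They are only feasible at tiny problem sizes.
"""

import itertools
import math
from fractions import Fraction

import numpy as np

from pbscan.simdata import BASE_CODE


def gl_triple_oracle(bases, quals, major, minor, min_base_quality=20):
    """GL triple by enumerating the chromosome-of-origin of every read.

    For genotype (a1, a2), each read independently comes from either
    chromosome with probability 1/2; summing over all 2^R assignment vectors
    gives the likelihood without ever forming the per-read mixture.
    """
    maj, mnr = BASE_CODE[major], BASE_CODE[minor]
    reads = [
        (BASE_CODE[b], 10.0 ** (-q / 10.0))
        for b, q in zip(bases, quals)
        if q >= min_base_quality and BASE_CODE[b] in (maj, mnr)
    ]
    genotypes = [(maj, maj), (maj, mnr), (mnr, mnr)]

    def e(b, a, eps):
        return 1.0 - eps if b == a else eps / 3.0

    out = []
    for a1, a2 in genotypes:
        total = 0.0
        for assign in itertools.product((a1, a2), repeat=len(reads)):
            prod = (0.5) ** len(reads)
            for (b, eps), allele in zip(reads, assign):
                prod *= e(b, allele, eps)
            total += prod
        out.append(total)
    out = np.array(out)
    if len(reads) == 0:
        return np.ones(3)
    return out / out.max()


def saf_oracle(gl_site):
    """SAF by exhaustive summation over all genotype configurations.

    P(data | j) = sum over (g_1..g_N) with sum g = j of
    prod GL_i(g_i) * prod C(2, g_i) / C(2N, j).
    """
    gl_site = np.asarray(gl_site, dtype=float)
    N = gl_site.shape[0]
    L = np.zeros(2 * N + 1)
    w = [1, 2, 1]
    for config in itertools.product(range(3), repeat=N):
        j = sum(config)
        term = 1.0
        for i, g in enumerate(config):
            term *= gl_site[i, g] * w[g]
        L[j] += term / math.comb(2 * N, j)
    return L / L.max()


def het_exact_oracle(n_AA, n_Aa, n_aa):
    """One-sided heterozygote-excess exact p with exact integer arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_minor = n_Aa + 2 * n_aa
    if n_minor > n:
        n_minor = 2 * n - n_minor
    if n_minor == 0:
        return 1.0
    n_major = 2 * n - n_minor
    ways = {}
    for h in range(n_minor % 2, min(n_minor, n_major) + 1, 2):
        ways[h] = (
            2**h
            * math.factorial(n)
            // (
                math.factorial((n_minor - h) // 2)
                * math.factorial(h)
                * math.factorial((n_major - h) // 2)
            )
        )
    total = sum(ways.values())
    upper = sum(v for h, v in ways.items() if h >= n_Aa)
    return float(Fraction(upper, total))


def fisher_oracle(table):
    """Two-sided Fisher exact p by hypergeometric enumeration (min-likelihood)."""
    table = np.asarray(table)
    r1, r2 = table.sum(axis=1)
    c1, _ = table.sum(axis=0)
    n = table.sum()
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def pmf(a):
        return Fraction(
            math.comb(r1, a) * math.comb(r2, c1 - a), math.comb(n, c1)
        )

    obs = pmf(table[0, 0])
    p = Fraction(0)
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        q = pmf(a)
        if q <= obs:
            p += q
    return float(p)


def fst_components_oracle(saf1, saf2, eta, n1, n2):
    """Posterior-expected Hudson components by an explicit double loop."""
    J, K = 2 * n1 + 1, 2 * n2 + 1
    a_num = d_num = z = 0.0
    for j in range(J):
        for k in range(K):
            p1, p2 = j / (2 * n1), k / (2 * n2)
            w = eta[j, k] * saf1[j] * saf2[k]
            N = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
            D = p1 * (1 - p2) + p2 * (1 - p1)
            a_num += w * N
            d_num += w * D
            z += w
    return a_num / z, d_num / z
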