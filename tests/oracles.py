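"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive enumeration, closed
forms, brute-force distance computations — and shares nothing with the
production code paths except the embedded isotope constant table (by design,
so the comparisons exercise the algorithms, not the constants).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from turnoverms.constants import ISOTOPES


def _count_vectors(n: int, k: int):
    """All ways to split n atoms over k isotopes."""
    if k == 1:
        yield (n,)
        return
    for i in range(n + 1):
        for rest in _count_vectors(n - i, k - 1):
            yield (i,) + rest


def _element_distribution(element: str, n: int, n15_p: float | None):
    """Exact shift -> (probability, probability-weighted mass offset) map."""
    isotopes = ISOTOPES[element]
    if element == "N" and n15_p is not None:
        isotopes = [
            (isotopes[0][0], 1.0 - n15_p),
            (isotopes[1][0], n15_p),
        ]
    base = isotopes[0][0]
    out: dict[int, list[float]] = {}
    for counts in _count_vectors(n, len(isotopes)):
        coeff = math.factorial(n)
        prob = 1.0
        shift = 0
        dmass = 0.0
        for c, (mass, p) in zip(counts, isotopes):
            coeff //= math.factorial(c)
            prob *= p**c
            shift += c * int(round(mass - base))
            dmass += c * (mass - base)
        prob *= coeff
        cell = out.setdefault(shift, [0.0, 0.0])
        cell[0] += prob
        cell[1] += prob * dmass
    return out


def brute_force_envelope(
    counts: dict[str, int], n15_p: float | None = None
) -> dict[int, tuple[float, float]]:
    """Isotopologue distribution by neutron shift via exhaustive enumeration.

    Returns shift -> (abundance, mean mass offset from the all-lightest
    isotopologue).  Elements are enumerated exactly and combined by explicit
    nested iteration over the per-element shift maps.
    """
    combined: dict[int, list[float]] = {0: [1.0, 0.0]}
    for element, n in counts.items():
        if n == 0:
            continue
        dist = _element_distribution(element, n, n15_p)
        merged: dict[int, list[float]] = {}
        for s1, (p1, pm1) in combined.items():
            for s2, (p2, pm2) in dist.items():
                cell = merged.setdefault(s1 + s2, [0.0, 0.0])
                cell[0] += p1 * p2
                cell[1] += p1 * pm2 + pm1 * p2
        combined = merged
    return {s: (p, pm / p if p > 0 else 0.0) for s, (p, pm) in combined.items()}


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric draw, from binomial coefficients."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(n, K) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def fisher_two_sided(table: list[list[int]]) -> float:
    """Two-sided Fisher exact p by enumerating tables with fixed margins."""
    (a, b), (c, d) = table
    row1, col1, N = a + b, a + c, a + b + c + d
    denom = math.comb(N, row1)

    def prob(x: int) -> float:
        return math.comb(col1, x) * math.comb(N - col1, row1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - N), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


def brute_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width from explicit pairwise distances."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    widths = []
    for i in range(n):
        dists = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
        own = dists[(labels == labels[i])]
        a = (own.sum()) / (len(own) - 1) if len(own) > 1 else 0.0
        b = min(
            dists[labels == other].mean()
            for other in set(labels)
            if other != labels[i]
        )
        widths.append(0.0 if len(own) <= 1 else (b - a) / max(a, b))
    return float(np.mean(widths))


def permutation_anova_p(
    groups: list[np.ndarray], n_perm: int = 10_000, seed: int = 0
) -> float:
    """Permutation p-value for the one-way ANOVA F statistic."""
    from scipy.stats import f_oneway

    rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    f_obs = f_oneway(*groups).statistic
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if f_oneway(*parts).statistic >= f_obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def kruskal_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H from the textbook rank formula (no tie correction)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, len(pooled) + 1)
    N = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() ** 2)
        start += len(g)
    return 12.0 / (N * (N + 1)) * h - 3 * (N + 1)


def student_t(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-variance two-sample t statistic from the hand formula."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    return float((np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb)))
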