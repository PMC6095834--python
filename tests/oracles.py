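"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive each statistic by direct enumeration or
exhaustive sorting, sharing no code with the implementations they check.
"""

import numpy as np
from scipy import stats
from scipy.special import comb


def brute_force_nb_p(k0, k1, s0, s1, alpha):
    """Conditional two-sided NB p-value by naive term-by-term enumeration."""
    k0, k1 = np.asarray(k0), np.asarray(k1)
    s0, s1 = np.asarray(s0, float), np.asarray(s1, float)
    K = int(k0.sum() + k1.sum())
    q0 = np.concatenate([k0 / s0, k1 / s1]).mean()
    mu_a, mu_b = q0 * s0.sum(), q0 * s1.sum()
    var_a = mu_a + alpha * q0**2 * (s0**2).sum()
    var_b = mu_b + alpha * q0**2 * (s1**2).sum()

    def pmf(k, m, v):
        if v <= m or m == 0:
            return stats.poisson.pmf(k, m)
        p, r = m / v, m * m / (v - m)
        return stats.nbinom.pmf(k, r, p)

    terms = [pmf(a, mu_a, var_a) * pmf(K - a, mu_b, var_b)
             for a in range(K + 1)]
    obs = terms[int(k0.sum())]
    return min(1.0, sum(t for t in terms if t <= obs * (1 + 1e-7)) / sum(terms))


def hypergeom_fisher(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration
    (minimum-likelihood rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / denom

    obs = prob(a)
    return min(1.0, sum(p for x in range(c1 + 1)
                        if (p := prob(x)) <= obs * (1 + 1e-7)))


def brute_force_ranks(results):
    """Exhaustive second-best-hairpin gene ranking: sort hairpins by
    (log2fc, p, id), take each gene's second smallest rank, order genes."""
    kept = results[results["retained"]]
    order = sorted(
        kept.index, key=lambda h: (kept.loc[h, "log2fc"],
                                   kept.loc[h, "p_value"], h)
    )
    hp_rank = {h: i + 1 for i, h in enumerate(order)}
    sentinel = len(order) + 1
    second, best = {}, {}
    for gene in kept["gene"].unique():
        ranks = sorted(hp_rank[h] for h in kept.index[kept["gene"] == gene])
        best[gene] = ranks[0]
        second[gene] = ranks[1] if len(ranks) > 1 else sentinel
    gene_order = sorted(second, key=lambda g: (second[g], best[g], g))
    return second, {g: i + 1 for i, g in enumerate(gene_order)}
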