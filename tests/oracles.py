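"""Independent brute-force reference implementations used as test oracles.

Deliberately written with plain loops and textbook formulas, sharing no
code with the package under test.
"""

import math


def mean(xs):
    return sum(xs) / len(xs)


def sample_sd(xs):
    m = mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def sample_var(xs):
    m = mean(xs)
    return sum((x - m) ** 2 for x in xs) / (len(xs) - 1)


def ols_fit(x, y):
    """Normal-equations OLS: returns (slope, intercept, r_squared)."""
    n = len(x)
    mx, my = mean(x), mean(y)
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((yi - (intercept + slope * xi)) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - my) ** 2 for yi in y)
    r2 = 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def pairwise_sd_brute(log2q, g1, g2):
    """log2q: dict gene -> list of per-sample log2 quantities."""
    ratios = [a - b for a, b in zip(log2q[g1], log2q[g2])]
    return sample_sd(ratios)


def m_value_brute(log2q, gene, panel):
    others = [k for k in panel if k != gene]
    return mean([pairwise_sd_brute(log2q, gene, k) for k in others])


def rank_stability_brute(log2q, genes):
    """Full iterative-exclusion reference: returns (m, rank, round) per gene."""
    panel = list(genes)
    G = len(panel)
    out = {}
    rnd = 0
    while len(panel) > 3:
        rnd += 1
        ms = {g: m_value_brute(log2q, g, panel) for g in panel}
        worst_m = max(ms.values())
        worst = max(g for g in panel if ms[g] == worst_m)
        out[worst] = (ms[worst], len(panel), rnd)
        panel.remove(worst)
    final = {g: m_value_brute(log2q, g, panel) for g in panel}
    for pos, g in enumerate(sorted(panel, key=lambda g: (final[g], g))):
        out[g] = (final[g], pos + 1, 0)
    return out


def nf_brute(log2q, genes):
    """Per-sample geometric mean of quantities (returned on linear scale)."""
    n_samples = len(next(iter(log2q.values())))
    return [
        2.0 ** mean([log2q[g][s] for g in genes]) for s in range(n_samples)
    ]


def v_brute(log2q, ranked, n, metric="sd"):
    nf_n = nf_brute(log2q, ranked[:n])
    nf_n1 = nf_brute(log2q, ranked[: n + 1])
    ratios = [math.log2(a / b) for a, b in zip(nf_n, nf_n1)]
    return sample_sd(ratios) if metric == "sd" else sample_var(ratios)


def pooled_t_brute(control, treated):
    """Textbook pooled two-sample t of mean(treated) - mean(control).

    Returns (d, se, t, df).
    """
    n1, n2 = len(control), len(treated)
    d = mean(treated) - mean(control)
    sp2 = ((n1 - 1) * sample_var(control) + (n2 - 1) * sample_var(treated)) / (
        n1 + n2 - 2
    )
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return d, se, d / se, n1 + n2 - 2


def bh_brute(pvalues):
    """Literal step-up definition: adj_(i) = min_{j >= i} (m * p_(j) / j)."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    for pos, idx in enumerate(indexed):
        candidates = [
            m * pvalues[indexed[j]] / (j + 1) for j in range(pos, m)
        ]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted
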