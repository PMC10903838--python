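"""Independent textbook-formula implementations of the statistical tests.

These deliberately avoid scipy.stats: statistics and degrees of freedom are
computed from the explicit formulas, and P values go through the incomplete
beta function directly, so they form an independent route against which the
package's statistics layer is checked.
"""

import math

from scipy.special import betainc


def _t_sf_two_sided(t, dof):
    # two-sided P for Student's t via the regularized incomplete beta function
    x = dof / (dof + t * t)
    return betainc(dof / 2.0, 0.5, x)


def _mean(xs):
    return sum(xs) / len(xs)


def _var(xs):
    m = _mean(xs)
    return sum((x - m) ** 2 for x in xs) / (len(xs) - 1)


def paired_t_oracle(deltas):
    n = len(deltas)
    m = _mean(deltas)
    sd = math.sqrt(_var(deltas))
    t = m / (sd / math.sqrt(n))
    dof = n - 1
    return t, dof, _t_sf_two_sided(t, dof)


def welch_t_oracle(a, b):
    na, nb = len(a), len(b)
    va, vb = _var(a), _var(b)
    se2 = va / na + vb / nb
    t = (_mean(a) - _mean(b)) / math.sqrt(se2)
    dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, dof, _t_sf_two_sided(t, dof)


def anova_oracle(groups):
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = _mean([x for g in groups for x in g])
    ss_between = sum(len(g) * (_mean(g) - grand) ** 2 for g in groups)
    ss_within = sum((x - _mean(g)) ** 2 for g in groups for x in g)
    d1, d2 = k - 1, N - k
    f = (ss_between / d1) / (ss_within / d2)
    p = betainc(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * f))
    return f, d1, d2, p


def average_ranks(xs):
    """Average ranks (1-based) with ties sharing the mean rank."""
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(xs):
        j = i
        while j + 1 < len(xs) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_oracle(x, y):
    mx, my = _mean(x), _mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def spearman_oracle(x, y):
    rho = pearson_oracle(average_ranks(x), average_ranks(y))
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, _t_sf_two_sided(t, n - 2)
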