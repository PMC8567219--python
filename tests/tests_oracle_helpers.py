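"""Independent brute-force oracles shared by test modules."""

from math import comb


def fisher_enum(table):
    """Two-sided Fisher exact p via full hypergeometric enumeration with
    exact integer binomial weights."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def weight(x):
        return comb(r1, x) * comb(r2, c1 - x)

    w_obs = weight(a)
    total = sum(
        weight(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if weight(x) <= w_obs
    )
    return total / comb(n, c1)


def bh_stepup(pvalues):
    """Textbook Benjamini-Hochberg step-up q-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvalues[i] * m / rank)
        q[i] = prev
    return q
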