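"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and exact (big integers / Fractions),
sharing no code with the package under test.
"""

from fractions import Fraction
from math import comb


def ac_pmf_prefix(x: int, kmax: int, n1: int, n2: int):
    """Exact prefix sums F(k) = sum_{j<=k} p(j|x) of the conditional law.

    p(j|x) = (n2/n1)^j * C(x+j, j) / (1 + n2/n1)^(x+j+1), exact rationals.
    """
    r = Fraction(n2, n1)
    p = Fraction(1, 1) / (1 + r) ** (x + 1)
    prefix = [p]
    for k in range(1, kmax + 1):
        p = p * r * (x + k) / (k * (1 + r))
        prefix.append(prefix[-1] + p)
    return prefix


def ac_pvalue_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided AC p-value by direct summation: 2*min(lower, upper) capped."""
    prefix = ac_pmf_prefix(x, y, n1, n2)
    lower = prefix[y]
    upper = 1 - (prefix[y - 1] if y > 0 else Fraction(0))
    return min(Fraction(1), 2 * min(lower, upper))


def hypergeom_upper_exact(N: int, n: int, M: int, m: int) -> Fraction:
    """P(X >= m) for X hypergeometric(N, M, n), exact."""
    total = comb(N, n)
    acc = sum(comb(M, i) * comb(N - M, n - i) for i in range(m))
    return 1 - Fraction(acc, total)


def naive_reference_tags(sequence: str):
    """All (position, 17bp tag) pairs 3' of CATG, by exhaustive window scan."""
    out = []
    for i in range(len(sequence) - 3):
        if sequence[i : i + 4] == "CATG":
            tag = sequence[i + 4 : i + 21]
            if len(tag) == 17 and "N" not in tag:
                out.append((i, tag))
    return out


def hamming(a: str, b: str) -> int:
    return sum(c != d for c, d in zip(a, b))


def brute_force_classify(tag: str, tag_to_genes: dict):
    """All-pairs Hamming resolution: exact hits take precedence, else d=1."""
    exact = tag_to_genes.get(tag)
    if exact is not None:
        return tuple(sorted(exact))
    genes = set()
    for ref, g in tag_to_genes.items():
        if len(ref) == len(tag) and hamming(ref, tag) == 1:
            genes.update(g)
    return tuple(sorted(genes))


def bh_adjust_naive(pvals):
    """Textbook step-up BH: q_i = min_{j>=i} p_(j) * m / j, order-aligned."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q
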