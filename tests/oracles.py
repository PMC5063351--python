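"""Independent oracles used by the test suite.

These deliberately avoid the package's own dynamic-programming code:
alignment scores come from exhaustive enumeration of alignments, tandem
repeats from direct (unit, count) enumeration, binomial tails from an
explicit sum.
"""

from itertools import product
from math import comb


def brute_global_score(a, b, match, mismatch, go, ge):
    """Best affine-gap global alignment score of a vs b by exhaustive
    recursion over alignment paths (a gap of length L costs go + L*ge)."""
    best = [None]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            rec(i + 1, j, score + ge + (go if last != "A" else 0), "A")
        if j < len(b):
            rec(i, j + 1, score + ge + (go if last != "B" else 0), "B")

    rec(0, 0, 0, "M")
    return best[0]


def brute_local_score(a, b, scheme):
    """Best local alignment score = max over all substring pairs of the
    exhaustive global score, floored at 0 (the empty alignment)."""
    best = 0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    s = brute_global_score(
                        a[i0:i1], b[j0:j1],
                        scheme.match, scheme.mismatch,
                        scheme.gap_open, scheme.gap_extend,
                    )
                    if s > best:
                        best = s
    return best


_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}


def naive_iupac_find(seq, consensus):
    """Forward-strand exact-IUPAC matching by expanding the consensus into
    every concrete string and running str-based search."""
    hits = set()
    for concrete in product(*(_IUPAC_SETS[c] for c in consensus)):
        pat = "".join(concrete)
        start = seq.find(pat)
        while start != -1:
            hits.add(start)
            start = seq.find(pat, start + 1)
    return sorted(hits)


def brute_tandem_runs(seq, max_unit=6, min_copies=3):
    """All (unit, count, start) tandem runs of primitive units, by direct
    enumeration."""
    out = []
    n = len(seq)
    for ulen in range(1, max_unit + 1):
        for i in range(n - ulen + 1):
            unit = seq[i : i + ulen]
            if any(
                ulen % p == 0 and unit == unit[:p] * (ulen // p)
                for p in range(1, ulen)
            ):
                continue
            if i >= ulen and seq[i - ulen : i] == unit:
                continue
            j = i + ulen
            while j + ulen <= n and seq[j : j + ulen] == unit:
                j += ulen
            count = (j - i) // ulen
            if count >= min_copies:
                out.append((unit, count, i))
    return out


def binomial_tail(k, n, p):
    """One-sided P(X >= k) for X ~ Binomial(n, p), by explicit summation."""
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))
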