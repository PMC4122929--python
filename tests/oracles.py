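"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through a different route than the
package (explicit dynamic programming, literal genetic-code table,
exhaustive enumeration) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

# literal standard genetic code (independent of the package's table)
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def local_affine_score(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> float:
    """Full Gotoh local-alignment optimum (score only).

    Gap scoring convention: first gapped position scores gap_open, each
    further position gap_extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Him = H[i], H[i - 1]
        Ei, Eim = E[i], E[i - 1]
        Fi = F[i]
        for j in range(1, m + 1):
            Ei[j] = max(Eim[j] + gap_extend, Him[j] + gap_open)
            Fi[j] = max(Fi[j - 1] + gap_extend, Hi[j - 1] + gap_open)
            s = match if ai == b[j - 1] else mismatch
            h = max(0.0, Him[j - 1] + s, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best = h
    return best


def global_affine_score(
    a: str, b: str, submat, gap_open: float = -10.0, gap_extend: float = -1.0
) -> float:
    """Global (end-gap-penalized) affine alignment optimum."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        F[0][j] = gap_open + gap_extend * (j - 1)
        H[0][j] = F[0][j]
    for i in range(1, n + 1):
        E[i][0] = gap_open + gap_extend * (i - 1)
        H[i][0] = E[i][0]
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            F[i][j] = max(F[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            s = submat[a[i - 1], b[j - 1]]
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[n][m]


def ng_sites(codon: str) -> float:
    """Synonymous sites of a sense codon by direct enumeration; changes
    into stops count as nonsynonymous."""
    aa = GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base != codon[pos]:
                alt = codon[:pos] + base + codon[pos + 1 :]
                if GENETIC_CODE[alt] == aa:
                    syn += 1
    return syn / 3.0


def ng_pathways(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences between sense codons;
    orderings through stop codons excluded unless all are blocked."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                blocked = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt] and GENETIC_CODE[cur] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, blocked))
    ok = [(s, n) for s, n, b in results if not b]
    if not ok:
        ok = [(s, n) for s, n, _ in results]
    return (
        sum(s for s, _ in ok) / len(ok),
        sum(n for _, n in ok) / len(ok),
    )


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric tail summation."""
    def log_fact(x: int) -> float:
        return math.lgamma(x + 1)

    def log_hyper(a_: int) -> float:
        b_ = a + b - a_
        c_ = a + c - a_
        d_ = d - a + a_
        return (
            log_fact(a + b) + log_fact(c + d) + log_fact(a + c) + log_fact(b + d)
            - log_fact(a_) - log_fact(b_) - log_fact(c_) - log_fact(d_)
            - log_fact(a + b + c + d)
        )

    lo = max(0, a - d)
    hi = min(a + b, a + c)
    p_obs = log_hyper(a)
    total = 0.0
    for a_ in range(lo, hi + 1):
        lp = log_hyper(a_)
        if lp <= p_obs + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)
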