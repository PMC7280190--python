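"""Independent reference implementations used only to check the package.

Deliberately naive: plain-Python dynamic programming, brute-force
enumeration, Monte-Carlo simulation.  Nothing here imports the package's
compute kernels.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

NEG = float("-inf")


def gotoh_local(q: str, s: str, match=2, mismatch=-3, gap_open=5, gap_ext=2):
    """Exhaustive affine-gap local alignment DP (plain Python).

    A gap of length L costs gap_open + L*gap_ext.  Returns a dict with
    score, coverage (% of query in the alignment), identity (% identical
    columns, gaps in the denominator).  Traceback prefers diagonal, then a
    gap in the query, then a gap in the subject; the best cell is the first
    strict maximum in row-major order.
    """
    m, n = len(q), len(s)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_ext, H[i][j - 1] - gap_open - gap_ext)
            F[i][j] = max(F[i - 1][j] - gap_ext, H[i - 1][j] - gap_open - gap_ext)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return {"score": 0.0, "coverage": 0.0, "identity": 0.0}
    i, j, state = bi, bj, "H"
    columns = ident = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            sub = match if q[i - 1] == s[j - 1] else mismatch
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + sub:
                columns += 1
                ident += q[i - 1] == s[j - 1]
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i][j - 1] - gap_open - gap_ext:
                state = "H"
            j -= 1
        else:
            columns += 1
            if F[i][j] == H[i - 1][j] - gap_open - gap_ext:
                state = "H"
            i -= 1
    return {
        "score": best,
        "coverage": 100.0 * (bi - i) / m,
        "identity": 100.0 * ident / columns,
    }


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_expansions(primer: str) -> list[str]:
    return ["".join(p) for p in itertools.product(*(IUPAC[c] for c in primer.upper()))]


def brute_force_primer_sites(sequence: str, primer: str) -> list[int]:
    """Every offset where some IUPAC expansion of the primer matches exactly."""
    seq = sequence.upper()
    k = len(primer)
    hits = []
    expansions = set(iupac_expansions(primer))
    for off in range(len(seq) - k + 1):
        if seq[off : off + k] in expansions:
            hits.append(off)
    return hits


def connected_components(n: int, relation) -> list[frozenset]:
    """Brute-force components of a symmetric relation via networkx."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if relation(i, j):
                g.add_edge(i, j)
    return [frozenset(c) for c in nx.connected_components(g)]


def mc_rarefaction_richness(counts, depth: int, n_rep: int, seed: int) -> np.ndarray:
    """Monte-Carlo expected richness after subsampling without replacement."""
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(counts)), counts)
    out = np.empty(n_rep)
    for r in range(n_rep):
        sub = rng.choice(pool, size=depth, replace=False)
        out[r] = len(np.unique(sub))
    return out


def exact_rank_sum_two_sided_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Uses midranks for ties; two-sided p doubles the smaller tail
    probability of the rank-sum of the first group (capped at 1).
    """
    from scipy.stats import rankdata

    x, y = list(x), list(y)
    pooled = np.array(x + y, dtype=float)
    ranks = rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    sums = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n1)]
    sums = np.array(sums)
    lower = np.mean(sums <= obs + 1e-9)
    upper = np.mean(sums >= obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


def expected_pairwise_identity(divergence: float) -> float:
    """Two lineages mutated independently from a common ancestor at rate d:
    a site matches iff neither mutated, or both mutated to the same base."""
    d = divergence
    return (1 - d) ** 2 + d**2 / 3.0
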