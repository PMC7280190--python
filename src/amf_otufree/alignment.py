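"""Local pairwise alignment with a BLASTN-like scoring scheme.

Per-read taxonomic classification needs, for every read/reference pair, the
best local alignment's *coverage* (fraction of the query spanned) and
*identity* (identical columns over all aligned columns, gap columns included
in the denominator).  The aligner is an affine-gap Smith-Waterman (Gotoh)
dynamic program with fixed scoring

    match +2, mismatch -3, gap of length L costs 5 + 2*L

i.e. BLASTN-like defaults.  The DP is JIT-compiled with numba; an optional
diagonal band (seeded from shared k-mers) makes the pipeline paths fast
without changing the contract — the unbanded DP is exact.

Tie-breaking is fixed so runs are reproducible: the best cell is the first
maximal cell in row-major order, and the traceback prefers diagonal moves,
then gaps in the query (horizontal), then gaps in the subject (vertical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 2
MISMATCH = -3
GAP_OPEN = 5  # charged once per gap run, on top of the per-base extension
GAP_EXTEND = 2

_NEG = -(10**7)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0-3; reject anything else."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size == 0:
        raise ValueError("empty sequence")
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return arr


@njit(cache=True)
def _gotoh_fill(q, s, lo, hi, match, mismatch, gap_open, gap_ext):
    m = q.shape[0]
    n = s.shape[0]
    H = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    for j in range(0, n + 1):
        if lo <= j <= hi:
            H[0, j] = 0
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        j0 = i + lo
        if j0 < 0:
            j0 = 0
        j1 = i + hi
        if j1 > n:
            j1 = n
        if j0 <= 0:
            if lo <= -i <= hi:
                H[i, 0] = 0
            j0 = 1
        for j in range(j0, j1 + 1):
            e = E[i, j - 1] - gap_ext
            t = H[i, j - 1] - gap_open - gap_ext
            if t > e:
                e = t
            E[i, j] = e
            f = F[i - 1, j] - gap_ext
            t = H[i - 1, j] - gap_open - gap_ext
            if t > f:
                f = t
            F[i, j] = f
            d = H[i - 1, j - 1]
            if d > _NEG:
                if q[i - 1] == s[j - 1]:
                    d += match
                else:
                    d += mismatch
            h = 0
            if d > h:
                h = d
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _gotoh_traceback(q, s, H, E, F, bi, bj, match, mismatch, gap_open, gap_ext):
    # returns (q_start, q_end, s_start, s_end, columns, identical)
    i = bi
    j = bj
    columns = 0
    ident = 0
    state = 0  # 0=H, 1=E (gap in subject column consumed), 2=F
    while i > 0 or j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            d = H[i - 1, j - 1] if (i > 0 and j > 0) else _NEG
            if d > _NEG:
                sc = match if q[i - 1] == s[j - 1] else mismatch
            else:
                sc = 0
            if i > 0 and j > 0 and H[i, j] == d + sc and d > _NEG:
                columns += 1
                if q[i - 1] == s[j - 1]:
                    ident += 1
                i -= 1
                j -= 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = 2
            else:  # pragma: no cover - defensive
                break
        elif state == 1:
            # gap in the query: consume a subject base
            columns += 1
            if E[i, j] == H[i, j - 1] - gap_open - gap_ext:
                j -= 1
                state = 0
            else:
                j -= 1
                # remain in E (longer gap run)
        else:
            # gap in the subject: consume a query base
            columns += 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_ext:
                i -= 1
                state = 0
            else:
                i -= 1
    return i, bi, j, bj, columns, ident


@njit(cache=True)
def _gotoh_fill_banded(q, s, lo, hi, match, mismatch, gap_open, gap_ext):
    # compact band storage: cell (i, j) lives at column c = j - i - lo + 1;
    # columns 0 and width-1 are permanent out-of-band sentinels.
    m = q.shape[0]
    n = s.shape[0]
    width = hi - lo + 3
    H = np.full((m + 1, width), _NEG, dtype=np.int32)
    E = np.full((m + 1, width), _NEG, dtype=np.int32)
    F = np.full((m + 1, width), _NEG, dtype=np.int32)
    for j in range(0, n + 1):
        c = j - lo + 1
        if 1 <= c <= width - 2:
            H[0, c] = 0
    best = 0
    bi = 0
    bc = 0
    for i in range(1, m + 1):
        j0 = i + lo
        if j0 < 0:
            j0 = 0
        j1 = i + hi
        if j1 > n:
            j1 = n
        if j0 <= 0:
            c0 = 0 - i - lo + 1
            if 1 <= c0 <= width - 2:
                H[i, c0] = 0
            j0 = 1
        for j in range(j0, j1 + 1):
            c = j - i - lo + 1
            e = E[i, c - 1] - gap_ext
            t = H[i, c - 1] - gap_open - gap_ext
            if t > e:
                e = t
            E[i, c] = e
            f = F[i - 1, c + 1] - gap_ext
            t = H[i - 1, c + 1] - gap_open - gap_ext
            if t > f:
                f = t
            F[i, c] = f
            d = H[i - 1, c]
            if d > _NEG:
                if q[i - 1] == s[j - 1]:
                    d += match
                else:
                    d += mismatch
            h = 0
            if d > h:
                h = d
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, c] = h
            if h > best:
                best = h
                bi = i
                bc = c
    return H, E, F, best, bi, bc


@njit(cache=True)
def _gotoh_traceback_banded(q, s, H, E, F, bi, bc, lo, match, mismatch, gap_open, gap_ext):
    i = bi
    c = bc
    columns = 0
    ident = 0
    state = 0
    while True:
        j = c + i + lo - 1
        if state == 0:
            if H[i, c] == 0 or i == 0 or j < 0:
                break
            d = H[i - 1, c]
            ok_diag = i > 0 and j > 0 and d > _NEG
            if ok_diag:
                sc = match if q[i - 1] == s[j - 1] else mismatch
                ok_diag = H[i, c] == d + sc
            if ok_diag:
                columns += 1
                if q[i - 1] == s[j - 1]:
                    ident += 1
                i -= 1
            elif j > 0 and H[i, c] == E[i, c]:
                state = 1
            elif i > 0 and H[i, c] == F[i, c]:
                state = 2
            else:  # pragma: no cover - defensive
                break
        elif state == 1:
            columns += 1
            if E[i, c] == H[i, c - 1] - gap_open - gap_ext:
                state = 0
            c -= 1
        else:
            columns += 1
            if F[i, c] == H[i - 1, c + 1] - gap_open - gap_ext:
                state = 0
            i -= 1
            c += 1
    j = c + i + lo - 1
    return i, bi, j, bc + bi + lo - 1, columns, ident


@dataclass
class AlignmentHit:
    """Best local alignment of a query against one subject.

    coverage is the percentage of *query* bases inside the local alignment;
    identity is identical columns over all aligned columns (gap columns count
    in the denominator), as a percentage.
    """

    query_id: str
    subject_accession: str
    coverage: float
    identity: float
    score: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def meets(self, min_cov: float, min_ident: float) -> bool:
        return self.coverage >= min_cov and self.identity >= min_ident


def align_pair(
    query: str,
    subject: str,
    query_id: str = "",
    subject_accession: str = "",
    band: tuple[int, int] | None = None,
) -> AlignmentHit:
    """Best local (Smith-Waterman/Gotoh) alignment of ``query`` vs ``subject``.

    ``band``, if given, restricts the DP to diagonals ``j - i`` in the closed
    interval ``band`` (a seeded heuristic; ``None`` means the exact full DP).
    Raises ValueError on empty or non-ACGT input.
    """
    q = encode_sequence(query)
    s = encode_sequence(subject)
    if band is None:
        lo, hi = -len(query), len(subject)
        H, E, F, best, bi, bj = _gotoh_fill(
            q, s, lo, hi, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND
        )
        if best <= 0:
            return AlignmentHit(query_id, subject_accession, 0.0, 0.0, 0.0)
        qs, qe, ss, se, columns, ident = _gotoh_traceback(
            q, s, H, E, F, bi, bj, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND
        )
    else:
        lo = max(int(band[0]), -len(query))
        hi = min(int(band[1]), len(subject))
        if lo > hi:
            return AlignmentHit(query_id, subject_accession, 0.0, 0.0, 0.0)
        H, E, F, best, bi, bc = _gotoh_fill_banded(
            q, s, lo, hi, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND
        )
        if best <= 0:
            return AlignmentHit(query_id, subject_accession, 0.0, 0.0, 0.0)
        qs, qe, ss, se, columns, ident = _gotoh_traceback_banded(
            q, s, H, E, F, bi, bc, lo, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND
        )
    coverage = 100.0 * (qe - qs) / len(query)
    identity = 100.0 * ident / columns if columns else 0.0
    return AlignmentHit(
        query_id, subject_accession, coverage, identity, float(best), qs, qe, ss, se
    )


class KmerIndex:
    """Inverted k-mer index over a set of subject sequences.

    Used as a seeding prefilter: a query shares many exact k-mers with any
    subject it is ≥97% identical to, so candidate subjects (and the diagonal
    band of the putative alignment) can be found without aligning against
    everything.
    """

    def __init__(self, sequences: list[str], k: int = 11):
        self.k = k
        self.n = len(sequences)
        self.lengths = [len(s) for s in sequences]
        index: dict[str, list[tuple[int, int]]] = {}
        for idx, seq in enumerate(sequences):
            for pos in range(0, len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((idx, pos))
        self._index = index

    def add(self, seq: str, idx: int | None = None) -> int:
        if idx is None:
            idx = self.n
        for pos in range(0, len(seq) - self.k + 1):
            self._index.setdefault(seq[pos : pos + self.k], []).append((idx, pos))
        self.n = max(self.n, idx + 1)
        self.lengths.append(len(seq))
        return idx

    def candidates(
        self,
        query: str,
        stride: int = 8,
        top_n: int = 3,
        min_share: int = 2,
        pad: int = 16,
    ) -> list[tuple[int, int, tuple[int, int]]]:
        """Rank subjects by shared (sampled) k-mers.

        Returns up to ``top_n`` tuples ``(subject_idx, shared, (lo, hi))``
        sorted by decreasing share, where (lo, hi) is a padded diagonal band
        covering the shared k-mer diagonals.
        """
        k = self.k
        index = self._index
        counts: dict[int, int] = {}
        dmin: dict[int, int] = {}
        dmax: dict[int, int] = {}
        for qpos in range(0, max(1, len(query) - k + 1), stride):
            hits = index.get(query[qpos : qpos + k])
            if not hits:
                continue
            for idx, spos in hits:
                d = spos - qpos
                if idx in counts:
                    counts[idx] += 1
                    if d < dmin[idx]:
                        dmin[idx] = d
                    elif d > dmax[idx]:
                        dmax[idx] = d
                else:
                    counts[idx] = 1
                    dmin[idx] = d
                    dmax[idx] = d
        ranked = sorted(
            ((idx, c) for idx, c in counts.items() if c >= min_share),
            key=lambda t: (-t[1], t[0]),
        )[:top_n]
        return [(idx, c, (dmin[idx] - pad, dmax[idx] + pad)) for idx, c in ranked]


def relation_band(len_a: int, len_b: int, pad: int = 32) -> tuple[int, int]:
    """A generous default band for comparing two near-identical sequences."""
    return (-pad, len_b - len_a + pad) if len_b >= len_a else (len_b - len_a - pad, pad)
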