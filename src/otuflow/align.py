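"""Numba-backed sequence comparison kernels.

All kernels share one base encoding: A,C,G,T -> 0..3, anything else
(N and the remaining IUPAC ambiguity codes) -> 4.  Two positions match only
when both codes are < 4 and equal, so ambiguous bases never match anything,
including themselves.

The pairwise aligner is semi-global Needleman-Wunsch: match +1, mismatch -1,
gap -2 (linear), terminal gaps free on both sequences.  Identity excludes
terminal gap columns and counts each internal gap column as one difference:

    identity = matches / (matches + mismatches + internal_gap_columns)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -2

_LUT = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A,C,G,T -> 0..3; other -> 4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[arr & 0x7F]


@dataclass
class Alignment:
    """A pairwise semi-global alignment between two sequences.

    ``identity`` excludes terminal gap columns entirely; ``glocal_identity``
    additionally charges the denominator for unaligned bases of sequence a
    (the query), so a short glancing alignment between unrelated sequences
    cannot masquerade as a high-identity hit.  Threshold decisions
    (clustering, mapping, classification) use ``glocal_identity``.
    """

    aligned_a: str
    aligned_b: str
    matches: int
    mismatches: int
    internal_gaps: int
    terminal_gaps: int
    score: int
    a_unaligned: int = 0
    b_unaligned: int = 0

    @property
    def identity(self) -> float:
        denom = self.matches + self.mismatches + self.internal_gaps
        return self.matches / denom if denom else 0.0

    @property
    def glocal_identity(self) -> float:
        denom = (
            self.matches + self.mismatches + self.internal_gaps + self.a_unaligned
        )
        return self.matches / denom if denom else 0.0


@njit(cache=True)
def _sg_fill(a, b):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), np.int32)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = 1 if (ai == b[j - 1] and ai < 4) else -1
            best = H[i - 1, j - 1] + s
            t = H[i - 1, j] - 2
            if t > best:
                best = t
            t = H[i, j - 1] - 2
            if t > best:
                best = t
            H[i, j] = best
    return H


@njit(cache=True)
def _sg_traceback(a, b):
    """Fill + traceback.  Returns (score, i0, j0, bi, bj, ops).

    ops are traceback steps from (i0,j0) to (bi,bj): 0 diagonal, 1 up
    (gap in b), 2 left (gap in a).  The best end cell is chosen over the
    last row and last column; ties prefer the cell closest to the corner
    (largest i+j, then largest i).
    """
    n, m = len(a), len(b)
    H = _sg_fill(a, b)
    best = H[n, m]
    bi, bj = n, m
    for j in range(m + 1):
        if H[n, j] > best or (H[n, j] == best and n + j > bi + bj):
            best = H[n, j]
            bi, bj = n, j
    for i in range(n + 1):
        if H[i, m] > best or (
            H[i, m] == best and (i + m > bi + bj or (i + m == bi + bj and i > bi))
        ):
            best = H[i, m]
            bi, bj = i, m
    ops = np.empty(n + m, np.uint8)
    k = 0
    i, j = bi, bj
    while i > 0 and j > 0:
        h = H[i, j]
        s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else -1
        if h == H[i - 1, j - 1] + s:
            ops[k] = 0
            i -= 1
            j -= 1
        elif h == H[i - 1, j] - 2:
            ops[k] = 1
            i -= 1
        else:
            ops[k] = 2
            j -= 1
        k += 1
    return best, i, j, bi, bj, ops[:k][::-1]


def semiglobal_align(a: str, b: str) -> Alignment:
    """Semi-global alignment of two nonempty sequences."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    ca, cb = encode(a), encode(b)
    score, i0, j0, bi, bj, ops = _sg_traceback(ca, cb)
    parts_a = []
    parts_b = []
    # leading terminal overhang (at most one of i0, j0 is nonzero)
    parts_a.append(a[:i0] + "-" * j0)
    parts_b.append("-" * i0 + b[:j0])
    matches = mismatches = internal = 0
    i, j = i0, j0
    for op in ops:
        if op == 0:
            parts_a.append(a[i])
            parts_b.append(b[j])
            if ca[i] == cb[j] and ca[i] < 4:
                matches += 1
            else:
                mismatches += 1
            i += 1
            j += 1
        elif op == 1:
            parts_a.append(a[i])
            parts_b.append("-")
            internal += 1
            i += 1
        else:
            parts_a.append("-")
            parts_b.append(b[j])
            internal += 1
            j += 1
    # trailing terminal overhang
    parts_a.append(a[bi:] + "-" * (len(b) - bj))
    parts_b.append("-" * (len(a) - bi) + b[bj:])
    terminal = i0 + j0 + (len(a) - bi) + (len(b) - bj)
    return Alignment(
        aligned_a="".join(parts_a),
        aligned_b="".join(parts_b),
        matches=matches,
        mismatches=mismatches,
        internal_gaps=internal,
        terminal_gaps=terminal,
        score=int(score),
        a_unaligned=i0 + (len(a) - bi),
        b_unaligned=j0 + (len(b) - bj),
    )


@njit(cache=True)
def _sg_score(a, b):
    n, m = len(a), len(b)
    H = _sg_fill(a, b)
    best = H[n, m]
    for j in range(m + 1):
        if H[n, j] > best:
            best = H[n, j]
    for i in range(n + 1):
        if H[i, m] > best:
            best = H[i, m]
    return best


@njit(cache=True)
def hamming(a, b):
    """Mismatch count between equal-length coded sequences (N mismatches)."""
    d = 0
    for i in range(len(a)):
        if a[i] != b[i] or a[i] >= 4:
            d += 1
    return d


@njit(cache=True)
def hamming_capped(a, b, cap):
    d = 0
    for i in range(len(a)):
        if a[i] != b[i] or a[i] >= 4:
            d += 1
            if d > cap:
                return d
    return d


@njit(cache=True)
def banded_edit_distance(a, b, k):
    """Unit-cost edit distance if ≤ k, else k+1 (band of half-width k).

    Substitution, insertion and deletion all cost 1; ambiguous codes (≥4)
    never match.
    """
    n, m = len(a), len(b)
    if n > m:
        a, b = b, a
        n, m = m, n
    if m - n > k:
        return k + 1
    INF = k + 1
    width = 2 * k + 1
    prev = np.empty(width, np.int32)
    cur = np.empty(width, np.int32)
    # column offset: cell (i, j) stored at index j - i + k
    for idx in range(width):
        j = idx - k
        prev[idx] = j if 0 <= j <= m else INF
    for i in range(1, n + 1):
        for idx in range(width):
            j = i + idx - k
            if j < 0 or j > m:
                cur[idx] = INF
                continue
            if j == 0:
                cur[idx] = i if i <= k else INF
                continue
            sub = prev[idx]
            cost = 0 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else 1
            best = sub + cost if sub < INF else INF
            if idx > 0:  # deletion from b side: cell (i, j-1)
                t = cur[idx - 1]
                if t < INF and t + 1 < best:
                    best = t + 1
            if idx < width - 1:  # cell (i-1, j)
                t = prev[idx + 1]
                if t < INF and t + 1 < best:
                    best = t + 1
            cur[idx] = best if best <= k else INF
        prev, cur = cur, prev
    d = prev[m - n + k]
    return d if d <= k else k + 1


@njit(cache=True)
def best_overlap(f, r, min_overlap):
    """Ungapped overlap scan between coded fwd and revcomped-rev reads.

    Tries every offset o ≥ 0 at which r may start within f (overlap length
    min(len(f)-o, len(r))), maximizing matches − mismatches (raw match
    count would favor long spurious overlaps over a short exact one); ties
    keep the largest overlap (smallest o, scanned first).  Returns
    (offset, matches, overlap_len) or (-1, -1, 0) when no offset reaches
    min_overlap.
    """
    nf, nr = len(f), len(r)
    best_o = -1
    best_m = 0
    best_len = 0
    best_score = -(1 << 30)
    for o in range(0, nf - min_overlap + 1):
        ol = nf - o
        if ol > nr:
            ol = nr
        if ol < min_overlap:
            break
        m = 0
        for t in range(ol):
            if f[o + t] == r[t] and f[o + t] < 4:
                m += 1
        score = 2 * m - ol
        if score > best_score:
            best_score = score
            best_m = m
            best_o = o
            best_len = ol
    return best_o, best_m, best_len


@njit(cache=True)
def kmer_codes(codes, k):
    """Canonical 2-bit k-mer codes for every window; -1 where the window
    contains an ambiguous base."""
    n = len(codes)
    out = np.full(max(n - k + 1, 0), -1, np.int64)
    if n < k:
        return out
    mask = (np.int64(1) << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = np.int64(0)
    rev = np.int64(0)
    bad = 0  # positions until the window is clean again
    for i in range(n):
        c = codes[i]
        if c >= 4:
            bad = k
            fwd = np.int64(0)
            rev = np.int64(0)
        else:
            fwd = ((fwd << 2) | np.int64(c)) & mask
            rev = (rev >> 2) | (np.int64(3 - c) << shift)
            if bad > 0:
                bad -= 1
        if i >= k - 1 and bad == 0:
            out[i - k + 1] = fwd if fwd <= rev else rev
    return out


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def canonical_kmer_code(kmer: str) -> int:
    """Canonical (min of forward / reverse-complement) code of a k-mer."""
    codes = encode(kmer)
    if (codes >= 4).any():
        raise ValueError(f"k-mer {kmer!r} contains an ambiguous base")
    arr = kmer_codes(codes, len(kmer))
    return int(arr[0])
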