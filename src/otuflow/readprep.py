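"""Read preparation: pre-assembly k-mer error correction, paired-end
merging with a quality-consensus conflict rule, expected-error computation,
and screening filters.

The k-mer corrector is a single-pass spectral corrector over canonical
k-mers: a position is rewritten only when it is covered by at least one
weak k-mer and exactly one substitution turns every window covering it
strong.  The merger finds the best ungapped overlap between the forward
read and the reverse-complemented reverse read and resolves per-column
conflicts by quality: a conflict with quality difference below
``dq_threshold`` becomes 'N' (quality 0), otherwise the higher-quality base
wins with quality |q_fwd - q_rev|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np

from . import align
from .seqio import Read, ReadPair, revcomp

DEFAULT_K = 15
DEFAULT_WEAK_MAX = 1
DEFAULT_STRONG_MIN = 3
DEFAULT_MAX_CORRECTIONS = 2
DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_MISMATCH_FRAC = 0.3
DEFAULT_DQ_THRESHOLD = 6
DEFAULT_MAX_HOMOP = 8


@dataclass
class MergedRead:
    """Consensus amplicon built from one mate pair."""

    id: str
    bases: str
    quals: List[int]
    overlap_len: int
    n_conflicts: int
    n_ambig: int

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"merged read {self.id}: bases/quals length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class MergeRejection:
    """Typed non-exceptional outcome of a failed merge."""

    id: str
    reason: str  # "no_overlap" | "too_divergent"


@dataclass
class ScreenVerdict:
    read_id: str
    kept: bool
    reason: str  # ok | ambig | homopolymer | length | maxee


@dataclass
class KmerSpectrum:
    """Counts of canonical k-mers (lexicographic min of k-mer and its
    reverse complement), stored as sorted 2-bit codes for scale."""

    k: int
    codes: np.ndarray  # sorted int64 canonical codes
    counts: np.ndarray  # int64, parallel to codes

    def get(self, kmer: str) -> int:
        """Count of a k-mer (canonicalized); 0 if absent."""
        code = align.canonical_kmer_code(kmer)
        idx = np.searchsorted(self.codes, code)
        if idx < len(self.codes) and self.codes[idx] == code:
            return int(self.counts[idx])
        return 0

    def get_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized count lookup; -1 codes (ambiguous windows) map to 0."""
        out = np.zeros(len(codes), dtype=np.int64)
        valid = codes >= 0
        idx = np.searchsorted(self.codes, codes[valid])
        idx_c = np.minimum(idx, len(self.codes) - 1) if len(self.codes) else idx
        if len(self.codes):
            hit = self.codes[idx_c] == codes[valid]
            vals = np.where(hit, self.counts[idx_c], 0)
            out[valid] = vals
        return out

    def as_dict(self) -> Dict[str, int]:
        """Counts keyed by canonical k-mer string (small spectra / tests)."""
        return {
            align.decode_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    @property
    def n_kmers(self) -> int:
        return len(self.codes)


def build_spectrum(reads: Iterable[Read], k: int = DEFAULT_K) -> KmerSpectrum:
    """Count canonical k-mers over all reads; windows containing an
    ambiguous base are skipped."""
    if k < 3:
        raise ValueError("k must be ≥ 3")
    chunks = []
    n_reads = 0
    shortest = None
    for read in reads:
        n_reads += 1
        if shortest is None or len(read.bases) < shortest:
            shortest = len(read.bases)
        codes = align.kmer_codes(align.encode(read.bases), k)
        if len(codes):
            chunks.append(codes[codes >= 0])
    if n_reads == 0:
        raise ValueError("cannot build a spectrum from zero reads")
    if shortest is not None and k > shortest:
        warnings.warn(
            f"k={k} exceeds the shortest read length ({shortest}); "
            "spectrum may be empty for those reads"
        )
    if not chunks:
        return KmerSpectrum(
            k=k, codes=np.empty(0, np.int64), counts=np.empty(0, np.int64)
        )
    allcodes = np.concatenate(chunks)
    codes, counts = np.unique(allcodes, return_counts=True)
    return KmerSpectrum(k=k, codes=codes, counts=counts.astype(np.int64))


@dataclass
class CorrectionResult:
    read: Read
    n_corrected: int
    flagged: bool  # ambiguous fix seen, or correction budget exceeded


def correct_read(
    read: Read,
    spectrum: KmerSpectrum,
    weak_max: int = DEFAULT_WEAK_MAX,
    strong_min: int = DEFAULT_STRONG_MIN,
    max_corrections: int = DEFAULT_MAX_CORRECTIONS,
) -> CorrectionResult:
    """Spectral correction of a single read (best-effort, never raises).

    A position is corrected to base b iff (a) it lies in ≥1 weak k-mer
    (count ≤ weak_max), (b) substituting b makes every window covering the
    position strong (count ≥ strong_min), and (c) b is unique.  At most
    ``max_corrections`` corrections; beyond that the read is returned
    unchanged and flagged.  Qualities are left untouched.
    """
    if weak_max >= strong_min:
        raise ValueError("weak_max must be < strong_min")
    k = spectrum.k
    if len(read.bases) < k:
        return CorrectionResult(read, 0, False)
    bases = list(read.bases)
    n_corr = 0
    flagged = False
    L = len(bases)
    for _round in range(max_corrections + 1):
        codes = align.kmer_codes(align.encode("".join(bases)), k)
        counts = spectrum.get_codes(codes)
        weak_windows = np.flatnonzero(counts <= weak_max)
        if len(weak_windows) == 0:
            break
        pos_fixed = None
        for p in _positions_in_windows(weak_windows, k, L):
            fixes = []
            for b in "ACGT":
                if b == bases[p]:
                    continue
                if _all_windows_strong(bases, p, b, spectrum, strong_min):
                    fixes.append(b)
            if len(fixes) == 1:
                pos_fixed = (p, fixes[0])
                break
            if len(fixes) > 1:
                flagged = True  # ambiguous alternatives at this position
        if pos_fixed is None:
            break
        n_corr += 1
        if n_corr > max_corrections:
            return CorrectionResult(read, 0, True)
        p, b = pos_fixed
        bases[p] = b
    if n_corr == 0:
        return CorrectionResult(read, 0, flagged)
    fixed = Read(id=read.id, bases="".join(bases), quals=list(read.quals))
    return CorrectionResult(fixed, n_corr, flagged)


def _positions_in_windows(windows: np.ndarray, k: int, L: int):
    """Positions covered by ≥1 of the given window start indices, in order."""
    covered = np.zeros(L, bool)
    for w in windows:
        covered[w : w + k] = True
    return np.flatnonzero(covered)


def _all_windows_strong(bases, p, b, spectrum, strong_min) -> bool:
    k = spectrum.k
    L = len(bases)
    lo = max(0, p - k + 1)
    hi = min(p, L - k)
    if hi < lo:
        return False
    trial = bases[lo : hi + k]
    trial[p - lo] = b
    codes = align.kmer_codes(align.encode("".join(trial)), k)
    counts = spectrum.get_codes(codes)
    return bool((counts >= strong_min).all())


def correct_reads(
    reads: List[Read],
    k: int = DEFAULT_K,
    weak_max: int = DEFAULT_WEAK_MAX,
    strong_min: int = DEFAULT_STRONG_MIN,
    max_corrections: int = DEFAULT_MAX_CORRECTIONS,
) -> Tuple[List[Read], int]:
    """Build a spectrum from the reads themselves and correct each read.
    Returns (corrected reads, number of corrections applied)."""
    spectrum = build_spectrum(reads, k)
    out = []
    total = 0
    for read in reads:
        res = correct_read(read, spectrum, weak_max, strong_min, max_corrections)
        out.append(res.read)
        total += res.n_corrected
    return out, total


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_overlap_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    dq_threshold: int = DEFAULT_DQ_THRESHOLD,
) -> Union[MergedRead, MergeRejection]:
    """Merge one mate pair into a consensus amplicon, or reject it.

    The reverse read is reverse-complemented (qualities reversed) and slid
    along the forward read without gaps; the offset maximizing matches wins
    (ties keep the largest overlap).  Consensus per overlap column: equal
    bases keep the base at max(q_f, q_r); conflicts go to the higher-quality
    base with quality |q_f − q_r| when |q_f − q_r| ≥ dq_threshold, else 'N'
    at quality 0.
    """
    fwd = pair.fwd
    if not fwd.bases or not pair.rev.bases:
        raise ValueError("cannot merge empty mates")
    rc_bases = revcomp(pair.rev.bases)
    rc_quals = list(reversed(pair.rev.quals)) if pair.rev.quals else [0] * len(rc_bases)
    f_quals = fwd.quals if fwd.quals else [0] * len(fwd.bases)
    frag_id = pair.fragment_id
    cf = align.encode(fwd.bases)
    cr = align.encode(rc_bases)
    off, matches, ol = align.best_overlap(cf, cr, min_overlap)
    if off < 0:
        return MergeRejection(id=frag_id, reason="no_overlap")
    mismatches = ol - matches
    if ol > 0 and mismatches / ol > max_overlap_mismatch_frac:
        return MergeRejection(id=frag_id, reason="too_divergent")
    bases: List[str] = list(fwd.bases[:off])
    quals: List[int] = list(f_quals[:off])
    n_conflicts = 0
    n_ambig = 0
    for t in range(ol):
        bf, br = fwd.bases[off + t], rc_bases[t]
        qf, qr = f_quals[off + t], rc_quals[t]
        if bf == br and cf[off + t] < 4:
            bases.append(bf)
            quals.append(max(qf, qr))
        else:
            n_conflicts += 1
            dq = abs(qf - qr)
            if dq >= dq_threshold:
                bases.append(bf if qf > qr else br)
                quals.append(dq)
            else:
                bases.append("N")
                quals.append(0)
                n_ambig += 1
    # tail: whichever read extends past the overlap
    if off + ol < len(fwd.bases):
        bases.extend(fwd.bases[off + ol :])
        quals.extend(f_quals[off + ol :])
    if ol < len(rc_bases):
        bases.extend(rc_bases[ol:])
        quals.extend(rc_quals[ol:])
    seq = "".join(bases)
    return MergedRead(
        id=frag_id,
        bases=seq,
        quals=quals,
        overlap_len=ol,
        n_conflicts=n_conflicts,
        n_ambig=seq.count("N"),
    )


def expected_errors(quals: Iterable[int]) -> float:
    """Expected number of erroneous bases, Σ 10^(−q/10)."""
    q = np.asarray(list(quals), dtype=float)
    if q.size == 0:
        return 0.0
    return float(np.sum(10.0 ** (-q / 10.0)))


def longest_homopolymer(bases: str) -> int:
    best = run = 0
    prev = ""
    for b in bases:
        run = run + 1 if b == prev else 1
        prev = b
        if run > best:
            best = run
    return best


def screen_read(
    read,
    max_ambig: int = 0,
    max_homop: int = DEFAULT_MAX_HOMOP,
    min_len: Optional[int] = None,
    max_len: Optional[int] = None,
    maxee: Optional[float] = None,
) -> ScreenVerdict:
    """Apply the screening filters in fixed order: ambiguous-base count,
    homopolymer run (> max_homop rejects), length window, then expected
    errors (only when ``maxee`` is set)."""
    if read.bases.count("N") > max_ambig:
        return ScreenVerdict(read.id, False, "ambig")
    if longest_homopolymer(read.bases) > max_homop:
        return ScreenVerdict(read.id, False, "homopolymer")
    if (min_len is not None and len(read.bases) < min_len) or (
        max_len is not None and len(read.bases) > max_len
    ):
        return ScreenVerdict(read.id, False, "length")
    if maxee is not None and expected_errors(read.quals) > maxee:
        return ScreenVerdict(read.id, False, "maxee")
    return ScreenVerdict(read.id, True, "ok")
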