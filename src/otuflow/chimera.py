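"""De novo bimera detection over abundance-ranked unique sequences.

A bimera is a PCR artifact stitched from two parent templates at a
crossover point.  Detection follows the abundance-skew logic common to de
novo chimera detectors: a query can only be explained by parents that are
sufficiently more abundant (they must have completed more PCR rounds), so
queries are scanned in decreasing abundance against the pool of retained,
more-abundant sequences.  The two-parent model for a candidate pair is
scored by projecting each parent's pairwise alignment onto query
coordinates and minimizing mismatches over every breakpoint and parent
ordering; the query is flagged when the two-parent model beats the best
single parent by ``min_advantage`` mismatches and each side of the
breakpoint carries ``min_support`` positions matching its own parent only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import align
from .denoise import UniqueSeq, sort_uniques

DEFAULT_SKEW = 2.0
DEFAULT_MIN_ADVANTAGE = 3
DEFAULT_MIN_SUPPORT = 3
DEFAULT_MAX_CONFLICTS = 1
DEFAULT_MIN_MODEL_IDENTITY = 0.9
CANDIDATE_KMER = 8
DEFAULT_TOP_PER_CHUNK = 4
DEFAULT_N_CHUNKS = 4


@dataclass
class ChimeraVerdict:
    query_id: str
    is_chimeric: bool
    parent_a: Optional[str] = None
    parent_b: Optional[str] = None
    breakpoint: Optional[int] = None
    score: float = 0.0
    detector: str = "bimera"

    def __post_init__(self) -> None:
        if self.is_chimeric:
            if self.parent_a is None or self.parent_b is None:
                raise ValueError(f"{self.query_id}: chimeric verdict without parents")
            if self.parent_a == self.parent_b:
                raise ValueError(f"{self.query_id}: identical parents")
            if self.breakpoint is None:
                raise ValueError(f"{self.query_id}: chimeric verdict without breakpoint")
        if self.score < 0:
            raise ValueError("score must be ≥ 0")


def _kmer_set(bases: str, k: int = CANDIDATE_KMER) -> set:
    codes = align.kmer_codes(align.encode(bases), k)
    return set(int(c) for c in codes if c >= 0)


def candidate_parents(
    query: UniqueSeq,
    pool: Sequence[UniqueSeq],
    skew: float = DEFAULT_SKEW,
    top_per_chunk: int = DEFAULT_TOP_PER_CHUNK,
    n_chunks: int = DEFAULT_N_CHUNKS,
    pool_kmers: Optional[Sequence[set]] = None,
) -> List[UniqueSeq]:
    """Shortlist potential parents by chunked shared-k-mer counting.

    The eligible pool is restricted by abundance skew (parent abundance ≥
    skew × query abundance); the query is cut into ``n_chunks`` pieces and
    each chunk keeps its ``top_per_chunk`` pool sequences by shared
    canonical 8-mer count (ties → higher abundance, then pool order).
    """
    eligible = [
        (i, u)
        for i, u in enumerate(pool)
        if u.abundance >= skew * query.abundance and u.bases != query.bases
    ]
    if not eligible:
        return []
    if pool_kmers is None:
        pool_kmers = [None] * len(pool)
    kmersets = {}
    for i, u in eligible:
        ks = pool_kmers[i]
        kmersets[i] = ks if ks is not None else _kmer_set(u.bases)
    L = len(query.bases)
    chunk = max(L // n_chunks, 1)
    picked: List[int] = []
    for c in range(n_chunks):
        lo = c * chunk
        hi = L if c == n_chunks - 1 else (c + 1) * chunk
        if lo >= L:
            break
        chunk_kmers = _kmer_set(query.bases[lo:hi])
        if not chunk_kmers:
            continue
        scored = []
        for i, u in eligible:
            shared = len(chunk_kmers & kmersets[i])
            if shared > 0:
                scored.append((-shared, -u.abundance, i))
        scored.sort()
        for _, _, i in scored[:top_per_chunk]:
            if i not in picked:
                picked.append(i)
    return [pool[i] for i in sorted(picked)]


def match_profile(query: str, parent: str) -> np.ndarray:
    """Boolean vector over query positions: True where the query base is
    aligned to (and matches) a parent base under semi-global alignment.
    Query positions in gaps or terminal overhangs count as non-matching."""
    aln = align.semiglobal_align(query, parent)
    prof = np.zeros(len(query), dtype=bool)
    qi = 0
    ca, cb = align.encode(aln.aligned_a), align.encode(aln.aligned_b)
    for col in range(len(aln.aligned_a)):
        a_ch = aln.aligned_a[col]
        if a_ch == "-":
            continue
        b_ch = aln.aligned_b[col]
        if b_ch != "-" and ca[col] == cb[col] and ca[col] < 4:
            prof[qi] = True
        qi += 1
    return prof


def bimera_score(
    query: str, parent_a: str, parent_b: str
) -> Tuple[int, int, int, int, int]:
    """Score the two-parent (bimera) model of ``query``.

    Returns (best_breakpoint, m_model, m_best_single, support_left,
    support_right): the breakpoint x minimizing left-parent mismatches on
    [0, x) plus right-parent mismatches on [x, L) over both parent
    orderings; the best single-parent mismatch total; and the number of
    positions on each side matching the assigned parent but not the other.
    """
    prof_a = match_profile(query, parent_a)
    prof_b = match_profile(query, parent_b)
    return _bimera_from_profiles(prof_a, prof_b)[:5]


def _bimera_from_profiles(
    prof_a: np.ndarray, prof_b: np.ndarray
) -> Tuple[int, int, int, int, int, int]:
    """Best two-parent split of a query given its per-position match
    profiles against two parents.

    Returns (x, m_model, m_best_single, support_left, support_right,
    conflicts): breakpoint, model and single-parent mismatch minima, the
    yes-votes per side (positions matching the assigned parent only), and
    the no-votes summed over both sides (positions matching the *other*
    parent only — evidence against the two-parent model).
    """
    L = len(prof_a)
    mis_a = ~prof_a
    mis_b = ~prof_b
    cum_a = np.concatenate(([0], np.cumsum(mis_a)))  # mismatches vs A on [0,x)
    cum_b = np.concatenate(([0], np.cumsum(mis_b)))
    tot_a, tot_b = int(cum_a[-1]), int(cum_b[-1])
    m_best_single = min(tot_a, tot_b)
    # ordering 1: A left, B right;   ordering 2: B left, A right
    model_ab = cum_a + (tot_b - cum_b)
    model_ba = cum_b + (tot_a - cum_a)
    best_x_ab = int(np.argmin(model_ab))
    best_x_ba = int(np.argmin(model_ba))
    if model_ab[best_x_ab] <= model_ba[best_x_ba]:
        x, m_model, left_is_a = best_x_ab, int(model_ab[best_x_ab]), True
    else:
        x, m_model, left_is_a = best_x_ba, int(model_ba[best_x_ba]), False
    only_a = prof_a & ~prof_b
    only_b = prof_b & ~prof_a
    if left_is_a:
        support_left = int(only_a[:x].sum())
        support_right = int(only_b[x:].sum())
        conflicts = int(only_b[:x].sum()) + int(only_a[x:].sum())
    else:
        support_left = int(only_b[:x].sum())
        support_right = int(only_a[x:].sum())
        conflicts = int(only_a[:x].sum()) + int(only_b[x:].sum())
    return x, m_model, m_best_single, support_left, support_right, conflicts


def detect_chimeras(
    uniques: List[UniqueSeq],
    min_advantage: int = DEFAULT_MIN_ADVANTAGE,
    min_support: int = DEFAULT_MIN_SUPPORT,
    skew: float = DEFAULT_SKEW,
    max_conflicts: int = DEFAULT_MAX_CONFLICTS,
    min_model_identity: float = DEFAULT_MIN_MODEL_IDENTITY,
    detector_name: str = "bimera",
) -> List[ChimeraVerdict]:
    """Run the bimera test on every unique sequence, most abundant first.

    A query is chimeric when some parent pair gives a two-parent model
    that (a) beats the best single parent by ``min_advantage`` mismatches,
    (b) has ``min_support`` sites matching the assigned parent only on
    each side of the breakpoint, (c) shows at most ``max_conflicts`` sites
    matching the wrong-side parent (a genuine crossover leaves essentially
    no opposing sites, whereas a sequence merely distant from both parents
    has them in proportion to its divergence), and (d) explains the query
    well: 1 − m_model/len(query) ≥ ``min_model_identity`` (an off-target
    sequence matches both parents only in short glancing stretches and
    fails this).  Flagged sequences are removed from the pool available to
    later (less abundant) queries.  Returns one verdict per input unique,
    in the abundance-sorted processing order.
    """
    ordered = sort_uniques(uniques)
    retained: List[UniqueSeq] = []
    retained_kmers: List[set] = []
    verdicts: List[ChimeraVerdict] = []
    profile_cache: Dict[Tuple[str, str], np.ndarray] = {}
    for query in ordered:
        cands = candidate_parents(
            query, retained, skew=skew, pool_kmers=retained_kmers
        )
        verdict = ChimeraVerdict(
            query_id=query.rep_id, is_chimeric=False, detector=detector_name
        )
        best = None  # (advantage, support_min, candidate pair info)
        profiles = {}
        for cand in cands:
            key = (query.bases, cand.bases)
            prof = profile_cache.get(key)
            if prof is None:
                prof = match_profile(query.bases, cand.bases)
                profile_cache[key] = prof
            profiles[cand.rep_id] = (cand, prof)
        for (ida, (ca, pa)), (idb, (cb, pb)) in combinations(profiles.items(), 2):
            x, m_model, m_single, s_left, s_right, conflicts = (
                _bimera_from_profiles(pa, pb)
            )
            advantage = m_single - m_model
            if (
                advantage < min_advantage
                or min(s_left, s_right) < min_support
                or conflicts > max_conflicts
                or 1 - m_model / len(query.bases) < min_model_identity
            ):
                continue
            rank = (advantage, min(s_left, s_right))
            if best is None or rank > best[0]:
                best = (rank, ca, cb, x, advantage)
        if best is not None:
            _, ca, cb, x, advantage = best
            verdict = ChimeraVerdict(
                query_id=query.rep_id,
                is_chimeric=True,
                parent_a=ca.rep_id,
                parent_b=cb.rep_id,
                breakpoint=x,
                score=advantage / len(query.bases),
                detector=detector_name,
            )
        else:
            retained.append(query)
            retained_kmers.append(_kmer_set(query.bases))
        verdicts.append(verdict)
    return verdicts


def ensemble_vote(verdict_sets: List[List[ChimeraVerdict]]) -> List[ChimeraVerdict]:
    """Majority vote across detectors: chimeric iff strictly more than half
    vote chimeric (ties → not chimeric).  All sets must cover the same
    query IDs."""
    if not verdict_sets:
        raise ValueError("no verdict sets to combine")
    maps = []
    for vs in verdict_sets:
        maps.append({v.query_id: v for v in vs})
    ids = set(maps[0])
    for m in maps[1:]:
        if set(m) != ids:
            raise ValueError("detectors cover different query ID sets")
    combined = []
    for v in verdict_sets[0]:
        qid = v.query_id
        votes = [m[qid] for m in maps]
        n_chim = sum(1 for w in votes if w.is_chimeric)
        provenance = "ensemble[" + ",".join(
            f"{w.detector}={'chimeric' if w.is_chimeric else 'clean'}" for w in votes
        ) + "]"
        if n_chim * 2 > len(votes):
            template = max(
                (w for w in votes if w.is_chimeric), key=lambda w: w.score
            )
            combined.append(
                ChimeraVerdict(
                    query_id=qid,
                    is_chimeric=True,
                    parent_a=template.parent_a,
                    parent_b=template.parent_b,
                    breakpoint=template.breakpoint,
                    score=template.score,
                    detector=provenance,
                )
            )
        else:
            combined.append(
                ChimeraVerdict(query_id=qid, is_chimeric=False, detector=provenance)
            )
    return combined


def ensemble_detect(
    uniques: List[UniqueSeq], skew: float = DEFAULT_SKEW
) -> List[ChimeraVerdict]:
    """Built-in two-detector ensemble: the bimera test at a strict (4/4)
    and a lenient (2/2) parameterization, majority-voted.  With two
    detectors the tie rule makes this the consensus (both must agree)."""
    strict = detect_chimeras(
        uniques, min_advantage=4, min_support=4, skew=skew, detector_name="strict"
    )
    lenient = detect_chimeras(
        uniques, min_advantage=2, min_support=2, skew=skew, detector_name="lenient"
    )
    return ensemble_vote([strict, lenient])


def remove_chimeras(
    uniques: List[UniqueSeq], verdicts: List[ChimeraVerdict]
) -> List[UniqueSeq]:
    flagged = {v.query_id for v in verdicts if v.is_chimeric}
    return [u for u in uniques if u.rep_id not in flagged]
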