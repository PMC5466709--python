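"""Greedy abundance-sorted centroid clustering at 97% identity, with an
integrated de novo bimera discard, plus read-to-centroid mapping.

Identity is computed from a semi-global alignment (terminal gaps free and
excluded): matches / (matches + mismatches + internal gap columns).  A
sequence joins the best centroid at identity ≥ t; otherwise, if the bimera
test against existing centroids flags it, it is discarded; otherwise it
founds a new centroid.  Singleton removal is deliberately off: every
unique, however rare, founds an OTU if nothing else claims it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from . import align
from .align import Alignment, semiglobal_align
from .chimera import (
    DEFAULT_MAX_CONFLICTS,
    DEFAULT_MIN_ADVANTAGE,
    DEFAULT_MIN_MODEL_IDENTITY,
    DEFAULT_MIN_SUPPORT,
    DEFAULT_SKEW,
    _bimera_from_profiles,
    candidate_parents,
    match_profile,
)
from .denoise import UniqueSeq, sort_uniques

DEFAULT_IDENTITY = 0.97


def global_identity(a: str, b: str) -> Alignment:
    """Semi-global alignment of two sequences (match +1, mismatch −1,
    gap −2, free terminal gaps); see :class:`otuflow.align.Alignment`."""
    return semiglobal_align(a, b)


@dataclass
class OTU:
    otu_id: str
    centroid: UniqueSeq
    member_uniques: List[UniqueSeq] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(u.abundance for u in self.member_uniques)

    @property
    def per_sample(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for u in self.member_uniques:
            for s, n in u.per_sample.items():
                out[s] = out.get(s, 0) + n
        return out


@dataclass
class OTUTable:
    otus: List[OTU]
    unassigned: int = 0
    params: Dict = field(default_factory=dict)
    discarded_bimeras: List[str] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(o.total_reads for o in self.otus)

    @property
    def samples(self) -> List[str]:
        names: List[str] = []
        for o in self.otus:
            for s in o.per_sample:
                if s not in names:
                    names.append(s)
        return names


def _best_centroid(bases: str, otus: List[OTU]) -> Tuple[Optional[int], float]:
    """Index and identity of the best centroid for ``bases``.

    Ties on identity prefer the more abundant centroid (founding
    abundance), then the earlier centroid.
    """
    best_idx: Optional[int] = None
    best = (-1.0, 0, 0)  # identity, founding abundance, -index
    for idx, otu in enumerate(otus):
        if otu.centroid.bases == bases:
            ident = 1.0
        else:
            ident = global_identity(bases, otu.centroid.bases).glocal_identity
        key = (ident, otu.centroid.abundance, -idx)
        if key > best:
            best = key
            best_idx = idx
    return best_idx, best[0]


def cluster_greedy(
    uniques: List[UniqueSeq],
    t: float = DEFAULT_IDENTITY,
    check_bimera: bool = True,
    min_advantage: int = DEFAULT_MIN_ADVANTAGE,
    min_support: int = DEFAULT_MIN_SUPPORT,
    skew: float = DEFAULT_SKEW,
) -> OTUTable:
    """Greedy centroid clustering over abundance-sorted uniques.

    Returns an OTU table skeleton whose per-OTU counts come from the
    uniques that joined each centroid; reads discarded as bimeras are
    listed in ``discarded_bimeras``.
    """
    if not (0 < t <= 1):
        raise ValueError("identity threshold t must be in (0, 1]")
    ordered = sort_uniques(uniques)
    otus: List[OTU] = []
    discarded: List[str] = []
    for uniq in ordered:
        idx, ident = _best_centroid(uniq.bases, otus)
        if idx is not None and ident >= t:
            otus[idx].member_uniques.append(uniq)
            continue
        if check_bimera and _is_bimera(
            uniq, otus, min_advantage, min_support, skew
        ):
            discarded.append(uniq.rep_id)
            continue
        otus.append(
            OTU(
                otu_id=f"OTU_{len(otus) + 1:04d}",
                centroid=uniq,
                member_uniques=[uniq],
            )
        )
    return OTUTable(
        otus=otus,
        unassigned=0,
        params={"t": t, "check_bimera": check_bimera},
        discarded_bimeras=discarded,
    )


def _is_bimera(uniq, otus, min_advantage, min_support, skew) -> bool:
    pool = [o.centroid for o in otus]
    cands = candidate_parents(uniq, pool, skew=skew)
    if len(cands) < 2:
        return False
    profiles = [(c, match_profile(uniq.bases, c.bases)) for c in cands]
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            _, m_model, m_single, s_l, s_r, conflicts = _bimera_from_profiles(
                profiles[i][1], profiles[j][1]
            )
            if (
                m_single - m_model >= min_advantage
                and min(s_l, s_r) >= min_support
                and conflicts <= DEFAULT_MAX_CONFLICTS
                and 1 - m_model / len(uniq.bases) >= DEFAULT_MIN_MODEL_IDENTITY
            ):
                return True
    return False


def map_reads(
    reads: Iterable,
    centroids: OTUTable,
    t: float = DEFAULT_IDENTITY,
    sample_of: Optional[Dict[str, str]] = None,
) -> OTUTable:
    """Map reads onto final centroids to build the OTU table proper.

    Each read joins the centroid of maximum identity when that identity is
    ≥ t (ties → more abundant centroid, then earlier); otherwise it counts
    as unassigned.  Internally reads are grouped by exact sequence so each
    distinct string is aligned once.
    """
    if not (0 < t <= 1):
        raise ValueError("identity threshold t must be in (0, 1]")
    otus = [
        OTU(otu_id=o.otu_id, centroid=o.centroid, member_uniques=[])
        for o in centroids.otus
    ]
    groups: Dict[str, UniqueSeq] = {}
    n_reads = 0
    exact = {o.centroid.bases: i for i, o in reversed(list(enumerate(otus)))}
    assignments: Dict[str, Optional[str]] = {}
    for read in reads:
        n_reads += 1
        sample = (sample_of or {}).get(read.id, "sample1")
        uniq = groups.get(read.bases)
        if uniq is None:
            uniq = UniqueSeq(rep_id=read.id, bases=read.bases, abundance=0)
            groups[read.bases] = uniq
        uniq.abundance += 1
        uniq.members.append(read.id)
        uniq.per_sample[sample] = uniq.per_sample.get(sample, 0) + 1
    unassigned = 0
    for bases, uniq in groups.items():
        idx = exact.get(bases)
        if idx is None:
            best_idx, ident = _best_centroid(bases, otus)
            idx = best_idx if (best_idx is not None and ident >= t) else None
        if idx is None:
            unassigned += uniq.abundance
            for rid in uniq.members:
                assignments[rid] = None
        else:
            otus[idx].member_uniques.append(uniq)
            for rid in uniq.members:
                assignments[rid] = otus[idx].otu_id
    table = OTUTable(
        otus=otus,
        unassigned=unassigned,
        params={"t": t, "mode": "map"},
    )
    table.assignments = assignments
    if table.total_reads + unassigned != n_reads:
        raise AssertionError("read-count conservation violated in map_reads")
    return table


def write_otu_table(table: OTUTable, path) -> None:
    """OTU table TSV: rows = OTUs, columns = centroid id + per-sample counts."""
    samples = table.samples
    with open(path, "w") as out:
        out.write("otu\tcentroid\ttotal\t" + "\t".join(samples) + "\n")
        for o in table.otus:
            per = o.per_sample
            row = [o.otu_id, o.centroid.rep_id, str(o.total_reads)] + [
                str(per.get(s, 0)) for s in samples
            ]
            out.write("\t".join(row) + "\n")
        if table.unassigned:
            out.write(
                "\t".join(
                    ["unassigned", "-", str(table.unassigned)]
                    + ["0"] * len(samples)
                )
                + "\n"
            )
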