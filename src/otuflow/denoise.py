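"""Dereplication and abundance-sorted single-linkage-style preclustering.

Preclustering is the greedy pass used throughout amplicon denoising: scan
unique sequences in decreasing abundance and absorb each into the first
already-retained (hence at least as abundant) sequence within ``diffs``
differences.  Distances are unaligned: Hamming for equal lengths, banded
unit-cost edit distance otherwise; 'N' always counts as a difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Union

from . import align
from .seqio import CountTable


@dataclass
class UniqueSeq:
    """A dereplicated sequence with its abundance and member read IDs."""

    rep_id: str
    bases: str
    abundance: int
    members: List[str] = field(default_factory=list)
    per_sample: Dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.abundance != len(self.members) or self.abundance != sum(
            self.per_sample.values()
        ):
            raise ValueError(
                f"{self.rep_id}: abundance {self.abundance} inconsistent with "
                f"{len(self.members)} members / per-sample counts"
            )


def dereplicate(
    reads: Iterable, sample_of: Optional[Mapping[str, str]] = None
) -> List[UniqueSeq]:
    """Collapse exact-duplicate sequences into :class:`UniqueSeq` records.

    Output is sorted by (abundance desc, first occurrence).  ``sample_of``
    maps read ID → sample name; unmapped reads fall into sample "sample1".
    """
    groups: Dict[str, UniqueSeq] = {}
    for read in reads:
        sample = (sample_of or {}).get(read.id, "sample1")
        uniq = groups.get(read.bases)
        if uniq is None:
            uniq = UniqueSeq(rep_id=read.id, bases=read.bases, abundance=0)
            groups[read.bases] = uniq
        uniq.abundance += 1
        uniq.members.append(read.id)
        uniq.per_sample[sample] = uniq.per_sample.get(sample, 0) + 1
    order = {id(u): i for i, u in enumerate(groups.values())}
    out = sorted(groups.values(), key=lambda u: (-u.abundance, order[id(u)]))
    return out


def sort_uniques(uniques: List[UniqueSeq]) -> List[UniqueSeq]:
    """Sort by (abundance desc, current order) — the pipeline's canonical
    processing order."""
    indexed = sorted(enumerate(uniques), key=lambda t: (-t[1].abundance, t[0]))
    return [u for _, u in indexed]


def seq_distance(a: str, b: str, cap: int) -> int:
    """Differences between two sequences, early-exited above ``cap``.

    Equal lengths → Hamming; unequal → banded edit distance with band
    half-width ``cap`` (each indel counts 1).  Returns cap+1 when above cap.
    """
    ca, cb = align.encode(a), align.encode(b)
    if len(a) == len(b):
        return int(align.hamming_capped(ca, cb, cap))
    return int(align.banded_edit_distance(ca, cb, cap))


def auto_diffs(uniques: List[UniqueSeq]) -> int:
    """1 difference per 100 bp of the (abundance-weighted) median length."""
    lengths = sorted(len(u.bases) for u in uniques)
    if not lengths:
        return 1
    median = lengths[len(lengths) // 2]
    return max(1, int(round(median / 100)))


def precluster(
    uniques: List[UniqueSeq], diffs: Union[int, str] = "auto"
) -> List[UniqueSeq]:
    """Greedy single-linkage-style preclustering.

    Each sequence, visited in decreasing abundance, merges into the first
    retained sequence within ``diffs`` differences; its abundance, members
    and per-sample counts accumulate onto the receiver (whose bases never
    change).  Total abundance is conserved.
    """
    if diffs == "auto":
        diffs = auto_diffs(uniques)
    diffs = int(diffs)
    if diffs < 0:
        raise ValueError("diffs must be ≥ 0")
    ordered = sort_uniques(uniques)
    retained: List[UniqueSeq] = []
    for uniq in ordered:
        receiver = None
        if diffs > 0:
            for cand in retained:
                if abs(len(cand.bases) - len(uniq.bases)) > diffs:
                    continue
                if seq_distance(cand.bases, uniq.bases, diffs) <= diffs:
                    receiver = cand
                    break
        if receiver is None:
            retained.append(
                UniqueSeq(
                    rep_id=uniq.rep_id,
                    bases=uniq.bases,
                    abundance=uniq.abundance,
                    members=list(uniq.members),
                    per_sample=dict(uniq.per_sample),
                )
            )
        else:
            receiver.abundance += uniq.abundance
            receiver.members.extend(uniq.members)
            for s, n in uniq.per_sample.items():
                receiver.per_sample[s] = receiver.per_sample.get(s, 0) + n
    return sort_uniques(retained)


def uniques_to_count_table(uniques: List[UniqueSeq]) -> CountTable:
    return CountTable(
        entries=[(u.rep_id, u.abundance, dict(u.per_sample)) for u in uniques]
    )
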