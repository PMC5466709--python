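"""Sequence and count-table I/O.

Reads are held as lightweight records (id, bases, per-base Phred qualities).
FASTQ is Sanger Phred+33 only; offset-64 input is rejected loudly rather
than guessed at.  All coordinates anywhere in the package are 0-based,
half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, TextIO, Tuple, Union

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConsistencyError, EncodingError, PairingError, ParseError

PHRED_OFFSET = 33

_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)
_IUPAC = set("ACGTUMRWSYKVHDBN")


@dataclass
class Read:
    """A named nucleotide sequence with optional per-base Phred qualities.

    ``quals`` is empty for FASTA-derived records; otherwise it has the same
    length as ``bases`` with values in [0, 93].
    """

    id: str
    bases: str
    quals: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be nonempty")
        if self.quals and len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id}: {len(self.quals)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadPair:
    """A forward/reverse mate pair; ``rev`` is as sequenced (not flipped)."""

    fwd: Read
    rev: Read

    @property
    def fragment_id(self) -> str:
        return fragment_id(self.fwd.id)


@dataclass
class CountTable:
    """Per-representative abundances, split by sample."""

    entries: List[Tuple[str, int, Dict[str, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rep, total, per_sample in self.entries:
            if rep in seen:
                raise ConsistencyError(f"duplicate representative id {rep!r}")
            seen.add(rep)
            if total != sum(per_sample.values()):
                raise ConsistencyError(
                    f"{rep}: total {total} != sum of sample counts "
                    f"{sum(per_sample.values())}"
                )

    @property
    def samples(self) -> List[str]:
        names: List[str] = []
        for _, _, per_sample in self.entries:
            for s in per_sample:
                if s not in names:
                    names.append(s)
        return names


def fragment_id(read_id: str) -> str:
    """Strip mate tags: whitespace comment first, then a /1 or /2 suffix."""
    head = read_id.split()[0]
    if head.endswith("/1") or head.endswith("/2"):
        head = head[:-2]
    return head


def read_fastq(path) -> Iterator[Read]:
    """Yield :class:`Read` records from a Sanger FASTQ file.

    Bases are uppercased and '.' is mapped to 'N'.  Malformed records raise
    :class:`ParseError` with the approximate line number; quality characters
    below '!' raise :class:`EncodingError`.
    """
    with open(path) as handle:
        yield from _parse_fastq(handle, str(path))


def _parse_fastq(handle: TextIO, name: str) -> Iterator[Read]:
    record_idx = 0
    it = FastqGeneralIterator(handle)
    while True:
        try:
            title, seq, qual = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ParseError(
                f"{name}: malformed FASTQ record near line "
                f"{record_idx * 4 + 1}: {exc}"
            ) from exc
        record_idx += 1
        quals = []
        for ch in qual:
            q = ord(ch) - PHRED_OFFSET
            if q < 0:
                raise EncodingError(
                    f"{name}, record {title!r}: quality character {ch!r} below "
                    f"'!'; input is not Sanger Phred+33"
                )
            quals.append(q)
        yield Read(id=title, bases=_clean_bases(seq), quals=quals)


def _clean_bases(seq: str) -> str:
    return seq.upper().replace(".", "N")


def pair_reads(
    fwd_stream: Iterable[Read], rev_stream: Iterable[Read]
) -> Iterator[ReadPair]:
    """Zip two identically-ordered mate streams into :class:`ReadPair`.

    Raises :class:`PairingError` on any ID mismatch or a length mismatch
    between the streams.
    """
    sentinel = object()
    for fwd, rev in itertools.zip_longest(fwd_stream, rev_stream, fillvalue=sentinel):
        if fwd is sentinel or rev is sentinel:
            short = "forward" if fwd is sentinel else "reverse"
            raise PairingError(f"{short} stream ended before its mate stream")
        fid, rid = fragment_id(fwd.id), fragment_id(rev.id)
        if fid != rid:
            raise PairingError(f"mate ID mismatch: {fwd.id!r} vs {rev.id!r}")
        yield ReadPair(fwd=fwd, rev=rev)


def read_fasta(path) -> Iterator[Read]:
    """Yield quality-less :class:`Read` records from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = _clean_bases(str(rec.seq))
        if not bases:
            raise ParseError(f"{path}: empty sequence under header {rec.id!r}")
        yield Read(id=rec.id, bases=bases, quals=[])


def write_fasta(records: Iterable[Read], path, wrap: int = 0) -> None:
    """Write records as FASTA. ``wrap=0`` writes each sequence on one line."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            if wrap and wrap > 0:
                for i in range(0, len(rec.bases), wrap):
                    out.write(rec.bases[i : i + wrap] + "\n")
            else:
                out.write(rec.bases + "\n")


def write_fastq(records: Iterable[Read], path) -> None:
    with open(path, "w") as out:
        for rec in records:
            if len(rec.quals) != len(rec.bases):
                raise ValueError(f"read {rec.id} has no per-base qualities")
            qstr = "".join(chr(q + PHRED_OFFSET) for q in rec.quals)
            out.write(f"@{rec.id}\n{rec.bases}\n+\n{qstr}\n")


def revcomp(bases: str) -> str:
    """Reverse complement over the IUPAC alphabet (N→N)."""
    for ch in bases:
        if ch.upper() not in _IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in sequence")
    return bases.translate(_COMPLEMENT)[::-1]


def write_count_table(table: CountTable, path) -> None:
    samples = table.samples
    with open(path, "w") as out:
        out.write("\t".join(["representative", "total"] + samples) + "\n")
        for rep, total, per_sample in table.entries:
            row = [rep, str(total)] + [str(per_sample.get(s, 0)) for s in samples]
            out.write("\t".join(row) + "\n")


def read_count_table(path) -> CountTable:
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        cols = header.split("\t")
        if cols[:2] != ["representative", "total"]:
            raise ParseError(f"{path}: unexpected count-table header {header!r}")
        samples = cols[2:]
        entries = []
        for lineno, line in enumerate(handle, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 + len(samples):
                raise ParseError(f"{path}:{lineno}: wrong column count")
            rep, total = parts[0], int(parts[1])
            per_sample = {
                s: int(v) for s, v in zip(samples, parts[2:]) if int(v) != 0
            }
            if total != sum(int(v) for v in parts[2:]):
                raise ConsistencyError(
                    f"{path}:{lineno}: total {total} != sum of sample counts"
                )
            entries.append((rep, total, per_sample))
    return CountTable(entries=entries)
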