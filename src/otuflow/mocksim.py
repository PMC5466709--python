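"""Synthetic mock-community paired-read generator with ground truth.

Emulates the structure that mock-community benchmarks quantify: a known
set of reference amplicons mixed at chosen proportions, read pairs drawn
from them with substitution/indel errors, PCR-crossover chimeras between
two parents at a uniform interior breakpoint, and optional contaminant
templates.  Each fragment is corrupted once and then split into a forward
read (first ``read_len`` bases) and a reverse read (reverse complement of
the last ``read_len`` bases), so mates are mutually consistent and overlap
on 2·read_len − fragment_length interior bases.

Per-read qualities follow a linear mean decay along sequencing cycles with
Gaussian jitter, deliberately NOT coupled to the realized errors: quality-
based filters downstream are exercised, but quality is not an oracle for
where the errors are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import SpecValidationError
from .seqio import Read, ReadPair, revcomp, write_fasta, write_fastq

# The packaged toy reference community: divergent ~250 bp amplicons derived
# once (fixed internal seed) by heavy seeded mutation of a common base
# sequence.  21 species mirrors a typical staggered mock community size.
_REFSET_SEED = 90517
DEFAULT_N_REFS = 21
DEFAULT_REF_LEN = 250
_REF_MUTATION_RATE = 0.18

QUAL_MIN, QUAL_MAX = 2, 41


def default_references(
    n: int = DEFAULT_N_REFS, length: int = DEFAULT_REF_LEN
) -> List[Tuple[str, str]]:
    """The packaged synthetic reference amplicons (species name, sequence).

    Generated deterministically: a random base amplicon is mutated
    independently per species at a substitution rate high enough that all
    pairwise identities sit far below the 97% clustering threshold.
    """
    rng = np.random.default_rng(_REFSET_SEED)
    base = rng.integers(0, 4, size=length)
    refs = []
    alphabet = np.array(list("ACGT"))
    for i in range(n):
        seq = base.copy()
        mutate = rng.random(length) < _REF_MUTATION_RATE
        shift = rng.integers(1, 4, size=length)
        seq[mutate] = (seq[mutate] + shift[mutate]) % 4
        refs.append((f"species_{i + 1:02d}", "".join(alphabet[seq])))
    return refs


@dataclass
class MockSpec:
    """Configuration of one simulated mock-community sequencing run."""

    refs: List[Tuple[str, str]]
    abundances: Optional[Sequence[float]] = None  # default: uniform
    sub_rate: float = 0.001
    ins_rate: float = 0.0001
    del_rate: float = 0.0001
    chimera_rate: float = 0.05
    contaminant_refs: Optional[List[Tuple[str, str]]] = None
    contaminant_rate: float = 0.0
    read_len: int = 150
    n_fragments: int = 1000
    q_start: float = 38.0
    q_end: float = 25.0
    q_jitter: float = 3.0
    min_overlap: int = 20
    seed: int = 0
    sample: str = "sample1"

    def __post_init__(self) -> None:
        if self.abundances is None:
            self.abundances = [1.0 / len(self.refs)] * len(self.refs)
        self.validate()

    def validate(self) -> None:
        if not self.refs:
            raise SpecValidationError("no reference amplicons")
        if len(self.abundances) != len(self.refs):
            raise SpecValidationError("abundance vector length != number of refs")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise SpecValidationError("abundances must sum to 1")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0 <= r < 1):
                raise SpecValidationError("error rates must be in [0, 1)")
        if not (0 <= self.chimera_rate <= 1 and 0 <= self.contaminant_rate <= 1):
            raise SpecValidationError("chimera/contaminant rates must be in [0, 1]")
        if self.chimera_rate > 0 and len(self.refs) < 2:
            raise SpecValidationError("chimera simulation needs ≥ 2 references")
        if self.contaminant_rate > 0 and not self.contaminant_refs:
            raise SpecValidationError("contaminant_rate > 0 without contaminant refs")
        lens = [len(s) for _, s in self.refs]
        if self.contaminant_refs:
            lens += [len(s) for _, s in self.contaminant_refs]
        if self.read_len > min(lens):
            raise SpecValidationError(
                f"read_len {self.read_len} exceeds shortest amplicon ({min(lens)})"
            )
        if 2 * self.read_len - max(lens) < self.min_overlap:
            raise SpecValidationError(
                "implied mate overlap "
                f"{2 * self.read_len - max(lens)} < min_overlap {self.min_overlap}"
            )


@dataclass
class TruthRecord:
    read_id: str
    kind: str  # "ref" | "chimera" | "contaminant"
    species: Optional[str] = None  # for ref / contaminant
    parent_a: Optional[str] = None
    parent_b: Optional[str] = None
    breakpoint: Optional[int] = None
    errors: List[Tuple[int, str, str, str]] = field(default_factory=list)
    # (template position, type sub|ins|del, original, observed)

    @property
    def n_substitutions(self) -> int:
        return sum(1 for e in self.errors if e[1] == "sub")


@dataclass
class MockTruth:
    records: List[TruthRecord]

    def by_id(self) -> Dict[str, TruthRecord]:
        return {r.read_id: r for r in self.records}

    @property
    def n_chimeric(self) -> int:
        return sum(1 for r in self.records if r.kind == "chimera")


def draw_fragment(
    spec: MockSpec, rng: np.random.Generator, read_id: str = "frag"
) -> Tuple[str, TruthRecord]:
    """Draw one template: contaminant, two-parent chimera, or single
    reference, by the spec's rates and abundance vector."""
    if spec.contaminant_rate > 0 and rng.random() < spec.contaminant_rate:
        name, seq = spec.contaminant_refs[rng.integers(len(spec.contaminant_refs))]
        return seq, TruthRecord(read_id=read_id, kind="contaminant", species=name)
    if spec.chimera_rate > 0 and rng.random() < spec.chimera_rate:
        if len(spec.refs) < 2:
            raise SpecValidationError("chimera requested with < 2 references")
        probs = np.asarray(spec.abundances, dtype=float)
        ia = int(rng.choice(len(spec.refs), p=probs))
        ib = ia
        while ib == ia:
            ib = int(rng.choice(len(spec.refs), p=probs))
        (na, sa), (nb, sb) = spec.refs[ia], spec.refs[ib]
        L = min(len(sa), len(sb))
        x = int(rng.integers(1, L))  # uniform interior breakpoint
        return sa[:x] + sb[x:], TruthRecord(
            read_id=read_id, kind="chimera", parent_a=na, parent_b=nb, breakpoint=x
        )
    probs = np.asarray(spec.abundances, dtype=float)
    i = int(rng.choice(len(spec.refs), p=probs))
    name, seq = spec.refs[i]
    return seq, TruthRecord(read_id=read_id, kind="ref", species=name)


def corrupt(
    template: str, spec: MockSpec, rng: np.random.Generator
) -> Tuple[str, List[Tuple[int, str, str, str]]]:
    """Apply per-position substitution/insertion/deletion errors.

    Returns the mutated sequence and the realized error list as
    (template position, type, original base, observed base) tuples.
    """
    out: List[str] = []
    errors: List[Tuple[int, str, str, str]] = []
    bases = "ACGT"
    for pos, b in enumerate(template):
        if spec.del_rate > 0 and rng.random() < spec.del_rate:
            errors.append((pos, "del", b, "-"))
        else:
            if spec.sub_rate > 0 and rng.random() < spec.sub_rate:
                alt = bases[(bases.index(b) + int(rng.integers(1, 4))) % 4] if b in bases else "A"
                errors.append((pos, "sub", b, alt))
                out.append(alt)
            else:
                out.append(b)
        if spec.ins_rate > 0 and rng.random() < spec.ins_rate:
            ins = bases[int(rng.integers(0, 4))]
            errors.append((pos, "ins", "-", ins))
            out.append(ins)
    return "".join(out), errors


def _draw_quals(n: int, spec: MockSpec, rng: np.random.Generator) -> List[int]:
    """Linear mean decay q_start→q_end along the read with Gaussian jitter,
    clamped to the MiSeq-style range [2, 41]."""
    if n == 0:
        return []
    pos = np.arange(n) / max(n - 1, 1)
    mean = spec.q_start + (spec.q_end - spec.q_start) * pos
    q = np.rint(mean + rng.normal(0.0, spec.q_jitter, size=n))
    return [int(v) for v in np.clip(q, QUAL_MIN, QUAL_MAX)]


def emit_paired_reads(spec: MockSpec) -> Tuple[List[ReadPair], MockTruth]:
    """Generate the full run: one read pair + one truth record per
    fragment, deterministic under the spec's seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pairs: List[ReadPair] = []
    records: List[TruthRecord] = []
    for i in range(spec.n_fragments):
        rid = f"frag{i + 1:06d}"
        template, truth = draw_fragment(spec, rng, read_id=rid)
        seq, errors = corrupt(template, spec, rng)
        truth.errors = errors
        L = len(seq)
        rl = min(spec.read_len, L)
        fwd_bases = seq[:rl]
        rev_bases = revcomp(seq[L - rl :])
        fwd = Read(id=f"{rid}/1", bases=fwd_bases, quals=_draw_quals(rl, spec, rng))
        rev = Read(id=f"{rid}/2", bases=rev_bases, quals=_draw_quals(rl, spec, rng))
        pairs.append(ReadPair(fwd=fwd, rev=rev))
        records.append(truth)
    return pairs, MockTruth(records=records)


def write_run(spec: MockSpec, outdir) -> MockTruth:
    """Write R1/R2 FASTQ, reference FASTA, truth TSV and a spec echo."""
    import os

    os.makedirs(outdir, exist_ok=True)
    pairs, truth = emit_paired_reads(spec)
    write_fastq((p.fwd for p in pairs), os.path.join(outdir, "reads_R1.fastq"))
    write_fastq((p.rev for p in pairs), os.path.join(outdir, "reads_R2.fastq"))
    write_fasta(
        (Read(id=name, bases=seq) for name, seq in spec.refs),
        os.path.join(outdir, "refs.fasta"),
    )
    if spec.contaminant_refs:
        write_fasta(
            (Read(id=name, bases=seq) for name, seq in spec.contaminant_refs),
            os.path.join(outdir, "contaminants.fasta"),
        )
    with open(os.path.join(outdir, "truth.tsv"), "w") as out:
        out.write("read_id\tkind\tspecies\tparent_a\tparent_b\tbreakpoint\tn_errors\n")
        for r in truth.records:
            out.write(
                "\t".join(
                    [
                        r.read_id,
                        r.kind,
                        r.species or "-",
                        r.parent_a or "-",
                        r.parent_b or "-",
                        "-" if r.breakpoint is None else str(r.breakpoint),
                        str(len(r.errors)),
                    ]
                )
                + "\n"
            )
    echo = {
        k: v
        for k, v in spec.__dict__.items()
        if k not in ("refs", "contaminant_refs")
    }
    echo["n_refs"] = len(spec.refs)
    echo["abundances"] = list(spec.abundances)
    with open(os.path.join(outdir, "spec.json"), "w") as out:
        json.dump(echo, out, indent=2)
    return truth
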