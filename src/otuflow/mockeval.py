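"""Mock-community evaluation: reference-based error rate, four-way OTU
categorization, OTUs-per-species over-splitting, analytic rarefaction, and
per-stage read accounting.

Because the community composition is known, every read can be aligned to
its best reference and its substitution/insertion/deletion errors counted
exactly; the error rate is the ratio of erroneous bases to total read
bases.  Reads that the reference set itself explains better as a two-parent
crossover are flagged as reference chimeras and, in the "chimera absent"
scenario, excluded from the error-rate denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .align import semiglobal_align
from .chimera import bimera_score
from .errors import ConsistencyError, OtuflowError
from .otucluster import OTUTable

DEFAULT_T_SIM = 0.97


@dataclass
class RefDB:
    """Known reference sequences of the mock community (and optionally of
    expected contaminants)."""

    mock_refs: List[Tuple[str, str]]
    contaminant_refs: Optional[List[Tuple[str, str]]] = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.mock_refs]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        for n, s in self.mock_refs:
            if not s:
                raise ValueError(f"empty reference sequence for {n}")


@dataclass
class ReadErrorRecord:
    read_id: str
    best_species: str
    substitutions: int
    insertions: int
    deletions: int
    aligned_length: int
    is_ref_chimera: bool = False
    identity: float = 0.0

    @property
    def n_errors(self) -> int:
        return self.substitutions + self.insertions + self.deletions


@dataclass
class EvalReport:
    error_rate: float
    n_reads_used: int
    n_ref_chimeras: int
    otu_categories: Dict[str, str] = field(default_factory=dict)
    otus_per_species: Dict[str, int] = field(default_factory=dict)
    missing_species: List[str] = field(default_factory=list)
    rarefaction: List[Tuple[int, float]] = field(default_factory=list)
    stage_counts: List[Tuple[str, int, int]] = field(default_factory=list)


def best_reference_alignment(read, db: RefDB) -> ReadErrorRecord:
    """Align a read to every mock reference; count errors vs the best.

    Best = maximum identity (ties → first reference in DB order).
    Substitutions are mismatch columns (an 'N' in the read counts as a
    substitution), insertions are read bases opposite a gap in the
    reference, deletions are reference bases opposite a gap in the read;
    terminal gap columns are excluded.  ``aligned_length`` is the read
    length.
    """
    read_id, bases = _read_fields(read)
    best = None
    for species, ref in db.mock_refs:
        aln = semiglobal_align(bases, ref)
        if best is None or aln.glocal_identity > best[1].glocal_identity:
            best = (species, aln)
    species, aln = best
    subs = aln.mismatches
    # Terminal overhangs are the maximal leading/trailing runs of gap
    # columns (free end gaps are never adjacent to a scored internal gap in
    # an optimal alignment); skip them, then partition the rest.
    cols = list(zip(aln.aligned_a, aln.aligned_b))
    lo, hi = 0, len(cols)
    while lo < hi and "-" in cols[lo]:
        lo += 1
    while hi > lo and "-" in cols[hi - 1]:
        hi -= 1
    ins = dels = 0
    for ca, cb in cols[lo:hi]:
        if ca == "-":
            dels += 1
        elif cb == "-":
            ins += 1
    return ReadErrorRecord(
        read_id=read_id,
        best_species=species,
        substitutions=subs,
        insertions=ins,
        deletions=dels,
        aligned_length=len(bases),
        identity=aln.glocal_identity,
    )


def _read_fields(read) -> Tuple[str, str]:
    if isinstance(read, str):
        return "read", read
    return read.id, read.bases


def reference_chimera_check(
    read, db: RefDB, min_advantage: int = 3
) -> bool:
    """Is the read better explained as a crossover of its two best-matching
    references than by any single reference?"""
    if len(db.mock_refs) < 2:
        raise ValueError("reference chimera check needs ≥ 2 references")
    _, bases = _read_fields(read)
    scored = []
    for i, (species, ref) in enumerate(db.mock_refs):
        aln = semiglobal_align(bases, ref)
        scored.append((-aln.glocal_identity, i, species, ref))
    scored.sort()
    (_, _, _, ref_a), (_, _, _, ref_b) = scored[0], scored[1]
    _, m_model, m_single, _, _ = bimera_score(bases, ref_a, ref_b)
    return m_single - m_model >= min_advantage


def error_rate(
    reads: Iterable,
    db: RefDB,
    exclude_ref_chimeras: bool = True,
    min_advantage: int = 3,
    min_identity: float = 0.90,
) -> Tuple[float, int, int]:
    """Ratio of erroneous bases to total bases over the given reads.

    With ``exclude_ref_chimeras`` (the "chimera absent" scenario), reads
    flagged by :func:`reference_chimera_check` are excluded; otherwise all
    reads count (the realistic scenario, applied after the pipeline's own
    chimera stage).  Reads whose best reference identity falls below
    ``min_identity`` are off-target (contaminants / alignment failures)
    and are always excluded: the statistic measures sequencing error of
    reads attributable to the mock community, and a single off-target read
    would otherwise contribute hundreds of spurious "errors".  Returns
    (rate, n_used, n_excluded).  Identical read sequences are aligned once.
    """
    err_cache: Dict[str, Tuple[int, int, bool]] = {}
    n_used = n_excluded = 0
    total_err = total_len = 0
    for read in reads:
        _, bases = _read_fields(read)
        hit = err_cache.get(bases)
        if hit is None:
            rec = best_reference_alignment(read, db)
            excl = rec.identity < min_identity
            if not excl and exclude_ref_chimeras:
                excl = reference_chimera_check(read, db, min_advantage)
            hit = (rec.n_errors, rec.aligned_length, excl)
            err_cache[bases] = hit
        n_err, length, chim = hit
        if chim:
            n_excluded += 1
            continue
        n_used += 1
        total_err += n_err
        total_len += length
    if n_used == 0:
        raise OtuflowError("no usable reads: error rate undefined")
    return total_err / total_len, n_used, n_excluded


def classify_otus(
    table: OTUTable, db: RefDB, t_sim: float = DEFAULT_T_SIM
) -> Dict[str, str]:
    """Four-way OTU categorization by centroid sequence.

    Fixed precedence per centroid: *original* when identity to any mock
    reference is strictly greater than ``t_sim``; else *chimeric* when the
    two-best-reference bimera check flags it and the two-parent model
    identity exceeds ``t_sim``; else *contaminant* when identity to any
    contaminant reference exceeds ``t_sim``; else *other*.
    """
    categories: Dict[str, str] = {}
    for otu in table.otus:
        bases = otu.centroid.bases
        best_ident = max(
            semiglobal_align(bases, ref).glocal_identity for _, ref in db.mock_refs
        )
        if best_ident > t_sim:
            categories[otu.otu_id] = "original"
            continue
        if len(db.mock_refs) >= 2:
            scored = sorted(
                (-semiglobal_align(bases, ref).glocal_identity, i, ref)
                for i, (_, ref) in enumerate(db.mock_refs)
            )
            ref_a, ref_b = scored[0][2], scored[1][2]
            _, m_model, m_single, _, _ = bimera_score(bases, ref_a, ref_b)
            model_ident = (len(bases) - m_model) / len(bases)
            if m_single - m_model >= 3 and model_ident > t_sim:
                categories[otu.otu_id] = "chimeric"
                continue
        if db.contaminant_refs:
            cont_ident = max(
                semiglobal_align(bases, ref).glocal_identity
                for _, ref in db.contaminant_refs
            )
            if cont_ident > t_sim:
                categories[otu.otu_id] = "contaminant"
                continue
        categories[otu.otu_id] = "other"
    return categories


def otus_per_species(
    categories: Dict[str, str], table: OTUTable, db: RefDB
) -> Tuple[Dict[str, int], List[str]]:
    """Credit each *original* OTU to its best-matching species; species
    with no OTU are reported missing."""
    counts = {name: 0 for name, _ in db.mock_refs}
    for otu in table.otus:
        if categories.get(otu.otu_id) != "original":
            continue
        best = None
        for name, ref in db.mock_refs:
            ident = semiglobal_align(otu.centroid.bases, ref).glocal_identity
            if best is None or ident > best[1]:
                best = (name, ident)
        counts[best[0]] += 1
    missing = [name for name, n in counts.items() if n == 0]
    return counts, missing


def average_otus_per_species(counts: Dict[str, int]) -> float:
    detected = [n for n in counts.values() if n > 0]
    return sum(detected) / len(detected) if detected else 0.0


def rarefaction(
    assignments: Dict[str, Optional[str]], depths: Sequence[int]
) -> List[Tuple[int, float]]:
    """Analytic expected OTU richness at each subsampling depth.

    E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)] over OTUs with N_i assigned
    reads (unassigned reads are excluded), computed via log-gamma.
    """
    otu_sizes: Dict[str, int] = {}
    for otu_id in assignments.values():
        if otu_id is not None:
            otu_sizes[otu_id] = otu_sizes.get(otu_id, 0) + 1
    sizes = np.array(sorted(otu_sizes.values()), dtype=float)
    N = int(sizes.sum())
    out: List[Tuple[int, float]] = []
    for n in depths:
        if n > N:
            raise ValueError(f"depth {n} exceeds total assigned reads {N}")
        if n < 0:
            raise ValueError("depth must be ≥ 0")
        out.append((int(n), expected_richness(sizes, N, int(n))))
    return out


def expected_richness(sizes: np.ndarray, N: int, n: int) -> float:
    """Σ_i [1 − C(N−N_i, n)/C(N, n)] via log-gamma, exact to float."""
    if n == 0:
        return 0.0
    sizes = np.asarray(sizes, dtype=float)
    rest = N - sizes  # reads outside OTU i
    terms = np.ones_like(rest)
    feasible = rest >= n  # else the OTU is certainly seen
    r = rest[feasible]
    log_p = (
        gammaln(r + 1)
        - gammaln(r - n + 1)
        + gammaln(N - n + 1)
        - gammaln(N + 1)
    )
    terms[feasible] = 1.0 - np.exp(log_p)
    return float(terms.sum())


@dataclass
class StageRow:
    stage: str
    reads_in: int
    reads_out: int
    removed: int
    frac_of_input: float  # reads_out / first stage's reads_in


def stage_accounting(
    stage_logs: Sequence[Tuple[str, int, int]]
) -> Tuple[List[StageRow], float]:
    """Per-stage removed counts and retained fractions.

    Stages must be contiguous (one stage's output is the next one's input)
    and non-increasing; returns (rows, overall retained fraction).
    """
    if not stage_logs:
        raise ValueError("no stages to account for")
    rows: List[StageRow] = []
    first_in = stage_logs[0][1]
    prev_out = None
    for stage, n_in, n_out in stage_logs:
        if n_out > n_in:
            raise ConsistencyError(f"stage {stage}: out {n_out} > in {n_in}")
        if prev_out is not None and n_in != prev_out:
            raise ConsistencyError(
                f"stage {stage}: in {n_in} != previous stage out {prev_out}"
            )
        rows.append(
            StageRow(
                stage=stage,
                reads_in=n_in,
                reads_out=n_out,
                removed=n_in - n_out,
                frac_of_input=n_out / first_in if first_in else 0.0,
            )
        )
        prev_out = n_out
    overall = prev_out / first_in if first_in else 0.0
    return rows, overall


def write_accounting(rows: List[StageRow], path) -> None:
    with open(path, "w") as out:
        out.write("stage\treads_in\treads_out\tremoved\tfrac_of_input\n")
        for r in rows:
            out.write(
                f"{r.stage}\t{r.reads_in}\t{r.reads_out}\t{r.removed}\t"
                f"{r.frac_of_input:.6f}\n"
            )
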