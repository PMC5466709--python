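# Methods

This note documents the models and procedures implemented in `otuflow`,
the defaults and why they were chosen, what the simulator does and does
not emulate, and the numerical conventions that make results reproducible.

## Sequence comparison

All pairwise comparisons share one alignment kernel: semi-global
Needleman–Wunsch with match +1, mismatch −1, linear gap −2, and free
terminal gaps on both sequences. Ambiguous bases (`N` and the other IUPAC
codes) never match anything, including themselves: an `N` produced by the
merger's conflict rule is evidence of error and must not be rewarded.

Two identity statistics are derived from an alignment of query *q*
against target *t*:

* `identity` = M / (M + X + G), where M, X, G are match, mismatch and
  internal-gap columns; terminal gap columns are excluded entirely. Each
  internal gap column counts as one difference (no affine weighting).
* `glocal_identity` = M / (M + X + G + U), where U is the number of
  query bases left unaligned in terminal overhangs.

The distinction matters because free terminal gaps make the optimal
alignment of two *unrelated* sequences a short "glancing" match — a
handful of matched columns and hundreds of free overhang columns — whose
plain `identity` can be 1.0. Every threshold decision (joining a centroid,
mapping a read, categorizing an OTU, choosing a best reference) therefore
uses `glocal_identity`, which requires the query to be substantially
covered. For full-length alignments, the two statistics coincide.

For preclustering, distances are unaligned: Hamming for equal lengths and
a banded unit-cost edit distance (band half-width = the allowed
difference count) otherwise. An alignment-space distance against a curated
reference multiple alignment is out of scope; the unaligned distances are
the substitute and behave identically for the near-identical sequences
preclustering is meant to absorb.

The kernels are numba-compiled; a 250×250 alignment costs ~0.15 ms, which
keeps full-DP mapping affordable at the problem sizes used here
(dereplicated inputs, tens of centroids). A k-mer prescreen hook exists in
spirit (candidate shortlisting in the chimera module) but mapping itself
aligns against every centroid so that results cannot depend on a filter.

## Read preparation

**Spectral k-mer correction.** A single-pass corrector over canonical
k-mers (lexicographic minimum of a k-mer and its reverse complement).
Defaults: k = 15, weak ≤ 1, strong ≥ 3, at most 2 corrections per read.
A position is rewritten to base *b* only when (a) it is covered by at
least one weak k-mer, (b) substituting *b* makes every window covering the
position strong, and (c) *b* is unique; reads needing more than the
correction budget, or with ambiguous alternatives, are left untouched and
flagged. k = 15 is long enough that a random 250 bp amplicon set shares no
k-mers between species, short enough that a 2 × 150 bp run at modest depth
makes true k-mers strong. The published spectral correctors add clustering
machinery on top of the same idea; this implementation deliberately stops
at the spectral rule.

**Merging.** The reverse read is reverse-complemented (qualities
reversed) and slid along the forward read without gaps. The offset
maximizing matches − mismatches wins; ties keep the largest overlap. Raw
match count is *not* the objective: a long spurious overlap at ~35% random
matches would outscore a short exact one, and merging must reconstruct
error-free templates exactly. Amplicon mates come from a fixed-length
molecule, so gapped overlap alignment is out of scope. Consensus per
overlap column: agreement keeps the base with quality max(q_f, q_r);
disagreement takes the higher-quality base with quality |q_f − q_r| when
|q_f − q_r| ≥ dq_threshold (default 6, a published contig-assembly
heuristic), else `N` with quality 0. The quality assignments are this
package's convention. Rejection (overlap < 20, or overlap mismatch
fraction > 0.3) is a typed outcome, not an exception.

**Screening.** Filters apply in a fixed order — ambiguous bases (> 0
rejects), homopolymer run (> 8 rejects; a run of exactly 8 passes),
length window, then expected errors E = Σ 10^(−Q/10) when a maxEE cap is
set. Kept/rejected status is order-independent; only the reported reason
depends on the order.

## Denoising

Dereplication groups exact strings; output is sorted by abundance
(descending), ties by first occurrence, and the representative ID is the
first member's. Preclustering then scans in that order and merges each
sequence into the *first* retained sequence within *d* differences —
"first" (most abundant), not "nearest", which is what makes the pass
single-linkage-like and order-deterministic. Abundances, members and
per-sample counts accumulate onto the receiver; the receiver's sequence
never changes; total abundance is conserved and the pass is idempotent.
`d = auto` means round(median length / 100) — the 1-difference-per-100 bp
community convention, giving d = 2 at 250 bp.

## Chimera detection

A bimera — the two-parent case of a PCR crossover — is detected de novo
from abundance structure alone. Candidate parents must be ≥ 2× more
abundant than the query (skew 2.0: a chimera arises late, so its parents
have completed more amplification rounds) and are shortlisted by shared
canonical 8-mers per query quarter (top 4 per quarter, ≤ 16 total).

For each candidate pair the query's per-position match profiles against
both parents (projected from the pairwise alignments onto query
coordinates) are combined over both parent orderings and every breakpoint
x: m_model(x) = mismatches vs the left parent on [0, x) + mismatches vs
the right parent on [x, L). The query is chimeric when the best split
satisfies all of:

1. **advantage** m_single − m_model ≥ 3 (the two-parent model must beat
   the best single parent meaningfully);
2. **support** ≥ 3 sites per side matching the assigned parent but not
   the other;
3. **conflicts** ≤ 1 site matching the wrong-side parent only;
4. **model fit** 1 − m_model/L ≥ 0.9.

Conditions 3 and 4 are what make the test specific, and they deserve
justification. For a query that is merely *distant* from both parents
(one genuine species tested against two others), the per-site difference
of the two mismatch profiles is a ±1 random walk, and the advantage
statistic is that walk's range — order √(number of informative sites), so
condition 1 alone would flag real species wholesale. But such a query
accumulates conflicting sites in proportion to its divergence, while a
genuine crossover has essentially none (condition 3). And an off-target
sequence (e.g. a contaminant) matches each parent only in short glancing
stretches, which mimic a high-advantage, zero-conflict split while
explaining only a fraction of the query (condition 4). A true bimera of
denoised parents has m_model ≈ its own sequencing errors, far inside both
bounds.

Detection proceeds in decreasing abundance, and flagged sequences leave
the pool, so a chimera never serves as another query's parent and no
sequence is ever compared against a less-abundant pool member. The
optional ensemble majority-votes a strict (4/4) and a lenient (2/2)
parameterization of the same test; with two voters the tie rule makes it
a consensus. External detectors can join the vote via the verdict TSV
interchange format.

## Clustering and mapping

Greedy abundance-sorted centroid clustering, threshold t = 0.97
(closed: identity ≥ t joins). Each unique, in decreasing abundance,
either joins the best existing centroid (ties → more abundant centroid,
then earlier), is discarded as a bimera against the existing centroids
(same four-condition test), or founds a new OTU. Singleton removal is
deliberately off, so rare sequences are judged by sequence identity and
chimera structure, not by abundance alone. Mapping assigns each read to
the centroid of maximum glocal identity if ≥ t, else counts it
unassigned; read counts are conserved exactly. The clustering threshold
and the evaluation's "original OTU" threshold are separate parameters:
clustering joins at ≥ 0.97, while the category test requires > 0.97,
matching the strict phrasing of the benchmark definition.

## Mock-community evaluation

**Error rate.** Each read is aligned to every mock reference; the best
(maximum glocal identity, ties → database order) yields substitution
(mismatch columns, including `N` in the read), insertion (read base
opposite a reference gap) and deletion (reference base opposite a read
gap) counts, terminal overhangs excluded. The rate is Σ errors / Σ read
lengths — the read-length denominator is this package's fixed choice.
Two exclusions apply: (i) reads better explained as a crossover of their
two best references (advantage ≥ 3) are reference-identified chimeras,
excluded in the "chimera absent" scenario; (ii) reads whose best
reference identity is below 0.90 are off-target and always excluded —
the statistic measures sequencing error of reads attributable to the
community, and one contaminant read would otherwise contribute hundreds
of phantom "errors".

**Categories.** Each OTU centroid is classified with fixed precedence:
*original* (> 97% identity to a mock reference), else *chimeric*
(reference crossover with model identity > 97%), else *contaminant*
(> 97% to a supplied contaminant reference; without contaminant
references this collapses into *other*), else *other*. Original OTUs are
credited to their best-matching species to quantify over-splitting and
missing species.

**Rarefaction.** The expected OTU count at depth n is analytic:
E[S_n] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], computed via log-gamma. Tests
verify exact enumeration on a 4-read/2-OTU table (5/3 at n = 2) and
agreement with Monte-Carlo subsampling within 3 standard errors.

**Accounting.** Stage logs are kept in read units end to end; stages must
be contiguous (one stage's output is the next one's input) and
non-increasing. Dereplication and preclustering conserve reads; the
chimera and clustering stages remove the reads of rejected uniques;
mapping reports assigned vs unassigned.

## The simulator

`mocksim` emulates what a mock-community benchmark quantifies, not a
sequencer. A fragment is drawn as a contaminant (probability
`contaminant_rate`), else a two-parent crossover at a uniform interior
breakpoint (probability `chimera_rate`, parents drawn by abundance and
distinct), else a single reference by abundance. The fragment is then
corrupted once — per-position substitution (uniform over the three
alternatives), insertion and deletion rates — and split into the mates:
forward read = first `read_len` bases, reverse read = reverse complement
of the last `read_len` bases. Because corruption happens at the fragment
level, mates are mutually consistent and merging reconstructs the
corrupted fragment exactly; this models PCR-propagated errors and makes
error-rate recovery unbiased, but it means the merger's conflict rule is
exercised by constructed tests (and by one-sided k-mer corrections), not
by the simulator's raw output.

Qualities follow a linear mean decay along the read (defaults 38 → 25,
Gaussian jitter sd 3, clamped to [2, 41]) and are deliberately *not*
coupled to the realized errors: expected-error filters are exercised, but
passing them says nothing about whether quality predicts error position —
a known gap between this simulator and real instrument data, along with
GC-dependent error profiles, phasing artifacts and flow-cell effects,
none of which are modeled.

The packaged reference set is 21 synthetic ~250 bp amplicons generated
once (fixed internal seed) by mutating a common random base sequence at
18% per site — pairwise identities ~70–75%, far below both the 97%
clustering threshold and 90%, so each reference founds its own OTU and
chimera parents are richly informative. Default run conditions:
substitution rate 10⁻³ per base (the dominant MiSeq error mode), indel
rates 10⁻⁴, 5% chimeric fragments, 150 bp reads from 250 bp amplicons
(50 bp overlap). One RNG stream per run; the seed is part of the spec,
and identical spec + seed reproduces byte-identical FASTQ output.

## Problem sizes and determinism

The default test suite and the acceptance script run simulations of
2,000–10,000 fragments with 10–21 references — sizes chosen so every
distributional check has comfortable statistical margin (e.g. error-rate
recovery uses ≥ 5×10⁵ aligned bases, where a 20% relative tolerance is
>6 binomial standard deviations) while the whole suite stays interactive.
No pipeline stage draws randomness, so identical inputs and configuration
reproduce byte-identical OTU tables, verdicts and accounting; all
simulator randomness derives from the user-supplied seed.

## Known limitations

* Chimera detection is pairwise only; 3-segment (multi-parent) chimeras
  are tested against two-parent models and may escape when each
  two-parent projection lacks support.
* The corrector assumes per-sample spectra: mixing samples with very
  different depths can push true rare k-mers below the strong threshold.
* Identity conventions differ between published tools; the definitions
  fixed here (internal gap columns count 1, terminal gaps free,
  query-coverage-adjusted for decisions) are documented rather than
  claimed equivalent to any specific tool's.
* The evaluator's reference-chimera check uses only the two best-matching
  references as parents; crossovers of two nearly identical references
  may go unflagged (they are also nearly harmless to the error rate).
* Off-target exclusion (identity < 0.90) means the error rate does not
  reflect contamination; contamination is reported through the OTU
  categories instead.
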