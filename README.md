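# otuflow

Amplicon reads → OTUs: an end-to-end processing toolkit for paired-end 16S
rRNA (MiSeq-style) amplicon sequencing data, with built-in mock-community
benchmarking.

Microbial ecologists estimate community composition by clustering amplicon
reads into Operational Taxonomic Units (OTUs) at 97% sequence identity,
where each OTU ideally represents one species. In practice the OTU count is
inflated by sequencing errors, PCR chimeras and contaminants, so a
processing pipeline must merge mate pairs, correct and filter errors,
detect chimeras and cluster carefully — and the only way to measure how
well it does is to run it on a *mock community* whose reference sequences
are known. `otuflow` provides both halves: the pipeline and the
benchmarking machinery, plus a simulator that generates realistic mock
runs with ground truth so everything is testable without downloads.

## What's inside

Stages (each a library function and a CLI subcommand, composable or run
end-to-end in a fixed order):

1. **k-mer correction** (`correct`) — pre-assembly spectral error
   correction: canonical k-mer counting (k = 15); a base is rewritten only
   if it lies in a weak k-mer (count ≤ 1) and exactly one substitution
   makes every covering window strong (count ≥ 3); at most 2 corrections
   per read.
2. **Paired-end merging** (`merge`) — ungapped overlap scan maximizing
   matches − mismatches; per-column consensus: agreement keeps the base at
   max(q_f, q_r); a conflict goes to the higher-quality base with quality
   |q_f − q_r| when |q_f − q_r| ≥ 6, else to `N` at quality 0.
3. **Screening** (`screen`) — drop reads with any ambiguous base, a
   homopolymer longer than 8, out-of-range length, or expected errors
   E = Σ 10^(−Q/10) above a maxEE cap.
4. **Dereplication** (`derep`) and **preclustering** (`precluster`) —
   exact-duplicate collapsing, then the greedy single-linkage-style pass:
   in decreasing abundance, absorb each unique into the first retained
   sequence within *d* differences (*d* = 1 per 100 bp by default).
5. **Chimera removal** (`chimera`) — de novo bimera detection with
   abundance skew (parents must be ≥ 2× more abundant): the query is
   flagged when a two-parent split beats the best single parent by ≥ 3
   mismatches, with ≥ 3 supporting sites per side, ≤ 1 conflicting site,
   and a model that explains ≥ 90% of the query. An optional ensemble
   majority-votes a strict and a lenient parameterization.
6. **OTU clustering** (`cluster`) and **read mapping** (`map`) — greedy
   abundance-sorted centroid clustering: join the best centroid at
   identity ≥ 0.97, else discard if the bimera test flags it, else found a
   new OTU; then map reads back to centroids to build the OTU table.
   Identity comes from semi-global alignment (match +1, mismatch −1, gap
   −2, free terminal gaps), with unaligned query bases charged to the
   denominator so unrelated sequences cannot produce spurious
   high-identity hits.

Evaluation (`evaluate` + `otuflow.mockeval`): reference-based error rate
(ratio of substitution + insertion + deletion bases to total read bases,
with chimeras either excluded using the known references or handled by the
pipeline's own detector), the four-way OTU categorization (original /
chimeric / contaminant / other), OTUs-per-species over-splitting, analytic
rarefaction E[S_n] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], and per-stage read
accounting.

Simulation (`simulate` + `otuflow.mocksim`): paired reads from a packaged
set of 21 divergent ~250 bp synthetic reference amplicons (or your own),
with per-base substitution/indel errors, PCR-crossover chimeras,
contaminants, a linear quality-decay model, and a ground-truth table.

## Worked example

```python
import otuflow as of

spec = of.MockSpec(
    refs=of.default_references(10),   # 10 synthetic species, ~250 bp
    n_fragments=2000,
    sub_rate=0.001,                   # 0.1% substitutions per base
    chimera_rate=0.05,                # 5% PCR crossover fragments
    seed=42,
)
pairs, truth = of.emit_paired_reads(spec)
result = of.process_pairs(pairs, of.PipelineConfig())

rows, retained = result.accounting
for row in rows:
    print(f"{row.stage:12s} {row.reads_in:6d} -> {row.reads_out:6d}")
print(f"retained {retained:.1%} of input read pairs")
print(f"OTUs: {len(result.otu_table.otus)}  (simulated species: {len(spec.refs)})")

db = of.RefDB(mock_refs=spec.refs)
rate, n_used, n_excluded = of.error_rate(result.screened, db, exclude_ref_chimeras=True)
print(f"chimera-absent error rate: {rate:.2e} over {n_used} reads")
```

prints

```
correct        2000 ->   2000
merge          2000 ->   2000
screen         2000 ->   1973
dereplicate    1973 ->   1973
precluster     1973 ->   1973
chimera        1973 ->   1867
cluster        1867 ->   1867
map            1867 ->   1867
retained 93.3% of input read pairs
OTUs: 10  (simulated species: 10)
chimera-absent error rate: 4.46e-04 over 1876 reads
```

Reading this: merging reconstructed every fragment (mates are consistent
slices of the same molecule); screening dropped 27 reads whose overlap
conflicts were resolved to `N` after one-sided correction; the chimera
stage removed 106 reads — close to the 5% simulated crossover fraction —
and clustering recovered exactly the 10 simulated species. The residual
error rate (4.5 × 10⁻⁴) is below the simulated 10⁻³ because the k-mer
corrector removed roughly half of the substitution errors before merging.

The same run from a shell:

```bash
otuflow simulate --out sim/ --n-fragments 2000 --seed 42
otuflow run --config run.toml        # r1/r2/outdir in a small TOML file
otuflow evaluate --reads sim_merged.fastq --refs sim/refs.fasta --out report.json
```

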