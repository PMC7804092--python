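# concerted

Detecting concerted evolution of rDNA repeats in amplicon sequencing
data.

Ribosomal DNA occurs in tandem arrays of hundreds to thousands of
near-identical repeats.  Gene conversion and unequal crossing-over
homogenise the repeats of an array, while point mutation keeps creating
new variants — so deep amplicon sequencing of one organism (or of one
species in an environmental metabarcoding series) shows a single
**dominant haplotype** at least an order of magnitude more abundant
than any other, surrounded by rare **minor haplotypes** a few
substitutions away.  This package is for molecular evolutionists and
metabarcoding practitioners who want to quantify that signature:

* a **generative simulator** of repeat-array evolution (Wright–Fisher
  lineages; per-copy gene conversion; block duplication/deletion by
  unequal crossing-over; substitution-only sequencing error) producing
  single-strain read sets and a seasonal environmental time series;
* **haplotype tables**: dereplication, length/quality filters
  (≥ 350 bp, mean Q ≥ 20), top-50 truncation, minimum-abundance
  filters, and the dominance statistic `log10(a_1/a_2) ≥ 1`;
* **rank-abundance model selection**: broken stick, geometric-series
  preemption, lognormal, Zipf (`a_r = N·p1·r^γ`) and Zipf–Mandelbrot
  (`a_r = N·c·(r+β)^γ`) fitted by Poisson maximum likelihood and ranked
  by `BIC = −2·loglik + k·ln S`;
* **similarity statistics**: percent-identity best matches, cumulative
  similarity classes (100 / 99.73 / 99.47 / 99.20 ≙ 0–3 mismatches on a
  ~382 bp amplicon), and homogenisation efficiency — the percentage of
  reads joining the dominant haplotype's cluster at 99% identity under
  greedy centroid clustering;
* **statistical-parsimony haplotype networks** (minimum-spanning-network
  construction with a 95% connection limit derived from sequence
  length, inferred intermediates for multi-step links, monthly read
  partitions) and a **Monte-Carlo Kolmogorov–Smirnov test** of whether
  each minor node shares the dominant node's temporal distribution
  (1000 permutations, add-one p-value, α = 0.05).

## Worked example

```python
from concerted import SimConfig, evolve_population, sample_strain_reads
from concerted import haplotypes as hp, radmodels as rm, similarity as sim

cfg = SimConfig(seed=1)                      # default study conditions
genomes = evolve_population(cfg)             # 10 lineages, 10^4 generations
reads = sample_strain_reads(genomes, cfg, ["lineage0"])   # 20,000 reads

table = hp.dereplicate(reads)
dom = hp.dominance(table)
print(f"reads: {table.N}   haplotypes: {table.S}")
print(f"dominant: {dom.dominant_id} ({dom.dominant_count} reads), "
      f"second: {dom.second_count} reads, log10 ratio {dom.log10_ratio:.2f}")

rep = sim.cluster_to_dominant(reads, 99.0)
print(f"homogenisation efficiency at 99% identity: {rep.efficiency:.2f}%")

for res in rm.select_model(hp.top_k(table, 50).abundances()):
    print(f"  {res.model:<16} k={res.k} BIC={res.bic:9.1f} "
          f"dBIC={res.delta_bic:9.1f}")
```

prints

```
reads: 20000   haplotypes: 2245
dominant: hap1 (13661 reads), second: 13 reads, log10 ratio 3.02
homogenisation efficiency at 99% identity: 99.89%
  zipf_mandelbrot  k=3 BIC=   1833.8 dBIC=      0.0
  zipf             k=2 BIC=   5595.0 dBIC=   3761.2
  lognormal        k=2 BIC=   7803.3 dBIC=   5969.5
  preemption       k=1 BIC=  27403.8 dBIC=  25570.0
  brokenstick      k=0 BIC=  62338.7 dBIC=  60504.9
```

Read it as: of 20,000 simulated strain reads, the dominant haplotype is
three orders of magnitude above the runner-up; 99.89% of reads sit
within 99% identity of it (efficient homogenisation, incomplete only
because mutation and sequencing error never stop); and the Zipf family
(here its Mandelbrot extension) beats the other rank-abundance models
by thousands of BIC units — the power-law decay of minor-haplotype
abundances that concerted evolution produces.

## Command line

The same pipeline is available as a console script:

```sh
concerted all --seed 1 --outdir results/demo          # full pipeline
concerted simulate --outdir sim/                      # stages separately
concerted derep sim/strain_reads.fasta --out strain.tsv
concerted radfit strain.tsv --top 50 --out fits.tsv
concerted similarity env.tsv strain.tsv --out matches.tsv
concerted network env.tsv sim/env_dates.tsv --min-abund 2 --nexus-out net.nex
concerted ks env.tsv sim/env_dates.tsv --n-perm 1000 --out ks.tsv
```

All outputs are plain text (TSV, FASTA, GML and a PopART-style NEXUS
with a monthly traits block).  Every `all` run writes a
`manifest.json` with the configuration, the seed and SHA-256 digests of
all artefacts; identical seeds reproduce the manifest byte for byte.

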