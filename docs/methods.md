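# Methods

## The question and the observables

Ribosomal DNA occurs in tandem arrays of hundreds to thousands of
repeats.  Gene conversion and unequal crossing-over continually
homogenise the repeats of an array (concerted evolution) while point
mutation creates new variants, so a genome at, or approaching,
mutation–homogenisation balance carries one highly abundant repeat
variant — the *dominant haplotype* — plus rare *minor haplotypes* a few
substitutions away.  Deep amplicon sequencing makes this structure
directly observable: in each monoclonal strain, and in each species of
an environmental metabarcoding series, the most abundant unique sequence
should (i) exceed the runner-up by at least an order of magnitude,
(ii) match the Sanger reference barcode, (iii) absorb ~99% of reads when
haplotypes are clustered at 99% identity, and (iv) sit at the centre of
a star-shaped haplotype network whose minor nodes share its seasonal
read profile.  The package computes each of these statistics and
provides a generative simulator so that every stage is testable without
sequencing data.

## The simulator

One lineage carries one repeat array: an ordered list of fixed-length
(default 380 bp) A/C/G/T sequences.  The model is indel-free — V4-type
amplicon haplotypes of a species differ essentially by substitutions —
so repeats never change length, only the *number* of repeats changes.
Per generation, in order:

1. **Clonal Wright–Fisher resampling** of the `n_lineages` lineages
   (diatom populations are effectively clonal at bloom timescales;
   generation-synchronous resampling keeps the model simple).
2. **Point mutation** at `mu` per site per copy; the new base is drawn
   uniformly from the three alternatives.
3. **Gene conversion**: each copy is, with probability `gc_rate`,
   overwritten by a uniformly chosen *other* copy of the same array
   (whole-repeat tract by default; a shorter tract at a uniform offset
   is available).  Conversions of one generation read from the
   pre-conversion state.
4. **Unequal crossing-over**: with probability `uco_rate` per genome, a
   uniformly placed block of `uco_block` contiguous copies is duplicated
   in place or deleted, with equal probability.  An event that would
   push the copy number outside `copy_number_bounds` is rejected
   outright rather than truncated, so event semantics stay clean.

Copy numbers start at 3600 and are bounded to 2002–5055, the range
reported for the diatom genus the package targets.

**Rates.**  No measurements of conversion or crossing-over rates exist
for diatom rDNA, so the defaults are explicit placeholders chosen for
the qualitative regime, not biological estimates.  The controlling
quantity is the pairwise coalescence probability of two repeat copies
per generation, `c = 2g(1-g)/(C-1) + g^2 (C-2)/(C-1)^2` (either copy
converts the other, or both pick the same donor), against the two-copy
mutation pressure `2u` with `u = mu * repeat_len`.  The expected
pairwise identity follows `F' = (1-u)^2 [c + (1-c) F]`, with fixed point
`F* = c(1-u)^2 / (1 - (1-c)(1-u)^2) ~ c/(c+2u)`.  The defaults
(`gc_rate = 0.5`, `mu = 5e-9`, 10,000 generations at C = 3600) put the
array near that balance with `F* ~ 0.98`: one dominant variant around
97–99% of copies and a small set of minor variants one or two
substitutions away.  This recursion is exact in expectation for the
whole-repeat conversion model and doubles as the independent oracle for
the simulator tests.  Note what it implies: at C = 3600 the
homogenising force per copy pair is at most `2/(C-1) ~ 5.6e-4` per
generation, so equilibrium dominance requires `mu << 7e-7` regardless
of the conversion rate — "strong" concerted evolution in a large array
is only possible because per-generation mutation rates are tiny.

**Sampling.**  Strain sequencing draws `reads_per_strain` (default
20,000) reads multinomially over one genome's copies with uniform
weight, then applies substitution-only sequencing error (`seq_error`,
default 1e-3 per site — the order of substitution error of
semiconductor sequencing after indel correction; indel errors are out
of scope).  The environmental series distributes `env_total_reads`
(default 40,000) over `n_months` (default 36) multinomially according
to a seasonal profile (default: a bimodal spring/autumn bloom pattern
tiled over three years); each read picks a lineage uniformly and then a
copy uniformly.  Minor haplotypes therefore co-vary with the dominant
haplotype by construction — the temporal signature the network stage is
designed to detect.

**What the generator does not emulate.**  PCR chimeras and indel
errors; between-species mixtures (one species per run — the
BLAST-validation stage of a real study is out of scope); biased gene
conversion; selection on repeats; physical linkage structure of the
array beyond block duplication.  Consequently, passing tests show that
the *analysis* behaves correctly on data with the paper-like
dominant/minor structure, not that real amplicon data are free of the
artefacts listed above.

## Haplotypes

A haplotype is a unique read sequence (exact string identity; real data
would be length-trimmed upstream).  Filters follow the printed
pre-processing rules: reads shorter than 350 bp or with mean quality
below 20 are discarded (boundaries: `>= 350` and `>= 20` retained,
since the discard rules are strict inequalities; mean rather than
per-base quality is an assumption, configurable).  Rank ties are broken
lexicographically by sequence so every ranking is deterministic.
Dominance is operationalised as `dominant/second >= 10`
(log10 ratio >= 1), i.e. "at least one order of magnitude"; a
single-haplotype table is dominant with an infinite ratio sentinel.

## Rank-abundance models

Counts at ranks 1..S are modelled as independent Poisson draws around
the model curve (counts are reads, and Poisson ML is the convention of
the standard community-ecology implementation of these fits):

| model            | a_r                          | k |
|------------------|------------------------------|---|
| broken stick     | (N/S) sum_{x=r..S} 1/x       | 0 |
| preemption       | N alpha (1-alpha)^(r-1)      | 1 |
| lognormal        | exp(mu + sigma z_r)          | 2 |
| Zipf             | N p1 r^gamma                 | 2 |
| Zipf–Mandelbrot  | N c (r+beta)^gamma           | 3 |

with `z_r` the standard-normal quantile at `(S-r+0.5)/S` (the standard
plotting-position convention; the choice matters only at small S).
`p1` is fitted, not fixed to the observed first-rank proportion.
Models are ranked by `BIC = -2 loglik + k ln S`; ties go to the smaller
k.  Numerical choices: lognormal and Zipf are Poisson GLMs (log link,
IRLS, tolerance 1e-8), which makes their fitted totals reproduce N
exactly (score equation of the canonical link).  Zipf–Mandelbrot
profiles the GLM over beta on a log1p grid (beta in (-1, 1000]) with a
bounded scalar polish; the beta = 0 start guarantees its likelihood
never falls below Zipf's.  Preemption is located on a 4097-point alpha
grid and polished by bounded search (xatol 1e-12), which provably
dominates any 1e-4-step grid.  Failures are flagged on the result
(`converged=False`, loglik = -inf) and never abort a model comparison.

One caveat documented rather than hidden: a Zipf parameter pair such as
(p1 = 0.5, gamma = -1) does not normalise to 1 over S ranks, so counts
generated from that curve have a total larger than the nominal N, and
the fitted `p1 = exp(intercept)/N_observed` is correspondingly smaller.
Parameter-recovery checks therefore compare `exp(intercept)` against
`p1 * N_generating`, which is the quantity the formula defines.

## Similarity and homogenisation

Equal-length sequences are compared by Hamming identity,
`100 (L - mismatches)/L`; for ~382 bp amplicons the similarity classes
100 / 99.73 / 99.47 / 99.20 are exactly the 0/1/2/3-mismatch classes.
Unequal lengths fall back to an end-gap-free global alignment (match
+1, mismatch -1, gap -2); identity is computed over the columns between
the first and last paired residues, internal gap columns counting as
differences, and the alignment is computed in a canonical argument
order so identity is symmetric under co-optimal alignments.
Homogenisation efficiency is the percentage of *reads* in the cluster
founded by the most abundant haplotype under greedy centroid clustering
(abundance-sorted, first-fit, threshold inclusive at 99%), the
convention of the usual centroid clustering tools.

## Networks and the temporal test

Pairwise Hamming distances are processed level by level in ascending
order; at each level, every pair joining two components of the
strictly-shorter-link graph is connected.  This yields exactly the
union of all minimum spanning trees (an edge is in some MST iff its
endpoints are in different components of the lighter subgraph), which
is the testable core of statistical-parsimony construction; links of d
steps get d-1 inferred intermediate nodes.  The 95% connection limit is
derived from sequence length alone: j substitutions thrown uniformly on
L sites are an unambiguous parsimonious path only if they hit j
distinct sites, probability `prod_{i=1..j-1}(1 - i/L)`; the limit is
the largest j keeping this >= 0.95 (L = 380 gives 6 steps).  This
reproduces the statistical-parsimony criterion semantically; matching
any particular software's internals bit for bit is not a goal, and the
limit can be overridden.  All pair processing is ordered
lexicographically by sequence, so the network is reproducible.

The temporal test treats months as ordered categories (calendar order,
month 1 = first month of the series).  D is the maximum absolute
difference of the two monthly ECDFs; the null redraws the node's month
counts from the pooled counts by multivariate hypergeometric sampling
(identical in law to permuting read labels with group sizes fixed),
1000 draws by default, and the p-value uses the add-one estimator
`p = (1 + #{D* >= D})/(1 + n_perm)` so p is never 0.  Nodes with
`p > 0.05` are *congruent* (the paper's "*" marks), the rest
*divergent* ("#").  All sampled non-dominant nodes are tested by
default; a node selection can be passed to mimic testing only chosen
peripheral nodes.

## Problem sizes

Chosen as the package's own defaults for desk-scale runs: simulations
use 10 lineages for 10,000 generations at 3600 copies (about 6 s per
run); the repository's end-to-end checks aggregate 20 seeded runs, the
KS calibration uses 200 replicate null tests at 1000 permutations, and
the acceptance script summarises 8 default simulations plus one
environmental series.  The statistics stabilise at these sizes; larger
replicate counts change the reported fractions by less than their
binomial standard errors.

## Known limitations

* Per-generation rates are placeholders (see above); absolute
  generation counts should not be read as calendar time.
* The neutral model cannot produce *many* mid-frequency minor variants
  at high dominance: the within-array variant-family size distribution
  is heavy-tailed, so most runs carry a handful of rare genomic
  variants and, rarely, one sizeable family.  Real arrays may differ
  (biased conversion, selection, locus structure).
* Poisson ML ignores the multinomial constraint between ranks and
  overdispersion from PCR; BIC rankings are conditional on that error
  family.
* The KS permutation null conditions on monthly totals and ignores
  within-month sample structure.
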