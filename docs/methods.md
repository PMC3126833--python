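# Methods

`pansort` implements the computational core of a two-species population
genetic analysis of the kind used to study incomplete lineage sorting
between bonobos and chimpanzees: a coalescent data generator, a
pyrosequencing heterozygote caller, classical diversity statistics with
divergence-calibrated effective sizes, a composite simulation-based test
of the standard neutral model, and posterior-monophyly analytics over
gene-tree samples. This note records the models, the numerical choices,
and what the synthetic data do and do not establish.

## Coalescent generator

Time is measured in units of 4N generations (Hudson's `ms` convention):
`theta` = 4Nµ·L and `rho` = 4Nr·L are locus-wide rates. The
single-population model is the Kingman coalescent; with `rho > 0`
ancestral lineages carry sets of half-open intervals of ancestral
material over the unit locus and experience crossover at rate
`rho × span` per lineage, Hudson-style. Coalescing lineages merge
segment lists; wherever both carry material a new genealogy node is
created, and an interval is retired as soon as it reaches its sample-wide
MRCA (so no time is spent above local roots). Mutations are Poisson on
branches with intensity `theta × interval length × branch length` —
infinite sites on a continuous locus, mapped afterwards to discrete base
positions with collisions re-drawn. Finite-sites corrections are ignored:
at ~1% outgroup divergence and 10 kb loci they are negligible, and the
all-ancestral reference returned as the outgroup surrogate is then the
correct polarizer at every polymorphic site.

Optional exponential growth multiplies the backwards coalescence
intensity by `exp(g·t)`; the waiting time is drawn by closed-form
inversion of the cumulative hazard. Growth interacts only with
coalescence, never with recombination. Only `g >= 0` is supported.

The two-population split model is a clean isolation model (no
migration): within-deme coalescence at rate `k(k-1)/size_ratio` until
`split_time`, then a single ancestral deme. It is implemented without
recombination so that each locus has a single realized genealogy, which
is recorded in Newick form — the lineage-sorting state
(polyphyly/paraphyly/reciprocal monophyly) of every simulated locus is
therefore known truth, not an inference.

Validation: E[S] = θ·a_n and E[π] = θ hold to Monte-Carlo precision with
and without recombination; for n = 2 the segregating-site count is
geometric with success probability 1/(1+θ) (chi-square goodness of fit at
α = 0.001); and the mean of Tajima's D and the variance-shrinking effect
of recombination on S both match msprime run at identical parameters.
msprime serves only as this cross-validation oracle; the simulator used
throughout the package is the one described here.

Determinism: every public entry point takes an integer seed; multi-locus
drivers draw per-locus seeds from a master PCG64 stream so individual
loci can be regenerated independently. Identical seeds give byte-identical
output.

## Read simulator

`simulate_reads` emulates amplicon pyrosequencing of one diploid over a
region: read lengths N(250, 30) truncated at 50 bp, uniform start
positions, random strand. Templates are duplicated with probability
`duplicate_rate` to mimic emulsion-PCR duplicates — duplicates share
start and strand (the signature the deduplication filter keys on) but
re-realize base calls independently. Allelic imbalance is modeled by
sampling the second haplotype with probability `allele_balance`
(0.5 = unbiased); `dropout=True` silences it entirely, producing the
spurious all-homozygous regions the skew/dropout screens look for.

Two error channels:

- **Homopolymer undercalls** — for each run of length ℓ ≥ 2 the last base
  is deleted (an alignment gap) with probability
  `min(0.5, rate × (ℓ−1))`, default rate 0.02. Overcalls (insertions) are
  not modeled: they would not change what the gap filter sees, and
  keeping reads free of insertions keeps pileup coordinates trivially
  consistent with the consensus.
- **Substitutions** — per-base qualities are drawn from a discrete phred
  profile (default mass on Q20–Q40, mean ≈ Q29); a base is substituted
  with probability `substitution_fraction × 10^(−q/10)`. The fraction
  (default 0.1) reflects that pyrosequencing quality values predominantly
  encode homopolymer/indel uncertainty — which this model already
  realizes through its own channel — while substitutions make up roughly
  5–10% of the platform's error budget. Realizing the full phred-implied
  rate as substitutions would double-count the indel component.

What the synthetic reads do not emulate: PCR chimeras, carry-forward /
incomplete-extension errors, position-dependent quality decay along the
read, and correlated errors between duplicates. Passing the caller's
false-positive/recovery checks on these reads therefore demonstrates the
filter cascade's logic and thresholds, not performance on any particular
real instrument run.

## SNP caller

The cascade follows the published pyrosequencing protocol exactly:
duplicate removal keeps the highest-quality read per (strand, start)
group, first-in-input on ties; reads with an alignment gap within 5 bp of
the candidate site, or more than one mismatch to the consensus within
±5 bp (the candidate allele itself excluded), do not count at that site;
sites within 10 bp of a homopolymer run ≥ 6 are never called; and the
neighbour-quality-score filter requires Q ≥ 20 at the site and Q ≥ 15 at
the five flanking bases on each side, within the read (flanks truncated
by the read boundary fail, so the outermost 5 bp of a read never support
a call — a conservative reading). Coverage below 8 reads after the
duplicate and gap filters is a no-call; otherwise the site is
heterozygous iff the minor-allele fraction among fully filter-passing
reads is strictly above 0.15 — both alleles are then automatically backed
by NQS-passing reads. Sites showing three alleles among eligible reads
are flagged no-call (`triallelic`); under infinite-sites truth these are
always error artifacts.

Two implementations are kept deliberately: a scalar per-site path written
directly from the filter definitions and a vectorized whole-region path
(cumulative-sum window filters over read × position matrices). The test
suite asserts they agree on simulated pileups, so each checks the other.

Caller validation runs two bundled experiments. The false-positive screen
calls every position of homozygous synthetic regions with the full error
model on (~134,000 callable sites) and requires zero heterozygous calls.
The recovery screen plants heterozygous sites in clean contexts and
requires every evaluable site to be called: a planted site is evaluable
when the preconditions for guaranteed detection hold — no homopolymer run
≥ 6 within 20 bp (so the masking filter cannot fire), filtered depth
≥ 20, and a realized minor-allele read fraction ≥ 0.35 at the site.
The last condition matters because allelic sampling at finite coverage
occasionally leaves one allele genuinely under-represented in the reads
(roughly one planted site in several hundred at 30× falls below the MAF
threshold by chance); such sites are undetectable in principle, by any
caller honouring the decision rule, and are excluded by construction
rather than counted against the cascade.

Region screens: `skew_flag` is set when a region has at least one SNP and
every SNP's minor-allele fraction is below 0.30 (the unequal-amplification
signature that triggers re-amplification with new primers in the lab
workflow); `all_homozygous_flag` when a region yields no heterozygous
call at all (the allelic-dropout alarm).

Coordinates are 0-based half-open internally, 1-based in written reports.

## Diversity statistics and Ne

Watterson's θ_w = S/(a_n·L), nucleotide diversity π as mean pairwise
difference per site, Tajima's D, and Fu & Li's D* use the classical
formulas; D* uses the corrected variance constants (the version with the
published erratum, as implemented in standard desktop software). The D
statistics are hand-verified against exact-fraction evaluations of the
formulas frozen into the tests, and their neutral-expectation behaviour
against coalescent simulation. Alignment columns containing any gap or
ambiguous base in the analysed sample are dropped entirely, and per-site
denominators use the remaining column count. Statistics are undefined
(NaN, never zero) when S = 0.

Multi-locus "pooled" rows sum S and length and compute D and D* from the
pooled totals — algebraically identical to concatenating the loci. Both
pooled and per-locus values are exposed; the neutrality test needs the
per-locus ones.

Ne = θ_w/(4µ) with µ = (d/2t)·g; the default calibration d = 1.35%
outgroup divergence, t = 6 My, g = 20 y gives µ = 2.25×10⁻⁸ per site per
generation. Report-style rounding is percentages to two decimals and Ne
to the nearest 100. With these conventions the bundled worked examples
(S, n, L triples at published scale) reproduce θ_w% and Ne exactly for
the bonobo (0.10%, 11,100), central (0.32%, 35,400) and
Nigerian-Cameroonian (0.20%, 22,400) rows; the western row lands within
one rounding unit (8,800 vs 8,900), which traces to sub-rounding
ambiguity in the printed inputs. Mean pairwise coalescent times are
4·Ne·g years.

Fst uses Hudson's 1 − H_w/H_b with H_b = p₁(1−p₂) + p₂(1−p₁), combined
across pooled biallelic SNPs as a ratio of averages and without
finite-sample correction terms, so identical allele frequencies give
exactly 0 and fixed differences exactly 1; Weir–Cockerham (1984) is
available as an option. Allele-sharing classification polarizes each
biallelic site on the outgroup and assigns it to one of the five
shared/fixed-derived categories; private polymorphisms with the other
group fixed ancestral, and sites whose outgroup carries a third allele,
are skipped.

## Composite neutrality test

Observed multi-locus data reduce to five summaries: the across-locus
variance of Tajima's D plus across-locus means of S, π, Fu & Li's D* and
Tajima's D. The null is the constant-size random-mating coalescent with
per-locus θ ~ Gamma(shape, scale) and ρ ~ log-normal, both
moment-matched to per-locus rate estimates (zero-variance inputs
degenerate to point masses with a warning). ρ is drawn — it shapes the
across-locus variance — but is never itself a summary statistic. Loci
with S = 0 contribute zero to the S and π means and are excluded from the
D means and variance.

Each summary receives a two-sided empirical p-value with add-one
smoothing, p = min(1, 2·min[(1+#≤)/(1+R), (1+#≥)/(1+R)]), so log p is
always finite. C is the sum of the five log p-values; the fit p-value is
the smoothed proportion of simulated datasets whose own C — computed
leave-one-out against the remaining replicates — is at least as small.
The two-sided tail and leave-one-out choices are documented switch
points; the leave-one-out difference is O(1/R).

Calibration, measured at 15 loci of 2 kb with n = 40, θ-Gamma(4, 0.5)
(per-locus mean 2, the study-scale per-site 10⁻³) and ρ log-normal with
natural-scale mean 1.6: over 200 datasets simulated under the null and
tested against 500-replicate null ensembles, the rejection rate at
α = 0.05 falls inside the binomial 99% interval. The 200 repetitions
share 8 independently simulated null ensembles (25 each) — fully
independent ensembles would be ~15× the compute for the same marginal
Bernoulli(α) property, at the price of mild within-ensemble correlation.
Against data from a strongly growing population (g = 20 in 1/(4N) units)
the median fit p-value collapses (observed ≈ 0.002 vs ≈ 0.5 under the
null), an excess-of-rare-alleles signal of exactly the kind that flags
expanding populations.

## Monophyly analytics

Trees are polarized by the outgroup without physical rerooting: each edge
bipartition contributes its outgroup-free side as a rooted clade, which
handles rooted and unrooted input identically. A group is monophyletic
iff its exact tip set is such a clade — a polytomy with extra tips fails;
singletons pass trivially. Posterior support is the fraction of sampled
trees containing the clade, pooled across runs after discarding the first
10% of each run (configurable). Classification uses the 95%/5%
convention: support above 0.95 counts as monophyly, below 0.05 as
paraphyly, anything else — including a support of 0.913 — is ambiguous.
Reciprocal monophyly requires both disjoint groups to be clades in the
same tree, so it can never exceed either marginal support (asserted at
run time).

The strict-majority consensus keeps exactly the clades with frequency
> 0.5 (frequency exactly 0.5 is excluded); such clades are pairwise
nested-or-disjoint by a standard counting argument, so the consensus tree
is assembled by nesting them by size. Supports are attached to nodes.
Clade detection is tested against dendropy's independent MRCA machinery
on 1,000 random 20-tip topologies, and the lineage-sorting gradient —
reciprocal-monophyly frequency rising monotonically with split time — is
verified on recorded gene trees from the split simulator (Spearman
ρ > 0.99 across a six-point grid from 0.1 to 2.5 in 4N units).

## Pipeline

The `pansort` CLI exposes the stages individually and as a YAML-driven
pipeline (simulate → callsnps → stats → neutrality → monophyly). All
protocol thresholds (depth 8, MAF 0.15, NQS 20/15, 1000 null replicates,
10% burn-in, 95%/5% support) are centralized defaults and overridable.
Runs write a manifest with the seed, parameters and SHA-256 checksums of
every output; identical configs reproduce identical bytes.

## Problem sizes used in validation

The bundled experiments run at sizes chosen to keep the full validation
suite in the minutes range on a single core: 10,000 replicates for
closed-form Monte-Carlo checks, 5,000–6,000 for estimator-bias and
oracle-comparison checks, 14 × 10 kb regions (~134,000 callable sites)
for the false-positive screen, 6 × 10 kb regions (~500 evaluable planted
sites) for the recovery screen, 500-replicate null ensembles × 200
repetitions for calibration, and 400 replicates per split-time grid
point. Monte-Carlo assertions use 3×SE tolerances computed from the runs
themselves.

## Known limitations

- The split model has no migration, admixture, selection or gene
  conversion, and records gene trees only in its recombination-free form.
- The read model omits insertions, chimeras and position-dependent
  quality decay; caller performance on real instrument data is not
  established here.
- Fu & Li's D* implements the corrected variance constants only; the
  uncorrected 1993 variant is not offered.
- The neutrality test assumes all loci share one sample size per
  population when pooling (as the study design does); heterogeneous n
  across loci is supported per locus but untested at scale.
- Growth is exponential and non-negative; bottlenecks and declines are
  out of scope.
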