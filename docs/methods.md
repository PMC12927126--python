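# Methods

## The mapping model

The analysis assumes a single fully penetrant recessive mutation in a selfed
M2 family: an M1 plant heterozygous at the causal locus (and at every other
EMS-induced SNP it carries) is self-pollinated, kernels segregate 1:2:1 at
the causal locus, and the mutant phenotype marks exactly the homozygous
mutant class. Two pools are formed by phenotype — a wild-type pool (WP) and
a mutant pool (MP) — and sequenced.

At the causal marker the expected alternative-allele frequency is 1 in the
MP and 1/3 in the WP (non-mutant kernels are 1/3 homozygous wild-type, 2/3
heterozygous, so the expected allele dosage is (2/3 · 1)/2). At a marker a
recombination fraction *r* away, the expectations follow from enumerating
the four gamete classes of the coupling-phase double heterozygote
conditioned on kernel phenotype; in the MP this reduces to 1 − *r*. These
expectations are implemented in `expected_pool_allele_frequency` and used
both by the simulator and as the test oracle.

Scoring and localization:

* `SNP-index = AD_alt / (AD_ref + AD_alt)` per pool; markers with total
  depth below `min_depth` (default 5) in either pool are excluded and
  counted. The statistic uses allele depths only; genotype calls are parsed
  but ignored.
* `SNP-index.DIV = |idx_WP − theo_WP| + |idx_MP − theo_MP|` with
  theoretical values 1/3 and 1 (both configurable for other inheritance
  scenarios). Markers pass the filter iff DIV is **strictly** below the
  threshold (default 1/3).
* The candidate chromosome maximizes the count of filtered markers; ties
  break by natural chromosome order.
* The peak is the argmax of a tricube-kernel (Nadaraya–Watson) smooth of
  SNP-index.MP over the filtered markers of the candidate chromosome. The
  smoothing method is a design choice — any local averager would do — and
  the bandwidth (default 2 Mb) is exposed. Smoothing SNP-index.MP rather
  than DIV keeps the close-up on the quantity that is monotone in linkage
  distance (1 − r); the genome-wide view still plots DIV.
* The candidate interval is reported as the span of filtered markers within
  one bandwidth of the peak; no formal confidence procedure is attached to
  it.
* Ranked candidates are filtered markers with `SNP-index.MP ≥ 1 −
  homozygosity_tolerance` (default tolerance 0, i.e. fully homozygous in
  the MP) and a MODERATE or HIGH predicted impact, ordered by distance to
  the peak, HIGH before MODERATE on ties. With finite depth, a single
  miscalled read removes a true causal marker under tolerance 0; the
  tolerance exists for that case and stays 0 by default so the default
  behaviour matches the strict homozygosity criterion. When several
  candidates survive (e.g. two homozygous coding mutations in one linkage
  block), all are reported — disambiguation is experimental work (allelism
  tests), not something the statistic can do.

## The synthetic-data generator

`simulate_dataset` draws, in order: a random reference genome (default ten
20-Mb chromosomes at GC 0.47, the approximate maize base composition); a
causal gene containing the requested mutation; EMS mutations; the pooled
kernels; and the read counts. All randomness flows from one
`numpy.random.Generator`, so a config plus seed reproduces files
byte-for-byte.

* **EMS spectrum.** Each of the 20,000 mutations is, with probability 0.98,
  a G→A or C→T transition at a random G/C site, otherwise a uniformly
  chosen other substitution at a random site. 0.98 reflects the strong
  alkylation bias of EMS.
* **Causal gene.** A 437-residue open reading frame is embedded in the
  reference around the causal position. The requested consequence is
  engineered by pinning one codon: missense `c.464C>T` (CCG→CTG, p.P155L),
  stop-gained `c.1231C>T` (CAG→TAG, p.Q411*), start-lost `c.3G>A` (p.M1?),
  or synonymous `c.465C>T` (GGC→GGT). All four are themselves EMS-type
  changes. Two small two-exon decoy genes per chromosome (alternating
  strands) give background markers realistic annotations.
* **Linkage.** Physical distance to the causal locus is converted to a
  recombination fraction with the Haldane map, r = ½(1 − e^(−2d/L)) with L
  the bp-per-Morgan constant. The default 150 kb/cM makes each 20-Mb toy
  chromosome span ~133 cM — the genetic length of a real maize chromosome
  on a 10×-scaled-down physical map — so filtered markers concentrate
  within a few Mb of the causal locus rather than covering the chromosome.
  Every EMS SNP arose in the single mutagenized pollen grain, so background
  SNPs on the causal chromosome are simulated in coupling phase with the
  causal allele; transmission to each pooled gamete is drawn per marker
  (marginal frequencies are exact; marker–marker correlation along a gamete
  is not modelled and is irrelevant to the per-marker statistic).
* **M1 state.** Each background SNP is heterozygous in the M1 (segregating;
  expected pooled frequency 1/2 when unlinked) except a configurable
  fraction emitted as fixed homozygous (frequency 1 in both pools). The
  fraction is not known for real M1 plants, so it is a parameter; the
  default 0.1 exercises the DIV filter on both marker classes.
* **Sequencing.** Per-site pool depth is Poisson with mean 30 (the standard
  shotgun-coverage model; only mean depths are specified by the design),
  and each read reports the wrong allele with probability 0.001.

What the generator does **not** emulate: read-level artefacts (mapping
bias, duplicates, indels, multi-allelic sites), depth heterogeneity beyond
Poisson, residual heterozygosity of the inbred background, and chromosome-
scale crossover interference. Passing tests therefore demonstrate that the
statistic and its implementation behave as designed under the stated
generative model, not that any particular real dataset will yield a single
clean peak.

## Numerical and design choices

* The DIV filter uses a strict `<` at 1/3, matching the stated rule; the
  boundary case (an unlinked marker landing exactly on DIV = 1/3) fails the
  filter.
* Zero-depth markers have an undefined SNP-index; they are excluded and
  counted, never scored as 0 or 1.
* The yield estimator reports the raw product and its floor (a 1e-9 epsilon
  guards against float round-off in the product); with 100 ears, 3.3
  seeds/ear, 40% survival, ½ pollination success and a 20% mutant ratio
  this gives 13.2 → 13.
* Effect classes are limited to missense / stop-gained / start-lost /
  synonymous / intronic / intergenic with the SnpEff impact convention
  (HIGH, HIGH, MODERATE→missense, LOW, MODIFIER, MODIFIER). Splice-site
  disruption is not modelled; loss of the terminal stop codon is reported
  as a coding change (missense) since the vocabulary has no stop-lost
  class. Only the first entry of a SnpEff `ANN` field is consumed (SnpEff
  orders by severity).
* Standard nuclear genetic code throughout; one-letter amino-acid codes in
  `p.` notation; synonymous changes print `p.X123=`.
* Coordinates are 1-based fully closed everywhere (VCF/GFF3 convention).

## Problem sizes used in tests

The unit-test fixture genome is two 400-kb chromosomes with 400 SNPs and a
proportionally scaled 3 kb/cM map, which preserves the genetic-length
regime of the default configuration while keeping each test fast. The
end-to-end recovery checks run twenty replicates of the full default
configuration (ten 20-Mb chromosomes, 20,000 SNPs) with seeds 0–19 and
require the candidate chromosome in ≥95% of replicates, the peak within
2 Mb of the causal position in ≥90%, the causal mutation in the ranked list
in ≥90%, and a median background DIV above 1/3 in every replicate.

## Known limitations

* The theoretical WP index of 1/3 assumes phenotype-perfect pooling; seed
  misclassification would shift it and is not modelled.
* The annotator validates toy gene models only (ATG start, in-frame stop,
  non-overlapping CDS); it is not a substitute for annotating real genomes
  against a curated gene set.
* Real-cohort SNP tallies depend on the sequencing run, aligner and caller;
  the package starts from variant tables and makes no attempt to reproduce
  upstream counts.
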