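# Methods

## The analysis model

The unit of analysis is the 1-kb genomic bin.  Each chromosome is tiled
left to right; the final bin per chromosome may be shorter and is kept and
analysed like any other bin (signals are per-bin weighted sums, not
densities, so no width correction is applied — a documented limitation for
the rare trailing bin).  Coordinates are 0-based half-open throughout;
printed region boundaries that are multiples of 1000 are interpreted as
bin-aligned half-open intervals.  The bin count is always reported from the
chromosome sizes actually supplied, never assumed.

**Multi-mapper weighting.**  A read with *k* genomic placements contributes
weight 1/*k* at each placement, so the total weighted signal of a library
equals its distinct-read count (tested to 1e-9).  For SAM input the
multiplicity comes from the NH tag, falling back to the count of records
sharing the read name; for BED6 input an optional seventh column carries
it.  Each placement is assigned to the single bin containing its midpoint
(not overlap-proportional): the simplest rule consistent with whole-bin
signal, and the same rule resolves exon/intron classification of junction
reads.  Duplicate reads are kept; no deduplication step is modelled.

**Normalisation.**  Tracks are scaled to reads per million of total
weighted reads.  ChIP input is carried as its own track and never
subtracted: the analysis compares genotype ratios of like antibodies, and
the per-assay fold change (mutant + ε)/(wild type + ε) cancels
antibody-specific efficiency.  The pseudocount ε defaults to the
per-million equivalent of one read in the smaller library of the pair: it
makes the ratio defined on empty bins (0/0 → 1) and shrinks fold changes at
low coverage toward 1.  A consequence worth knowing: when a mutant gains a
lot of signal at desilenced regions, per-million rescaling deflates all its
bins, so recovered fold changes sit a few percent below the generative
fold (visible in the synthetic studies).

**Region calling.**  GRTS: fold change ≥ cutoff in all three Pol II
antibody pairs (8WG16, Ser2-P, Ser5-P), tiers 3/2/1.5 nest by
construction.  An optional minimum-signal filter (default: mutant signal ≥
the per-million equivalent of 5 reads in every assay) suppresses 1-vs-0
read artefacts at ~4× coverage; calling with the filter off is a one-flag
change for transparency.  GRH: H3K9me3 reduction ≥ cutoff,
(wt + ε)/(mut + ε), in every supplied mutant, with optional intersection
against a published reference region set (the retained fraction is
reported).  Pol II-decreased bins are emitted by the same machinery with
the ratio inverted, for completeness only.  A multi-bin region counts as
desilenced when its maximal bin fold change reaches the cutoff.

**Clustering and the binomial null.**  Loci are merged when connected by
chains of gaps ≤ 5 kb (merge is idempotent and verified against a
brute-force transitive-closure oracle).  The proximity statistic is the
fraction of query loci whose distance to the nearest reference locus is ≤
a cutoff, where overlap or abutment counts as distance 0.  The null places
each 1-kb query uniformly among all valid start positions; the hit
probability is computed exactly: a query of width *w* starting at *s* is
within distance *d* of reference [a, b) iff s ∈ [a − w − d, b + d], and
these start-ranges are clipped, merged and summed per chromosome.  The
rejection threshold is the smallest k/n with upper binomial tail ≤ α
(default α = 1e-12 for the proximity curve, cutoffs 0–50 kb in 1-kb
steps).  Both genome-wide and chromosome-restricted placement universes
are available, since silencing targets are autosome-biased.  "Adjacent" is
reported as distance ≤ 1 kb and is configurable.

**Monte Carlo enrichment.**  Cluster-annotation enrichment re-places every
cluster, length preserved, uniformly at random (chromosomes weighted by
capacity; non-overlapping by rejection), and recounts clusters overlapping
≥ 1 feature — partial overlaps count, matching "full or partial" element
annotation.  Fraction statistics draw same-size bin sets without
replacement from the analyzable bins.  p-values use the add-one estimator,
so they are bounded below by 1/(N+1) and never zero; the default
N = 10,000 resolves p = 1e-4.  The generator seed is recorded in every
result, and identical seeds reproduce identical null samples.

**RNA metrics.**  Reads are classified exonic/intronic/other by midpoint
against transcript models (GFF3 via gffutils; introns are derived as
inter-exon gaps; exon wins where overlapping genes disagree).  The
pre-mRNA enrichment factor is the ratio of [intron/exon] tag ratios,
pre-mRNA-seq over mRNA-seq; reads outside any model are excluded from that
ratio.  Weighted counting is the default, unique-only a flag.  Strand bias
is the weighted fraction of in-region reads on a reference strand.

**Small RNA.**  The signature is the weighted length (18–30 nt) ×
5′-nucleotide matrix of reads with midpoint in a region set.  The 5′ base
is the strand-corrected first nucleotide of the read; BED input without
sequence yields base N, which is excluded from the matrix and reported as
unassigned weight.  Per-region genotype comparisons use summed per-region
per-million signal with the same ε rule as region calling.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
not sequence-level realism (no motifs, no GC bias, no RdRP mechanics).
Per-bin read counts are Poisson with genotype/assay-specific means;
planted regions multiply the background mean by the configured folds.
Default conditions mirror the real study at desk scale:

| parameter | default | rationale |
|---|---|---|
| genome | 5 × 1 Mb autosomes + 1 Mb chrX | six chromosomes, X carries no planted targets (a planted property mirroring the observed autosome restriction, not a model of its cause) |
| background | 20 reads/bin | the real libraries average ~2.1 M reads over ~100 k bins ≈ 21/bin (~4× coverage) |
| Pol II fold (mutant, GRTS) | 6 | observed median folds are 5.3–9.0 |
| H3K9me3 fold (wild type, GRH) | 6 | observed median reduction 6.1 |
| pre-mRNA fold | 50 | desilencing spans the 10–200-fold range |
| mRNA fold | 5; 70 % of GRTS regions desilenced | mRNA response is partial across targets |
| GRTS regions | 16 clusters of 3 bins; LTR-like elements planted in 10/16 | the printed top-16 cluster scale |
| GRH regions | 22 bins, 8 shared with GRTS | overlapping-and-distinct response classes |
| siRNA | targets 10× background; lengths {20:0.10, 21:0.35, 22:0.45, 23:0.10}; 5′ G 0.75; antisense | 22G signature |
| repeats | 4 identical 2-kb blocks | every read with midpoint in a block is emitted at all copies with weight 1/4 |

Gene structure is one two-exon gene per full bin (exons [0, 600) and
[900, 1000), intron [600, 900)), alternating strands, forced sense (+) in
planted regions.  Intronic placement probabilities (0.2 pre-mRNA, 0.01
mRNA) therefore translate directly into tag percentages, giving a
closed-form expected enrichment factor
(0.2/0.8)/(0.01/0.99) ≈ 24.75 used as the test oracle.

Every library's read stream is seeded by spawning from the single config
seed, so outputs are byte-identical across runs and generating a subset of
libraries reproduces exactly the content of a full run.  An analytic
`expected_bin_mean` exposes the Poisson mean the generator used for any
bin/library, which is the oracle for mean-recovery tests.

What passing tests on this generator do **not** show about real data:
mappability structure beyond idealised equal-copy repeats, fragment-length
and GC effects, antibody cross-reactivity, replicate variance, and partial
or heterogeneous fold effects within a region.  The generator demonstrates
that the pipeline recovers what it models, with calibrated nulls — not
that real libraries satisfy the model.

## Numerical and design choices

- Fold-change tiers use the highest of {3, 2, 1.5} met by the minimum
  per-assay fold, so tier-3 calls are a subset of tier-2, of tier-1.5.
- Distance convention: overlap or abutment is distance 0 everywhere
  (merging, proximity, the binomial span arithmetic); the exact span count
  for a reference [a, b), query width w, cutoff 0 is (b − a) + w + 1
  starts, verified against full enumeration.
- Empty inputs: empty bins are fold-neutral (ratio 1); an empty call set
  summarises to explicit zeros; an empty reference set in proximity
  queries warns and returns 0; empty anchor sets and empty mutant sets are
  errors.
- The Monte Carlo placement null preserves cluster lengths and is uniform
  over capacity-weighted chromosomes; a per-chromosome-restricted variant
  is exposed because the real randomisation scheme is underdetermined.
- Simulation scale in the shipped tests (0.4–1 Mb chromosomes for
  stage-level checks, the 6 Mb default genome for end-to-end recovery) was
  chosen to keep every suite fast while leaving ≥ 3σ separation between
  planted effects and Poisson noise; all thresholds appearing in outputs
  are echoed from configuration.

## Known limitations

- No per-bin significance model: calling is threshold-based, as the
  analysis it implements; replicate variance modelling is out of scope.
- Spliced (CIGAR-split) alignments are handled by midpoint, not split.
- No input-track correction of ChIP signal; genotype ratios of like
  antibodies are the comparison unit.
- The binned fold change conflates within-bin heterogeneity; a region
  desilenced in only part of a bin is diluted.
- Liftover, assembly gaps and GC-matched nulls are out of scope.
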