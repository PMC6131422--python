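# Methods

## The design being modelled

A quantitative trait (caffeine content, % dry-matter basis) is scored in a
population of 232 allotetraploid individuals. The 18 lowest- and 18
highest-scoring individuals form two DNA bulks; each bulk's pooled DNA is
short-read sequenced (mean depth 28× for the low bulk, 40× for the high
bulk; read length 147 bp; mean base quality Phred 37; genome GC ≈ 36%).
At a biallelic site, an individual carries 0–4 copies of the alternate
allele, so a bulk's pooled allele frequency is the mean dosage of its
18 × 4 = 72 chromosomes. Trait-linked sites show a between-bulk frequency
differential; the pipeline's job is to find them and narrow them to
candidate genes in the caffeine biosynthesis network.

## Synthetic study generator (`synth`)

**Reference and gene models.** Contigs are i.i.d. base draws at the target
GC (default 0.36). Each contig hosts two-exon protein-coding genes,
alternating strand, CDS length a multiple of 3, codons drawn at the target
GC with stop codons rejected — so every generated CDS translates cleanly,
which the effect-annotation stage relies on.

**Trait model.** The trait is additive per allele dose with Gaussian noise:

    y_i = baseline + Σ_s effect_s · dosage_{i,s} + N(0, σ²)

Per-site dosages are Binomial(4, p) with p = 0.5 at causal sites and
p ~ U(0.1, 0.9) at neutral sites. Defaults: 2 causal sites of effect
0.08 %dmb per dose, noise SD 0.04, baseline 0.935. These were chosen by
order-statistic arithmetic: total trait SD ≈ √(2·0.08² + 0.04²) ≈ 0.12,
and the mean of an 18/232 tail of a near-normal distribution sits ≈ 1.88 SD
from the centre, so the bulk means land at 1.255 ± 0.225 ≈ 1.03 / 1.48 %dmb,
the calibration target. The two-site/large-effect choice (rather than many
small effects) makes the causal between-bulk frequency differential
typically exceed 0.5, the regime the recovery study conditions on.

**Pileups.** Site depth is Poisson around the bulk mean (only the averages
are specified by the design). Each read's allele is a Bernoulli draw from
the bulk's exact pooled dosage fraction; base quality is Normal(37, 3)
rounded and clipped to [2, 41]; a read is mis-called with probability
10^(−Q/10), substituting uniformly to the three other bases; strands are
balanced; broken-pair and nonspecific-mapping flags are set independently
at rate 0.02 each (free parameters; typical modern paired-end libraries).
The neighbourhood quality attached to each read is Normal(37, 1) — a
summary of the ±5 bp window the simulator does not model base-by-base.
Everything is replayable from one seed via spawned generators.

**What the generator does not emulate**: linkage between sites, alignment
artefacts (indels, soft-clips, reference bias), GC-dependent coverage,
overdispersed (non-Poisson) depth, and unequal individual representation
in the pool. Passing tests therefore certify the statistical logic of the
pipeline under idealised sampling, not robustness to mapping artefacts.

## Variant caller (`varcall`)

All threshold comparisons are inclusive. "Minimum of 4 reads or 20%" is
applied conjunctively (count ≥ 4 AND frequency ≥ 20%) — at the minimum
coverage of 20 the clauses coincide (4/20 = 20%), and above it the
frequency clause dominates; a `count_frequency_mode="or"` switch gives the
disjunctive reading. The strand-balance clause is evaluated per allele from
integer counts (min(forward, reverse)/count ≥ 0.20), which is exact at the
20% boundary where floating-point `1 − fraction` is not. Coverage bounds
use post-filter depth, since the read filters precede calling. Frequencies
snap to the nearest tetraploid dosage {0.25, 0.5, 0.75, 1.0}; ties (e.g.
0.375) round down — deterministic and conservative. Neighbourhood quality
is the mean Phred of the up-to-11 bases within radius 5 on the same read,
truncated at read ends (the SAM reader computes it this way; the simulator
supplies it directly).

## Between-bulk contrast (`contrast`)

The union of sites called in either bulk is re-genotyped in both bulks from
the filtered pileups, symmetrically (the direction of the seeding bulk does
not matter). The chi-square is Pearson's on the 2×k allele-count table
without continuity correction, zero-total columns dropped before computing
degrees of freedom; a table left with fewer than two alleles is reported as
(statistic 0, p 1). α defaults to 0.05 with no multiple-testing correction,
matching the emulated workflow; `statsmodels`-style correction can be
layered on the returned p-values by the caller if wanted.

The contrast rule is the ≥50%/≤50% predicate with one refinement: the two
frequencies must differ, excluding the degenerate 50/50-vs-50/50 case that
the literal text would admit. A site fixed in one bulk (100%) against a
71%/29% split in the other *fails* the literal rule; such sites are
reported with the flag false rather than silently promoted.

**Comparability floor.** A site called in one bulk but with fewer than half
the calling floor (< 10 reads) of filtered coverage in the other is flagged
incomparable and never significant. The full floor of 20 is a *discovery*
criterion; requiring it again for re-genotyping would discard ~7% of true
positives at 28× (Poisson depth dips) while a 10–19-read column still
yields a stable frequency and a decisive chi-square.

**Known limitation — null calibration.** The chi-square treats reads as the
sampling unit, but reads are drawn from a pool of only 72 chromosomes per
bulk. The between-bulk pool-composition variance (≈ 2·fpc/72 in frequency
units) is therefore missing from the test's null model, inflating the
statistic by a factor λ ≈ 1 + (2·fpc/72)/(1/d_low + 1/d_high) ≈ 1.4 at
28×/40× effective depth, and the empirical null significant fraction at
α = 0.05 to ≈ 0.10–0.12 rather than 0.05. This is inherent to testing
pooled read counts at these bulk sizes and depths — not an implementation
artefact (drawing both bulks' reads from the same pool restores ≈ 0.05) —
and the unit suite asserts the inflated rate against the λ-corrected
prediction. Practical consequence: raw chi-square p-values from BSA read
counts are anticonservative; downstream candidate lists should lean on the
frequency-differential rule and pathway evidence, as the workflow does.

## Effect annotation (`effects`)

Variants are mapped to transcript-relative coding offsets across multi-exon
CDS chains; for '−' genes the chain is walked in reverse genomic order and
alleles are reverse-complemented before codon substitution. Translation
uses the standard nuclear code (table 1), appropriate for plant nuclear
genes. SNPs only — a single-base change sits inside one codon, so no
boundary handling is needed; indels are out of scope. A variant overlapping
several gene models is annotated once per model, and the site counts as
nonsynonymous for selection if any annotation is; stop-gain/stop-loss
count as nonsynonymous for selection purposes. A stated reference allele
that disagrees with the reference sequence raises an error rather than
being repaired.

## Pathway narrowing (`pathways`)

The gene→pathway annotation is a TSV contract (`cds_id`, `pathway`,
`ec_number`, `enzyme_label`), emulating a functional-annotation export; the
tool that produces it is not executed here. Matching against the curated
caffeine-network table is case-insensitive, whitespace-trimmed and
"EC:"-prefix agnostic; malformed EC codes warn and are kept raw. The
packaged curated table encodes the caffeine biosynthesis network: 12 rows,
7 unique pathways, 10 unique enzymes, 8 substrates, 65 total sequences,
with duplication notes preserved (two purine-metabolism rows share
sequences; their unique-sequence resolution requires per-sequence
identifiers and is only computed when those are supplied). Candidates are
deduplicated per (CDS, position, allele).

## Reports (`io_formats`)

All file coordinates are 1-based inclusive (GFF3/VCF convention). The TAV
VCF (4.2) is written with a fixed header and INFO key order so reruns under
one seed are byte-identical; the funnel TSV lists one count per stage, and
the log is timestamp-free for the same reason. The pileup TSV dialect is
one row per read observation (contig, pos, base, phred, strand,
properly_paired, unique_mapping, neighbourhood_mean_quality); a SAM reader
derives identical records using proper-pair flags, MAPQ 0 / XA / SA as the
nonspecific signal, and read-local quality windows.

## Problem sizes in the test and acceptance runs

Unit and acceptance tests use one or two 20–50 kb contigs with 6–10 genes,
2 causal + 30–250 neutral sites, and the full 232/18+18/28×/40× sampling
design; the recovery study uses 20 seeds and the null study ≥ 400 scored
neutral contrasts. These sizes give stable statistics (binomial SEs of a
few percent) while a full run of the suite completes in well under a
minute.
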