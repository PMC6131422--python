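# tetrabsa

Pooled bulked-segregant SNP discovery for tetraploid crops.

In bulked segregant analysis (BSA-seq), DNA from individuals at the two
phenotypic extremes of a population is pooled into bulks and each bulk is
sequenced; alleles linked to the trait show a frequency differential between
the bulks. `tetrabsa` implements the full desk side of such a study for an
allotetraploid crop (the motivating case is caffeine content in arabica
coffee, measured in % dry-matter basis):

- **Per-bulk pooled variant calling** at ploidy 4 under a five-filter stack:
  coverage in [20, 1000]; broken pairs and nonspecific matches removed;
  allele accepted at count ≥ 4 *and* frequency ≥ 20%; central base quality
  ≥ 20 with neighbourhood (±5 bp) quality ≥ 15; and ≥ 20% of an allele's
  supporting reads on each strand. Called frequencies are snapped to the
  nearest tetraploid dosage (25/50/75/100%).
- **Between-bulk contrast**: each bulk is re-genotyped at the union of
  called sites, a Pearson chi-square (no continuity correction) is applied
  to the 2×k allele-count table, and a contrast rule asks for an allele at
  ≥ 50% in one bulk and ≤ 50% in the other.
- **Amino-acid-change classification**: strand-aware codon extraction
  against multi-exon CDS models and translation under the standard nuclear
  code; trait-associated variants (TAVs) must be nonsynonymous.
- **Curated pathway narrowing**: TAVs are joined with a gene→KEGG-pathway/EC
  table and intersected with a curated substrate–pathway–enzyme table of
  the caffeine biosynthesis network (packaged; 7 pathways, 10 enzymes,
  8 substrates, 65 sequences).
- **A synthetic study generator**: 232 tetraploid individuals, an additive
  dosage trait, 18-individual tail bulks, and pooled pileups at 28×/40× with
  Phred-37 qualities — so every stage is testable with known ground truth.

## Worked example

```
python examples/full_pipeline.py
```

prints (seed 7, one 20 kb contig, 2 causal + 40 neutral sites):

```
funnel (per-stage site counts):
  variants_low_bulk        32
  variants_high_bulk       34
  variants_between_bulks   37
  chi_square_significant   5
  contrast_rule_passing    4
  nonsynonymous_tav_sites  4
  cds_with_tav             4
  pathway_candidates       1
injected causal sites recovered as TAVs: 2/2
```

The funnel narrows monotonically from per-bulk calls to pathway candidates,
and both injected causal sites (true between-bulk frequency differential
≥ 0.5) survive every stage. The final VCF carries per-bulk counts and
frequencies, the chi-square verdicts, the amino-acid change and pathway
hits per record. The other scripts in `examples/` each demonstrate one
stage: `simulate_study.py` (bulk calibration: tail trait means ≈ 1.03 and
1.48 %dmb at 28×/40× depth), `call_variants.py`, `contrast_bulks.py`,
`amino_acid_changes.py` (Ala→Pro on '+', Arg→Ile via genomic C>A on '−'),
and `curated_pathways.py`.

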