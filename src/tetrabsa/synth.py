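"""Synthetic two-bulk study generator.

Emulates the study design the pipeline assumes: a population of tetraploid
individuals scored for a quantitative trait (caffeine content, % dry-matter
basis), two 18-individual bulks drawn from the phenotypic tails, and pooled
short-read pileups over the bulks at known variant sites. Every downstream
stage (calling, contrast, effect annotation, pathway narrowing) is testable
against the ground truth this module records.

The trait model is additive per allele dose with Gaussian noise: with the
default two causal sites of effect 0.08 %dmb per dose at population allele
frequency 0.5 and noise SD 0.04, the total trait SD is ~0.12, which places
the means of the 18-individual tails of a 232-individual population near
1.03 and 1.48 %dmb (mean of the extreme ~7.8% tail of a near-normal
distribution sits ~1.88 SD from the centre).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import CoordinateError, PlacementError, SizingError
from .models import GeneModel, IndividualGenotype, Reference, SiteObservation, TruthSite

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters; defaults reproduce the emulated design."""

    n_population: int = 232
    bulk_size: int = 18
    ploidy: int = 4
    n_contigs: int = 2
    contig_length: int = 50_000
    gc_fraction: float = 0.36
    coverage_low_bulk: float = 28.0
    coverage_high_bulk: float = 40.0
    read_length: int = 147
    phred_mean: float = 37.0
    phred_sd: float = 3.0
    seq_error_from_phred: bool = True
    n_causal_sites: int = 2
    n_neutral_sites: int = 200
    causal_effect_size: float = 0.08
    causal_allele_freq: float = 0.5
    # baseline + expected genetic value (2 sites x 2 doses x 0.08 = 0.32)
    # puts the population trait mean at 1.255 %dmb
    trait_baseline: float = 0.935
    trait_noise_sd: float = 0.04
    neutral_synonymous_fraction: float = 0.0
    neutral_intergenic_fraction: float = 0.0
    broken_pair_rate: float = 0.02
    nonspecific_rate: float = 0.02
    n_genes_per_contig: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bulk_size > self.n_population // 2:
            raise ValueError("bulk_size must be <= n_population / 2")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        for name in ("broken_pair_rate", "nonspecific_rate", "causal_allele_freq",
                     "neutral_synonymous_fraction", "neutral_intergenic_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


# ---------------------------------------------------------------------------
# reference + gene models


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def _draw_stopfree_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Codons drawn base-by-base at the target GC, rejecting stop codons."""
    out: list[str] = []
    while len(out) < n_codons:
        block = _draw_bases(rng, 3 * (n_codons - len(out) + 4), gc)
        for i in range(0, len(block) - 2, 3):
            codon = "".join(block[i : i + 3])
            if codon not in STOP_CODONS:
                out.append(codon)
                if len(out) == n_codons:
                    break
    return "".join(out)


def generate_reference(config: SimConfig, seed=None) -> Reference:
    """Build random contigs at the target GC plus two-exon CDS models on both strands.

    Every CDS chain has length divisible by 3 and translates without internal
    stop codons on its coding strand.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    for ci in range(config.n_contigs):
        contig = f"contig{ci + 1}"
        seq = _draw_bases(rng, config.contig_length, config.gc_fraction)
        stride = config.contig_length // max(config.n_genes_per_contig, 1)
        for gi in range(config.n_genes_per_contig):
            exon1 = 3 * int(rng.integers(40, 61))
            exon2 = 3 * int(rng.integers(40, 61))
            intron = int(rng.integers(80, 121))
            span = exon1 + intron + exon2
            if span + 200 > stride:
                raise SizingError(
                    f"{contig}: gene span {span} + margin exceeds stride {stride}; "
                    "increase contig_length or reduce n_genes_per_contig"
                )
            start = gi * stride + 100  # 1-based
            strand = "+" if (ci * config.n_genes_per_contig + gi) % 2 == 0 else "-"
            seg1 = (start, start + exon1 - 1)
            seg2 = (start + exon1 + intron, start + exon1 + intron + exon2 - 1)
            coding = _draw_stopfree_codons(rng, (exon1 + exon2) // 3, config.gc_fraction)
            genomic = coding if strand == "+" else _revcomp(coding)
            seq[seg1[0] - 1 : seg1[1]] = list(genomic[:exon1])
            seq[seg2[0] - 1 : seg2[1]] = list(genomic[exon1:])
            gene_id = f"gene_{contig}_{gi + 1:02d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    cds_id=f"{gene_id}.cds",
                    contig=contig,
                    strand=strand,
                    segments=(seg1, seg2),
                )
            )
        sequences[contig] = "".join(seq)
    return Reference(sequences=sequences, genes=genes)


def spliced_cds(reference: Reference, gene: GeneModel) -> str:
    """Coding-strand CDS sequence of a gene (reverse-complemented for '-')."""
    seq = reference.sequences[gene.contig]
    chain = "".join(seq[start - 1 : end] for start, end in gene.segments)
    return chain if gene.strand == "+" else _revcomp(chain)


def _cds_genomic_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of the CDS in coding order."""
    positions: list[int] = []
    for start, end in gene.segments:
        positions.extend(range(start, end + 1))
    if gene.strand == "-":
        positions.reverse()
    return positions


def _enumerate_coding_substitutions(reference: Reference) -> dict[str, list[tuple]]:
    """All single-base CDS substitutions, keyed by effect class.

    Each entry is (contig, genomic_pos, genomic_ref, genomic_alt).
    """
    out: dict[str, list[tuple]] = {"nonsynonymous": [], "synonymous": []}
    for gene in reference.genes:
        coding = spliced_cds(reference, gene)
        positions = _cds_genomic_positions(gene)
        for ci in range(len(coding) // 3):
            codon = coding[3 * ci : 3 * ci + 3]
            ref_aa = str(Seq(codon).translate())
            for j in range(3):
                for alt_base in "ACGT":
                    if alt_base == codon[j]:
                        continue
                    alt_codon = codon[:j] + alt_base + codon[j + 1 :]
                    alt_aa = str(Seq(alt_codon).translate())
                    gpos = positions[3 * ci + j]
                    gref = reference.base(gene.contig, gpos)
                    galt = alt_base if gene.strand == "+" else _revcomp(alt_base)
                    cls = "synonymous" if alt_aa == ref_aa else "nonsynonymous"
                    out[cls].append((gene.contig, gpos, gref, galt))
    return out


# ---------------------------------------------------------------------------
# genotypes + trait


def assign_genotypes_and_trait(
    config: SimConfig, reference: Reference, seed=None
) -> tuple[list[IndividualGenotype], list[TruthSite]]:
    """Place causal and neutral variant sites and draw per-individual dosages.

    Causal sites are always nonsynonymous; neutral sites default to
    nonsynonymous placement too, with optional synonymous/intergenic
    fractions. Dosages are Binomial(ploidy, p) per individual; the trait is
    baseline + sum(effect x causal dosage) + Gaussian noise.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    subs = _enumerate_coding_substitutions(reference)

    n_syn = int(round(config.n_neutral_sites * config.neutral_synonymous_fraction))
    n_inter = int(round(config.n_neutral_sites * config.neutral_intergenic_fraction))
    n_nonsyn_neutral = config.n_neutral_sites - n_syn - n_inter

    def _pick_distinct(pool: list[tuple], n: int, taken: set, label: str) -> list[tuple]:
        by_pos: dict[tuple, list[tuple]] = {}
        for entry in pool:
            key = (entry[0], entry[1])
            if key not in taken:
                by_pos.setdefault(key, []).append(entry)
        keys = sorted(by_pos)
        if len(keys) < n:
            raise PlacementError(
                f"requested {n} {label} sites but only {len(keys)} candidate positions remain"
            )
        chosen_keys = [keys[i] for i in rng.choice(len(keys), size=n, replace=False)]
        picked = []
        for key in sorted(chosen_keys):
            options = by_pos[key]
            picked.append(options[int(rng.integers(len(options)))])
            taken.add(key)
        return picked

    taken: set[tuple] = set()
    causal_entries = _pick_distinct(subs["nonsynonymous"], config.n_causal_sites, taken, "causal")
    neutral_entries = [
        (entry, "nonsynonymous")
        for entry in _pick_distinct(subs["nonsynonymous"], n_nonsyn_neutral, taken, "neutral nonsynonymous")
    ]
    if n_syn:
        neutral_entries += [
            (entry, "synonymous")
            for entry in _pick_distinct(subs["synonymous"], n_syn, taken, "neutral synonymous")
        ]
    if n_inter:
        gene_spans = [(g.contig, *g.span) for g in reference.genes]
        intergenic_pool = []
        for contig, seq in reference.sequences.items():
            inside = np.zeros(len(seq), dtype=bool)
            for gcontig, lo, hi in gene_spans:
                if gcontig == contig:
                    inside[lo - 1 : hi] = True
            for pos in np.flatnonzero(~inside) + 1:
                ref_base = seq[pos - 1]
                alts = [b for b in "ACGT" if b != ref_base]
                intergenic_pool.append((contig, int(pos), ref_base, alts[0]))
        neutral_entries += [
            (entry, "intergenic")
            for entry in _pick_distinct(intergenic_pool, n_inter, taken, "neutral intergenic")
        ]

    records: list[tuple] = [(e, True, "nonsynonymous") for e in causal_entries]
    records += [(e, False, placement) for e, placement in neutral_entries]
    records.sort(key=lambda r: (r[0][0], r[0][1]))

    truth: list[TruthSite] = []
    freqs: list[float] = []
    for idx, ((contig, pos, ref, alt), is_causal, placement) in enumerate(records):
        truth.append(
            TruthSite(
                site_id=f"s{idx:04d}",
                contig=contig,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                is_causal=is_causal,
                placement=placement,
            )
        )
        freqs.append(config.causal_allele_freq if is_causal else float(rng.uniform(0.1, 0.9)))

    n = config.n_population
    dosage_matrix = np.column_stack(
        [rng.binomial(config.ploidy, p, size=n) for p in freqs]
    ) if truth else np.zeros((n, 0), dtype=int)
    causal_idx = [i for i, site in enumerate(truth) if site.is_causal]
    genetic = dosage_matrix[:, causal_idx].sum(axis=1) * config.causal_effect_size
    traits = config.trait_baseline + genetic + rng.normal(0.0, config.trait_noise_sd, size=n)

    population = [
        IndividualGenotype(
            individual_id=i,
            dosages={site.site_id: int(dosage_matrix[i, j]) for j, site in enumerate(truth)},
            trait_value=float(traits[i]),
        )
        for i in range(n)
    ]
    return population, truth


def select_bulks(
    population: list[IndividualGenotype], bulk_size: int
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Phenotypic-tail bulks: the ``bulk_size`` smallest and largest trait values.

    Ties broken by ascending individual id (stable sort), so selection is
    deterministic even when traits are identical.
    """
    if len(population) < 2 * bulk_size:
        raise ValueError("population must contain at least 2 x bulk_size individuals")
    ordered = sorted(population, key=lambda g: (g.trait_value, g.individual_id))
    low = tuple(sorted(g.individual_id for g in ordered[:bulk_size]))
    high = tuple(sorted(g.individual_id for g in ordered[-bulk_size:]))
    return low, high


def pooled_alt_fraction(
    population: list[IndividualGenotype], bulk_ids, site_id: str, ploidy: int
) -> float:
    """Exact alternate-allele fraction of the bulk's pooled chromosomes."""
    by_id = {g.individual_id: g for g in population}
    total = sum(by_id[i].dosages[site_id] for i in bulk_ids)
    return total / (ploidy * len(bulk_ids))


def annotate_expected_freqs(
    truth: list[TruthSite],
    population: list[IndividualGenotype],
    low_ids,
    high_ids,
    ploidy: int,
) -> list[TruthSite]:
    """Fill per-bulk expected allele frequencies from the exact pooled dosages."""
    for site in truth:
        site.expected_freq_low_bulk = pooled_alt_fraction(population, low_ids, site.site_id, ploidy)
        site.expected_freq_high_bulk = pooled_alt_fraction(population, high_ids, site.site_id, ploidy)
    return truth


# ---------------------------------------------------------------------------
# pooled pileups


def simulate_bulk_pileup(
    bulk_ids,
    population: list[IndividualGenotype],
    truth: list[TruthSite],
    config: SimConfig,
    mean_coverage: float,
    seed=None,
    reference: Reference | None = None,
) -> dict[tuple[str, int], SiteObservation]:
    """Pooled pileup of one bulk at every truth site.

    Depth is Poisson around the bulk mean; each read's allele is a draw from
    the bulk's pooled allele pool; base qualities are normal around the mean
    Phred (clipped to [2, 41]); sequencing errors occur per read at
    10^(-Q/10) with uniform substitution; strands are balanced; broken-pair
    and nonspecific flags are set at the configured rates.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    out: dict[tuple[str, int], SiteObservation] = {}
    for site in truth:
        if reference is not None:
            seq = reference.sequences.get(site.contig)
            if seq is None or not 1 <= site.position <= len(seq):
                raise CoordinateError(f"site {site.site_id} at {site.contig}:{site.position} outside reference")
        p_alt = pooled_alt_fraction(population, bulk_ids, site.site_id, config.ploidy)
        depth = int(rng.poisson(mean_coverage))
        is_alt = rng.random(depth) < p_alt
        bases = np.where(is_alt, site.alt_allele, site.ref_allele).astype("U1")
        quals = np.clip(np.rint(rng.normal(config.phred_mean, config.phred_sd, depth)), 2, 41).astype(int)
        if config.seq_error_from_phred and depth:
            err = rng.random(depth) < 10.0 ** (-quals / 10.0)
            for i in np.flatnonzero(err):
                others = [b for b in "ACGT" if b != bases[i]]
                bases[i] = others[int(rng.integers(3))]
        obs = SiteObservation(
            contig=site.contig,
            position=site.position,
            ref_allele=site.ref_allele,
            bases=bases,
            quals=quals,
            forward=rng.random(depth) < 0.5,
            properly_paired=rng.random(depth) >= config.broken_pair_rate,
            unique_mapping=rng.random(depth) >= config.nonspecific_rate,
            neighbourhood_quality=np.round(rng.normal(config.phred_mean, 1.0, depth), 1),
        )
        out[(site.contig, site.position)] = obs
    return out


# ---------------------------------------------------------------------------
# gene -> pathway annotation table (Blast2GO-export-like contract)

_DECOY_ANNOTATIONS = [
    ("Flavonoid biosynthesis", "1.14.11.9", "hydroxylase"),
    ("Phenylpropanoid biosynthesis", "1.11.1.7", "peroxidase"),
    ("Glycolysis / Gluconeogenesis", "2.7.1.11", "6-phosphofructokinase"),
    ("Starch and sucrose metabolism", "3.2.1.21", "beta-glucosidase"),
    ("Carotenoid biosynthesis", "5.2.1.14", "isomerase"),
    ("Fatty acid biosynthesis", "2.3.1.85", "fatty-acid synthase"),
]


def generate_annotation_table(
    genes: list[GeneModel],
    seed=None,
    annotated_fraction: float = 0.8,
    curated_hit_fraction: float = 0.35,
    curated_pairs: list[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Gene -> KEGG pathway/EC table emulating a Blast2GO export.

    A configurable fraction of annotated genes receives a (pathway, EC) pair
    drawn from the curated caffeine set so that pathway narrowing has hits.
    """
    rng = _as_rng(seed)
    if curated_pairs is None:
        from .pathways import load_curated

        cur = load_curated()
        curated_pairs = list(
            cur[["pathway", "ec_number", "enzyme_label"]].drop_duplicates().itertuples(index=False, name=None)
        )
    rows = []
    for gene in genes:
        if rng.random() >= annotated_fraction:
            continue
        n_terms = 1 + int(rng.random() < 0.25)
        for _ in range(n_terms):
            pool = curated_pairs if rng.random() < curated_hit_fraction else _DECOY_ANNOTATIONS
            pathway, ec, label = pool[int(rng.integers(len(pool)))]
            rows.append({"cds_id": gene.cds_id, "pathway": pathway, "ec_number": ec, "enzyme_label": label})
    return pd.DataFrame(rows, columns=["cds_id", "pathway", "ec_number", "enzyme_label"]).drop_duplicates()


# ---------------------------------------------------------------------------
# whole-study convenience


@dataclass
class SimulatedStudy:
    config: SimConfig
    reference: Reference
    population: list[IndividualGenotype]
    truth: list[TruthSite]
    low_bulk_ids: tuple[int, ...]
    high_bulk_ids: tuple[int, ...]
    pileup_low: dict[tuple[str, int], SiteObservation]
    pileup_high: dict[tuple[str, int], SiteObservation]
    annotation: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def truth_by_key(self) -> dict[tuple[str, int], TruthSite]:
        return {(t.contig, t.position): t for t in self.truth}


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a complete two-bulk study from one seed (fully replayable)."""
    ss = np.random.SeedSequence(config.seed)
    rng_ref, rng_geno, rng_low, rng_high, rng_annot = (np.random.default_rng(c) for c in ss.spawn(5))
    reference = generate_reference(config, seed=rng_ref)
    population, truth = assign_genotypes_and_trait(config, reference, seed=rng_geno)
    low_ids, high_ids = select_bulks(population, config.bulk_size)
    annotate_expected_freqs(truth, population, low_ids, high_ids, config.ploidy)
    pileup_low = simulate_bulk_pileup(
        low_ids, population, truth, config, config.coverage_low_bulk, seed=rng_low, reference=reference
    )
    pileup_high = simulate_bulk_pileup(
        high_ids, population, truth, config, config.coverage_high_bulk, seed=rng_high, reference=reference
    )
    annotation = generate_annotation_table(reference.genes, seed=rng_annot)
    return SimulatedStudy(
        config=config,
        reference=reference,
        population=population,
        truth=truth,
        low_bulk_ids=low_ids,
        high_bulk_ids=high_ids,
        pileup_low=pileup_low,
        pileup_high=pileup_high,
        annotation=annotation,
    )
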