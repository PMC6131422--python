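"""File formats and the end-to-end pipeline driver.

Readers/writers for reference FASTA, gene-model GFF3, the per-read pileup
TSV dialect, an optional SAM ingester, and a deterministic VCF 4.2 writer.
``run_pipeline`` wires the stages together (call -> contrast -> effects ->
pathways) and emits a report bundle: a TAV VCF, a funnel TSV echoing the
staged count reduction, and a plain-text log. All emitted coordinates are
1-based inclusive, and outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from . import contrast as contrast_mod
from . import effects as effects_mod
from . import pathways as pathways_mod
from . import synth as synth_mod
from . import varcall as varcall_mod
from .errors import ConfigurationError, ModelIntegrityError
from .models import GeneModel, Reference, SiteObservation

logger = logging.getLogger("tetrabsa")

PILEUP_COLUMNS = [
    "contig",
    "pos",
    "base",
    "phred",
    "strand",
    "properly_paired",
    "unique_mapping",
    "neighbourhood_mean_quality",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Reference:
    """Read reference contigs; lowercase (masked) bases are uppercased with the
    mask retained as a per-contig boolean array."""
    sequences: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        raw = str(record.seq)
        mask = np.array([c.islower() for c in raw], dtype=bool)
        sequences[record.id] = raw.upper()
        if mask.any():
            masks[record.id] = mask
    return Reference(sequences=sequences, genes=[], masks=masks)


def write_fasta(reference: Reference, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference.sequences):
            fh.write(f">{name}\n")
            seq = reference.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: list[GeneModel], path) -> None:
    """Emit gene/mRNA/CDS features, 1-based inclusive, phase 0 chains."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(genes, key=lambda g: (g.contig, g.span[0])):
            lo, hi = gene.span
            fh.write(
                f"{gene.contig}\ttetrabsa\tgene\t{lo}\t{hi}\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            mrna_id = f"{gene.gene_id}.mrna"
            fh.write(
                f"{gene.contig}\ttetrabsa\tmRNA\t{lo}\t{hi}\t.\t{gene.strand}\t.\t"
                f"ID={mrna_id};Parent={gene.gene_id}\n"
            )
            segments = gene.segments if gene.strand == "+" else tuple(reversed(gene.segments))
            consumed = 0
            rows = []
            for start, end in segments:
                phase = (3 - consumed % 3) % 3
                consumed += end - start + 1
                rows.append((start, end, phase))
            for start, end, phase in sorted(rows):
                fh.write(
                    f"{gene.contig}\ttetrabsa\tCDS\t{start}\t{end}\t.\t{gene.strand}\t{phase}\t"
                    f"ID={gene.cds_id};Parent={mrna_id}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Read CDS chains grouped by parent transcript via gffutils."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    chains: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        if cds.strand not in ("+", "-"):
            raise ModelIntegrityError(f"CDS {cds.id}: missing strand")
        if cds.frame is None or cds.frame == ".":
            raise ModelIntegrityError(f"CDS {cds.id}: missing phase")
        parents = cds.attributes.get("Parent", [cds.id])
        key = parents[0]
        entry = chains.setdefault(
            key, {"cds_id": cds.id, "contig": cds.seqid, "strand": cds.strand, "segments": []}
        )
        entry["segments"].append((cds.start, cds.end))
    genes: list[GeneModel] = []
    for mrna_id, entry in sorted(chains.items()):
        gene_id = mrna_id[:-5] if mrna_id.endswith(".mrna") else mrna_id
        genes.append(
            GeneModel(
                gene_id=gene_id,
                cds_id=entry["cds_id"],
                contig=entry["contig"],
                strand=entry["strand"],
                segments=tuple(sorted(entry["segments"])),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# pileup TSV dialect (one row per read observation)


def write_pileup_tsv(pileup: dict[tuple[str, int], SiteObservation], path) -> None:
    rows = []
    for key in sorted(pileup):
        obs = pileup[key]
        for i in range(obs.depth):
            rows.append(
                (
                    obs.contig,
                    obs.position,
                    str(obs.bases[i]),
                    int(obs.quals[i]),
                    "+" if obs.forward[i] else "-",
                    int(obs.properly_paired[i]),
                    int(obs.unique_mapping[i]),
                    f"{float(obs.neighbourhood_quality[i]):.1f}",
                )
            )
    frame = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path, reference: Reference) -> dict[tuple[str, int], SiteObservation]:
    frame = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = set(PILEUP_COLUMNS) - set(frame.columns)
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"pileup TSV missing columns: {sorted(missing)}")
    out: dict[tuple[str, int], SiteObservation] = {}
    for (contig, pos), group in frame.groupby(["contig", "pos"], sort=True):
        out[(contig, int(pos))] = SiteObservation(
            contig=contig,
            position=int(pos),
            ref_allele=reference.base(contig, int(pos)),
            bases=group["base"].to_numpy(dtype="U1"),
            quals=group["phred"].to_numpy(dtype=int),
            forward=(group["strand"] == "+").to_numpy(),
            properly_paired=group["properly_paired"].to_numpy(dtype=bool),
            unique_mapping=group["unique_mapping"].to_numpy(dtype=bool),
            neighbourhood_quality=group["neighbourhood_mean_quality"].to_numpy(dtype=float),
        )
    return out


def read_sam_pileup(
    path, reference: Reference, positions=None, neighbourhood_radius: int = 5
) -> dict[tuple[str, int], SiteObservation]:
    """Derive pileup records from a SAM file.

    Neighbourhood quality is the mean Phred of the bases within the radius
    on the same read (read ends truncate the window); broken pair = paired
    but not properly paired; nonspecific = mapping quality 0 or an XA/SA
    multi-mapping tag.
    """
    import pysam

    wanted = set(positions) if positions is not None else None
    acc: dict[tuple[str, int], dict[str, list]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.query_sequence is None:
                continue
            quals = read.query_qualities
            proper = not (read.is_paired and not read.is_proper_pair)
            unique = read.mapping_quality > 0 and not (read.has_tag("XA") or read.has_tag("SA"))
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                key = (read.reference_name, rpos + 1)
                if wanted is not None and key not in wanted:
                    continue
                lo = max(0, qpos - neighbourhood_radius)
                hi = min(len(quals), qpos + neighbourhood_radius + 1)
                entry = acc.setdefault(
                    key,
                    {"bases": [], "quals": [], "forward": [], "paired": [], "unique": [], "nq": []},
                )
                entry["bases"].append(read.query_sequence[qpos].upper())
                entry["quals"].append(int(quals[qpos]))
                entry["forward"].append(not read.is_reverse)
                entry["paired"].append(proper)
                entry["unique"].append(unique)
                entry["nq"].append(float(np.mean(quals[lo:hi])))
    out: dict[tuple[str, int], SiteObservation] = {}
    for key in sorted(acc):
        contig, pos = key
        entry = acc[key]
        out[key] = SiteObservation(
            contig=contig,
            position=pos,
            ref_allele=reference.base(contig, pos),
            bases=np.array(entry["bases"], dtype="U1"),
            quals=np.array(entry["quals"], dtype=int),
            forward=np.array(entry["forward"], dtype=bool),
            properly_paired=np.array(entry["paired"], dtype=bool),
            unique_mapping=np.array(entry["unique"], dtype=bool),
            neighbourhood_quality=np.array(entry["nq"], dtype=float),
        )
    return out


# ---------------------------------------------------------------------------
# VCF writer


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_vcf(tavs, reference: Reference, path, candidates: pd.DataFrame | None = None) -> None:
    """Write the final TAV set as VCF 4.2 with deterministic field order.

    INFO carries per-bulk allele counts and frequencies (low then high), the
    chi-square verdicts, the amino-acid change, and any curated pathway hits.
    """
    pathway_hits: dict[tuple, list[str]] = {}
    if candidates is not None and len(candidates):
        for row in candidates.itertuples(index=False):
            key = (row.contig, int(row.position), row.allele)
            pathway_hits.setdefault(key, []).append(
                f"{row.pathway.replace(' ', '_')}:{row.ec_number}"
            )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tetrabsa\n")
        for name in sorted(reference.sequences):
            fh.write(f"##contig=<ID={name},length={len(reference.sequences[name])}>\n")
        for line in (
            '##INFO=<ID=LC,Number=R,Type=Integer,Description="Low-bulk allele counts">',
            '##INFO=<ID=HC,Number=R,Type=Integer,Description="High-bulk allele counts">',
            '##INFO=<ID=LF,Number=R,Type=Float,Description="Low-bulk allele frequencies">',
            '##INFO=<ID=HF,Number=R,Type=Float,Description="High-bulk allele frequencies">',
            '##INFO=<ID=CHI2,Number=1,Type=Float,Description="Pearson chi-square statistic">',
            '##INFO=<ID=PVAL,Number=1,Type=Float,Description="Chi-square p-value">',
            '##INFO=<ID=DF,Number=1,Type=Integer,Description="Degrees of freedom">',
            '##INFO=<ID=RULE,Number=0,Type=Flag,Description="Allele-frequency contrast rule passed">',
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">',
            '##INFO=<ID=CDS,Number=1,Type=String,Description="CDS id">',
            '##INFO=<ID=AAREF,Number=1,Type=String,Description="Reference amino acid">',
            '##INFO=<ID=AAALT,Number=1,Type=String,Description="Alternate amino acid">',
            '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Substitution class">',
            '##INFO=<ID=PATH,Number=.,Type=String,Description="Curated pathway:EC hits">',
        ):
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for t in tavs:
            bc = t.contrast
            # reorder so REF comes first, then this TAV's allele, then the rest
            order = [bc.alleles.index(bc.ref_allele), bc.alleles.index(t.allele)]
            order += [i for i in range(len(bc.alleles)) if i not in order]
            alts = [bc.alleles[i] for i in order[1:]]
            effect = next(
                (e for e in t.effects if e.classification in contrast_mod.NONSYNONYMOUS_CLASSES),
                t.effects[0],
            )
            info = [
                "LC=" + ",".join(str(int(bc.counts_low[i])) for i in order),
                "HC=" + ",".join(str(int(bc.counts_high[i])) for i in order),
                "LF=" + ",".join(_fmt(bc.freq_low[i]) for i in order),
                "HF=" + ",".join(_fmt(bc.freq_high[i]) for i in order),
                "CHI2=" + _fmt(bc.chi2_statistic),
                "PVAL=" + _fmt(bc.p_value),
                "DF=" + str(bc.degrees_of_freedom),
            ]
            if bc.passes_contrast_rule:
                info.append("RULE")
            info += [
                f"GENE={effect.gene_id}",
                f"CDS={effect.cds_id}",
                f"AAREF={effect.ref_aa}",
                f"AAALT={effect.alt_aa}",
                f"EFFECT={effect.classification}",
            ]
            hits = pathway_hits.get((bc.contig, bc.position, t.allele))
            if hits:
                info.append("PATH=" + ",".join(sorted(hits)))
            fh.write(
                f"{bc.contig}\t{bc.position}\ttav_{bc.contig}_{bc.position}_{t.allele}\t"
                f"{bc.ref_allele}\t{','.join(alts)}\t.\tPASS\t{';'.join(info)}\n"
            )


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class RunConfig:
    reference_fasta: Path
    gff3: Path
    pileup_low: Path
    pileup_high: Path
    annotation_tsv: Path
    output_dir: Path
    curated_tsv: Path | None = None
    caller: varcall_mod.CallerParams = field(default_factory=varcall_mod.CallerParams)
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")

    def validate_paths(self) -> None:
        for name in ("reference_fasta", "gff3", "pileup_low", "pileup_high", "annotation_tsv"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")


@dataclass
class PipelineResult:
    funnel: pd.DataFrame
    tavs: list
    candidates: pd.DataFrame
    contrasts: list
    vcf_path: Path
    funnel_path: Path
    log_path: Path


FUNNEL_STAGES = [
    "variants_low_bulk",
    "variants_high_bulk",
    "variants_between_bulks",
    "chi_square_significant",
    "contrast_rule_passing",
    "nonsynonymous_tav_sites",
    "cds_with_tav",
    "pathway_candidates",
]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute calling -> contrast -> effect annotation -> pathway narrowing.

    Emits ``tavs.vcf``, ``funnel.tsv`` and ``pipeline.log`` under the output
    directory; all three are byte-stable for a fixed config and inputs.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    reference = read_fasta(config.reference_fasta)
    reference.genes = read_gff3(config.gff3)
    log(f"reference: {len(reference.sequences)} contigs, {len(reference.genes)} gene models")

    pileup_low = read_pileup_tsv(config.pileup_low, reference)
    pileup_high = read_pileup_tsv(config.pileup_high, reference)
    log(f"pileups: {len(pileup_low)} low-bulk sites, {len(pileup_high)} high-bulk sites")

    calls_low = varcall_mod.call_bulk(pileup_low, reference, config.caller)
    calls_high = varcall_mod.call_bulk(pileup_high, reference, config.caller)

    contrasts = contrast_mod.union_sites(calls_low, calls_high, pileup_low, pileup_high, config.caller)
    contrast_mod.score_contrasts(contrasts, config.alpha)

    variants = []
    for bc in contrasts:
        for i, allele in enumerate(bc.alleles):
            if allele == bc.ref_allele or (bc.counts_low[i] == 0 and bc.counts_high[i] == 0):
                continue
            variants.append(
                effects_mod.Variant(
                    contig=bc.contig, position=bc.position, ref_allele=bc.ref_allele, alt_allele=allele
                )
            )
    effect_index = effects_mod.annotate_all(variants, reference)

    tavs = contrast_mod.select_tavs(contrasts, effect_index, config.alpha)

    annotation = pathways_mod.load_annotation_table(config.annotation_tsv)
    curated = pathways_mod.load_curated(config.curated_tsv)
    joined = pathways_mod.join_annotations(tavs, annotation)
    candidates = pathways_mod.filter_curated(joined, curated) if len(joined) else joined.head(0)

    sig_sites = {bc.key for bc in contrasts if bc.significant}
    rule_sites = {bc.key for bc in contrasts if bc.significant and bc.passes_contrast_rule}
    tav_sites = {t.key for t in tavs}
    counts = {
        "variants_low_bulk": len(calls_low),
        "variants_high_bulk": len(calls_high),
        "variants_between_bulks": len(contrasts),
        "chi_square_significant": len(sig_sites),
        "contrast_rule_passing": len(rule_sites),
        "nonsynonymous_tav_sites": len(tav_sites),
        "cds_with_tav": len({t.cds_id for t in tavs}),
        "pathway_candidates": len(candidates),
    }
    funnel = pd.DataFrame({"stage": FUNNEL_STAGES, "count": [counts[s] for s in FUNNEL_STAGES]})
    for stage in FUNNEL_STAGES:
        log(f"funnel {stage}: {counts[stage]}")

    vcf_path = outdir / "tavs.vcf"
    funnel_path = outdir / "funnel.tsv"
    log_path = outdir / "pipeline.log"
    write_vcf(tavs, reference, vcf_path, candidates)
    funnel.to_csv(funnel_path, sep="\t", index=False)
    log_path.write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        funnel=funnel,
        tavs=tavs,
        candidates=candidates,
        contrasts=contrasts,
        vcf_path=vcf_path,
        funnel_path=funnel_path,
        log_path=log_path,
    )


def simulate_to_files(sim_config: synth_mod.SimConfig, directory, alpha: float = 0.05) -> RunConfig:
    """Materialise a simulated study as the pipeline's file contract.

    Writes reference.fasta, genes.gff3, pileup_low.tsv, pileup_high.tsv,
    annotation.tsv and truth.tsv, and returns a ready RunConfig.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study = synth_mod.simulate_study(sim_config)
    write_fasta(study.reference, directory / "reference.fasta")
    write_gff3(study.reference.genes, directory / "genes.gff3")
    write_pileup_tsv(study.pileup_low, directory / "pileup_low.tsv")
    write_pileup_tsv(study.pileup_high, directory / "pileup_high.tsv")
    study.annotation.to_csv(directory / "annotation.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "site_id": t.site_id,
                "contig": t.contig,
                "position": t.position,
                "ref_allele": t.ref_allele,
                "alt_allele": t.alt_allele,
                "is_causal": int(t.is_causal),
                "placement": t.placement,
                "expected_freq_low_bulk": t.expected_freq_low_bulk,
                "expected_freq_high_bulk": t.expected_freq_high_bulk,
            }
            for t in study.truth
        ]
    ).to_csv(directory / "truth.tsv", sep="\t", index=False)
    return RunConfig(
        reference_fasta=directory / "reference.fasta",
        gff3=directory / "genes.gff3",
        pileup_low=directory / "pileup_low.tsv",
        pileup_high=directory / "pileup_high.tsv",
        annotation_tsv=directory / "annotation.tsv",
        output_dir=directory / "out",
        alpha=alpha,
        seed=sim_config.seed,
    )
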