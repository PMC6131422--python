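"""Strand-aware amino-acid-change classification against CDS gene models.

A variant inside a CDS chain is mapped to its transcript-relative coding
offset (multi-segment chains, both strands), the reference and alternate
codons are extracted from the coding strand (alleles reverse-complemented
for '-' genes), and both are translated under the standard nuclear genetic
code (translation table 1) to classify the substitution.

SNPs only: a single-base substitution always sits inside one codon, so
codon-boundary spanning cannot arise. A variant overlapping the CDS of
several gene models yields one annotation per model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .errors import ModelIntegrityError, ReferenceMismatchError
from .models import GeneModel, Reference
from .synth import _cds_genomic_positions, _revcomp, spliced_cds


@dataclass(frozen=True)
class Variant:
    contig: str
    position: int
    ref_allele: str
    alt_allele: str


@dataclass(frozen=True)
class EffectAnnotation:
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    classification: str
    gene_id: str | None = None
    cds_id: str | None = None
    codon_index: int | None = None
    position_in_codon: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


@dataclass(frozen=True)
class CdsHit:
    gene: GeneModel
    offset: int  # 0-based offset into the spliced coding sequence


def locate_in_cds(variant: Variant, gene_models: Sequence[GeneModel]) -> list[CdsHit]:
    """All CDS chains overlapping the variant with its coding offset in each.

    Returns an empty list for positions outside every CDS; use
    :func:`classify_location` to distinguish intergenic from genic-non-CDS.
    """
    hits: list[CdsHit] = []
    for gene in gene_models:
        if gene.contig != variant.contig or not gene.contains(variant.position):
            continue
        if gene.cds_length % 3 != 0:
            raise ModelIntegrityError(f"CDS chain of {gene.gene_id} has length {gene.cds_length}, not divisible by 3")
        offset = _cds_genomic_positions(gene).index(variant.position)
        hits.append(CdsHit(gene=gene, offset=offset))
    return hits


def classify_location(variant: Variant, gene_models: Sequence[GeneModel]) -> str:
    """'cds', 'non_cds_genic' (inside a gene span but outside CDS) or 'intergenic'."""
    in_span = False
    for gene in gene_models:
        if gene.contig != variant.contig:
            continue
        if gene.contains(variant.position):
            return "cds"
        if gene.in_span(variant.position):
            in_span = True
    return "non_cds_genic" if in_span else "intergenic"


def _classify(ref_aa: str, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "nonsynonymous"


def annotate(
    variant: Variant, reference: Reference, gene_models: Sequence[GeneModel] | None = None
) -> list[EffectAnnotation]:
    """Annotate a SNP against every overlapping CDS model.

    Returns one EffectAnnotation per overlapping model, or a single
    intergenic / non_cds_genic annotation when no CDS overlaps. The stated
    reference allele must match the reference sequence; a disagreement is
    reported as an error, never silently repaired.
    """
    if gene_models is None:
        gene_models = reference.genes
    genomic_ref = reference.base(variant.contig, variant.position)
    if genomic_ref != variant.ref_allele:
        raise ReferenceMismatchError(
            f"{variant.contig}:{variant.position}: stated ref {variant.ref_allele!r} "
            f"but reference has {genomic_ref!r}"
        )
    hits = locate_in_cds(variant, gene_models)
    if not hits:
        return [
            EffectAnnotation(
                contig=variant.contig,
                position=variant.position,
                ref_allele=variant.ref_allele,
                alt_allele=variant.alt_allele,
                classification=classify_location(variant, gene_models),
            )
        ]
    annotations: list[EffectAnnotation] = []
    for hit in hits:
        gene = hit.gene
        coding = spliced_cds(reference, gene)
        codon_index = hit.offset // 3  # 0-based
        pos_in_codon = hit.offset % 3  # 0-based
        ref_codon = coding[3 * codon_index : 3 * codon_index + 3]
        coding_alt = variant.alt_allele if gene.strand == "+" else _revcomp(variant.alt_allele)
        alt_codon = ref_codon[:pos_in_codon] + coding_alt + ref_codon[pos_in_codon + 1 :]
        ref_aa = str(Seq(ref_codon).translate(table=1))
        alt_aa = str(Seq(alt_codon).translate(table=1))
        annotations.append(
            EffectAnnotation(
                contig=variant.contig,
                position=variant.position,
                ref_allele=variant.ref_allele,
                alt_allele=variant.alt_allele,
                classification=_classify(ref_aa, alt_aa),
                gene_id=gene.gene_id,
                cds_id=gene.cds_id,
                codon_index=codon_index + 1,
                position_in_codon=pos_in_codon + 1,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
            )
        )
    return annotations


def annotate_all(
    variants: Sequence[Variant], reference: Reference, gene_models: Sequence[GeneModel] | None = None
) -> dict[tuple[str, int, str], list[EffectAnnotation]]:
    """Annotation lookup keyed by (contig, position, alt_allele)."""
    out: dict[tuple[str, int, str], list[EffectAnnotation]] = {}
    for v in variants:
        out[(v.contig, v.position, v.alt_allele)] = annotate(v, reference, gene_models)
    return out
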