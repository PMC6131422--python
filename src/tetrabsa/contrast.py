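"""Between-bulk comparison at the union of called sites.

Each site called in either bulk is re-genotyped in both bulks from the
filtered pileups (so a bulk contributes counts even where it emitted no
call), a Pearson chi-square is applied to the 2 x k allele-count table, and
the allele-frequency contrast rule asks for an allele at >= 50% in one bulk
and <= 50% in the other. The chi-square is computed on pooled read counts,
as in the emulated workflow; reads are pseudo-replicates of the underlying
chromosomes, a deliberate fidelity choice documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import PipelineOrderError, SchemaError
from .models import SiteObservation
from .varcall import CallerParams, VariantCall, filter_reads

NONSYNONYMOUS_CLASSES = {"nonsynonymous", "stop_gained", "stop_lost"}


@dataclass
class BulkContrast:
    """Paired per-bulk allele counts at one site with the association verdicts."""

    contig: str
    position: int
    ref_allele: str
    alleles: tuple[str, ...]
    counts_low: np.ndarray
    counts_high: np.ndarray
    freq_low: np.ndarray
    freq_high: np.ndarray
    incomparable: bool = False
    chi2_statistic: float | None = None
    degrees_of_freedom: int | None = None
    p_value: float | None = None
    passes_contrast_rule: bool | None = None
    significant: bool | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.position)

    @property
    def coverage_low(self) -> int:
        return int(self.counts_low.sum())

    @property
    def coverage_high(self) -> int:
        return int(self.counts_high.sum())

    def max_freq_differential(self) -> float:
        return float(np.max(np.abs(self.freq_low - self.freq_high))) if self.alleles else 0.0


def _allele_counts(site: SiteObservation, alleles: Sequence[str]) -> np.ndarray:
    return np.array([int((site.bases == a).sum()) for a in alleles])


def union_sites(
    calls_low: Mapping[tuple[str, int], list[VariantCall]],
    calls_high: Mapping[tuple[str, int], list[VariantCall]],
    pileup_low: Mapping[tuple[str, int], SiteObservation],
    pileup_high: Mapping[tuple[str, int], SiteObservation],
    params: CallerParams,
) -> list[BulkContrast]:
    """One BulkContrast per site called in at least one bulk.

    Allele counts for both bulks are recomputed from their filtered pileups;
    the allele list is the union of observed alleles, reference first. A
    site absent from a bulk's pileup (or below the coverage floor there) is
    retained but flagged incomparable, never silently dropped.
    """
    out: list[BulkContrast] = []
    for key in sorted(set(calls_low) | set(calls_high)):
        contig, position = key
        any_call = (calls_low.get(key) or calls_high.get(key))[0]
        ref = any_call.ref_allele
        sites = {}
        for label, pileup in (("low", pileup_low), ("high", pileup_high)):
            raw = pileup.get(key)
            sites[label] = filter_reads(raw, params) if raw is not None else None
        observed: set[str] = set()
        for s in sites.values():
            if s is not None:
                observed.update(np.unique(s.bases).tolist())
        alleles = (ref,) + tuple(sorted(observed - {ref}))
        counts = {}
        for label, s in sites.items():
            counts[label] = _allele_counts(s, alleles) if s is not None else np.zeros(len(alleles), dtype=int)
        cov_low, cov_high = counts["low"].sum(), counts["high"].sum()
        # discovery keeps the full coverage floor; cross-bulk re-genotyping
        # needs only a stable frequency, so half the floor suffices
        floor = max(1, -(-params.min_coverage // 2))
        incomparable = cov_low < floor or cov_high < floor
        freq = {
            label: (c / c.sum() if c.sum() else np.zeros(len(alleles)))
            for label, c in counts.items()
        }
        out.append(
            BulkContrast(
                contig=contig,
                position=position,
                ref_allele=ref,
                alleles=alleles,
                counts_low=counts["low"],
                counts_high=counts["high"],
                freq_low=freq["low"],
                freq_high=freq["high"],
                incomparable=incomparable,
            )
        )
    return out


def chi_square(counts_low, counts_high) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2 x k allele table.

    Columns with zero total count are dropped before computing degrees of
    freedom; a table degenerate after the drop (k < 2) yields (0, 0, 1).
    """
    low = np.asarray(counts_low, dtype=float)
    high = np.asarray(counts_high, dtype=float)
    if low.shape != high.shape or low.ndim != 1:
        raise SchemaError("counts_low and counts_high must be equal-length 1-d vectors")
    if np.any(low < 0) or np.any(high < 0):
        raise SchemaError("allele counts must be non-negative")
    if low.sum() == 0 or high.sum() == 0:
        raise SchemaError("both bulks must have positive total count")
    keep = (low + high) > 0
    low, high = low[keep], high[keep]
    if low.size < 2:
        return 0.0, 0, 1.0
    table = np.vstack([low, high])
    result = stats.chi2_contingency(table, correction=False)
    return float(result.statistic), int(result.dof), float(result.pvalue)


def contrast_rule(freq_low, freq_high) -> bool:
    """True iff some allele sits at >= 50% in one bulk and <= 50% in the other.

    The two frequencies must differ (a 50/50-vs-50/50 tie is not a
    between-bulk difference). Symmetric in bulk order.
    """
    fl = np.asarray(freq_low, dtype=float)
    fh = np.asarray(freq_high, dtype=float)
    if fl.shape != fh.shape:
        raise SchemaError("frequency vectors must have equal length")
    for a, b in zip(fl, fh):
        if a == b:
            continue
        if (a >= 0.5 and b <= 0.5) or (b >= 0.5 and a <= 0.5):
            return True
    return False


def score_contrast(bc: BulkContrast, alpha: float = 0.05) -> BulkContrast:
    """Fill chi-square, contrast-rule and significance fields in place.

    Incomparable sites (coverage floor not met in a bulk) are reported but
    never significant.
    """
    if bc.incomparable:
        bc.chi2_statistic, bc.degrees_of_freedom, bc.p_value = 0.0, 0, 1.0
        bc.passes_contrast_rule = False
        bc.significant = False
        return bc
    stat, dof, p = chi_square(bc.counts_low, bc.counts_high)
    bc.chi2_statistic, bc.degrees_of_freedom, bc.p_value = stat, dof, p
    bc.passes_contrast_rule = contrast_rule(bc.freq_low, bc.freq_high)
    bc.significant = p < alpha
    return bc


def score_contrasts(contrasts: list[BulkContrast], alpha: float = 0.05) -> list[BulkContrast]:
    return [score_contrast(bc, alpha) for bc in contrasts]


@dataclass
class Tav:
    """A trait-associated variant: contrast verdicts joined with its effect."""

    contrast: BulkContrast
    allele: str
    effects: tuple
    gene_id: str
    cds_id: str

    @property
    def key(self) -> tuple[str, int]:
        return self.contrast.key


def select_tavs(
    contrasts: list[BulkContrast],
    effects_by_allele: Mapping[tuple[str, int, str], Sequence],
    alpha: float = 0.05,
) -> list[Tav]:
    """Retain nonsynonymous sites that are chi-square significant and pass the rule.

    ``effects_by_allele`` maps (contig, position, alt_allele) to the
    EffectAnnotation records for that substitution; every non-reference
    allele observed at a contrasted site must be annotated (intergenic
    annotations count), otherwise the stage order was wrong.
    """
    tavs: list[Tav] = []
    for bc in contrasts:
        if bc.significant is None:
            raise PipelineOrderError(f"contrast at {bc.contig}:{bc.position} not scored; run score_contrasts first")
        if not (bc.significant and bc.passes_contrast_rule):
            continue
        for i, allele in enumerate(bc.alleles):
            if allele == bc.ref_allele:
                continue
            if bc.counts_low[i] == 0 and bc.counts_high[i] == 0:
                continue
            effect_key = (bc.contig, bc.position, allele)
            if effect_key not in effects_by_allele:
                raise PipelineOrderError(
                    f"no effect annotation for {bc.contig}:{bc.position} {bc.ref_allele}>{allele}"
                )
            effects = tuple(effects_by_allele[effect_key])
            nonsyn = [e for e in effects if e.classification in NONSYNONYMOUS_CLASSES]
            if not nonsyn:
                continue
            primary = nonsyn[0]
            tavs.append(
                Tav(
                    contrast=bc,
                    allele=allele,
                    effects=effects,
                    gene_id=primary.gene_id,
                    cds_id=primary.cds_id,
                )
            )
    tavs.sort(key=lambda t: (t.contrast.contig, t.contrast.position, t.allele))
    return tavs
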