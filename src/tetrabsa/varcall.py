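"""Per-bulk pooled variant detection under the five-filter stack.

The caller reproduces a "basic variant detection" workflow for a pooled
tetraploid sample: read-level filters (pairing, mapping uniqueness, central
base quality, neighbourhood quality), site-level coverage bounds, and
per-allele acceptance on count, frequency and read-direction balance, with
the called frequency snapped to the nearest tetraploid dosage.

All threshold comparisons are inclusive (>=). "Minimum of 4 reads or 20%"
is applied conjunctively by default (count >= 4 AND frequency >= 20%; at
the minimum coverage of 20 the two clauses coincide), with a
``count_frequency_mode`` switch for the disjunctive reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError
from .models import Reference, SiteObservation, VALID_BASES

TETRAPLOID_DOSAGES = (0.25, 0.50, 0.75, 1.00)


@dataclass(frozen=True)
class CallerParams:
    min_coverage: int = 20
    max_coverage: int = 1000
    min_count: int = 4
    min_frequency: float = 0.20
    min_central_quality: int = 20
    neighbourhood_radius: int = 5
    min_neighbourhood_quality: float = 15.0
    min_read_direction_frequency: float = 0.20
    ploidy: int = 4
    exclude_broken_pairs: bool = True
    exclude_nonspecific: bool = True
    count_frequency_mode: str = "and"

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= self.max_coverage:
            raise ValueError("require 0 < min_coverage <= max_coverage")
        for name in ("min_frequency", "min_read_direction_frequency"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.count_frequency_mode not in ("and", "or"):
            raise ValueError("count_frequency_mode must be 'and' or 'or'")


@dataclass(frozen=True)
class VariantCall:
    """A called non-reference allele at one site in one bulk."""

    contig: str
    position: int
    ref_allele: str
    allele: str
    count: int
    effective_coverage: int
    frequency: float
    forward_fraction: float
    mean_base_quality: float
    nearest_dosage: float

    def __post_init__(self) -> None:
        assert self.count <= self.effective_coverage
        assert abs(self.frequency - self.count / self.effective_coverage) < 1e-12


def nearest_tetraploid_dosage(frequency: float) -> float:
    """Member of {0.25, 0.5, 0.75, 1.0} closest to ``frequency``; ties go low."""
    best = TETRAPLOID_DOSAGES[0]
    best_dist = abs(frequency - best)
    for d in TETRAPLOID_DOSAGES[1:]:
        dist = abs(frequency - d)
        if dist < best_dist - 1e-12:
            best, best_dist = d, dist
    return best


def filter_reads(site: SiteObservation, params: CallerParams) -> SiteObservation:
    """Drop reads failing the pairing/uniqueness/quality filters; order preserved."""
    for name in ("properly_paired", "unique_mapping", "quals", "neighbourhood_quality"):
        if getattr(site, name, None) is None:
            raise SchemaError(f"site {site.contig}:{site.position}: missing attribute {name}")
    mask = np.ones(site.depth, dtype=bool)
    if params.exclude_broken_pairs:
        mask &= site.properly_paired.astype(bool)
    if params.exclude_nonspecific:
        mask &= site.unique_mapping.astype(bool)
    mask &= site.quals >= params.min_central_quality
    mask &= site.neighbourhood_quality >= params.min_neighbourhood_quality
    return site.subset(mask)


def call_site(site: SiteObservation, ref_allele: str, params: CallerParams) -> list[VariantCall]:
    """Call non-reference alleles at one read-filtered site.

    No calls are emitted when effective coverage is outside
    [min_coverage, max_coverage]. An allele is called iff it clears the
    count/frequency clause and each strand carries at least
    ``min_read_direction_frequency`` of its supporting reads. Multi-allelic
    sites emit one call per passing allele, ordered by descending count then
    allele.
    """
    if ref_allele not in VALID_BASES:
        raise ValueError(f"ref_allele must be one of {VALID_BASES}, got {ref_allele!r}")
    eff_cov = site.depth
    if eff_cov < params.min_coverage or eff_cov > params.max_coverage:
        return []
    calls: list[VariantCall] = []
    for allele in VALID_BASES:
        if allele == ref_allele:
            continue
        support = site.bases == allele
        count = int(support.sum())
        if count == 0:
            continue
        frequency = count / eff_cov
        count_ok = count >= params.min_count
        freq_ok = frequency >= params.min_frequency
        if params.count_frequency_mode == "and":
            if not (count_ok and freq_ok):
                continue
        elif not (count_ok or freq_ok):
            continue
        fwd = int((support & site.forward.astype(bool)).sum())
        forward_fraction = fwd / count
        # minority-strand share from integer counts: exact at the 20% boundary
        if min(fwd, count - fwd) / count < params.min_read_direction_frequency:
            continue
        calls.append(
            VariantCall(
                contig=site.contig,
                position=site.position,
                ref_allele=ref_allele,
                allele=allele,
                count=count,
                effective_coverage=eff_cov,
                frequency=frequency,
                forward_fraction=forward_fraction,
                mean_base_quality=float(site.quals[support].mean()),
                nearest_dosage=nearest_tetraploid_dosage(frequency),
            )
        )
    calls.sort(key=lambda c: (-c.count, c.allele))
    return calls


def call_bulk(
    pileup: dict[tuple[str, int], SiteObservation],
    reference: Reference,
    params: CallerParams,
) -> dict[tuple[str, int], list[VariantCall]]:
    """Filter and call every site of a bulk's pileup; sites with calls only."""
    out: dict[tuple[str, int], list[VariantCall]] = {}
    for key in sorted(pileup):
        site = filter_reads(pileup[key], params)
        calls = call_site(site, reference.base(*key), params)
        if calls:
            out[key] = calls
    return out
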