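"""Shared domain containers used by more than one pipeline stage.

Coordinates are 1-based inclusive throughout (GFF3/VCF convention); any
half-open arithmetic is internal to a function and never leaks into a
container or a file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError

VALID_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene represented by its CDS chain.

    ``segments`` are 1-based inclusive (start, end) pairs in ascending
    genomic order regardless of strand; for '-' genes the coding order is
    the reverse of the genomic order.
    """

    gene_id: str
    cds_id: str
    contig: str
    strand: str
    segments: tuple[tuple[int, int], ...]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SchemaError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.segments:
            raise SchemaError(f"gene {self.gene_id}: empty CDS chain")
        prev_end = 0
        for start, end in self.segments:
            if start <= prev_end or end < start:
                raise SchemaError(f"gene {self.gene_id}: segments must be ascending and non-overlapping")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.segments[0][0], self.segments[-1][1]

    def contains(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.segments)

    def in_span(self, position: int) -> bool:
        lo, hi = self.span
        return lo <= position <= hi


@dataclass
class Reference:
    """Reference contigs plus their gene models."""

    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def base(self, contig: str, position: int) -> str:
        seq = self.sequences[contig]
        if not 1 <= position <= len(seq):
            from .errors import CoordinateError

            raise CoordinateError(f"{contig}:{position} outside contig of length {len(seq)}")
        return seq[position - 1]


@dataclass
class SiteObservation:
    """All read-level evidence at one reference position for one bulk.

    Parallel arrays, one entry per aligned read covering the site.
    """

    contig: str
    position: int
    ref_allele: str
    bases: np.ndarray
    quals: np.ndarray
    forward: np.ndarray
    properly_paired: np.ndarray
    unique_mapping: np.ndarray
    neighbourhood_quality: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.bases)
        for name in ("quals", "forward", "properly_paired", "unique_mapping", "neighbourhood_quality"):
            arr = getattr(self, name)
            if arr is None:
                raise SchemaError(f"site {self.contig}:{self.position}: missing attribute {name}")
            if len(arr) != n:
                raise SchemaError(
                    f"site {self.contig}:{self.position}: {name} has length {len(arr)}, expected {n}"
                )

    @property
    def depth(self) -> int:
        return len(self.bases)

    def subset(self, mask: np.ndarray) -> "SiteObservation":
        """Return a copy restricted to reads where ``mask`` is True (order preserved)."""
        return SiteObservation(
            contig=self.contig,
            position=self.position,
            ref_allele=self.ref_allele,
            bases=self.bases[mask],
            quals=self.quals[mask],
            forward=self.forward[mask],
            properly_paired=self.properly_paired[mask],
            unique_mapping=self.unique_mapping[mask],
            neighbourhood_quality=self.neighbourhood_quality[mask],
        )


@dataclass
class IndividualGenotype:
    """One tetraploid individual: per-site alternate-allele dosage and trait value."""

    individual_id: int
    dosages: dict[str, int]
    trait_value: float


@dataclass
class TruthSite:
    """Ground truth for one simulated variant site (simulation bookkeeping)."""

    site_id: str
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    is_causal: bool
    placement: str
    expected_freq_low_bulk: float | None = None
    expected_freq_high_bulk: float | None = None


SiteKey = tuple[str, int]


def site_key(obs_or_contig, position: int | None = None) -> SiteKey:
    if position is None:
        return (obs_or_contig.contig, obs_or_contig.position)
    return (obs_or_contig, position)
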