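"""Core domain types shared by every analysis stage.

The objects here model the minimal facts the pipeline reasons about: a
catalog of fixed retroviral LTR insertions in the reference (human)
genome, per-species LiftOver-style mapping outcomes, per-locus
conservation calls, a gene universe with functional category flags, and
2x2 contingency summaries used for enrichment reporting.

Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "LTR7_SUBFAMILIES",
    "FAMILIES",
    "LTRKitError",
    "ParseError",
    "ValidationError",
    "ContractError",
    "Species",
    "SpeciesPanel",
    "LTRLocus",
    "MappingRecord",
    "ConservationStatus",
    "ConservationCall",
    "HumanSpecificCall",
    "GeneRecord",
    "ContingencyResult",
]

#: The eleven monophyletic LTR7 sequence subtypes.
LTR7_SUBFAMILIES = (
    "LTR7B",
    "LTR7C",
    "LTR7bc",
    "LTR7o",
    "LTR7d1",
    "LTR7d2",
    "LTR7u1",
    "LTR7u2",
    "LTR7up1",
    "LTR7up2",
    "LTR7Y",
)

FAMILIES = ("LTR7", "LTR5_Hs")


class LTRKitError(Exception):
    """Base class for all package errors."""


class ParseError(LTRKitError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(LTRKitError):
    """A record violates a domain invariant."""


class ContractError(LTRKitError):
    """An operation was called with arguments violating its precondition."""


@dataclass(frozen=True)
class Species:
    species_id: str
    clade: str
    divergence_mya: float
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.divergence_mya < 0:
            raise ValidationError(
                f"species {self.species_id}: divergence_mya must be >= 0"
            )


@dataclass(frozen=True)
class SpeciesPanel:
    """A reference species plus non-reference species with divergence times.

    Exactly one entry is the reference (the human genome) and carries
    divergence time 0; every other entry has a strictly positive
    divergence time from the extinct common ancestor, in MYA.
    """

    entries: tuple[Species, ...]

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("species_id values must be unique")
        refs = [s for s in self.entries if s.is_reference]
        if len(refs) != 1:
            raise ValidationError("panel must contain exactly one reference species")
        if refs[0].divergence_mya != 0:
            raise ValidationError("reference species must have divergence_mya = 0")
        for s in self.entries:
            if not s.is_reference and s.divergence_mya <= 0:
                raise ValidationError(
                    f"non-reference species {s.species_id} must have divergence_mya > 0"
                )

    @property
    def reference(self) -> Species:
        return next(s for s in self.entries if s.is_reference)

    @property
    def non_reference(self) -> tuple[Species, ...]:
        return tuple(s for s in self.entries if not s.is_reference)

    def divergence_of(self, species_id: str) -> float:
        for s in self.entries:
            if s.species_id == species_id:
                return s.divergence_mya
        raise KeyError(species_id)

    def __contains__(self, species_id: object) -> bool:
        return any(s.species_id == species_id for s in self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class LTRLocus:
    """One fixed retroviral LTR insertion in the reference genome."""

    locus_id: str
    family: str
    subfamily: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"{self.locus_id}: unknown family {self.family!r}")
        if self.family == "LTR7":
            if self.subfamily not in LTR7_SUBFAMILIES:
                raise ValidationError(
                    f"{self.locus_id}: unknown LTR7 subfamily {self.subfamily!r}"
                )
        elif self.subfamily != "LTR5_Hs":
            raise ValidationError(
                f"{self.locus_id}: LTR5_Hs loci carry subfamily 'LTR5_Hs', "
                f"got {self.subfamily!r}"
            )
        if not self.start < self.end:
            raise ValidationError(
                f"{self.locus_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"{self.locus_id}: bad strand {self.strand!r}")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class MappingRecord:
    """Outcome of mapping one locus into one target genome.

    ``identity`` is the fraction of the query sequence recovered at the
    mapped locus and is defined only when at least one hit exists.
    ``intersects_chain`` records whether any alignment chain covers the
    query at all, even when no mapping met the threshold.
    """

    locus_id: str
    query_species: str
    target_species: str
    n_hits: int
    mapped_chrom: Optional[str] = None
    mapped_start: Optional[int] = None
    mapped_end: Optional[int] = None
    identity: Optional[float] = None
    intersects_chain: bool = False

    def __post_init__(self) -> None:
        if self.n_hits < 0:
            raise ValidationError(f"{self.locus_id}: n_hits must be >= 0")
        if self.n_hits == 0:
            if self.mapped_chrom is not None or self.identity is not None:
                raise ValidationError(
                    f"{self.locus_id}: n_hits = 0 implies no mapped interval/identity"
                )
        else:
            if self.mapped_chrom is None or self.mapped_start is None or self.mapped_end is None:
                raise ValidationError(
                    f"{self.locus_id}: n_hits >= 1 requires a mapped interval"
                )
            if self.identity is None or not (0.0 <= self.identity <= 1.0):
                raise ValidationError(
                    f"{self.locus_id}: identity must be in [0,1] when mapped, "
                    f"got {self.identity!r}"
                )
            if not self.intersects_chain:
                raise ValidationError(
                    f"{self.locus_id}: a mapped locus necessarily intersects a chain"
                )

    @property
    def mapped_interval(self) -> Optional[tuple[str, int, int]]:
        if self.n_hits == 0:
            return None
        return (self.mapped_chrom, self.mapped_start, self.mapped_end)


class ConservationStatus(enum.Enum):
    HIGHLY_CONSERVED = "HIGHLY_CONSERVED"
    DIVERGED = "DIVERGED"
    ABSENT = "ABSENT"


@dataclass(frozen=True)
class ConservationCall:
    locus_id: str
    species: str
    status: ConservationStatus


@dataclass(frozen=True)
class HumanSpecificCall:
    locus_id: str
    human_specific: bool
    bona_fide: bool

    def __post_init__(self) -> None:
        if self.bona_fide and not self.human_specific:
            raise ValidationError(
                f"{self.locus_id}: bona_fide implies human_specific"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A gene in the analysis universe, with TSS and category flags.

    Standard flags are ``OS`` (mammalian offspring survival), ``SYNAPTIC``
    (synaptic-transmission network member) and ``FETAL_GONAD_MARKER``;
    perturbation/virus-response experiments contribute arbitrarily named
    additional flags.
    """

    symbol: str
    chrom: str
    tss: int
    strand: str
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.symbol}: gene strand must be + or -")
        if self.tss < 0:
            raise ValidationError(f"{self.symbol}: TSS must be >= 0")


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 enrichment summary in the style of the published tables.

    ``a``/``b`` are the observed in-category and out-of-category counts
    among linked genes.  ``c``/``d`` depend on the table construction:
    for the standard universe partition they are the unlinked
    in-category / out-of-category counts (a+b+c+d = universe size); for
    the observed-vs-expected construction that reproduces the published
    p-values they are the expected-by-chance split of the same
    linked-gene total (a+b = c+d).  ``enrichment`` is the ratio of the
    observed to the expected category percentage, identical under both.
    """

    a: int
    b: int
    c: int
    d: int
    observed_pct: float
    expected_pct: float
    enrichment: float
    p_two_sided: float

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValidationError("contingency cells must be non-negative")
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValidationError("p_two_sided must be in (0, 1]")

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


def subfamily_counts(catalog: Iterable[LTRLocus]) -> dict[str, int]:
    """Count loci per subfamily; keys appear in catalog order of first use."""
    counts: dict[str, int] = {}
    for locus in catalog:
        counts[locus.subfamily] = counts.get(locus.subfamily, 0) + 1
    return counts
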