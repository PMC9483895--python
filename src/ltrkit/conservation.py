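"""Reciprocal-mapping conservation calls and human-specific classification.

A reference-genome LTR locus is called HIGHLY_CONSERVED in a target
genome only when two requirements hold: (1) the direct mapping places
the locus at a single orthologous target locus with identity at or above
the threshold (default 95%), and (2) the reciprocal mapping of that
target locus returns, again uniquely and at or above the threshold, to
the exact same reference interval.  Loci with no direct hit at all are
ABSENT; everything else is DIVERGED.

A locus is human-specific when neither chimpanzee nor bonobo retains any
mapping at a permissive identity floor (default 10%); it is additionally
a bona fide human-specific insertion when no alignment chain covers it
in either genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .types import (
    ConservationCall,
    ConservationStatus,
    ContractError,
    HumanSpecificCall,
    LTRLocus,
    MappingRecord,
    SpeciesPanel,
)

__all__ = [
    "classify_conservation",
    "classify_human_specific",
    "ConservedCountMatrix",
    "conserved_count_matrix",
    "gains_losses",
    "GainLossRecord",
]


def classify_conservation(
    locus: LTRLocus,
    direct: Optional[MappingRecord],
    reciprocal: Optional[MappingRecord],
    min_identity: float = 0.95,
    slop: int = 0,
    species: Optional[str] = None,
) -> ConservationCall:
    """Apply the two-requirement reciprocal-mapping rule to one locus.

    ``direct`` is the reference->target mapping of the locus; ``reciprocal``
    is the target->reference mapping of the direct hit (None when the
    direct mapping is absent or was not followed up).  ``slop`` is the
    tolerated total coordinate discrepancy |dstart| + |dend| when deciding
    whether the reciprocal hit returned to the same reference interval.
    ``species`` names the target species when no direct record exists.
    """
    if direct is not None:
        species = direct.target_species
    elif reciprocal is not None:
        raise ContractError(
            f"{locus.locus_id}: reciprocal record supplied without a direct record"
        )

    if direct is None or direct.n_hits == 0:
        if reciprocal is not None:
            raise ContractError(
                f"{locus.locus_id}: reciprocal record supplied without a direct hit"
            )
        return ConservationCall(
            locus.locus_id, species or "", ConservationStatus.ABSENT
        )

    status = ConservationStatus.DIVERGED
    if (
        direct.n_hits == 1
        and direct.identity is not None
        and direct.identity >= min_identity
        and reciprocal is not None
        and reciprocal.n_hits == 1
        and reciprocal.identity is not None
        and reciprocal.identity >= min_identity
        and reciprocal.mapped_chrom == locus.chrom
        and (
            abs(reciprocal.mapped_start - locus.start)
            + abs(reciprocal.mapped_end - locus.end)
        )
        <= slop
    ):
        status = ConservationStatus.HIGHLY_CONSERVED
    return ConservationCall(locus.locus_id, species, status)


def classify_human_specific(
    locus: LTRLocus,
    chimp_records: Sequence[MappingRecord],
    bonobo_records: Sequence[MappingRecord],
    hs_identity_cutoff: float = 0.10,
) -> HumanSpecificCall:
    """Classify a locus as human-specific relative to the Pan genomes.

    ``human_specific`` requires that in BOTH species no hit reaches the
    identity floor; ``bona_fide`` additionally requires that no alignment
    chain intersects the locus in either genome.
    """

    def no_hit(records: Sequence[MappingRecord]) -> bool:
        return all(
            r.n_hits == 0 or (r.identity is not None and r.identity < hs_identity_cutoff)
            for r in records
        )

    def no_chain(records: Sequence[MappingRecord]) -> bool:
        return all(not r.intersects_chain for r in records)

    human_specific = no_hit(chimp_records) and no_hit(bonobo_records)
    bona_fide = human_specific and no_chain(chimp_records) and no_chain(bonobo_records)
    return HumanSpecificCall(locus.locus_id, human_specific, bona_fide)


@dataclass(frozen=True)
class GainLossRecord:
    """Gains (conserved count) and losses (deficit vs reference) per species."""

    species: str
    gain: int
    loss: int


class ConservedCountMatrix:
    """Species x subfamily counts of highly conserved loci.

    Rows are species (the reference row equals the catalog), columns are
    subfamilies plus a ``total`` column.  ``percentages()`` reports each
    cell relative to the reference catalog count of that subfamily.
    """

    def __init__(self, counts: pd.DataFrame, reference_species: str):
        if reference_species not in counts.index:
            raise ValueError(f"reference {reference_species!r} missing from matrix")
        self.counts = counts
        self.reference_species = reference_species

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subfamilies(self) -> list[str]:
        return [c for c in self.counts.columns if c != "total"]

    def count(self, species: str, subfamily: str = "total") -> int:
        return int(self.counts.at[species, subfamily])

    def percentages(self) -> pd.DataFrame:
        ref = self.counts.loc[self.reference_species]
        return 100.0 * self.counts / ref

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="species")


def conserved_count_matrix(
    calls: Iterable[ConservationCall],
    catalog: Sequence[LTRLocus],
    panel: SpeciesPanel,
) -> ConservedCountMatrix:
    """Tabulate highly conserved loci per species and subfamily.

    ``calls`` must cover every catalog locus for every non-reference
    species in the panel; gaps raise with an explicit listing.  The
    reference row is the catalog itself.
    """
    subfamily_of = {loc.locus_id: loc.subfamily for loc in catalog}
    subfams = list(dict.fromkeys(loc.subfamily for loc in catalog))
    species_ids = [s.species_id for s in panel.non_reference]
    counts = pd.DataFrame(0, index=species_ids, columns=subfams + ["total"])

    seen: set[tuple[str, str]] = set()
    for call in calls:
        if call.locus_id not in subfamily_of or call.species not in species_ids:
            continue
        seen.add((call.locus_id, call.species))
        if call.status is ConservationStatus.HIGHLY_CONSERVED:
            counts.at[call.species, subfamily_of[call.locus_id]] += 1
            counts.at[call.species, "total"] += 1

    expected = {(lid, sp) for lid in subfamily_of for sp in species_ids}
    missing = expected - seen
    if missing:
        sample = sorted(missing)[:10]
        raise ValueError(
            f"{len(missing)} locus x species pairs lack conservation calls, "
            f"e.g. {sample}"
        )

    ref_id = panel.reference.species_id
    ref_row = {sf: sum(1 for loc in catalog if loc.subfamily == sf) for sf in subfams}
    ref_row["total"] = len(catalog)
    counts.loc[ref_id] = pd.Series(ref_row)
    counts = counts.loc[[ref_id] + species_ids]
    return ConservedCountMatrix(counts, ref_id)


def gains_losses(matrix: ConservedCountMatrix) -> list[GainLossRecord]:
    """Per-species balance of gains (conserved loci) and losses (deficit).

    The loss is the reference catalog total minus the species' conserved
    total, so gain + loss equals the reference total for every species.
    """
    reference_total = matrix.count(matrix.reference_species)
    return [
        GainLossRecord(sp, matrix.count(sp), reference_total - matrix.count(sp))
        for sp in matrix.species
    ]


def classify_batch(
    catalog: Sequence[LTRLocus],
    species: str,
    direct_by_locus: Mapping[str, Optional[MappingRecord]],
    reciprocal_by_locus: Mapping[str, Optional[MappingRecord]],
    min_identity: float = 0.95,
    slop: int = 0,
) -> list[ConservationCall]:
    """Classify every catalog locus against one target species."""
    return [
        classify_conservation(
            locus,
            direct_by_locus.get(locus.locus_id),
            reciprocal_by_locus.get(locus.locus_id),
            min_identity=min_identity,
            slop=slop,
            species=species,
        )
        for locus in catalog
    ]
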