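"""Molecular dating from LTR locus acquisition rates.

The model: loci accumulate on the lineage leading to the reference
genome at an approximately constant rate.  Anchor species with a known
(externally dated) split time pin the rate,

    rate = (reference_count - mean(anchor counts)) / (anchor_time - reference_time)

in loci per MYA, and any other species' divergence from the extinct
common ancestor is then dated from its deficit of highly conserved
loci,

    t = (reference_count - conserved_count) / rate.

The estimator ignores locus losses on non-reference lineages, so with
retention loss the deficit overstates age and estimates are biased
upward; the anchor default in the wider pipeline is the Old World
Monkey split at 29 MYA.

The module exposes a small statsmodels-flavoured surface: build an
:class:`AcquisitionRateModel` from anchor data, ``fit()`` it, and query
the :class:`DatingResults` for rate, per-species dates and a
``summary()`` table, alongside plain functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import LTRKitError

__all__ = [
    "ModelViolationError",
    "RateEstimate",
    "DatingEstimate",
    "AcquisitionRateModel",
    "DatingResults",
    "acquisition_rate",
    "estimate_divergence",
]


class ModelViolationError(LTRKitError):
    """The data contradict the linear-accumulation model's preconditions."""


@dataclass(frozen=True)
class RateEstimate:
    """Loci gained per MYA on the reference lineage, with its anchors."""

    rate: float
    anchors: tuple[tuple[str, int], ...]
    anchor_time: float
    reference_count: int
    reference_time: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ModelViolationError("acquisition rate must be positive")
        if not self.anchors:
            raise ModelViolationError("at least one anchor species required")


@dataclass(frozen=True)
class DatingEstimate:
    species: str
    conserved_count: int
    estimated_divergence_mya: float
    rate_used: float


def acquisition_rate(
    anchor_counts: Sequence[tuple[str, int]],
    anchor_time: float,
    reference_count: int,
    reference_time: float = 0.0,
) -> RateEstimate:
    """Estimate the per-MYA locus acquisition rate from anchor species."""
    if not anchor_counts:
        raise ModelViolationError("at least one anchor species required")
    if not reference_time < anchor_time:
        raise ModelViolationError("reference_time must precede anchor_time")
    mean_anchor = float(np.mean([c for _, c in anchor_counts]))
    if reference_count <= mean_anchor:
        raise ModelViolationError(
            "reference count must exceed the mean anchor count "
            f"({reference_count} <= {mean_anchor:g}): no accumulation to date"
        )
    rate = (reference_count - mean_anchor) / (anchor_time - reference_time)
    return RateEstimate(
        rate=rate,
        anchors=tuple(anchor_counts),
        anchor_time=anchor_time,
        reference_count=reference_count,
        reference_time=reference_time,
    )


def estimate_divergence(
    conserved_count: int,
    rate: RateEstimate,
    reference_count: int | None = None,
    species: str = "",
) -> DatingEstimate:
    """Date a species' split from its deficit of conserved loci."""
    ref = rate.reference_count if reference_count is None else reference_count
    if conserved_count > ref:
        raise ModelViolationError(
            f"conserved count {conserved_count} exceeds reference count {ref}"
        )
    t = (ref - conserved_count) / rate.rate
    return DatingEstimate(species, conserved_count, t, rate.rate)


class AcquisitionRateModel:
    """Linear locus-accumulation dating model.

    Parameters
    ----------
    anchor_counts
        ``(species, conserved_count)`` pairs for the anchor clade.
    anchor_time
        Externally dated split time of the anchor clade, MYA.
    reference_count
        Catalog size in the reference genome.
    reference_time
        Time coordinate of the reference genome (0 = present).
    """

    def __init__(
        self,
        anchor_counts: Sequence[tuple[str, int]],
        anchor_time: float,
        reference_count: int,
        reference_time: float = 0.0,
    ):
        self.anchor_counts = tuple(anchor_counts)
        self.anchor_time = anchor_time
        self.reference_count = reference_count
        self.reference_time = reference_time

    @classmethod
    def from_count_matrix(
        cls,
        matrix,
        anchor_species: Sequence[str],
        anchor_time: float,
    ) -> "AcquisitionRateModel":
        """Build from a :class:`~ltrkit.conservation.ConservedCountMatrix`."""
        anchors = [(sp, matrix.count(sp)) for sp in anchor_species]
        return cls(anchors, anchor_time, matrix.count(matrix.reference_species))

    def fit(self) -> "DatingResults":
        rate = acquisition_rate(
            self.anchor_counts,
            self.anchor_time,
            self.reference_count,
            self.reference_time,
        )
        return DatingResults(self, rate)


class DatingResults:
    """Fitted acquisition rate plus divergence-date predictions."""

    def __init__(self, model: AcquisitionRateModel, rate_estimate: RateEstimate):
        self.model = model
        self.rate_estimate = rate_estimate

    @property
    def rate(self) -> float:
        return self.rate_estimate.rate

    def estimate_divergence(self, conserved_count: int, species: str = "") -> DatingEstimate:
        return estimate_divergence(conserved_count, self.rate_estimate, species=species)

    def date_species(
        self, counts: Iterable[tuple[str, int]]
    ) -> list[DatingEstimate]:
        return [self.estimate_divergence(c, species=sp) for sp, c in counts]

    def report(self, counts: Iterable[tuple[str, int]]) -> pd.DataFrame:
        rows = []
        for est in self.date_species(counts):
            rows.append(
                {
                    "species": est.species,
                    "conserved_count": est.conserved_count,
                    "deficit": self.rate_estimate.reference_count - est.conserved_count,
                    "estimated_divergence_mya": est.estimated_divergence_mya,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        re_ = self.rate_estimate
        lines = [
            "Acquisition-rate dating model",
            "=============================",
            f"reference count:      {re_.reference_count}",
            f"reference time (MYA): {re_.reference_time:g}",
            f"anchor time (MYA):    {re_.anchor_time:g}",
            f"anchors:              {len(re_.anchors)}",
            f"mean anchor count:    {np.mean([c for _, c in re_.anchors]):g}",
            f"rate (loci/MYA):      {re_.rate:.2f}",
        ]
        return "\n".join(lines)
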