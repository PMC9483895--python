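"""Set algebra over locus-linked genes and perturbation-response lists.

A linked gene graduates to a high-confidence regulatory target when any
perturbation experiment (CRISPR interference/activation, epigenetic
silencing of the corresponding LTR class, ...) altered its expression.
Family-level partitions (LTR7-only / LTR5_Hs-only / both / either) and
coverage fractions of nested sets mirror the published catalog tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable

from .types import ValidationError

__all__ = [
    "high_confidence_targets",
    "coverage_fraction",
    "family_partition",
    "FamilyPartition",
    "TargetCatalog",
]


def high_confidence_targets(
    linked: Collection[str], response_sets: Iterable[Collection[str]]
) -> set[str]:
    """Linked genes altered in at least one perturbation experiment."""
    responded: set[str] = set()
    for rs in response_sets:
        responded |= set(rs)
    return set(linked) & responded


def coverage_fraction(subset: Collection[str], parent: Collection[str]) -> float:
    """Percentage of ``parent`` covered by ``subset`` (full precision)."""
    subset, parent = set(subset), set(parent)
    if not parent:
        raise ValidationError("parent set must be nonempty")
    if not subset <= parent:
        raise ValidationError("subset must be contained in parent")
    return 100.0 * len(subset) / len(parent)


@dataclass(frozen=True)
class FamilyPartition:
    """Disjoint partition of linked genes by LTR family membership."""

    both: frozenset[str]
    ltr7_only: frozenset[str]
    ltr5_only: frozenset[str]

    @property
    def either(self) -> frozenset[str]:
        return self.both | self.ltr7_only | self.ltr5_only

    def sizes(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "ltr7_only": len(self.ltr7_only),
            "ltr5_only": len(self.ltr5_only),
            "either": len(self.either),
        }


def family_partition(
    ltr7_targets: Collection[str], ltr5_targets: Collection[str]
) -> FamilyPartition:
    a, b = set(ltr7_targets), set(ltr5_targets)
    return FamilyPartition(
        both=frozenset(a & b),
        ltr7_only=frozenset(a - b),
        ltr5_only=frozenset(b - a),
    )


@dataclass
class TargetCatalog:
    """Linked, response and derived high-confidence gene sets per family."""

    linked: dict[str, set[str]] = field(default_factory=dict)
    responses: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add_family(
        self,
        family: str,
        linked: Collection[str],
        responses: dict[str, Collection[str]] | None = None,
    ) -> None:
        self.linked[family] = set(linked)
        self.responses[family] = {
            name: set(genes) for name, genes in (responses or {}).items()
        }

    def high_confidence(self, family: str) -> set[str]:
        return high_confidence_targets(
            self.linked[family], self.responses[family].values()
        )

    def partition(self, family_a: str = "LTR7", family_b: str = "LTR5_Hs") -> FamilyPartition:
        return family_partition(self.linked[family_a], self.linked[family_b])

    def summary_rows(self) -> list[dict]:
        rows = []
        for family, linked in self.linked.items():
            hc = self.high_confidence(family)
            row = {
                "family": family,
                "linked_genes": len(linked),
                "high_confidence": len(hc),
                "high_confidence_pct": coverage_fraction(hc, linked) if linked else 0.0,
            }
            rows.append(row)
        return rows
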