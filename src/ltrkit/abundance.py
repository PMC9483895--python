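"""Subfamily abundance profiles and their cross-species resemblance.

A species' abundance profile is the percentage breakdown of its highly
conserved loci over the eleven LTR7 subfamilies.  Resemblance between
species is the Pearson correlation of their profiles; across a panel,
the correlation of each species' resemblance-to-reference against its
divergence time summarises how profile similarity decays with
evolutionary distance (expected strongly negative when subfamily
retention decays with age).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .conservation import ConservedCountMatrix
from .types import LTRKitError, SpeciesPanel

__all__ = [
    "AbundanceProfile",
    "UndefinedProfileError",
    "UndefinedCorrelationError",
    "subfamily_profile",
    "profile_correlation",
    "resemblance_vs_divergence",
]


class UndefinedProfileError(LTRKitError):
    """Raised for a species with zero conserved loci."""


class UndefinedCorrelationError(LTRKitError):
    """Raised when either profile has zero variance."""


@dataclass(frozen=True)
class AbundanceProfile:
    species: str
    subfamilies: tuple[str, ...]
    values: tuple[float, ...]  # percentages summing to 100

    def __post_init__(self) -> None:
        if len(self.subfamilies) != len(self.values):
            raise ValueError("subfamilies/values length mismatch")
        if abs(sum(self.values) - 100.0) > 1e-9:
            raise ValueError("profile percentages must sum to 100")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def subfamily_profile(matrix: ConservedCountMatrix, species: str) -> AbundanceProfile:
    """Percentage of a species' conserved loci in each subfamily."""
    subfams = matrix.subfamilies
    counts = np.array([matrix.count(species, sf) for sf in subfams], dtype=float)
    total = counts.sum()
    if total == 0:
        raise UndefinedProfileError(f"{species}: no conserved loci, profile undefined")
    values = 100.0 * counts / total
    # renormalise the float round-off so the sum-to-100 invariant is exact
    values *= 100.0 / values.sum()
    return AbundanceProfile(species, tuple(subfams), tuple(values))


def profile_correlation(pa: AbundanceProfile, pb: AbundanceProfile) -> float:
    """Pearson product-moment correlation of two abundance profiles."""
    xa, xb = pa.as_array(), pb.as_array()
    if xa.shape != xb.shape:
        raise ValueError("profiles must have equal length")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in profile of {pa.species if np.ptp(xa) == 0 else pb.species}"
        )
    if len(xa) == 2:
        # degenerate but permitted: sign of the (perfect) linear relation
        return 1.0 if (xa[1] - xa[0]) * (xb[1] - xb[0]) > 0 else -1.0
    return float(stats.pearsonr(xa, xb).statistic)


def resemblance_vs_divergence(
    profiles: Mapping[str, AbundanceProfile],
    panel: SpeciesPanel,
) -> tuple[list[tuple[str, float, float]], float]:
    """Correlate resemblance-to-reference with divergence time.

    Returns per-species triples ``(species, divergence_mya, r_to_reference)``
    and the Pearson correlation of divergence time against resemblance
    across the panel.  Species without a defined profile are skipped with
    a warning.
    """
    ref_id = panel.reference.species_id
    if ref_id not in profiles:
        raise ValueError("reference profile required")
    ref = profiles[ref_id]
    pairs: list[tuple[str, float, float]] = []
    for sp in panel.non_reference:
        prof = profiles.get(sp.species_id)
        if prof is None:
            warnings.warn(
                f"{sp.species_id}: no abundance profile, excluded from "
                "resemblance-vs-divergence",
                stacklevel=2,
            )
            continue
        pairs.append(
            (sp.species_id, sp.divergence_mya, profile_correlation(ref, prof))
        )
    if len(pairs) < 2:
        raise ValueError("need >= 2 non-reference species with profiles")
    times = np.array([t for _, t, _ in pairs])
    rs = np.array([r for _, _, r in pairs])
    if np.ptp(times) == 0 or np.ptp(rs) == 0:
        raise UndefinedCorrelationError(
            "resemblance-vs-divergence undefined: zero variance"
        )
    if len(pairs) == 2:
        r_assoc = 1.0 if (times[1] - times[0]) * (rs[1] - rs[0]) > 0 else -1.0
    else:
        r_assoc = float(stats.pearsonr(times, rs).statistic)
    return pairs, r_assoc
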