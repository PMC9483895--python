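"""Synthetic inputs with ground-truth bookkeeping for every stage.

The generator emulates the data regime the analysis assumes: LTR loci
are born along the lineage to the reference genome at a constant rate
over the family's residence time, are present in a non-reference
species when born before that species' split and not lost on its
branch, and accumulate sequence divergence linearly with the species'
age (with Gaussian jitter).  Subfamily identity is drawn with smoothly
age-shifted intensities so that subfamily composition drifts with
evolutionary distance, which is what makes abundance-profile
resemblance decay with divergence time.  Coupled losses on the
chimpanzee+bonobo branch plant loci that are "human-specific yet
conserved in more distant species".  Every planted event is recorded so
downstream calls can be checked against truth exactly.

A gene universe with category flags and perturbation-response gene
lists enriched among locus-linked genes complete the pipeline inputs.
All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Collection, Optional

import numpy as np

from . import io as ltrio
from .types import (
    GeneRecord,
    LTR7_SUBFAMILIES,
    LTRLocus,
    MappingRecord,
    Species,
    SpeciesPanel,
)

__all__ = [
    "SimulationConfig",
    "LocusHistory",
    "SyntheticDataset",
    "default_panel",
    "simulate_locus_history",
    "simulate_gene_universe",
    "simulate_perturbation_response",
    "simulate_dataset",
    "write_dataset",
]


def default_panel() -> SpeciesPanel:
    """Primate panel with consensus molecular divergence times (MYA)."""
    return SpeciesPanel(
        (
            Species("Human", "Hominini", 0.0, is_reference=True),
            Species("Chimpanzee", "Hominini", 13.0),
            Species("Bonobo", "Hominini", 13.0),
            Species("Gorilla", "Homininae", 15.1),
            Species("Orangutan", "Ponginae", 16.0),
            Species("Gibbon", "Hylobatidae", 16.8),
            Species("Rhesus", "Old World Monkey", 29.0),
            Species("Crab_eating_macaque", "Old World Monkey", 29.0),
            Species("Baboon", "Old World Monkey", 29.0),
            Species("Green_monkey", "Old World Monkey", 29.0),
            Species("Gelada", "Old World Monkey", 29.0),
        )
    )


#: Relative insertion weights per LTR7 subfamily (human-catalog-like
#: proportions) and activity-peak ages (MYA) driving composition drift.
_SUBFAMILY_WEIGHTS = {
    "LTR7B": (547, 34.0),
    "LTR7C": (412, 32.0),
    "LTR7bc": (307, 30.0),
    "LTR7o": (243, 28.0),
    "LTR7d1": (215, 24.0),
    "LTR7d2": (445, 22.0),
    "LTR7u1": (143, 18.0),
    "LTR7u2": (195, 16.0),
    "LTR7up1": (378, 14.0),
    "LTR7up2": (96, 12.0),
    "LTR7Y": (373, 8.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data regime, with field defaults.

    Rates are per MYA, probabilities per branch (species), sizes in
    genes or base pairs.  ``identity_decay`` is expected identity loss
    per MYA of divergence; ``identity_sigma`` the jitter around it.
    """

    seed: int = 0
    panel: SpeciesPanel = field(default_factory=default_panel)
    family: str = "LTR7"
    origin_mya: float = 40.0
    insertion_rate: float = 84.0
    identity_decay: float = 0.001
    identity_sigma: float = 0.005
    retention_loss_prob: float = 0.05
    pan_loss_prob: float = 0.03
    pan_species: tuple[str, str] = ("Chimpanzee", "Bonobo")
    reciprocal_failure_prob: float = 0.02
    residual_chain_prob: float = 0.08
    universe_size: int = 18777
    os_fraction: float = 2413 / 18777
    synaptic_count: int = 355
    fetal_gonad_count: int = 88
    linked_response_prob: float = 0.53
    unlinked_response_prob: float = 0.04
    n_chromosomes: int = 5
    chrom_size: int = 50_000_000

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_sizes(self) -> dict[str, int]:
        return {name: self.chrom_size for name in self.chrom_names()}

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class LocusHistory:
    """Simulated catalog, mapping tables and the planted truth."""

    config: SimulationConfig
    catalog: list[LTRLocus]
    ages: dict[str, float]
    #: species -> set of locus_ids genuinely present in that genome
    truth_present: dict[str, set[str]]
    #: species -> locus_ids whose reciprocal mapping was planted to fail
    truth_reciprocal_fail: dict[str, set[str]]
    #: locus_ids lost on the chimpanzee+bonobo branch despite old age
    planted_pan_losses: set[str]
    #: species -> locus_id -> direct mapping record
    direct: dict[str, dict[str, MappingRecord]]
    #: species -> locus_id -> reciprocal mapping record (mapped loci only)
    reciprocal: dict[str, dict[str, MappingRecord]]

    def truth_conserved(self, species: str) -> set[str]:
        """Loci whose conservation call should be HIGHLY_CONSERVED,
        barring identity jitter."""
        return self.truth_present[species] - self.truth_reciprocal_fail[species]


def _subfamily_probs(age: np.ndarray, origin: float) -> np.ndarray:
    """Per-locus subfamily probabilities, smoothly shifted with age."""
    weights = np.array([w for w, _ in _SUBFAMILY_WEIGHTS.values()], dtype=float)
    peaks = np.array([p for _, p in _SUBFAMILY_WEIGHTS.values()], dtype=float)
    # a broad bump around each subfamily's activity peak, with a floor so
    # every subfamily is present at every age (all are seen in the most
    # distant species)
    bump = 0.25 + np.exp(-0.5 * ((age[:, None] - peaks[None, :]) / 10.0) ** 2)
    intens = weights[None, :] * bump
    return intens / intens.sum(axis=1, keepdims=True)


def simulate_locus_history(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> LocusHistory:
    """Simulate the locus catalog plus direct/reciprocal mapping tables."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = int(round(config.insertion_rate * config.origin_mya))
    ages = rng.uniform(0.0, config.origin_mya, n)
    chroms = rng.integers(0, config.n_chromosomes, n)
    lengths = rng.integers(300, 501, n)
    starts = rng.integers(0, config.chrom_size - 501, n)
    strands = rng.choice(np.array(["+", "-"]), n)
    chrom_names = config.chrom_names()

    if config.family == "LTR7":
        probs = _subfamily_probs(ages, config.origin_mya)
        sub_idx = np.array(
            [rng.choice(len(LTR7_SUBFAMILIES), p=probs[i]) for i in range(n)]
        )
        subfamilies = [LTR7_SUBFAMILIES[j] for j in sub_idx]
    else:
        subfamilies = [config.family] * n

    catalog = [
        LTRLocus(
            locus_id=f"L{i:06d}",
            family=config.family,
            subfamily=subfamilies[i],
            chrom=chrom_names[chroms[i]],
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            strand=str(strands[i]),
        )
        for i in range(n)
    ]
    age_of = {loc.locus_id: float(ages[i]) for i, loc in enumerate(catalog)}

    pan_pair = set(config.pan_species)
    pan_split = max(
        (s.divergence_mya for s in config.panel.non_reference
         if s.species_id in pan_pair),
        default=0.0,
    )
    pan_lost = set()
    if pan_pair & {s.species_id for s in config.panel.non_reference}:
        old_enough = [loc.locus_id for loc in catalog if age_of[loc.locus_id] > pan_split]
        lost_mask = rng.random(len(old_enough)) < config.pan_loss_prob
        pan_lost = {lid for lid, m in zip(old_enough, lost_mask) if m}

    truth_present: dict[str, set[str]] = {}
    truth_rfail: dict[str, set[str]] = {}
    direct: dict[str, dict[str, MappingRecord]] = {}
    reciprocal: dict[str, dict[str, MappingRecord]] = {}

    for sp in config.panel.non_reference:
        t = sp.divergence_mya
        present: set[str] = set()
        rfail: set[str] = set()
        dmap: dict[str, MappingRecord] = {}
        rmap: dict[str, MappingRecord] = {}
        for loc in catalog:
            lid = loc.locus_id
            born_before = age_of[lid] > t
            lost = rng.random() < config.retention_loss_prob
            if sp.species_id in pan_pair and lid in pan_lost:
                lost = True
            if born_before and not lost:
                present.add(lid)
                ident_d = float(
                    np.clip(1.0 - config.identity_decay * t
                            + rng.normal(0.0, config.identity_sigma), 0.0, 1.0)
                )
                ident_r = float(
                    np.clip(1.0 - config.identity_decay * t
                            + rng.normal(0.0, config.identity_sigma), 0.0, 1.0)
                )
                dmap[lid] = MappingRecord(
                    locus_id=lid,
                    query_species="Human",
                    target_species=sp.species_id,
                    n_hits=1,
                    mapped_chrom=loc.chrom,
                    mapped_start=loc.start,
                    mapped_end=loc.end,
                    identity=ident_d,
                    intersects_chain=True,
                )
                if rng.random() < config.reciprocal_failure_prob:
                    rfail.add(lid)
                    back = (loc.chrom, loc.start + 5000, loc.end + 5000)
                else:
                    back = (loc.chrom, loc.start, loc.end)
                rmap[lid] = MappingRecord(
                    locus_id=lid,
                    query_species=sp.species_id,
                    target_species="Human",
                    n_hits=1,
                    mapped_chrom=back[0],
                    mapped_start=back[1],
                    mapped_end=back[2],
                    identity=ident_r,
                    intersects_chain=True,
                )
            else:
                dmap[lid] = MappingRecord(
                    locus_id=lid,
                    query_species="Human",
                    target_species=sp.species_id,
                    n_hits=0,
                    intersects_chain=bool(rng.random() < config.residual_chain_prob),
                )
        truth_present[sp.species_id] = present
        truth_rfail[sp.species_id] = rfail
        direct[sp.species_id] = dmap
        reciprocal[sp.species_id] = rmap

    return LocusHistory(
        config=config,
        catalog=catalog,
        ages=age_of,
        truth_present=truth_present,
        truth_reciprocal_fail=truth_rfail,
        planted_pan_losses=pan_lost,
        direct=direct,
        reciprocal=reciprocal,
    )


def simulate_gene_universe(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[GeneRecord]:
    """Gene universe with OS, synaptic and fetal-gonad category flags."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.universe_size
    chrom_names = config.chrom_names()
    chroms = rng.integers(0, config.n_chromosomes, n)
    tss = rng.integers(10_000, config.chrom_size - 10_000, n)
    strands = rng.choice(np.array(["+", "-"]), n)
    os_flags = rng.random(n) < config.os_fraction
    synaptic = set(rng.choice(n, size=min(config.synaptic_count, n), replace=False))
    gonad = set(rng.choice(n, size=min(config.fetal_gonad_count, n), replace=False))
    genes = []
    for i in range(n):
        cats = set()
        if os_flags[i]:
            cats.add("OS")
        if i in synaptic:
            cats.add("SYNAPTIC")
        if i in gonad:
            cats.add("FETAL_GONAD_MARKER")
        genes.append(
            GeneRecord(
                symbol=f"GENE{i:05d}",
                chrom=chrom_names[chroms[i]],
                tss=int(tss[i]),
                strand=str(strands[i]),
                categories=frozenset(cats),
            )
        )
    return genes


def simulate_perturbation_response(
    linked: Collection[str],
    universe: Collection[str],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    experiments: tuple[str, ...] = ("CRISPRI", "SILENCING"),
) -> dict[str, set[str]]:
    """Perturbation-response gene sets enriched among linked genes.

    Each gene responds with ``linked_response_prob`` when linked, else
    ``unlinked_response_prob``; responders are spread over the named
    experiments (every responder lands in at least one), so the union
    of the experiment sets recovers the planted probabilities.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    linked = set(linked)
    if not linked <= set(universe):
        raise ValueError("linked genes must be inside the universe")
    sets: dict[str, set[str]] = {name: set() for name in experiments}
    for symbol in sorted(universe):
        p = config.linked_response_prob if symbol in linked else config.unlinked_response_prob
        if rng.random() < p:
            members = [name for name in experiments if rng.random() < 0.7]
            if not members:
                members = [experiments[int(rng.integers(len(experiments)))]]
            for name in members:
                sets[name].add(symbol)
    return sets


@dataclass
class SyntheticDataset:
    """A full set of pipeline inputs plus the generator's truth."""

    config: SimulationConfig
    history: LocusHistory
    genes: list[GeneRecord]
    response_sets: dict[str, set[str]] | None = None


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate the locus history and a matching gene universe."""
    history = simulate_locus_history(config)
    genes = simulate_gene_universe(config)
    return SyntheticDataset(config=config, history=history, genes=genes)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write all inputs in the package's interchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ltrio.write_locus_bed(dataset.history.catalog, outdir / "catalog.bed")
    ltrio.write_gene_table(dataset.genes, outdir / "genes.tsv")
    ltrio.write_species_panel(dataset.config.panel, outdir / "species.tsv")
    for sp, dmap in dataset.history.direct.items():
        ltrio.write_mapping_table(dmap.values(), outdir / f"direct_{sp}.tsv")
    for sp, rmap in dataset.history.reciprocal.items():
        ltrio.write_mapping_table(rmap.values(), outdir / f"reciprocal_{sp}.tsv")
    if dataset.response_sets:
        for name, genes in dataset.response_sets.items():
            ltrio.write_gene_list(genes, outdir / f"response_{name}.txt")
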