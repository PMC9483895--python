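"""End-to-end orchestration: files in, diff-able TSV reports out.

``run_pipeline`` drives every stage over a directory of inputs laid out
as the synthetic-data writer emits them (``catalog.bed``, ``genes.tsv``,
``species.tsv``, ``direct_<species>.tsv``, ``reciprocal_<species>.tsv``,
optional ``response_<name>.txt``) and writes one TSV per stage, each
with a one-line provenance header carrying the tool version and a hash
of the configuration.  The pipeline is a pure function of its inputs
and configuration: reruns produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as ltrio
from .abundance import (
    UndefinedProfileError,
    profile_correlation,
    resemblance_vs_divergence,
    subfamily_profile,
)
from .association import assign_loci, build_domains, genes_with_min_loci
from .conservation import (
    classify_batch,
    classify_human_specific,
    conserved_count_matrix,
    gains_losses,
)
from .dating import AcquisitionRateModel
from .enrichment import category_enrichment, round_half_up
from .reported import replay_printed_tables
from .targets import coverage_fraction, high_confidence_targets

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "replay_printed_tables"]

logger = logging.getLogger("ltrkit")


class PipelineError(Exception):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    input_dir: Path
    output_dir: Path
    family: str = "LTR7"
    min_identity: float = 0.95
    hs_identity_cutoff: float = 0.10
    slop: int = 0
    basal_up: int = 5_000
    basal_down: int = 1_000
    max_extension: int = 1_000_000
    min_loci: int = 2
    anchor_time: float = 29.0
    pan_species: tuple[str, str] = ("Chimpanzee", "Bonobo")
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.hs_identity_cutoff <= 1:
            raise ValueError("hs_identity_cutoff must be in (0, 1]")
        for name in ("basal_up", "basal_down", "max_extension", "min_loci"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def config_hash(self) -> str:
        # only analysis parameters: identical settings on identical inputs
        # must yield identical reports wherever they are written
        skip = {"input_dir", "output_dir"}
        text = "|".join(
            f"{f.name}={getattr(self, f.name)}"
            for f in fields(self)
            if f.name not in skip
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ltrkit {__version__} config={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the mapping of report name to path.

    Raises :class:`PipelineError` naming the failed stage.  Input files
    are all checked before any stage runs.
    """
    indir, outdir = config.input_dir, config.output_dir
    required = ["catalog.bed", "genes.tsv", "species.tsv"]
    missing = [f for f in required if not (indir / f).exists()]
    if missing:
        raise PipelineError(f"startup: missing input files {missing} in {indir}")
    panel = ltrio.read_species_panel(indir / "species.tsv")
    for sp in panel.non_reference:
        for prefix in ("direct", "reciprocal"):
            p = indir / f"{prefix}_{sp.species_id}.tsv"
            if not p.exists():
                raise PipelineError(f"startup: missing mapping table {p}")
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("load")
        catalog = ltrio.read_locus_bed(indir / "catalog.bed", config.family)
        genes = ltrio.read_gene_table(indir / "genes.tsv")
        direct = {
            sp.species_id: {
                r.locus_id: r
                for r in ltrio.read_mapping_table(
                    indir / f"direct_{sp.species_id}.tsv"
                )
            }
            for sp in panel.non_reference
        }
        reciprocal = {
            sp.species_id: {
                r.locus_id: r
                for r in ltrio.read_mapping_table(
                    indir / f"reciprocal_{sp.species_id}.tsv"
                )
            }
            for sp in panel.non_reference
        }
        response_sets = {
            p.stem.removeprefix("response_"): ltrio.read_gene_list(p)
            for p in sorted(indir.glob("response_*.txt"))
        }
        logger.info("loaded %d loci, %d genes, %d species", len(catalog),
                    len(genes), len(panel.entries))
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(f"load: {exc}") from exc

    try:
        stage("conserve")
        calls = []
        for sp in panel.non_reference:
            sp_calls = classify_batch(
                catalog,
                sp.species_id,
                direct[sp.species_id],
                {
                    lid: reciprocal[sp.species_id].get(lid)
                    for lid in direct[sp.species_id]
                },
                min_identity=config.min_identity,
                slop=config.slop,
            )
            calls.extend(sp_calls)
        matrix = conserved_count_matrix(calls, catalog, panel)
        calls_df = pd.DataFrame(
            {
                "locus_id": [c.locus_id for c in calls],
                "species": [c.species for c in calls],
                "status": [c.status.value for c in calls],
            }
        )
        _write_tsv(calls_df, outdir / "conservation_calls.tsv", config)
        matrix_df = matrix.counts.reset_index(names="species")
        _write_tsv(matrix_df, outdir / "conserved_counts.tsv", config)
        gl = gains_losses(matrix)
        _write_tsv(
            pd.DataFrame(
                {
                    "species": [g.species for g in gl],
                    "gain": [g.gain for g in gl],
                    "loss": [g.loss for g in gl],
                }
            ),
            outdir / "gains_losses.tsv",
            config,
        )
        outputs["conservation_calls"] = outdir / "conservation_calls.tsv"
        outputs["conserved_counts"] = outdir / "conserved_counts.tsv"
        outputs["gains_losses"] = outdir / "gains_losses.tsv"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"conserve: {exc}") from exc

    try:
        stage("human_specific")
        pan_a, pan_b = config.pan_species
        if pan_a in panel and pan_b in panel:
            hs_calls = [
                classify_human_specific(
                    locus,
                    [direct[pan_a][locus.locus_id]],
                    [direct[pan_b][locus.locus_id]],
                    hs_identity_cutoff=config.hs_identity_cutoff,
                )
                for locus in catalog
            ]
            hs_df = pd.DataFrame(
                {
                    "locus_id": [h.locus_id for h in hs_calls],
                    "human_specific": [int(h.human_specific) for h in hs_calls],
                    "bona_fide": [int(h.bona_fide) for h in hs_calls],
                }
            )
            _write_tsv(hs_df, outdir / "human_specific.tsv", config)
            outputs["human_specific"] = outdir / "human_specific.tsv"
    except Exception as exc:
        raise PipelineError(f"human_specific: {exc}") from exc

    try:
        stage("profile")
        profiles = {}
        for sp in [panel.reference, *panel.non_reference]:
            try:
                profiles[sp.species_id] = subfamily_profile(matrix, sp.species_id)
            except UndefinedProfileError:
                logger.warning("%s: zero conserved loci, excluded from profiles",
                               sp.species_id)
        prof_rows = [
            {"species": p.species, **dict(zip(p.subfamilies, p.values))}
            for p in profiles.values()
        ]
        _write_tsv(pd.DataFrame(prof_rows), outdir / "profiles.tsv", config)
        pair_rows = []
        ids = list(profiles)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                pair_rows.append(
                    {"species_a": a, "species_b": b,
                     "r": profile_correlation(profiles[a], profiles[b])}
                )
        _write_tsv(pd.DataFrame(pair_rows), outdir / "profile_correlations.tsv", config)
        pairs, r_assoc = resemblance_vs_divergence(profiles, panel)
        res_df = pd.DataFrame(
            pairs, columns=["species", "divergence_mya", "r_to_reference"]
        )
        res_df["r_divergence_vs_resemblance"] = r_assoc
        _write_tsv(res_df, outdir / "resemblance.tsv", config)
        outputs["profiles"] = outdir / "profiles.tsv"
        outputs["profile_correlations"] = outdir / "profile_correlations.tsv"
        outputs["resemblance"] = outdir / "resemblance.tsv"
    except Exception as exc:
        raise PipelineError(f"profile: {exc}") from exc

    try:
        stage("date")
        anchors = [
            sp.species_id
            for sp in panel.non_reference
            if sp.divergence_mya == config.anchor_time
        ]
        if anchors:
            results = AcquisitionRateModel.from_count_matrix(
                matrix, anchors, config.anchor_time
            ).fit()
            counts = [
                (sp.species_id, matrix.count(sp.species_id))
                for sp in panel.non_reference
            ]
            report = results.report(counts)
            report["true_divergence_mya"] = [
                panel.divergence_of(sp) for sp, _ in counts
            ]
            _write_tsv(report, outdir / "dating.tsv", config)
            outputs["dating"] = outdir / "dating.tsv"
        else:
            logger.warning("no anchor species at %s MYA; dating skipped",
                           config.anchor_time)
    except Exception as exc:
        raise PipelineError(f"date: {exc}") from exc

    try:
        stage("associate")
        domains = build_domains(
            genes,
            basal_up=config.basal_up,
            basal_down=config.basal_down,
            max_extension=config.max_extension,
        )
        table = assign_loci(catalog, domains)
        assoc_rows = [
            {"locus_id": lid, "gene": g}
            for lid, gs in sorted(table.locus_to_genes.items())
            for g in sorted(gs)
        ]
        _write_tsv(pd.DataFrame(assoc_rows, columns=["locus_id", "gene"]),
                   outdir / "association.tsv", config)
        count_rows = sorted(table.gene_locus_counts.items())
        _write_tsv(
            pd.DataFrame(count_rows, columns=["gene", "locus_count"]),
            outdir / "gene_locus_counts.tsv",
            config,
        )
        outputs["association"] = outdir / "association.tsv"
        outputs["gene_locus_counts"] = outdir / "gene_locus_counts.tsv"
        linked = table.linked_genes
        logger.info("associate: %d loci -> %d linked genes (%d unlinked loci)",
                    len(catalog), len(linked), len(table.unlinked_loci))
    except Exception as exc:
        raise PipelineError(f"associate: {exc}") from exc

    try:
        stage("enrich")
        universe = {g.symbol for g in genes}
        enrich_rows = []
        for flag in ("OS", "SYNAPTIC", "FETAL_GONAD_MARKER"):
            category = {g.symbol for g in genes if flag in g.categories}
            if not category:
                continue
            res = category_enrichment(linked, category, universe)
            enrich_rows.append(
                {
                    "category": flag,
                    "linked_total": res.a + res.b,
                    "linked_in_category": res.a,
                    "observed_pct": round_half_up(res.observed_pct, 2),
                    "expected_pct": round_half_up(res.expected_pct, 2),
                    "enrichment": round_half_up(res.enrichment, 2),
                    "p_two_sided": res.p_two_sided,
                }
            )
        _write_tsv(pd.DataFrame(enrich_rows), outdir / "enrichment.tsv", config)
        outputs["enrichment"] = outdir / "enrichment.tsv"
    except Exception as exc:
        raise PipelineError(f"enrich: {exc}") from exc

    try:
        stage("targets")
        if response_sets:
            hc = high_confidence_targets(linked, response_sets.values())
            multi = genes_with_min_loci(table, config.min_loci)
            hc_multi = high_confidence_targets(multi, response_sets.values())
            target_rows = [
                {
                    "set": "linked",
                    "size": len(linked),
                    "high_confidence": len(hc),
                    "pct": round_half_up(coverage_fraction(hc, linked), 2)
                    if linked else 0.0,
                },
                {
                    "set": f"linked_min_{config.min_loci}_loci",
                    "size": len(multi),
                    "high_confidence": len(hc_multi),
                    "pct": round_half_up(coverage_fraction(hc_multi, multi), 2)
                    if multi else 0.0,
                },
            ]
            _write_tsv(pd.DataFrame(target_rows), outdir / "targets.tsv", config)
            outputs["targets"] = outdir / "targets.tsv"
    except Exception as exc:
        raise PipelineError(f"targets: {exc}") from exc

    return outputs
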