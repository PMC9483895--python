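"""Reciprocal-mapping conservation rule and human-specific classification."""

import numpy as np
import pytest

from ltrkit.conservation import (
    classify_batch,
    classify_conservation,
    classify_human_specific,
    conserved_count_matrix,
    gains_losses,
)
from ltrkit.types import (
    ConservationStatus,
    ContractError,
    LTRLocus,
    MappingRecord,
    Species,
    SpeciesPanel,
)

LOCUS = LTRLocus("L1", "LTR7", "LTR7Y", "chr1", 1000, 1450)


def direct(n_hits=1, identity=0.97, chain=True):
    return MappingRecord(
        "L1", "Human", "Chimpanzee", n_hits,
        "chr5" if n_hits else None, 2000 if n_hits else None,
        2450 if n_hits else None, identity if n_hits else None,
        intersects_chain=chain if not n_hits else True,
    )


def reciprocal(n_hits=1, identity=0.96, start=1000, end=1450, chrom="chr1"):
    return MappingRecord(
        "L1", "Chimpanzee", "Human", n_hits,
        chrom if n_hits else None, start if n_hits else None,
        end if n_hits else None, identity if n_hits else None,
        intersects_chain=bool(n_hits),
    )


class TestConservationRule:
    @pytest.mark.parametrize(
        "d, r, expected",
        [
            # both requirements met
            (direct(), reciprocal(), ConservationStatus.HIGHLY_CONSERVED),
            # direct identity below threshold
            (direct(identity=0.94), reciprocal(), ConservationStatus.DIVERGED),
            # single-orthologous-locus requirement fails on a multi-hit
            (direct(n_hits=2, identity=0.99), reciprocal(), ConservationStatus.DIVERGED),
            # reciprocal identity below threshold
            (direct(), reciprocal(identity=0.90), ConservationStatus.DIVERGED),
            # reciprocal lands elsewhere
            (direct(), reciprocal(start=9000, end=9450), ConservationStatus.DIVERGED),
            (direct(), reciprocal(chrom="chr9"), ConservationStatus.DIVERGED),
            # reciprocal multi-hit
            (direct(), reciprocal(n_hits=2), ConservationStatus.DIVERGED),
            # reciprocal missing entirely
            (direct(), None, ConservationStatus.DIVERGED),
            # no direct hit at all
            (direct(n_hits=0), None, ConservationStatus.ABSENT),
            (None, None, ConservationStatus.ABSENT),
        ],
    )
    def test_rule(self, d, r, expected):
        call = classify_conservation(LOCUS, d, r, species="Chimpanzee")
        assert call.status is expected

    def test_boundary_identity_is_conserved(self):
        call = classify_conservation(LOCUS, direct(identity=0.95), reciprocal(identity=0.95))
        assert call.status is ConservationStatus.HIGHLY_CONSERVED

    def test_slop_tolerates_small_offsets(self):
        r = reciprocal(start=1002, end=1451)
        assert (
            classify_conservation(LOCUS, direct(), r).status
            is ConservationStatus.DIVERGED
        )
        assert (
            classify_conservation(LOCUS, direct(), r, slop=3).status
            is ConservationStatus.HIGHLY_CONSERVED
        )

    def test_reciprocal_without_direct_is_contract_error(self):
        with pytest.raises(ContractError):
            classify_conservation(LOCUS, None, reciprocal())
        with pytest.raises(ContractError):
            classify_conservation(LOCUS, direct(n_hits=0), reciprocal())

    def test_lower_threshold_never_loses_conserved_calls(self, small_dataset):
        """Monotonicity: relaxing min_identity can only add conserved loci."""
        history = small_dataset.history
        catalog = history.catalog
        counts = []
        for thr in (0.99, 0.95, 0.80, 0.50):
            n = 0
            for sp in history.direct:
                calls = classify_batch(
                    catalog, sp, history.direct[sp],
                    {lid: history.reciprocal[sp].get(lid) for lid in history.direct[sp]},
                    min_identity=thr,
                )
                n += sum(
                    c.status is ConservationStatus.HIGHLY_CONSERVED for c in calls
                )
            counts.append(n)
        assert counts == sorted(counts)

    def test_batch_equals_per_record_rule_text(self, small_dataset):
        """Oracle: batch classification equals a literal re-evaluation of
        the two-requirement rule, record by record."""
        history = small_dataset.history
        sp = "Gorilla"
        calls = classify_batch(
            history.catalog, sp, history.direct[sp],
            {lid: history.reciprocal[sp].get(lid) for lid in history.direct[sp]},
        )
        by_id = {c.locus_id: c for c in calls}
        for locus in history.catalog:
            d = history.direct[sp].get(locus.locus_id)
            r = history.reciprocal[sp].get(locus.locus_id)
            if d is None or d.n_hits == 0:
                expected = ConservationStatus.ABSENT
            elif (
                d.n_hits == 1 and d.identity >= 0.95
                and r is not None and r.n_hits == 1 and r.identity >= 0.95
                and r.mapped_interval == locus.interval
            ):
                expected = ConservationStatus.HIGHLY_CONSERVED
            else:
                expected = ConservationStatus.DIVERGED
            assert by_id[locus.locus_id].status is expected, locus.locus_id


class TestHumanSpecific:
    def test_no_hits_no_chains_is_bona_fide(self):
        no_hit = MappingRecord("L1", "Human", "x", 0, intersects_chain=False)
        call = classify_human_specific(LOCUS, [no_hit], [no_hit])
        assert call.human_specific and call.bona_fide

    def test_substantial_hit_in_one_species_defeats(self):
        hit = MappingRecord("L1", "Human", "x", 1, "chr1", 0, 450, 0.50, True)
        no_hit = MappingRecord("L1", "Human", "x", 0, intersects_chain=False)
        call = classify_human_specific(LOCUS, [hit], [no_hit])
        assert not call.human_specific and not call.bona_fide

    def test_residual_chain_defeats_bona_fide_only(self):
        chain_only = MappingRecord("L1", "Human", "x", 0, intersects_chain=True)
        no_hit = MappingRecord("L1", "Human", "x", 0, intersects_chain=False)
        call = classify_human_specific(LOCUS, [chain_only], [no_hit])
        assert call.human_specific and not call.bona_fide

    def test_sub_cutoff_hit_still_human_specific(self):
        weak = MappingRecord("L1", "Human", "x", 1, "chr1", 0, 450, 0.05, True)
        call = classify_human_specific(LOCUS, [weak], [weak])
        assert call.human_specific and not call.bona_fide


def toy_matrix():
    panel = SpeciesPanel(
        (
            Species("Human", "ref", 0.0, is_reference=True),
            Species("X", "other", 10.0),
        )
    )
    catalog = [
        LTRLocus(f"L{i}", "LTR7", "LTR7Y", "chr1", i * 1000, i * 1000 + 450)
        for i in range(10)
    ]
    calls = [
        classify_conservation(
            loc,
            MappingRecord(loc.locus_id, "Human", "X", 1, "chr1", 0, 450,
                          0.99 if i < 4 else 0.50, True),
            MappingRecord(loc.locus_id, "X", "Human", 1, loc.chrom, loc.start,
                          loc.end, 0.99 if i < 4 else 0.50, True),
        )
        for i, loc in enumerate(catalog)
    ]
    return conserved_count_matrix(calls, catalog, panel), catalog, panel


class TestCountMatrix:
    def test_toy_counts_and_percentages(self):
        matrix, _, _ = toy_matrix()
        assert matrix.count("X") == 4
        assert matrix.percentages().at["X", "total"] == pytest.approx(40.0)

    def test_reference_row_is_catalog(self):
        matrix, catalog, _ = toy_matrix()
        assert matrix.count("Human") == len(catalog)
        assert matrix.percentages().at["Human", "total"] == pytest.approx(100.0)

    def test_missing_pairs_reported(self):
        matrix, catalog, panel = toy_matrix()
        calls = [
            classify_conservation(loc, None, None, species="X")
            for loc in catalog[:-1]
        ]
        with pytest.raises(ValueError, match="lack conservation calls"):
            conserved_count_matrix(calls, catalog, panel)

    def test_matrix_matches_generator_truth(self, small_dataset):
        """Counts equal the generator's bookkeeping minus planted
        reciprocity failures and identity jitter casualties."""
        history = small_dataset.history
        calls = []
        for sp in history.direct:
            calls.extend(
                classify_batch(
                    history.catalog, sp, history.direct[sp],
                    {lid: history.reciprocal[sp].get(lid)
                     for lid in history.direct[sp]},
                )
            )
        matrix = conserved_count_matrix(
            calls, history.catalog, small_dataset.config.panel
        )
        for sp in history.direct:
            truth = history.truth_conserved(sp)
            # jitter may push a handful of identities below threshold
            assert abs(matrix.count(sp) - len(truth)) <= 0.01 * max(len(truth), 1)

    def test_gains_plus_losses_equal_reference_total(self, small_dataset):
        history = small_dataset.history
        calls = []
        for sp in history.direct:
            calls.extend(
                classify_batch(
                    history.catalog, sp, history.direct[sp],
                    {lid: history.reciprocal[sp].get(lid)
                     for lid in history.direct[sp]},
                )
            )
        matrix = conserved_count_matrix(
            calls, history.catalog, small_dataset.config.panel
        )
        for rec in gains_losses(matrix):
            assert rec.gain + rec.loss == len(history.catalog)
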