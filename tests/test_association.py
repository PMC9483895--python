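"""Basal-plus-extension domain construction and locus assignment."""

import numpy as np
import pytest

from ltrkit.association import (
    assign_loci,
    build_domains,
    genes_with_min_loci,
)
from ltrkit.types import GeneRecord, LTRLocus, ValidationError


def gene(symbol, tss, strand="+", chrom="chr1"):
    return GeneRecord(symbol, chrom, tss, strand)


def locus(lid, start, end, chrom="chr1"):
    return LTRLocus(lid, "LTR7", "LTR7Y", chrom, start, end)


# ---------------------------------------------------------------------------
# independent brute-force oracle: the extension on each side is the largest
# distance (up to max_extension) whose flank interval avoids every other
# gene's basal domain; everything evaluated pairwise, no sorting tricks
# ---------------------------------------------------------------------------

def oracle_domains(genes, basal_up, basal_down, max_extension):
    def basal(g):
        if g.strand == "+":
            s, e = g.tss - basal_up, g.tss + basal_down
        else:
            s, e = g.tss - basal_down, g.tss + basal_up
        s = max(0, s)
        return s, max(e, s + 1)

    out = {}
    for g in genes:
        bs, be = basal(g)
        left = min(bs, max_extension)
        right = max_extension
        for other in genes:
            if other.symbol == g.symbol or other.chrom != g.chrom:
                continue
            obs, obe = basal(other)
            if obs < bs:
                left = min(left, bs - min(obe, bs))
            if obe > be:
                right = min(right, max(obs, be) - be)
        out[g.symbol] = (g.chrom, bs, be, bs - left, be + right)
    return out


def oracle_assign(loci, domains, mode="overlap"):
    links = {}
    for loc in loci:
        hit = set()
        for sym, (chrom, _, _, es, ee) in domains.items():
            if chrom != loc.chrom:
                continue
            if mode == "overlap":
                if loc.start < ee and es < loc.end:
                    hit.add(sym)
            else:
                mid = (loc.start + loc.end) // 2
                if es <= mid < ee:
                    hit.add(sym)
        links[loc.locus_id] = hit
    return links


class TestDomainConstruction:
    def test_single_gene_defaults(self):
        (d,) = build_domains([gene("A", 100_000)])
        assert (d.basal_start, d.basal_end) == (95_000, 101_000)
        assert (d.ext_start, d.ext_end) == (0, 1_101_000)

    def test_minus_strand_mirror(self):
        (d,) = build_domains([gene("A", 100_000, strand="-")])
        assert (d.basal_start, d.basal_end) == (99_000, 105_000)

    def test_chromosome_end_clips(self):
        (d,) = build_domains(
            [gene("A", 100_000)], chrom_sizes={"chr1": 500_000}
        )
        assert d.ext_end == 500_000

    def test_two_close_genes_truncate_each_other(self):
        genes = [gene("A", 100_000), gene("B", 110_000)]
        domains = {d.symbol: d for d in build_domains(genes)}
        expected = oracle_domains(genes, 5000, 1000, 1_000_000)
        for sym, d in domains.items():
            assert (d.chrom, d.basal_start, d.basal_end, d.ext_start, d.ext_end) \
                == expected[sym]
        # A's right extension stops at B's basal start, and vice versa
        assert domains["A"].ext_end == domains["B"].basal_start
        assert domains["B"].ext_start == domains["A"].basal_end

    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_domains([gene("A", 1000), gene("A", 2000)])

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = int(rng.integers(1, 30))
            genes = [
                gene(
                    f"g{i}",
                    int(rng.integers(0, 300_000)),
                    strand=str(rng.choice(["+", "-"])),
                    chrom=f"chr{rng.integers(1, 3)}",
                )
                for i in range(n)
            ]
            up, down = int(rng.integers(1, 8000)), int(rng.integers(1, 3000))
            ext = int(rng.integers(1000, 100_000))
            got = {
                d.symbol: (d.chrom, d.basal_start, d.basal_end, d.ext_start, d.ext_end)
                for d in build_domains(genes, up, down, ext)
            }
            assert got == oracle_domains(genes, up, down, ext)


class TestAssignment:
    def test_locus_in_basal_domain_is_linked(self):
        domains = build_domains([gene("A", 100_000), gene("B", 2_500_000)])
        table = assign_loci([locus("L1", 96_000, 96_450)], domains)
        assert "A" in table.genes_of("L1")

    def test_distant_locus_is_unlinked(self):
        domains = build_domains([gene("A", 100_000)])
        table = assign_loci([locus("L1", 2_200_000, 2_200_450)], domains)
        assert table.genes_of("L1") == frozenset()
        assert table.unlinked_loci == {"L1"}

    def test_one_bp_overlap_suffices(self):
        domains = build_domains([gene("A", 100_000)])  # extended ends 1_101_000
        table = assign_loci([locus("L1", 1_100_999, 1_101_400)], domains)
        assert table.genes_of("L1") == {"A"}
        table = assign_loci([locus("L2", 1_101_000, 1_101_400)], domains)
        assert table.genes_of("L2") == frozenset()

    def test_midpoint_mode(self):
        domains = build_domains([gene("A", 100_000)])
        straddling = locus("L1", 1_100_800, 1_101_600)  # midpoint 1_101_200
        assert assign_loci([straddling], domains).genes_of("L1") == {"A"}
        assert (
            assign_loci([straddling], domains, mode="midpoint").genes_of("L1")
            == frozenset()
        )

    def test_toy_chromosome_matches_all_pairs_oracle(self):
        genes = [gene("A", 50_000), gene("B", 80_000), gene("C", 300_000)]
        loci = [
            locus("L1", 45_000, 45_450),
            locus("L2", 79_500, 79_950),
            locus("L3", 120_000, 120_450),
            locus("L4", 1_200_000, 1_200_450),
            locus("L5", 299_000, 299_450),
        ]
        domains = build_domains(genes)
        table = assign_loci(loci, domains)
        dom_map = oracle_domains(genes, 5000, 1000, 1_000_000)
        assert {lid: set(gs) for lid, gs in table.locus_to_genes.items()} \
            == oracle_assign(loci, dom_map)

    def test_growing_extension_never_removes_links(self):
        rng = np.random.default_rng(3)
        genes = [gene(f"g{i}", int(rng.integers(0, 400_000))) for i in range(12)]
        loci = [
            locus(f"L{i}", int(s := rng.integers(0, 400_000)), int(s + 450))
            for i in range(60)
        ]
        previous: dict[str, frozenset] = {}
        for ext in (1000, 10_000, 100_000, 1_000_000):
            table = assign_loci(loci, build_domains(genes, max_extension=ext))
            for lid, gs in table.locus_to_genes.items():
                assert previous.get(lid, frozenset()) <= gs
            previous = table.locus_to_genes


class TestGeneLocusCounts:
    def test_min_loci_filter(self):
        genes = [gene("A", 50_000), gene("B", 3_000_000, chrom="chr2")]
        loci = [
            locus("L1", 49_000, 49_450),
            locus("L2", 51_000, 51_450),
            locus("L3", 3_000_500, 3_000_950, chrom="chr2"),
        ]
        table = assign_loci(loci, build_domains(genes))
        assert genes_with_min_loci(table, 1) == {"A", "B"}
        assert genes_with_min_loci(table, 2) == {"A"}
        with pytest.raises(ValueError):
            genes_with_min_loci(table, 0)

    def test_counts_consistent_with_multimap(self, small_dataset):
        domains = build_domains(small_dataset.genes)
        table = assign_loci(small_dataset.history.catalog, domains)
        recount: dict[str, int] = {}
        for gs in table.locus_to_genes.values():
            for g in gs:
                recount[g] = recount.get(g, 0) + 1
        assert table.gene_locus_counts == recount
        for k in (1, 2, 3):
            assert genes_with_min_loci(table, k) == {
                g for g, n in recount.items() if n >= k
            }
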