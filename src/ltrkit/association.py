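"""Regulatory-domain construction and locus-to-gene assignment.

Each gene gets a basal regulatory domain around its TSS (default 5 kb
upstream / 1 kb downstream, orientation-aware) which is then extended
on each side up to a maximum distance (default 1 Mb) but never into a
neighbouring gene's basal domain.  A distal locus is associated with
every gene whose extended domain it overlaps by at least one base
(optionally: whose domain contains the locus midpoint).  This is the
"basal plus extension" association rule popularised by the GREAT tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .types import GeneRecord, LTRLocus, ValidationError

__all__ = [
    "RegulatoryDomain",
    "AssociationTable",
    "build_domains",
    "assign_loci",
    "genes_with_min_loci",
]

DEFAULT_BASAL_UP = 5_000
DEFAULT_BASAL_DOWN = 1_000
DEFAULT_MAX_EXTENSION = 1_000_000


@dataclass(frozen=True)
class RegulatoryDomain:
    """Basal and extended regulatory intervals of one gene (half-open)."""

    symbol: str
    chrom: str
    basal_start: int
    basal_end: int
    ext_start: int
    ext_end: int

    def __post_init__(self) -> None:
        if not (self.ext_start <= self.basal_start < self.basal_end <= self.ext_end):
            raise ValidationError(
                f"{self.symbol}: basal domain must lie within the extended domain"
            )


def _basal_interval(gene: GeneRecord, basal_up: int, basal_down: int) -> tuple[int, int]:
    if gene.strand == "+":
        start, end = gene.tss - basal_up, gene.tss + basal_down
    else:
        start, end = gene.tss - basal_down, gene.tss + basal_up
    return max(0, start), max(end, max(0, start) + 1)


def build_domains(
    genes: Sequence[GeneRecord],
    basal_up: int = DEFAULT_BASAL_UP,
    basal_down: int = DEFAULT_BASAL_DOWN,
    max_extension: int = DEFAULT_MAX_EXTENSION,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Construct basal-plus-extension regulatory domains for all genes.

    Extension on each side stops at the nearer of ``max_extension`` from
    the basal boundary and the closest neighbouring basal-domain
    boundary; chromosome ends (0 and ``chrom_sizes``, when given) clip
    the result.  Overlapping basal domains never shrink a gene's own
    basal domain: extensions are clipped so the basal interval is always
    contained in the extended interval.
    """
    symbols = [g.symbol for g in genes]
    if len(set(symbols)) != len(symbols):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValidationError(f"duplicate gene symbols: {dupes}")

    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    domains: list[RegulatoryDomain] = []
    for chrom, chrom_genes in by_chrom.items():
        chrom_genes = sorted(chrom_genes, key=lambda g: (g.tss, g.symbol))
        basal = np.array(
            [_basal_interval(g, basal_up, basal_down) for g in chrom_genes]
        )
        bs, be = basal[:, 0], basal[:, 1]
        chrom_end = chrom_sizes.get(chrom) if chrom_sizes else None
        n = len(chrom_genes)

        # The extension on each side is the largest distance (<= max_extension)
        # whose interval avoids every OTHER basal domain.  Left side: the
        # binding neighbour is the largest basal end among genes whose basal
        # starts strictly left of ours (clipped at our basal start); right
        # side, symmetrically, the smallest basal start among genes whose
        # basal ends strictly right of ours (clipped at our basal end).
        order_s = np.argsort(bs, kind="stable")
        pref_max = np.concatenate(([-np.inf], np.maximum.accumulate(be[order_s])))
        k_left = np.searchsorted(bs[order_s], bs, side="left")
        left_nb = np.minimum(pref_max[k_left], bs)

        order_e = np.argsort(be, kind="stable")
        suf_min = np.concatenate(
            (np.minimum.accumulate(bs[order_e][::-1])[::-1], [np.inf])
        )
        k_right = np.searchsorted(be[order_e], be, side="right")
        right_nb = np.maximum(suf_min[k_right], be)

        ext_start = np.maximum.reduce([bs - max_extension, left_nb, np.zeros(n)])
        ext_start = np.minimum(ext_start, bs)
        ext_end = np.minimum(be + max_extension, right_nb)
        if chrom_end is not None:
            ext_end = np.minimum(ext_end, chrom_end)
        ext_end = np.maximum(ext_end, be)

        for i, g in enumerate(chrom_genes):
            domains.append(
                RegulatoryDomain(
                    g.symbol, chrom, int(bs[i]), int(be[i]),
                    int(ext_start[i]), int(ext_end[i]),
                )
            )
    return domains


@dataclass
class AssociationTable:
    """Locus->genes multimap with the derived gene->locus-count map."""

    locus_to_genes: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def gene_locus_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for genes in self.locus_to_genes.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return counts

    @property
    def linked_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.locus_to_genes.values():
            out |= genes
        return out

    @property
    def unlinked_loci(self) -> set[str]:
        return {lid for lid, genes in self.locus_to_genes.items() if not genes}

    def genes_of(self, locus_id: str) -> frozenset[str]:
        return self.locus_to_genes[locus_id]


def assign_loci(
    loci: Sequence[LTRLocus],
    domains: Sequence[RegulatoryDomain],
    mode: str = "overlap",
) -> AssociationTable:
    """Link every locus to the genes whose extended domains it touches.

    ``mode="overlap"`` requires >= 1 bp of interval overlap;
    ``mode="midpoint"`` requires the locus midpoint to fall inside the
    domain.  Loci touching nothing are recorded with an empty gene set.
    """
    if mode not in ("overlap", "midpoint"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.chrom, IntervalTree()).addi(d.ext_start, d.ext_end, d.symbol)

    table = AssociationTable()
    for locus in loci:
        tree = trees.get(locus.chrom)
        if tree is None:
            hits: frozenset[str] = frozenset()
        elif mode == "overlap":
            hits = frozenset(iv.data for iv in tree.overlap(locus.start, locus.end))
        else:
            mid = (locus.start + locus.end) // 2
            hits = frozenset(iv.data for iv in tree.at(mid))
        table.locus_to_genes[locus.locus_id] = hits
    return table


def genes_with_min_loci(table: AssociationTable, k: int = 1) -> set[str]:
    """Genes linked by at least ``k`` loci."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return {g for g, n in table.gene_locus_counts.items() if n >= k}


def domains_to_bed(domains: Iterable[RegulatoryDomain], path) -> None:
    """Export extended domains as BED for inspection."""
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chrom}\t{d.ext_start}\t{d.ext_end}\t{d.symbol}\n")
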