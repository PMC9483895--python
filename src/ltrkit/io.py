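"""Readers and writers for the pipeline's plain-text interchange formats.

Formats:

* locus catalogs: 6-column BED; the name field encodes ``locus_id|subfamily``
* mapping tables: TSV with header ``locus_id query_species target_species
  n_hits chrom start end identity intersects_chain``
* gene annotation: TSV with header ``symbol chrom tss strand categories``
  (categories semicolon-separated, may be empty)
* species panels: TSV with header ``species_id clade divergence_mya
  is_reference``
* gene lists: one symbol per line, UTF-8

Writing then reading any of these reproduces the records exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from .types import (
    GeneRecord,
    LTRLocus,
    MappingRecord,
    ParseError,
    Species,
    SpeciesPanel,
    ValidationError,
)

__all__ = [
    "read_locus_bed",
    "write_locus_bed",
    "read_mapping_table",
    "write_mapping_table",
    "read_gene_table",
    "write_gene_table",
    "read_species_panel",
    "write_species_panel",
    "read_gene_list",
    "write_gene_list",
]

MAPPING_COLUMNS = (
    "locus_id",
    "query_species",
    "target_species",
    "n_hits",
    "chrom",
    "start",
    "end",
    "identity",
    "intersects_chain",
)


def read_locus_bed(path: str | Path, family: str) -> list[LTRLocus]:
    """Read a locus catalog from BED.

    The BED name field must be ``locus_id|subfamily``; for LTR5_Hs
    catalogs a bare locus_id is accepted (the subfamily is the family
    itself).
    """
    loci: list[LTRLocus] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: malformed coordinates {start_s!r}/{end_s!r}"
                ) from exc
            if "|" in name:
                locus_id, subfamily = name.split("|", 1)
            else:
                locus_id, subfamily = name, family
            try:
                loci.append(
                    LTRLocus(
                        locus_id=locus_id,
                        family=family,
                        subfamily=subfamily,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return loci


def write_locus_bed(loci: Iterable[LTRLocus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t"
                f"{locus.locus_id}|{locus.subfamily}\t0\t{locus.strand}\n"
            )


def _parse_bool(value: str, where: str) -> bool:
    if value in ("1", "true", "True"):
        return True
    if value in ("0", "false", "False"):
        return False
    raise ParseError(f"{where}: expected boolean, got {value!r}")


def read_mapping_table(path: str | Path) -> list[MappingRecord]:
    records: list[MappingRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != MAPPING_COLUMNS:
            raise ParseError(
                f"{path}: expected header {' '.join(MAPPING_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            where = f"{path}:{lineno}"
            if len(row) != len(MAPPING_COLUMNS):
                raise ParseError(f"{where}: expected {len(MAPPING_COLUMNS)} columns")
            (locus_id, qsp, tsp, n_hits_s, chrom, start_s, end_s,
             identity_s, chain_s) = row
            try:
                n_hits = int(n_hits_s)
            except ValueError as exc:
                raise ParseError(f"{where}: malformed n_hits {n_hits_s!r}") from exc
            mapped = n_hits >= 1
            try:
                records.append(
                    MappingRecord(
                        locus_id=locus_id,
                        query_species=qsp,
                        target_species=tsp,
                        n_hits=n_hits,
                        mapped_chrom=chrom if mapped else None,
                        mapped_start=int(start_s) if mapped else None,
                        mapped_end=int(end_s) if mapped else None,
                        identity=float(identity_s) if mapped else None,
                        intersects_chain=_parse_bool(chain_s, where),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{where}: {exc}") from exc
            except ValidationError as exc:
                raise ValidationError(f"{where}: {exc}") from exc
    return records


def write_mapping_table(records: Iterable[MappingRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(MAPPING_COLUMNS) + "\n")
        for r in records:
            if r.n_hits >= 1:
                chrom, start, end = r.mapped_chrom, r.mapped_start, r.mapped_end
                identity = repr(r.identity)
            else:
                chrom, start, end, identity = ".", ".", ".", "."
            fh.write(
                f"{r.locus_id}\t{r.query_species}\t{r.target_species}\t{r.n_hits}\t"
                f"{chrom}\t{start}\t{end}\t{identity}\t{int(r.intersects_chain)}\n"
            )


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        expected = ("symbol", "chrom", "tss", "strand", "categories")
        if header is None or tuple(header) != expected:
            raise ParseError(f"{path}: expected header {' '.join(expected)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            where = f"{path}:{lineno}"
            if len(row) != 5:
                raise ParseError(f"{where}: expected 5 columns")
            symbol, chrom, tss_s, strand, cats = row
            if symbol in seen:
                raise ValidationError(f"{where}: duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            try:
                tss = int(tss_s)
            except ValueError as exc:
                raise ParseError(f"{where}: malformed tss {tss_s!r}") from exc
            categories = frozenset(c for c in cats.split(";") if c)
            genes.append(GeneRecord(symbol, chrom, tss, strand, categories))
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("symbol\tchrom\ttss\tstrand\tcategories\n")
        for g in genes:
            cats = ";".join(sorted(g.categories))
            fh.write(f"{g.symbol}\t{g.chrom}\t{g.tss}\t{g.strand}\t{cats}\n")


def read_species_panel(path: str | Path) -> SpeciesPanel:
    entries: list[Species] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        expected = ("species_id", "clade", "divergence_mya", "is_reference")
        if header is None or tuple(header) != expected:
            raise ParseError(f"{path}: expected header {' '.join(expected)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            where = f"{path}:{lineno}"
            if len(row) != 4:
                raise ParseError(f"{where}: expected 4 columns")
            species_id, clade, mya_s, ref_s = row
            try:
                mya = float(mya_s)
            except ValueError as exc:
                raise ParseError(f"{where}: malformed divergence_mya {mya_s!r}") from exc
            entries.append(Species(species_id, clade, mya, _parse_bool(ref_s, where)))
    return SpeciesPanel(tuple(entries))


def write_species_panel(panel: SpeciesPanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("species_id\tclade\tdivergence_mya\tis_reference\n")
        for s in panel:
            fh.write(
                f"{s.species_id}\t{s.clade}\t{s.divergence_mya!r}\t{int(s.is_reference)}\n"
            )


def read_gene_list(path: str | Path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(symbols):
            fh.write(s + "\n")


def group_mappings_by_locus(
    records: Sequence[MappingRecord],
) -> dict[str, list[MappingRecord]]:
    grouped: dict[str, list[MappingRecord]] = {}
    for r in records:
        grouped.setdefault(r.locus_id, []).append(r)
    return grouped
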