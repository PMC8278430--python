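"""Target-gene / pathway membership counting.

Takes per-miRNA lists of validated target genes and a gene-set (pathway)
database snapshot in GMT format, and counts which targets fall in which
pathways — per miRNA or pooled over the whole panel — plus overlap
summaries (unique targets, targets shared by several miRNAs) and
per-category rollups of distinct hitting genes.  These are raw membership
counts, not over-representation statistics; an optional hypergeometric
p-value per pathway is available as an extension.

Gene identity is the upper-cased symbol string; no alias resolution is
attempted.  Database snapshots replace live target/pathway web services, so
counts are reproducible for a fixed pair of input files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)

#: miRNA name -> set of upper-cased target gene symbols
TargetMap = dict[str, set[str]]


@dataclass
class GeneSet:
    set_id: str
    description: str
    genes: set[str]


@dataclass
class GeneSetDB:
    """Ordered collection of gene sets with unique ids."""

    sets: list[GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def ids(self) -> list[str]:
        return [s.set_id for s in self.sets]


@dataclass
class EnrichmentRow:
    pathway_id: str
    description: str
    hit_count: int
    hitting_genes: tuple[str, ...]
    contributing_mirnas: tuple[str, ...]


@dataclass
class EnrichmentTable:
    """Pathway membership hits, sorted by hit count desc then pathway id."""

    rows: list[EnrichmentRow]
    genes_in_pathways: int  # distinct targets hitting >= 1 pathway
    pathways_hit: int       # pathways with >= 1 hit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pathway_id": r.pathway_id,
                    "description": r.description,
                    "hit_count": r.hit_count,
                    "hitting_genes": ";".join(r.hitting_genes),
                    "contributing_mirnas": ";".join(r.contributing_mirnas),
                }
                for r in self.rows
            ],
            columns=[
                "pathway_id", "description", "hit_count",
                "hitting_genes", "contributing_mirnas",
            ],
        )


def _split_line(path, lineno: int, line: str, sep: str = "\t") -> list[str]:
    return line.rstrip("\n").rstrip("\r").split(sep)


def read_target_lists(path) -> TargetMap:
    """Read a two-column delimited file (mirna, gene) into a TargetMap.

    Symbols are upper-cased and deduplicated per miRNA; duplicate rows are
    counted and logged.  Tab and comma delimiters are both accepted (tab
    preferred when present).
    """
    targets: TargetMap = {}
    duplicates = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise InputError(f"{path}: missing header line")
        sep = "\t" if "\t" in header else ","
        n_rows = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _split_line(path, lineno, line, sep)
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}: expected two fields (mirna, gene), got {line.rstrip()!r}",
                    line_number=lineno,
                )
            mirna, gene = fields[0].strip(), fields[1].strip().upper()
            bucket = targets.setdefault(mirna, set())
            if gene in bucket:
                duplicates += 1
            bucket.add(gene)
            n_rows += 1
    if duplicates:
        logger.warning("%s: %d duplicate target row(s) collapsed", path, duplicates)
    if n_rows == 0:
        logger.warning("%s: no target rows after the header", path)
    return targets


def read_gmt(path) -> GeneSetDB:
    """Parse a standard GMT file: ``name<TAB>description<TAB>gene...``.

    Blank lines are skipped; duplicate set names and lines with fewer than
    three fields are format errors.  Gene symbols are upper-cased.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_line(path, lineno, line)
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: GMT line needs name, description and >= 1 gene",
                    line_number=lineno,
                )
            set_id, description = fields[0], fields[1]
            if set_id in seen:
                raise ParseError(f"{path}: duplicate gene-set id {set_id!r}", lineno)
            seen.add(set_id)
            genes = {g.strip().upper() for g in fields[2:] if g.strip()}
            if not genes:
                raise ParseError(f"{path}: gene set {set_id!r} is empty", lineno)
            sets.append(GeneSet(set_id, description, genes))
    return GeneSetDB(sets)


def write_gmt(db: GeneSetDB, path) -> None:
    """Write a GeneSetDB back to GMT (genes sorted for stable round-trips)."""
    with open(path, "w") as fh:
        for s in db:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.genes)]) + "\n")


@dataclass
class OverlapSummary:
    unique_targets: int
    multi_mirna_targets: int
    multiplicity: dict[str, int]  # gene -> number of miRNAs targeting it

    def as_dict(self) -> dict:
        return {
            "unique_targets": self.unique_targets,
            "multi_mirna_targets": self.multi_mirna_targets,
        }


def target_overlap_summary(targets: TargetMap) -> OverlapSummary:
    """Unique-target and shared-target counts across the panel's miRNAs."""
    if not targets:
        raise InputError("empty target map")
    multiplicity: dict[str, int] = {}
    for genes in targets.values():
        for g in genes:
            multiplicity[g] = multiplicity.get(g, 0) + 1
    multi = sum(1 for c in multiplicity.values() if c >= 2)
    return OverlapSummary(
        unique_targets=len(multiplicity),
        multi_mirna_targets=multi,
        multiplicity=dict(sorted(multiplicity.items())),
    )


def _hit_table(targets: TargetMap, db: GeneSetDB) -> EnrichmentTable:
    union = set().union(*targets.values()) if targets else set()
    rows: list[EnrichmentRow] = []
    genes_hit: set[str] = set()
    for s in db:
        hits = s.genes & union
        if not hits:
            continue
        contributing = tuple(
            sorted(m for m, genes in targets.items() if genes & hits)
        )
        genes_hit |= hits
        rows.append(
            EnrichmentRow(s.set_id, s.description, len(hits), tuple(sorted(hits)), contributing)
        )
    rows.sort(key=lambda r: (-r.hit_count, r.pathway_id))
    return EnrichmentTable(rows, genes_in_pathways=len(genes_hit), pathways_hit=len(rows))


def pathway_hits(
    targets: TargetMap, db: GeneSetDB, scope: str = "pooled"
) -> EnrichmentTable | dict[str, EnrichmentTable]:
    """Membership hits of targets in pathways.

    ``pooled``: one table for the union of all targets.  ``per_mirna``:
    a table per miRNA, counting only that miRNA's targets.  Pathways with
    zero hits are omitted.
    """
    if not targets or len(db) == 0:
        if scope == "pooled":
            return EnrichmentTable([], 0, 0)
        return {m: EnrichmentTable([], 0, 0) for m in targets}
    if scope == "pooled":
        return _hit_table(targets, db)
    if scope == "per_mirna":
        return {m: _hit_table({m: genes}, db) for m, genes in targets.items()}
    raise ValueError(f"unknown scope {scope!r}")


def hypergeometric_pvalues(
    table: EnrichmentTable, targets: TargetMap, db: GeneSetDB, background_size: int
) -> dict[str, float]:
    """Optional extension: one-sided hypergeometric over-representation
    p-value per hit pathway, against a stated background gene-universe size.
    Membership counting above is the primary output; these p-values are an
    add-on and are not multiplicity-adjusted."""
    union = set().union(*targets.values())
    k = len(union)
    by_id = {s.set_id: s for s in db}
    out = {}
    for row in table.rows:
        pw = by_id[row.pathway_id]
        out[row.pathway_id] = float(
            hypergeom.sf(row.hit_count - 1, background_size, len(pw.genes), k)
        )
    return out


def category_rollup(
    table: EnrichmentTable, category_map: dict[str, str]
) -> dict[str, int]:
    """Distinct hitting genes per named pathway category.

    Pathways missing from ``category_map`` are rolled into
    ``"uncategorized"``.  Returns a category -> distinct-gene-count dict
    (categories with no hits absent).
    """
    genes_by_cat: dict[str, set[str]] = {}
    for row in table.rows:
        cat = category_map.get(row.pathway_id, "uncategorized")
        genes_by_cat.setdefault(cat, set()).update(row.hitting_genes)
    return {cat: len(genes) for cat, genes in sorted(genes_by_cat.items())}


def read_category_map(path) -> dict[str, str]:
    """Two-column delimited file (pathway_id, category) -> dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise InputError(f"{path}: missing header line")
        sep = "\t" if "\t" in header else ","
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _split_line(path, lineno, line, sep)
            if len(fields) != 2:
                raise ParseError(f"{path}: expected (pathway_id, category)", lineno)
            out[fields[0].strip()] = fields[1].strip()
    return out
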