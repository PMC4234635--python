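"""Strict TSV readers and writers for count, term, Ct and result tables.

The on-disk dialect is deliberately rigid: tab-separated, UTF-8, Unix
newlines, fixed headers, no quoting and no tabs inside fields.  That buys
bit-exact round-trips and diffable fixtures.  All validation errors carry
the 1-based line number of the offending row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

VALID_NAMESPACES = ("GO", "KEGG")

COUNT_HEADER = ["gene_id", "length_bp", "count_a", "count_b"]
TERM_HEADER = ["gene_id", "term_id", "namespace", "term_name"]
CT_HEADER = ["sample_id", "gene", "ct"]
DEG_HEADER = ["gene_id", "rpkm_a", "rpkm_b", "log2_ratio", "p_value", "fdr", "status"]
ENRICHMENT_HEADER = [
    "term_id", "namespace", "term_name", "m", "n", "M", "N",
    "p_value", "q_value", "enriched",
]
QPCR_HEADER = ["sample_id", "gene", "delta_ct", "delta_delta_ct", "fold"]
TRUTH_HEADER = ["gene_id", "true_log2_fc", "is_de", "planted_term_ids"]


class TableFormatError(ValueError):
    """A table violated the dialect or a field-level invariant."""


@dataclass(frozen=True)
class GeneCount:
    """One gene's length and integer tag counts in the two libraries."""

    gene_id: str
    length_bp: int
    count_a: int
    count_b: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.length_bp < 1:
            raise ValueError(f"{self.gene_id}: length_bp must be >= 1, got {self.length_bp}")
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError(f"{self.gene_id}: counts must be non-negative")


@dataclass(frozen=True)
class LibraryPair:
    """An ordered two-library count table with recomputed depth totals.

    ``total_a`` / ``total_b`` are always the column sums of the member
    genes, never values trusted from a file.
    """

    label_a: str
    label_b: str
    genes: tuple[GeneCount, ...]
    total_a: int = field(init=False)
    total_b: int = field(init=False)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate gene_id {dup!r}")
        ta = sum(g.count_a for g in self.genes)
        tb = sum(g.count_b for g in self.genes)
        if ta < 1 or tb < 1:
            raise ValueError("each library must contain at least one tag")
        object.__setattr__(self, "total_a", ta)
        object.__setattr__(self, "total_b", tb)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class TermAssignment:
    """A (gene, term) membership edge in the GO or KEGG namespace."""

    gene_id: str
    term_id: str
    namespace: str
    term_name: str = ""

    def __post_init__(self) -> None:
        if self.namespace not in VALID_NAMESPACES:
            raise ValueError(
                f"namespace must be one of {VALID_NAMESPACES}, got {self.namespace!r}"
            )
        if not self.term_id:
            raise ValueError("term_id must be non-empty")


def _read_rows(path: str | Path, header: Sequence[str]) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    with open(path, encoding="utf-8", newline="") as fh:
        first = fh.readline().rstrip("\n")
        if first.split("\t") != list(header):
            raise TableFormatError(
                f"{path}:1: expected header {list(header)}, got {first.split(chr(9))}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            yield lineno, fields


def _parse_int(token: str, what: str, where: str, minimum: int) -> int:
    try:
        value = int(token)
    except ValueError:
        raise TableFormatError(f"{where}: {what} must be an integer, got {token!r}") from None
    if value < minimum:
        raise TableFormatError(f"{where}: {what} must be >= {minimum}, got {value}")
    return value


def read_count_table(
    path: str | Path, label_a: str = "A", label_b: str = "B"
) -> LibraryPair:
    """Read a two-library gene count table.

    Expects columns ``gene_id  length_bp  count_a  count_b`` in that exact
    order.  Row order is preserved, totals are recomputed, and malformed
    rows are reported with their 1-based line number.
    """
    genes: list[GeneCount] = []
    seen: dict[str, int] = {}
    for lineno, (gene_id, length_s, a_s, b_s) in _read_rows(path, COUNT_HEADER):
        where = f"{path}:{lineno}"
        if not gene_id:
            raise TableFormatError(f"{where}: empty gene_id")
        if gene_id in seen:
            raise TableFormatError(
                f"{where}: duplicate gene_id {gene_id!r} (first seen on line {seen[gene_id]})"
            )
        seen[gene_id] = lineno
        genes.append(
            GeneCount(
                gene_id=gene_id,
                length_bp=_parse_int(length_s, "length_bp", where, 1),
                count_a=_parse_int(a_s, "count_a", where, 0),
                count_b=_parse_int(b_s, "count_b", where, 0),
            )
        )
    return LibraryPair(label_a=label_a, label_b=label_b, genes=tuple(genes))


def read_term_table(path: str | Path) -> list[TermAssignment]:
    """Read gene->term assignments; duplicate (gene, term) rows collapse to one."""
    assignments: list[TermAssignment] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for lineno, (gene_id, term_id, namespace, term_name) in _read_rows(path, TERM_HEADER):
        where = f"{path}:{lineno}"
        if not gene_id:
            raise TableFormatError(f"{where}: empty gene_id")
        if not term_id:
            raise TableFormatError(f"{where}: empty term_id")
        if namespace not in VALID_NAMESPACES:
            raise TableFormatError(
                f"{where}: unknown namespace {namespace!r} (allowed: {', '.join(VALID_NAMESPACES)})"
            )
        key = (gene_id, term_id)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        assignments.append(TermAssignment(gene_id, term_id, namespace, term_name))
    if n_dup:
        log.warning("%s: collapsed %d duplicate (gene, term) rows", path, n_dup)
    return assignments


def read_ct_table(path: str | Path) -> list[tuple[str, str, float]]:
    """Read qPCR Ct replicates, one row per replicate: (sample_id, gene, ct)."""
    rows: list[tuple[str, str, float]] = []
    for lineno, (sample_id, gene, ct_s) in _read_rows(path, CT_HEADER):
        where = f"{path}:{lineno}"
        if not sample_id or not gene:
            raise TableFormatError(f"{where}: empty sample_id or gene")
        try:
            ct = float(ct_s)
        except ValueError:
            raise TableFormatError(f"{where}: ct must be numeric, got {ct_s!r}") from None
        if not (0.0 < ct < 60.0):
            raise TableFormatError(f"{where}: ct must lie in (0, 60), got {ct}")
        rows.append((sample_id, gene, ct))
    return rows


def _fmt(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isinf(value):
            return "inf" if value > 0 else "-inf"
        return f"{value:.6g}"
    if isinstance(value, (tuple, list, set, frozenset)):
        return ",".join(sorted(str(v) for v in value))
    return str(value)


_HEADERS_BY_TYPE: dict[str, list[str]] = {
    "DegRecord": DEG_HEADER,
    "EnrichmentRecord": ENRICHMENT_HEADER,
    "RelativeExpression": QPCR_HEADER,
    "GeneCount": COUNT_HEADER,
    "TermAssignment": TERM_HEADER,
    "SyntheticTruth": TRUTH_HEADER,
}


def write_results(records: Sequence[object], path: str | Path, header: Sequence[str] | None = None) -> None:
    """Write a homogeneous record collection as TSV with a fixed header.

    The header is inferred from the record type (DegRecord, EnrichmentRecord,
    RelativeExpression, GeneCount, SyntheticTruth) unless given explicitly;
    an empty collection needs an explicit header.  Floats are rendered with
    6 significant digits and round-trip through the matching reader.
    """
    path = Path(path)
    if header is None:
        if not records:
            raise ValueError("cannot infer a header for an empty collection")
        typename = type(records[0]).__name__
        if typename not in _HEADERS_BY_TYPE:
            raise TypeError(f"no registered header for record type {typename}")
        header = _HEADERS_BY_TYPE[typename]
    if records:
        kinds = {type(r) for r in records}
        if len(kinds) > 1:
            raise TypeError(f"records are not homogeneous: {sorted(k.__name__ for k in kinds)}")
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in records:
            values = [_fmt(getattr(rec, col)) for col in header]
            for v in values:
                if "\t" in v or "\n" in v:
                    raise ValueError(f"tabs/newlines forbidden inside fields: {v!r}")
            fh.write("\t".join(values) + "\n")


def write_count_table(pair: LibraryPair, path: str | Path) -> None:
    """Write a LibraryPair back to the count-table dialect."""
    write_results(pair.genes, path, header=COUNT_HEADER)
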