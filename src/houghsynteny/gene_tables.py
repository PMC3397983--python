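"""Gene-coordinate table ingestion and same-name orthologue pairing.

Input tables follow the BioMart export dialect: tab-separated rows of
(chromosome name, gene start in bp, associated gene name), with an
optional header line. Gene symbols are simplified to their first
whitespace-delimited word and matched case-insensitively across species,
so a human ``WWP1`` pairs with a medaka ``wwp1``. Same-name pairs become
2-D points (query start, target start) in megabases — the dot-plot that
the Hough module scans for collinear runs.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

__all__ = [
    "GeneRecord",
    "Region",
    "OrthologPoint",
    "NameRules",
    "simplify_name",
    "read_gene_table",
    "pair_orthologs",
    "write_points_tsv",
    "read_points_tsv",
]

logger = logging.getLogger(__name__)

BP_PER_MB = 1_000_000


@dataclass(frozen=True)
class GeneRecord:
    """One row of a gene table: chromosome, start (bp, 0-based), symbol."""

    chromosome: str
    start: int
    name: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"gene start must be >= 0, got {self.start}")
        if not self.chromosome:
            raise ValueError("chromosome label must be non-empty")
        if not self.name:
            raise ValueError("gene name must be non-empty")


@dataclass(frozen=True)
class Region:
    """A half-open genomic interval [start_bp, end_bp) on one chromosome."""

    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(
                f"region start {self.start_bp} must be < end {self.end_bp}"
            )

    def contains(self, chromosome: str, position: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.start_bp <= position < self.end_bp
        )

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``chr:start-end`` (0-based half-open) region syntax."""
        m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chr:start-end")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


@dataclass(frozen=True)
class OrthologPoint:
    """A same-name gene pair as a dot-plot point, coordinates in Mb."""

    name: str
    x: float
    y: float


@dataclass(frozen=True)
class NameRules:
    """Exclusion rules applied after first-word simplification.

    Empty and purely numeric tokens are always rejected; tokens starting
    with any of ``excluded_prefixes`` (case-insensitive) are rejected as
    classes of symbols prone to ambiguous cross-species naming
    (small-RNA genes, clone-derived placeholders, uncharacterised ORFs).
    """

    excluded_prefixes: tuple[str, ...] = (
        "mir",       # microRNAs
        "snord",     # small nucleolar RNAs
        "snora",
        "rnu",       # small nuclear RNAs
        "rn7",
        "loc",       # provisional loci
        "si:",       # teleost clone-based names
        "zgc:",
        "wu:",
        "ab gene",
    )

    def rejects(self, token: str) -> bool:
        if not token or token.isdigit():
            return True
        low = token.lower()
        return any(low.startswith(p) for p in self.excluded_prefixes)


DEFAULT_NAME_RULES = NameRules()


def simplify_name(raw: str, rules: NameRules = DEFAULT_NAME_RULES) -> str | None:
    """Reduce a raw gene symbol to its matchable form.

    Takes the first whitespace-delimited word and case-folds it, so
    ``"WWP1 (1 of 2)"`` and ``"wwp1"`` both become ``"wwp1"``. Returns
    None when the token is rejected by the exclusion rules.
    """
    token = raw.split()[0] if raw.split() else ""
    if rules.rejects(token):
        return None
    return token.casefold()


class TableParseError(ValueError):
    """A malformed gene-table row, reported with its line number."""


_HEADER_HINTS = ("chromosome", "gene start", "associated gene name", "name")


def _looks_like_header(fields: Sequence[str]) -> bool:
    # keyword-based only: a malformed first data row must surface as a
    # parse error, not vanish as a presumed header
    joined = "\t".join(fields).lower()
    return any(h in joined for h in _HEADER_HINTS[:3])


def read_gene_table(
    stream: TextIO,
    rules: NameRules = DEFAULT_NAME_RULES,
) -> list[GeneRecord]:
    """Read a BioMart-style 3-column TSV into GeneRecords.

    The first line is skipped when it looks like a header. Names are
    passed through :func:`simplify_name`; rows whose name is rejected
    are dropped. Malformed rows raise :class:`TableParseError` naming
    the offending line.
    """
    records: list[GeneRecord] = []
    reader = csv.reader(stream, delimiter="\t")
    for lineno, fields in enumerate(reader, start=1):
        if not fields or (len(fields) == 1 and not fields[0].strip()):
            continue
        if lineno == 1 and _looks_like_header(fields):
            continue
        if len(fields) != 3:
            raise TableParseError(
                f"line {lineno}: expected 3 tab-separated columns, got {len(fields)}"
            )
        chrom, start_text, raw_name = (f.strip() for f in fields)
        try:
            start = int(start_text)
        except ValueError:
            raise TableParseError(
                f"line {lineno}: gene start {start_text!r} is not an integer"
            ) from None
        name = simplify_name(raw_name, rules)
        if name is None:
            continue
        try:
            records.append(GeneRecord(chrom, start, name))
        except ValueError as exc:
            raise TableParseError(f"line {lineno}: {exc}") from None
    if not records:
        logger.warning("gene table produced no usable records")
    return records


def pair_orthologs(
    query: Iterable[GeneRecord],
    target: Iterable[GeneRecord],
    query_region: Region | None = None,
    target_chromosome: str | None = None,
    unique_names: bool = False,
) -> list[OrthologPoint]:
    """All same-name cross pairs of query × target genes, as Mb points.

    Records failing the optional query-region / target-chromosome
    restriction are dropped before pairing. A name occurring m times in
    the query and n times in the target yields m·n points unless
    ``unique_names`` restricts pairing to names unique in both tables.
    Output is sorted by (x, y, name) so downstream results are
    reproducible regardless of input order.
    """
    q = [
        r
        for r in query
        if query_region is None or query_region.contains(r.chromosome, r.start)
    ]
    t = [
        r
        for r in target
        if target_chromosome is None or r.chromosome == target_chromosome
    ]
    by_name: dict[str, list[GeneRecord]] = {}
    for r in t:
        by_name.setdefault(r.name, []).append(r)
    if unique_names:
        q_counts: dict[str, int] = {}
        for r in q:
            q_counts[r.name] = q_counts.get(r.name, 0) + 1
        q = [r for r in q if q_counts[r.name] == 1]
        by_name = {k: v for k, v in by_name.items() if len(v) == 1}
    points = [
        OrthologPoint(qr.name, qr.start / BP_PER_MB, tr.start / BP_PER_MB)
        for qr in q
        for tr in by_name.get(qr.name, ())
    ]
    points.sort(key=lambda p: (p.x, p.y, p.name))
    return points


def write_points_tsv(points: Iterable[OrthologPoint], stream: TextIO) -> None:
    stream.write("name\tx_mb\ty_mb\n")
    for p in points:
        stream.write(f"{p.name}\t{p.x:.6f}\t{p.y:.6f}\n")


def read_points_tsv(stream: TextIO) -> list[OrthologPoint]:
    points = []
    for lineno, line in enumerate(stream, start=1):
        fields = line.rstrip("\n").split("\t")
        if not line.strip():
            continue
        if lineno == 1 and fields[:1] == ["name"]:
            continue
        if len(fields) != 3:
            raise TableParseError(f"line {lineno}: expected 3 columns")
        points.append(OrthologPoint(fields[0], float(fields[1]), float(fields[2])))
    return points
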