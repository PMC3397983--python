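"""Cysteine-knot spacing notation, PROSITE-style patterns, classification.

Agouti-family peptides (AgRP, ASIP and the teleost ASIP2/AgRP2 pair)
close their inhibitor-cystine-knot domain with ten cysteines whose
spacing is diagnostic: the A1 knot opens C-x(6)-C-x(6)-C (AgRP, ASIP)
while the teleost A2 knot has the first loop shortened by one residue,
C-x(6)-C-x(5)-C (AgRP2, ASIP2). Within A2 knots the active-site
triplet distinguishes the paralogues — R-L-F indicates AgRP2 and R-F-F
indicates ASIP2 — and the L-F-A-R motif of the second coding exon marks
A2 precursors. This module renders sequences into the C-x(n) spacing
notation, matches PROSITE-style patterns such as the AgRP2 PHI pattern

    C-x(6)-C-x(5)-C-C-x(2)-C-x(2)-C-x-C-x(6)-C-x-C-x(6,8)-C

and applies the classification rules above.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Sequence

__all__ = [
    "KnotPattern",
    "MotifPattern",
    "KnotClassification",
    "PHI_PATTERN",
    "knot_notation",
    "parse_notation",
    "find_knot_domain",
    "match_pattern",
    "classify_knot",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class KnotPattern:
    """Inter-cysteine run lengths of a knot, renderable as C-x(n) text."""

    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.gaps):
            raise ValueError("gaps must be non-negative")

    @property
    def n_cysteines(self) -> int:
        return len(self.gaps) + 1

    @property
    def notation(self) -> str:
        parts = ["C"]
        for g in self.gaps:
            if g == 0:
                parts.append("C")
            elif g == 1:
                parts.extend(["x", "C"])
            else:
                parts.extend([f"x({g})", "C"])
        return "-".join(parts)


def knot_notation(domain_seq: str) -> KnotPattern:
    """Spacing pattern between the first and last cysteine of a sequence.

    Case-insensitive; every non-C residue (including ambiguity codes)
    counts as one gap position.
    """
    positions = [i for i, aa in enumerate(domain_seq.upper()) if aa == "C"]
    if len(positions) < 2:
        raise ValueError(
            f"need >= 2 cysteines to form a knot, found {len(positions)}"
        )
    gaps = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    return KnotPattern(gaps)


_NOTATION_TOKEN = re.compile(r"C|x(?:\((\d+)\))?")


def parse_notation(text: str) -> KnotPattern:
    """Parse "C-x(6)-C-C-x-C" style text back into a gap list."""
    gaps: list[int] = []
    pending = 0
    seen_c = False
    for token in text.strip().split("-"):
        m = _NOTATION_TOKEN.fullmatch(token)
        if m is None:
            raise ValueError(f"bad notation token {token!r}")
        if token == "C":
            if seen_c:
                gaps.append(pending)
            seen_c = True
            pending = 0
        else:
            pending += int(m.group(1)) if m.group(1) else 1
    if not seen_c or pending:
        raise ValueError("notation must start and end with C")
    return KnotPattern(tuple(gaps))


def find_knot_domain(full_seq: str, n_cys: int = 10) -> tuple[int, int]:
    """Span of the C-terminal knot: n_cys-th cysteine from the end
    through the last cysteine, as a half-open (start, end) index pair.

    Agouti-family precursors carry their ten-cysteine knot at the
    C-terminus, after a signal peptide and basic N-terminal region.
    """
    positions = [i for i, aa in enumerate(full_seq.upper()) if aa == "C"]
    if len(positions) < n_cys:
        raise ValueError(
            f"need {n_cys} cysteines for the knot domain, found {len(positions)}"
        )
    return positions[-n_cys], positions[-1] + 1


@dataclass(frozen=True)
class MotifPattern:
    """A PROSITE-style pattern: elements of (residue set, repeat range).

    ``residues`` of None means the wildcard x. Text syntax: elements
    joined by "-"; an element is a residue letter, a bracket set like
    [VI], or x; an optional suffix (n) or (n,m) repeats it.
    """

    elements: tuple[tuple[frozenset[str] | None, int, int], ...]

    _ELEMENT = re.compile(
        r"(?P<res>[A-Z]|\[[A-Z]+\]|x)(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?"
    )

    @classmethod
    def parse(cls, text: str) -> "MotifPattern":
        elements = []
        for token in text.strip().split("-"):
            m = cls._ELEMENT.fullmatch(token)
            if m is None:
                raise ValueError(f"malformed pattern element {token!r}")
            res = m.group("res")
            residues = (
                None if res == "x" else frozenset(res.strip("[]"))
            )
            lo = int(m.group("lo")) if m.group("lo") else 1
            hi = int(m.group("hi")) if m.group("hi") else lo
            if lo > hi:
                raise ValueError(f"repeat range ({lo},{hi}) has min > max in {token!r}")
            elements.append((residues, lo, hi))
        if not elements:
            raise ValueError("empty pattern")
        return cls(tuple(elements))

    def to_regex(self) -> str:
        parts = []
        for residues, lo, hi in self.elements:
            atom = "[A-Z]" if residues is None else (
                next(iter(residues)) if len(residues) == 1
                else "[" + "".join(sorted(residues)) + "]"
            )
            if (lo, hi) == (1, 1):
                parts.append(atom)
            elif lo == hi:
                parts.append(f"{atom}{{{lo}}}")
            else:
                parts.append(f"{atom}{{{lo},{hi}}}")
        return "".join(parts)


PHI_PATTERN = MotifPattern.parse(
    "C-x(6)-C-x(5)-C-C-x(2)-C-x(2)-C-x-C-x(6)-C-x-C-x(6,8)-C"
)


def match_pattern(seq: str, pattern: MotifPattern | str) -> list[int]:
    """All start positions where the pattern matches, overlaps included.

    Fixed residues match only their exact letter, so ambiguity codes
    (B, Z, X) in the sequence fail fixed positions but satisfy
    wildcards. Variable repeats are tried over their whole range, so a
    match at a start is found regardless of greediness.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern.parse(pattern)
    rx = re.compile(f"(?=({pattern.to_regex()}))")
    return [m.start() for m in rx.finditer(seq.upper())]


@dataclass(frozen=True)
class KnotClassification:
    knot_class: Literal["A1", "A2", "other"]
    functional_motif: Literal["RFF", "RLF", "none"]
    lfar_present: bool
    notation: str


def classify_knot(domain_seq: str, full_seq: str | None = None) -> KnotClassification:
    """Classify a knot domain by its first two gaps and its motifs.

    Gaps (6, 6) open an A1 knot (AgRP/ASIP) and (6, 5) an A2 knot
    (AgRP2/ASIP2); anything else — e.g. the fungal C-x(8,9)-C-C
    variants — is "other". The functional motif is the first R-F-F or
    R-L-F triplet in the domain; L-F-A-R is searched in the full
    precursor when given, else in the domain.
    """
    pattern = knot_notation(domain_seq)
    first_two = pattern.gaps[:2]
    if first_two == (6, 6):
        knot_class: Literal["A1", "A2", "other"] = "A1"
    elif first_two == (6, 5):
        knot_class = "A2"
    else:
        knot_class = "other"
    upper = domain_seq.upper()
    hits = [(upper.find(m), m) for m in ("RFF", "RLF") if upper.find(m) != -1]
    functional = min(hits)[1] if hits else "none"
    scan = (full_seq or domain_seq).upper()
    return KnotClassification(
        knot_class=knot_class,
        functional_motif=functional,  # type: ignore[arg-type]
        lfar_present="LFAR" in scan,
        notation=pattern.notation,
    )
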