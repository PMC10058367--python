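"""Pattern-based detection of venom-associated protein domains.

Domains are described with PROSITE-like spacing patterns — ordered literal
residues (or bracketed residue classes) separated by bounded wildcard gaps,
e.g. ``C-x(2,4)-C``.  This is a deliberate approximation of profile-HMM
domain models: most sea anemone toxin domains (ShKT, Kunitz, Kazal,
BDS/defensin, EGF) are cysteine-stabilised, so their cysteine spacing is a
usable signature at desk scale.  Every report produced from these matches
is labelled "pattern-scan (PFAM-like)"; pattern boundaries are validated
against synthetic plants only, never asserted to equal curated domain
boundaries.

Matching semantics: leftmost starting position wins; at a given start,
wildcard gaps are matched greedily (longest first).  The default scan is
non-overlapping (scanning resumes at the end of each match); an
overlapping mode reports a match at every satisfying start.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

_DATA_DIR = Path(__file__).parent / "data"

_GAP_RE = re.compile(r"^x(?:\((\d+)(?:,(\d+))?\))?$", re.IGNORECASE)
_CLASS_RE = re.compile(r"^\[([A-Z]+)\]$")


@dataclass(frozen=True)
class DomainPattern:
    """A named spacing pattern, e.g. ``("ShKT", "C-x(3,8)-C-...")``."""

    name: str
    pattern: str
    source_note: str = ""
    low_confidence: bool = False


@dataclass(frozen=True)
class DomainMatch:
    protein_id: str
    domain: str
    span: tuple[int, int]  # 0-based half-open
    matched: str


def parse_pattern(pattern: str) -> list:
    """Parse ``"C-x(2,4)-C"`` into literal / gap elements.

    Elements: ``("lit", frozenset)`` for a residue or bracket class,
    ``("gap", min, max)`` for a wildcard run.  Raises on malformed gap
    ranges (min > max) and on patterns without a literal element.
    """
    elements = []
    for token in pattern.split("-"):
        token = token.strip()
        if not token:
            raise ValueError(f"empty element in pattern {pattern!r}")
        gap = _GAP_RE.match(token)
        if gap:
            lo = int(gap.group(1)) if gap.group(1) else 1
            hi = int(gap.group(2)) if gap.group(2) else lo
            if lo > hi:
                raise ValueError(f"malformed gap range in {token!r}: min > max")
            elements.append(("gap", lo, hi))
            continue
        cls = _CLASS_RE.match(token)
        if cls:
            elements.append(("lit", frozenset(cls.group(1))))
        elif len(token) == 1 and token.isalpha():
            elements.append(("lit", frozenset(token.upper())))
        else:
            raise ValueError(f"unrecognised pattern element {token!r}")
    if not any(kind == "lit" for kind, *_ in elements):
        raise ValueError(f"pattern {pattern!r} has no literal element")
    return elements


class DomainMatcher:
    """Compiled pattern; find leftmost (greedy-gap) matches in a sequence."""

    def __init__(self, pattern: DomainPattern):
        self.pattern = pattern
        self.elements = parse_pattern(pattern.pattern)
        parts = []
        for element in self.elements:
            if element[0] == "gap":
                _, lo, hi = element
                parts.append(f".{{{lo},{hi}}}")
            else:
                residues = "".join(sorted(element[1]))
                parts.append(residues if len(residues) == 1 else f"[{residues}]")
        self._regex = re.compile("".join(parts))

    @property
    def n_literal_cys(self) -> int:
        return sum(
            1 for kind, *rest in self.elements if kind == "lit" and rest[0] == frozenset("C")
        )

    def finditer(self, seq: str, overlapping: bool = False):
        """Yield (start, end, matched) tuples, 0-based half-open."""
        if overlapping:
            for start in range(len(seq)):
                m = self._regex.match(seq, start)
                if m:
                    yield (m.start(), m.end(), m.group())
        else:
            for m in self._regex.finditer(seq):
                yield (m.start(), m.end(), m.group())


def compile_pattern(p: DomainPattern) -> DomainMatcher:
    return DomainMatcher(p)


def scan_protein(
    prot, patterns: Sequence[DomainPattern], overlapping: bool = False
) -> list[DomainMatch]:
    """Apply every pattern to a protein; matches sorted by (start, name).

    ``prot`` is a PredictedProtein (uses ``aa_sequence``/``protein_id``)
    or a plain ``(id, sequence)`` pair.  A protein may legitimately carry
    several domains, including several copies of the same one.
    """
    if hasattr(prot, "aa_sequence"):
        pid, seq = prot.protein_id, prot.aa_sequence.rstrip("*")
    else:
        pid, seq = prot
    matches = []
    for pattern in patterns:
        matcher = compile_pattern(pattern)
        for start, end, sub in matcher.finditer(seq, overlapping=overlapping):
            matches.append(DomainMatch(pid, pattern.name, (start, end), sub))
    matches.sort(key=lambda m: (m.span[0], m.domain))
    return matches


def cysteine_framework(seq: str) -> str:
    """Inter-cysteine spacing signature, e.g. ``"C-1-C-14-C-9-C-6-C-0-C"``.

    Each number is the count of non-cysteine residues between consecutive
    cysteines.  Sequences with fewer than two cysteines yield "".
    """
    positions = [i for i, ch in enumerate(seq) if ch == "C"]
    if len(positions) < 2:
        return ""
    parts = ["C"]
    for prev, nxt in zip(positions, positions[1:]):
        parts.append(str(nxt - prev - 1))
        parts.append("C")
    return "-".join(parts)


def framework_to_sequence(framework: str, filler: str = "A") -> str:
    """Synthesize a sequence realising a framework string (alanine filler);
    inverse of :func:`cysteine_framework` (round-trip invariant)."""
    if not framework:
        return ""
    out = []
    for token in framework.split("-"):
        out.append("C" if token == "C" else filler * int(token))
    return "".join(out)


# ---------------------------------------------------------------------------
# Pattern files
# ---------------------------------------------------------------------------


def read_pattern_file(path: str | Path) -> list[DomainPattern]:
    """Read patterns from TSV (name, pattern, note[, low_confidence])."""
    patterns = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            patterns.append(
                DomainPattern(
                    row["name"],
                    row["pattern"],
                    row.get("note") or "",
                    (row.get("low_confidence") or "").strip().lower()
                    in {"1", "true", "yes"},
                )
            )
    return patterns


def default_patterns(include_low_confidence: bool = False) -> list[DomainPattern]:
    """The packaged default pattern set (editable TSV in the package data)."""
    patterns = read_pattern_file(_DATA_DIR / "domain_patterns.tsv")
    if not include_low_confidence:
        patterns = [p for p in patterns if not p.low_confidence]
    return patterns


def write_matches_tsv(matches: Iterable[DomainMatch], path: str | Path) -> None:
    """Matches as TSV with 1-based inclusive coordinates."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["protein_id", "domain", "start1", "end1", "subsequence"])
        for m in matches:
            writer.writerow(
                [m.protein_id, m.domain, m.span[0] + 1, m.span[1], m.matched]
            )
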