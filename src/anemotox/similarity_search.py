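"""Local-alignment search of predicted proteins against a toxin reference set.

The reference set is a ToxProt-style collection: protein FASTA plus an
annotation table carrying each entry's toxin family and source taxon.  At
desk scale (reference sets of at most a few thousand entries) the search
runs an *exact* affine-gap Smith-Waterman (Gotoh) dynamic program instead
of a heuristic seeded search; this is recorded in the run provenance, and
hit counts are therefore not expected to match heuristic-search outputs.

Gap convention: a gap of length k costs ``gap_open + k * gap_extend``
(the NCBI convention for "open 11, extend 1").  E-values follow
Karlin-Altschul statistics, E = K * m * n * exp(-lambda * S), with the
published gapped BLOSUM62 constants (lambda = 0.267, K = 0.041) as
defaults.  Identity is computed over alignment columns *including* gap
columns, one of the several conventions in circulation; it is fixed here
and documented so reported percentages are comparable across runs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices

from .io_formats import PipelineConfig, format_scientific, log, read_fasta
from .orf_predictor import PredictedProtein

_DATA_DIR = Path(__file__).parent / "data"


def _default_matrix():
    return substitution_matrices.load("BLOSUM62")


def simple_matrix(match: float = 1.0, mismatch: float = -1.0) -> dict:
    """A toy substitution matrix for tests and worked examples."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return {
        (a, b): (match if a == b else mismatch)
        for a in alphabet
        for b in alphabet
    }


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value constants."""

    matrix: object = field(default_factory=_default_matrix)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin-Altschul constants must be > 0")

    def alphabet(self) -> frozenset[str]:
        if isinstance(self.matrix, dict):
            return frozenset(a for a, _ in self.matrix)
        return frozenset(str(self.matrix.alphabet))

    def score(self, a: str, b: str) -> float:
        if isinstance(self.matrix, dict):
            return self.matrix.get((a, b), self.matrix.get((b, a)))
        return float(self.matrix[a, b])


@dataclass
class AlignmentHit:
    """One local alignment between a query protein and a reference toxin.

    Spans are 0-based half-open on the respective protein.  ``evalue`` and
    the family/taxon annotations are filled in by the database search; the
    bare aligner leaves them None/empty.
    """

    query_id: str
    subject_id: str
    raw_score: int
    identity_pct: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    evalue: float | None = None
    subject_family: str = ""
    subject_taxon: str = ""
    n_columns: int = 0
    n_identical: int = 0
    n_mismatches: int = 0
    n_gap_opens: int = 0


# ---------------------------------------------------------------------------
# Smith-Waterman (Gotoh)
# ---------------------------------------------------------------------------

_PTR_STOP, _PTR_DIAG, _PTR_UP, _PTR_LEFT = 0, 1, 2, 3


def _validate(seq: str, label: str, alphabet: frozenset[str]) -> None:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    for ch in seq:
        if ch not in alphabet:
            raise ValueError(f"invalid residue {ch!r} in {label} sequence")


def smith_waterman(
    query: str,
    subject: str,
    s: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Optimal local alignment under affine gaps, with traceback.

    Among equally scoring optimal alignments the one with the smallest
    query start, then smallest subject start, is reported.  A best score
    of 0 yields an empty alignment (empty spans, identity 0).
    """
    if s is None:
        s = ScoringScheme()
    alphabet = s.alphabet()
    _validate(query, "query", alphabet)
    _validate(subject, "subject", alphabet)

    m, n = len(query), len(subject)
    open_cost = s.gap_open + s.gap_extend
    ext = s.gap_extend
    score_fn = s.score

    NEG = -math.inf
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (move left)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject (move up)
    ptrH = [[_PTR_STOP] * (n + 1) for _ in range(m + 1)]
    extE = [[False] * (n + 1) for _ in range(m + 1)]
    extF = [[False] * (n + 1) for _ in range(m + 1)]

    best = 0.0
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        pHi, eEi, eFi = ptrH[i], extE[i], extF[i]
        for j in range(1, n + 1):
            e_open = Hi[j - 1] - open_cost
            e_ext = Ei[j - 1] - ext
            if e_ext > e_open:
                Ei[j] = e_ext
                eEi[j] = True
            else:
                Ei[j] = e_open
            f_open = Hi1[j] - open_cost
            f_ext = Fi1[j] - ext
            if f_ext > f_open:
                Fi[j] = f_ext
                eFi[j] = True
            else:
                Fi[j] = f_open
            diag = Hi1[j - 1] + score_fn(qi, subject[j - 1])
            h, p = 0.0, _PTR_STOP
            if diag > h:
                h, p = diag, _PTR_DIAG
            if Fi[j] > h:
                h, p = Fi[j], _PTR_UP
            if Ei[j] > h:
                h, p = Ei[j], _PTR_LEFT
            Hi[j] = h
            pHi[j] = p
            if h > best:
                best = h

    raw = int(round(best))
    if best <= 0:
        return AlignmentHit(query_id, subject_id, 0, 0.0, (0, 0), (0, 0))

    def traceback(i: int, j: int):
        cols = ident = mism = gap_opens = 0
        qend, send = i, j
        while ptrH[i][j] != _PTR_STOP:
            p = ptrH[i][j]
            if p == _PTR_DIAG:
                cols += 1
                if query[i - 1] == subject[j - 1]:
                    ident += 1
                else:
                    mism += 1
                i -= 1
                j -= 1
            elif p == _PTR_UP:
                gap_opens += 1
                while True:
                    cols += 1
                    was_ext = extF[i][j]
                    i -= 1
                    if not was_ext:
                        break
            else:  # _PTR_LEFT
                gap_opens += 1
                while True:
                    cols += 1
                    was_ext = extE[i][j]
                    j -= 1
                    if not was_ext:
                        break
        return (i, j, qend, send, cols, ident, mism, gap_opens)

    candidates = [
        traceback(i, j)
        for i in range(1, m + 1)
        for j in range(1, n + 1)
        if H[i][j] == best
    ]
    qs, ss, qe, se, cols, ident, mism, gaps = min(
        candidates, key=lambda c: (c[0], c[1])
    )
    identity = 100.0 * ident / cols if cols else 0.0
    return AlignmentHit(
        query_id,
        subject_id,
        raw,
        identity,
        (qs, qe),
        (ss, se),
        n_columns=cols,
        n_identical=ident,
        n_mismatches=mism,
        n_gap_opens=gaps,
    )


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------


def karlin_altschul_evalue(
    score: float, m: int, n: int, s: ScoringScheme | None = None
) -> float:
    """E = K * m * n * exp(-lambda * score); strictly decreasing in score."""
    if s is None:
        s = ScoringScheme()
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return s.karlin_K * m * n * math.exp(-s.karlin_lambda * score)


def bit_score(score: float, s: ScoringScheme | None = None) -> float:
    if s is None:
        s = ScoringScheme()
    return (s.karlin_lambda * score - math.log(s.karlin_K)) / math.log(2)


# ---------------------------------------------------------------------------
# Database search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceProtein:
    """A ToxProt-style reference entry with its annotations."""

    id: str
    sequence: str
    family: str
    taxon: str
    accession: str = ""


def read_reference_db(
    fasta_path: str | Path, annotation_path: str | Path
) -> list[ReferenceProtein]:
    """Load reference FASTA plus TSV annotations (id, family, taxon, accession)."""
    records = read_fasta(fasta_path, alphabet="protein")
    annot: dict[str, dict] = {}
    with open(annotation_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            annot[row["subject_id"]] = row
    db = []
    for rec in records:
        meta = annot.get(rec.id)
        if meta is None:
            raise ValueError(f"reference entry {rec.id!r} has no annotation row")
        db.append(
            ReferenceProtein(
                rec.id,
                rec.sequence,
                meta.get("family", ""),
                meta.get("taxon", ""),
                meta.get("uniprot_accession", ""),
            )
        )
    return db


def search_toxin_db(
    queries: Sequence[PredictedProtein],
    db: Sequence[ReferenceProtein],
    cfg: PipelineConfig | None = None,
    taxon_filter: str | None = None,
    scheme: ScoringScheme | None = None,
    keep_all: bool = False,
) -> list[AlignmentHit]:
    """Align every query to the reference set and keep significant hits.

    The search space for E-values is m = query length, n = total residue
    count of the (taxon-filtered) database.  Hits with E-value above the
    configured cutoff are discarded.  Unless ``keep_all`` is set, only the
    top hit per query survives: maximum raw score, ties broken by smallest
    E-value, then lexicographic subject id.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if scheme is None:
        scheme = ScoringScheme()
    if taxon_filter is not None:
        db = [entry for entry in db if taxon_filter.lower() in entry.taxon.lower()]
    if not db:
        raise ValueError("reference database is empty (after taxon filtering)")
    total_db_len = sum(len(entry.sequence) for entry in db)

    results: list[AlignmentHit] = []
    for query in queries:
        qseq = query.aa_sequence.rstrip("*")
        hits = []
        for entry in db:
            hit = smith_waterman(
                qseq, entry.sequence, scheme, query.protein_id, entry.id
            )
            if hit.raw_score <= 0:
                continue
            evalue = karlin_altschul_evalue(
                hit.raw_score, len(qseq), total_db_len, scheme
            )
            hit = replace(
                hit,
                evalue=evalue,
                subject_family=entry.family,
                subject_taxon=entry.taxon,
            )
            if evalue <= cfg.evalue_cutoff:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.raw_score, h.evalue, h.subject_id))
        if keep_all:
            results.extend(hits)
        elif hits:
            results.append(hits[0])
    return results


# ---------------------------------------------------------------------------
# Family -> category assignment
# ---------------------------------------------------------------------------

_category_map_cache: dict[str, str] | None = None


def load_category_map(path: str | Path | None = None) -> dict[str, str]:
    """Family -> category map (neurotoxin / mixed-function enzyme /
    membrane-active / unknown), from the packaged defaults or a user TSV."""
    global _category_map_cache
    if path is None:
        if _category_map_cache is None:
            _category_map_cache = load_category_map(
                _DATA_DIR / "family_categories.tsv"
            )
        return _category_map_cache
    mapping = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            mapping[row["family"].strip().lower()] = row["category"].strip()
    return mapping


def assign_family(
    hit: AlignmentHit, category_map: Mapping[str, str] | None = None
) -> tuple[str, str]:
    """Return the hit's toxin family and its broad category.

    Families absent from the map fall into the "unknown" bin rather than
    raising — uncharacterised families are an expected outcome.
    """
    if category_map is None:
        category_map = load_category_map()
    family = hit.subject_family
    category = category_map.get(family.strip().lower(), "unknown")
    return family, category


# ---------------------------------------------------------------------------
# Tabular output (12-column pairwise-hit records)
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatches",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    # annotation columns appended after the 12 standard fields
    "family",
    "taxon",
]


def write_hits_tsv(
    hits: Iterable[AlignmentHit],
    path: str | Path,
    scheme: ScoringScheme | None = None,
) -> None:
    """Write hits in the conventional 12-column tab-separated layout
    (coordinates rendered 1-based inclusive)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(HIT_COLUMNS)
        for h in hits:
            writer.writerow(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.identity_pct:.1f}",
                    h.n_columns,
                    h.n_mismatches,
                    h.n_gap_opens,
                    h.query_span[0] + 1,
                    h.query_span[1],
                    h.subject_span[0] + 1,
                    h.subject_span[1],
                    format_scientific(h.evalue) if h.evalue is not None else "-",
                    f"{bit_score(h.raw_score, scheme):.1f}",
                    h.subject_family,
                    h.subject_taxon,
                ]
            )
    log.info("wrote %s", path)
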