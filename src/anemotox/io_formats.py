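"""Readers, writers, configuration and logging for the pipeline.

All external files (FASTA, CSV/TSV quantification tables, YAML config,
candidate report tables) pass through this module; the other stages only
exchange the domain types defined here and in their own modules.

Conventions
-----------
* Internal coordinates are 0-based half-open; anything rendered for a human
  (FASTA headers, report tables) is 1-based inclusive.
* A missing quantification cell ("-" in PEAKS-style exports) is represented
  as ``NaN`` and is distinct from a measured value of 0, which PEAKS uses
  for detected-but-low signal. The two states receive different treatment
  downstream, so the distinction is preserved end to end.
* Scientific notation in reports uses an upper-case "E" and two significant
  digits by default.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("anemotox")

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

#: Sentinel used when a quantification cell is absent ("-" in the export).
MISSING = float("nan")

#: Unicode minus used in presence patterns ("+/−"), matching report style.
MINUS = "−"


def setup_logging(level: int = logging.INFO) -> None:
    """Configure pipeline logging to standard error with level prefixes."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


def is_missing(value: float) -> bool:
    """True when *value* is the MISSING sentinel (NaN)."""
    return isinstance(value, float) and math.isnan(value)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptRecord:
    """An assembled transcript (or, with a protein alphabet, a protein record).

    ``id`` follows Trinity-style identifiers (e.g. ``TRINITY_DN14686_c0_g1_i1``);
    ``sequence`` is upper-case over the declared alphabet.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QuantTable:
    """Per-sample label-free areas for a set of features.

    ``values`` is indexed by feature id with a (group, sample_index) column
    MultiIndex; missing cells are NaN.  ``layout`` maps each group label to
    its replicate count (3 + 3 in the tentacle/mucus design).  ``meta``
    carries any non-area annotation columns of the source file (names,
    peptide sequences).  ``imputed`` is a boolean mask of the same shape as
    ``values`` marking cells filled in by the imputation step; it is None
    on a raw table.
    """

    values: pd.DataFrame
    layout: dict[str, int]
    meta: pd.DataFrame | None = None
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r} in quantification table")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative area in quantification table")

    @property
    def groups(self) -> list[str]:
        return list(self.layout)

    def copy(self) -> "QuantTable":
        return QuantTable(
            self.values.copy(),
            dict(self.layout),
            None if self.meta is None else self.meta.copy(),
            None if self.imputed is None else self.imputed.copy(),
        )

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[group]

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


DEFAULT_MOD_DELTAS: dict[str, float] = {
    # variable modifications of the upstream database search, in Da
    "oxidation": 15.99,
    "acetylation": 42.01,
    "carbamidomethylation": 57.02,
    # neuropeptide maturation marks (C-terminal amidation, N-terminal
    # pyroglutamate from Gln), needed for Antho-RFamide/LWamide handling
    "amidation": -0.98402,
    "pyroglutamate": -17.02655,
}


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline with their defaults.

    ``provenance`` records upstream search settings that the pipeline does
    not act on (FDR, mass tolerances) so that reports are self-describing.
    """

    evalue_cutoff: float = 1e-4
    presence_k: int = 2
    presence_n: int = 3
    imputation_floor: float = 1e-2
    min_orf_len: int = 50
    species_code: str = "Bcs"
    mod_deltas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOD_DELTAS)
    )
    provenance: dict[str, str] = field(
        default_factory=lambda: {
            "upstream_search": "PEAKS-style export, FDR <= 1%",
            "precursor_tolerance": "+/-30 ppm",
            "fragment_tolerance": "+/-0.5 Da",
            "orf_calling": "longest-ORF heuristic (no coding-potential scoring)",
            "similarity_search": "exact affine-gap Smith-Waterman",
            "domain_detection": "pattern-scan (PFAM-like)",
        }
    )

    def __post_init__(self) -> None:
        if not (0 < self.presence_k <= self.presence_n):
            raise ValueError("require 0 < presence_k <= presence_n")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.imputation_floor <= 0:
            raise ValueError("imputation_floor must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        return {
            "evalue_cutoff": self.evalue_cutoff,
            "presence_k": self.presence_k,
            "presence_n": self.presence_n,
            "imputation_floor": self.imputation_floor,
            "min_orf_len": self.min_orf_len,
            "species_code": self.species_code,
            "mod_deltas": dict(self.mod_deltas),
            "provenance": dict(self.provenance),
        }


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(
    path: str | Path, alphabet: str = "nucleotide"
) -> list[TranscriptRecord]:
    """Read a FASTA file into validated records, preserving input order.

    ``alphabet`` is ``"nucleotide"`` (A/C/G/T/N) or ``"protein"``.
    Sequences are whitespace-stripped and upper-cased.  Duplicate ids,
    empty sequences and out-of-alphabet characters are errors.
    """
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(" ", "").replace("\t", "").upper()
        if not seq:
            raise ValueError(f"empty sequence under header {rec.id!r} in {path}")
        for pos, ch in enumerate(seq):
            if ch not in allowed:
                raise ValueError(
                    f"record {rec.id!r}: character {ch!r} at position {pos} "
                    f"is not in the {alphabet} alphabet"
                )
        records.append(TranscriptRecord(rec.id, seq))
    return records


def write_fasta(
    records: Iterable[TranscriptRecord], path: str | Path, width: int = 60
) -> None:
    """Write records to FASTA; inverse of :func:`read_fasta` on content/order."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------


def _parse_area(cell, row: int, col: str) -> float:
    if isinstance(cell, float) and math.isnan(cell):
        return MISSING
    text = str(cell).strip()
    if text in {"-", ""}:
        return MISSING
    try:
        value = float(text)
    except ValueError as exc:
        raise ValueError(
            f"unparseable area cell {cell!r} at row {row}, column {col!r}"
        ) from exc
    if value < 0:
        raise ValueError(f"negative area {value} at row {row}, column {col!r}")
    return value


def read_quant_table(
    path: str | Path,
    dialect: str = "tsv",
    feature_col: str | None = None,
    area_columns: Mapping[str, tuple[str, int]] | None = None,
) -> QuantTable:
    """Read a PEAKS-style export into a :class:`QuantTable`.

    ``area_columns`` maps a column name in the file to a (group,
    sample_index) pair; because export schemas vary, the mapping is
    declared by the caller rather than guessed.  When omitted, columns
    whose names contain a group label ("tentacle"/"mucus", any case) are
    auto-assigned, numbered in file order.  "-" cells become MISSING;
    numeric cells (including scientific notation such as ``9.06E+09``)
    become floats.  Non-area columns are kept as annotations.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if feature_col is None:
        feature_col = raw.columns[0]

    if area_columns is None:
        area_columns = {}
        counters = {"tentacle": 0, "mucus": 0}
        for col in raw.columns:
            lowered = col.lower()
            for group in counters:
                if group in lowered:
                    counters[group] += 1
                    area_columns[col] = (group, counters[group])
        if not area_columns:
            raise ValueError(
                f"no area columns recognised in {path}; pass area_columns"
            )

    parsed = {}
    for col, key in area_columns.items():
        parsed[key] = [
            _parse_area(cell, row, col) for row, cell in enumerate(raw[col])
        ]
    values = pd.DataFrame(parsed, index=raw[feature_col].astype(str))
    values.columns = pd.MultiIndex.from_tuples(
        values.columns, names=["group", "sample"]
    )
    values.index.name = "feature_id"
    # replicate count per group = highest declared sample index
    layout: dict[str, int] = {}
    for group, sample in area_columns.values():
        layout[group] = max(layout.get(group, 0), sample)

    meta_cols = [c for c in raw.columns if c not in area_columns and c != feature_col]
    meta = raw[meta_cols].set_index(values.index) if meta_cols else None
    return QuantTable(values.astype(float), layout, meta)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def format_scientific(value: float, sig: int = 2) -> str:
    """Render ``4.4e-13`` as ``"4.4E-13"`` (upper-case E, *sig* digits)."""
    if value == 0:
        return "0"
    return f"{value:.{sig - 1}E}"


def format_presence(tentacle: bool, mucus: bool) -> str:
    """Render a tentacle/mucus presence pattern, e.g. ``"+/−"``."""
    return f"{'+' if tentacle else MINUS}/{'+' if mucus else MINUS}"


CANDIDATE_COLUMNS = [
    "Toxin",
    "Trinity Code",
    "Transcript (Identity)",
    "E-Value",
    "Toxin Family",
    "Tentacle/Mucus",
    "Omic Approach",
]


def candidate_row(candidate) -> dict[str, str]:
    """Render one toxin candidate as a report row (see CANDIDATE_COLUMNS)."""
    hit = candidate.evidence.similarity_hit
    if hit is not None:
        transcript = f"{hit.subject_id} ({hit.identity_pct:.1f}%)"
        evalue = format_scientific(hit.evalue)
    else:
        transcript = "-"
        evalue = "-"
    return {
        "Toxin": candidate.assigned_name or "-",
        "Trinity Code": "".join(candidate.transcript_ids)
        if len(candidate.transcript_ids) == 1
        else "; ".join(candidate.transcript_ids),
        "Transcript (Identity)": transcript,
        "E-Value": evalue,
        "Toxin Family": candidate.family,
        "Tentacle/Mucus": format_presence(
            candidate.evidence.tentacle_present, candidate.evidence.mucus_present
        ),
        "Omic Approach": candidate.evidence.omic_approach(),
    }


def write_candidate_table(candidates: Sequence, path: str | Path) -> None:
    """Write candidates as a TSV with the standard report columns.

    An empty candidate list yields a header-only file.  Candidates without
    a similarity hit (domain-only) render "-" in the identity and E-value
    columns.
    """
    rows = [candidate_row(c) for c in candidates]
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
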