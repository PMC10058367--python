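"""Peptidome-layer computations.

Covers PTM-aware monoisotopic mass, exact peptide-to-precursor mapping,
cleavage-site (P1/P1') frequency analysis, and mass-distribution
histograms.  Masses are monoisotopic throughout (standard residue table
from pyteomics); post-translational modifications add the fixed deltas
declared in the pipeline configuration, which include the variable
modifications of the upstream database search (Met oxidation +15.99 Da,
acetylation +42.01 Da, carbamidomethylation +57.02 Da) and the
neuropeptide maturation marks (C-terminal amidation, N-terminal
pyroglutamate from Gln).

P1 counting convention: the residue immediately upstream of a peptide's
N-terminus and the residue immediately downstream of its C-terminus are
both cleavage-site events; they are tabulated separately (upstream table,
downstream table).  Peptides flush with a precursor terminus have no
flanking residue on that side — a frequent situation for C-terminal
fragments of processed precursors — and are counted as BOUNDARY cases,
excluded from the frequency denominators (both denominators are
reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from pyteomics import mass as pmass

from .io_formats import PipelineConfig, is_missing, log

#: Flank marker for peptides flush with a precursor terminus.
BOUNDARY = "BOUNDARY"

WATER_MONO = pmass.calculate_mass(formula="H2O")

_IL_TABLE = str.maketrans("L", "I")


@dataclass
class PeptideObservation:
    """An identified peptide with its PTMs, source fraction and areas.

    ``modifications`` holds (position-or-terminus, mod name) pairs where a
    position is a 0-based residue index and a terminus is ``"N-term"`` or
    ``"C-term"``.  ``areas`` is keyed by (group, sample_index); missing
    observations are NaN.
    """

    sequence: str
    modifications: list[tuple[object, str]] = field(default_factory=list)
    precursor_ids: list[str] = field(default_factory=list)
    fraction: str = "tentacle"
    layer: str = "RA_peptidome"
    areas: dict[tuple[str, int], float] = field(default_factory=dict)


@dataclass
class CleavageProfile:
    """P1 (upstream) and P1' (downstream) residue counts over a peptidome."""

    upstream_counts: dict[str, int]
    downstream_counts: dict[str, int]
    n_peptides_total: int
    n_upstream_boundary: int
    n_downstream_boundary: int

    def upstream_frequencies(self) -> pd.Series:
        return self._freq(self.upstream_counts, self.n_upstream_boundary)

    def downstream_frequencies(self) -> pd.Series:
        return self._freq(self.downstream_counts, self.n_downstream_boundary)

    def _freq(self, counts: dict[str, int], n_boundary: int) -> pd.Series:
        denom = self.n_peptides_total - n_boundary
        if denom == 0:
            return pd.Series(dtype=float)
        series = pd.Series(counts, dtype=float) / denom
        return series.sort_values(ascending=False)


def monoisotopic_mass(
    p: PeptideObservation | str, cfg: PipelineConfig | None = None
) -> float:
    """Monoisotopic peptide mass: residue masses + water + PTM deltas (Da)."""
    if cfg is None:
        cfg = PipelineConfig()
    if isinstance(p, str):
        p = PeptideObservation(p)
    if not p.sequence:
        raise ValueError("cannot compute the mass of an empty peptide")
    total = WATER_MONO
    for ch in p.sequence:
        try:
            total += pmass.std_aa_mass[ch]
        except KeyError as exc:
            raise ValueError(f"unknown residue {ch!r} in {p.sequence!r}") from exc
    for where, name in p.modifications:
        if name not in cfg.mod_deltas:
            raise ValueError(f"unknown modification {name!r}")
        if isinstance(where, int) and not (0 <= where < len(p.sequence)):
            raise ValueError(
                f"modification position {where} outside peptide of length "
                f"{len(p.sequence)}"
            )
        total += cfg.mod_deltas[name]
    return total


def map_to_precursors(
    p: PeptideObservation | str,
    proteins: Sequence,
    il_equivalent: bool = False,
) -> list[tuple[str, int]]:
    """All exact substring occurrences of the peptide in the protein set.

    With ``il_equivalent`` (off by default, matching exact database
    search behaviour) isoleucine and leucine are treated as the same
    residue — they are isobaric and indistinguishable by mass.  Results
    are sorted by (protein_id, offset); an unmapped peptide yields [].
    """
    seq = p.sequence if isinstance(p, PeptideObservation) else p
    if not proteins:
        raise ValueError("protein database is empty")
    needle = seq.translate(_IL_TABLE) if il_equivalent else seq
    out = []
    for prot in proteins:
        if hasattr(prot, "aa_sequence"):
            pid, pseq = prot.protein_id, prot.aa_sequence.rstrip("*")
        else:
            pid, pseq = prot
        haystack = pseq.translate(_IL_TABLE) if il_equivalent else pseq
        start = haystack.find(needle)
        while start != -1:
            out.append((pid, start))
            start = haystack.find(needle, start + 1)
    out.sort()
    return out


def cleavage_context(
    protein, offset: int, pep_len: int
) -> tuple[str, str]:
    """Residues flanking a mapped peptide: (P1 upstream, P1' downstream).

    Peptides starting at the precursor N-terminus or ending at its
    C-terminus return BOUNDARY on the corresponding side.
    """
    if hasattr(protein, "aa_sequence"):
        seq = protein.aa_sequence.rstrip("*")
    elif isinstance(protein, tuple):
        seq = protein[1]
    else:
        seq = protein
    if offset < 0 or offset + pep_len > len(seq):
        raise ValueError(
            f"peptide span [{offset}, {offset + pep_len}) outside protein "
            f"of length {len(seq)}"
        )
    upstream = seq[offset - 1] if offset > 0 else BOUNDARY
    end = offset + pep_len
    downstream = seq[end] if end < len(seq) else BOUNDARY
    return upstream, downstream


def cleavage_frequency_table(
    peptides: Sequence[PeptideObservation],
    proteins: Sequence,
    il_equivalent: bool = False,
    multi_mapping: str = "first",
) -> CleavageProfile:
    """Tabulate P1/P1' residue counts over all mappable peptides.

    Ambiguous multi-mapping peptides contribute once via their first
    mapping in deterministic (protein_id, offset) order by default;
    ``multi_mapping="all"`` counts every mapping.  Unmapped peptides are
    logged and excluded; if nothing maps, that is an error.
    """
    if multi_mapping not in {"first", "all"}:
        raise ValueError(f"unknown multi-mapping policy {multi_mapping!r}")
    by_id = {}
    for prot in proteins:
        if hasattr(prot, "aa_sequence"):
            by_id[prot.protein_id] = prot.aa_sequence.rstrip("*")
        else:
            by_id[prot[0]] = prot[1]

    up: dict[str, int] = {}
    down: dict[str, int] = {}
    n_mapped = up_boundary = down_boundary = n_unmapped = 0
    for p in peptides:
        mappings = map_to_precursors(p, list(by_id.items()), il_equivalent)
        if not mappings:
            n_unmapped += 1
            continue
        if multi_mapping == "first":
            mappings = mappings[:1]
        n_mapped += 1
        for pid, offset in mappings:
            upstream, downstream = cleavage_context(
                by_id[pid], offset, len(p.sequence)
            )
            if upstream == BOUNDARY:
                up_boundary += 1
            else:
                up[upstream] = up.get(upstream, 0) + 1
            if downstream == BOUNDARY:
                down_boundary += 1
            else:
                down[downstream] = down.get(downstream, 0) + 1
    if n_unmapped:
        log.warning("%d peptide(s) did not map to any precursor", n_unmapped)
    if n_mapped == 0:
        raise ValueError("no peptide mapped to any precursor")
    # under the "all" policy each mapping is one event, so the totals are
    # event counts rather than peptide counts
    if multi_mapping == "first":
        total_events = n_mapped
    else:
        total_events = up_boundary + sum(up.values())
    return CleavageProfile(
        upstream_counts=up,
        downstream_counts=down,
        n_peptides_total=total_events,
        n_upstream_boundary=up_boundary,
        n_downstream_boundary=down_boundary,
    )


def mass_histogram(
    peptides: Sequence,
    bin_width: float,
    origin: float = 0.0,
    cfg: PipelineConfig | None = None,
) -> list[tuple[float, int]]:
    """Histogram of peptide masses over half-open bins.

    Bin k covers [origin + k*w, origin + (k+1)*w).  ``peptides`` may be
    observations (masses are computed) or plain floats.  Empty bins
    between occupied ones are included so the histogram is contiguous;
    counts sum to the number of peptides.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    masses = [
        p if isinstance(p, (int, float)) else monoisotopic_mass(p, cfg)
        for p in peptides
    ]
    if not masses:
        return []
    ks = [math.floor((mz - origin) / bin_width) for mz in masses]
    lo, hi = min(ks), max(ks)
    counts = {k: 0 for k in range(lo, hi + 1)}
    for k in ks:
        counts[k] += 1
    return [(origin + k * bin_width, counts[k]) for k in range(lo, hi + 1)]


def count_cysteine_peptides(peptides: Sequence[PeptideObservation]) -> int:
    """Number of peptides containing at least one cysteine residue."""
    return sum(1 for p in peptides if "C" in p.sequence)


def presence_by_fraction(
    peptides: Sequence[PeptideObservation],
) -> dict[str, set[str]]:
    """Peptide sequences observed per fraction (area present and > 0)."""
    seen: dict[str, set[str]] = {}
    for p in peptides:
        observed = any(
            not is_missing(v) and v > 0 for v in p.areas.values()
        ) or not p.areas
        if observed:
            seen.setdefault(p.fraction, set()).add(p.sequence)
    return seen
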