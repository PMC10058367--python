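"""Cross-omics confirmation of toxin candidates and actitoxin naming.

A transcript becomes a candidate when it carries similarity evidence (a
significant hit against the toxin reference set) or domain evidence (a
pattern-scan match).  A candidate is *confirmed* when mass-spectrometry
layers support it in more than one sample — implemented as at least two
sample-level observations summed across the proteome and the two
peptidome preparations (reduced/alkylated and non-reduced/non-alkylated,
each a pooled sample per tissue fraction).  The per-run report splits
confirmed candidates into a similarity-based table and a domain-only
table, and also tallies the layer overlap (proteome only / peptidome only
/ both / neither) across all evidence-bearing transcripts.

New candidates receive sea anemone toxin nomenclature in the Oliveira
style: activity prefix (U when the activity is unknown, kappa/pi/delta...
otherwise), "-actitoxin-", a species code, a family number and an isoform
letter.  The family number is inherited from the best-hit described
toxin's own name when parseable (Bgr3d -> 3), else the next unused
integer for that family; the isoform letter is the first unused.  Greek
prefixes are stored as ASCII tokens and rendered either way.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .domain_scan import DomainMatch
from .io_formats import PipelineConfig, log, write_candidate_table
from .similarity_search import AlignmentHit, assign_family

GREEK_PREFIXES = {
    "U": "U",
    "Kappa": "Κ",            # Κ
    "Pi": "Π",               # Π
    "Delta": "Δ",            # Δ
    "KappaPi": "ΚΠ",    # ΚΠ
    "Omega": "Ω",            # Ω
    "Sigma": "Σ",            # Σ
}


@dataclass
class EvidenceFlags:
    """Everything known about one transcript across the omics layers."""

    similarity_hit: AlignmentHit | None = None
    domain_matches: list[DomainMatch] = field(default_factory=list)
    proteome_samples: int = 0
    ra_peptidome: dict[str, bool] = field(default_factory=dict)
    nrna_peptidome: dict[str, bool] = field(default_factory=dict)
    tentacle_present: bool = False
    mucus_present: bool = False

    def sample_observations(self) -> int:
        """Sample-level MS observations summed across layers."""
        return (
            self.proteome_samples
            + sum(self.ra_peptidome.values())
            + sum(self.nrna_peptidome.values())
        )

    def has_evidence(self) -> bool:
        return self.similarity_hit is not None or bool(self.domain_matches)

    def omic_approach(self) -> str:
        layers = []
        if self.proteome_samples > 0:
            layers.append("Proteome")
        if any(self.ra_peptidome.values()):
            layers.append("RA peptidome")
        if any(self.nrna_peptidome.values()):
            layers.append("NRNA peptidome")
        return ", ".join(layers) if layers else "-"


@dataclass
class ToxinCandidate:
    transcript_ids: list[str]
    assigned_name: str | None
    family: str
    category: str
    evidence: EvidenceFlags
    status: str  # confirmed | putative_unconfirmed


# ---------------------------------------------------------------------------
# Nomenclature
# ---------------------------------------------------------------------------

_FAMILY_NUMBER = re.compile(r"(\d+)([a-z])\s*$")


class NameRegistry:
    """Issues unique actitoxin names within one run."""

    def __init__(self, species_code: str = "Bcs", ascii_mode: bool = False):
        if not species_code:
            raise ValueError("species_code must be non-empty")
        self.species_code = species_code
        self.ascii_mode = ascii_mode
        self.taken: set[tuple[str, str, int, str]] = set()

    def render(self, prefix: str, family_number: int, letter: str) -> str:
        if prefix not in GREEK_PREFIXES:
            raise ValueError(f"unknown activity prefix {prefix!r}")
        shown = prefix.lower() if self.ascii_mode else GREEK_PREFIXES[prefix]
        if prefix == "U":
            shown = "U"
        return f"{shown}-actitoxin-{self.species_code}{family_number}{letter}"

    def assign(self, prefix: str, family_number: int, letter: str = "a") -> str:
        """Reserve and render a name; collisions advance the isoform letter."""
        if not ("a" <= letter <= "z"):
            raise ValueError(f"isoform letter must be a-z, got {letter!r}")
        code = ord(letter)
        while code <= ord("z"):
            key = (prefix, self.species_code, family_number, chr(code))
            if key not in self.taken:
                self.taken.add(key)
                return self.render(prefix, family_number, chr(code))
            code += 1
        raise ValueError(
            f"isoform letters exhausted for {prefix}-actitoxin-"
            f"{self.species_code}{family_number}"
        )


def assign_name(
    activity_prefix: str,
    species_code: str,
    family_number: int,
    isoform_letter: str,
    registry: NameRegistry | None = None,
    ascii_mode: bool = False,
) -> str:
    """One-shot naming helper over a (possibly fresh) registry."""
    if registry is None:
        registry = NameRegistry(species_code, ascii_mode)
    return registry.assign(activity_prefix, family_number, isoform_letter)


def family_number_from_hit(hit: AlignmentHit) -> int | None:
    """Inherit the family number from the best hit's name (Bgr3d -> 3)."""
    m = _FAMILY_NUMBER.search(hit.subject_id)
    return int(m.group(1)) if m else None


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def integrate_evidence(
    evidence: Mapping[str, EvidenceFlags],
    cfg: PipelineConfig | None = None,
    min_samples: int = 2,
    protein_db_ids: set[str] | None = None,
    ascii_names: bool = False,
    category_map: Mapping[str, str] | None = None,
) -> tuple[list[ToxinCandidate], dict[str, int]]:
    """Build candidates from per-transcript evidence bundles.

    Returns the candidate list (deterministically ordered by (family,
    transcript id)) plus the layer-overlap counts over evidence-bearing
    transcripts.  Transcripts referenced by an MS layer but absent from
    the protein database are orphans and an error.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if protein_db_ids is not None:
        orphans = sorted(
            tid
            for tid, ev in evidence.items()
            if ev.sample_observations() > 0 and tid not in protein_db_ids
        )
        if orphans:
            raise ValueError(
                "transcripts with MS evidence but no protein database entry: "
                + ", ".join(orphans)
            )

    registry = NameRegistry(cfg.species_code, ascii_names)
    next_family_number: dict[str, int] = {}
    candidates: list[ToxinCandidate] = []
    overlap = {"proteome_only": 0, "peptidome_only": 0, "both": 0, "neither": 0}

    bearing = [
        (tid, ev) for tid, ev in sorted(evidence.items()) if ev.has_evidence()
    ]
    # order by (family, transcript id) for stable naming across reruns
    def family_of(ev: EvidenceFlags) -> str:
        if ev.similarity_hit is not None:
            return ev.similarity_hit.subject_family
        return ev.domain_matches[0].domain if ev.domain_matches else ""

    bearing.sort(key=lambda item: (family_of(item[1]), item[0]))

    for tid, ev in bearing:
        in_proteome = ev.proteome_samples > 0
        in_peptidome = any(ev.ra_peptidome.values()) or any(
            ev.nrna_peptidome.values()
        )
        if in_proteome and in_peptidome:
            overlap["both"] += 1
        elif in_proteome:
            overlap["proteome_only"] += 1
        elif in_peptidome:
            overlap["peptidome_only"] += 1
        else:
            overlap["neither"] += 1

        status = (
            "confirmed"
            if ev.sample_observations() >= min_samples
            else "putative_unconfirmed"
        )
        if ev.similarity_hit is not None:
            family, category = assign_family(ev.similarity_hit, category_map)
            number = family_number_from_hit(ev.similarity_hit)
            if number is None:
                number = next_family_number.get(family, 0) + 1
            next_family_number[family] = max(
                next_family_number.get(family, 0), number
            )
            name = registry.assign("U", number, "a")
        else:
            family = f"{ev.domain_matches[0].domain} domain-like"
            category = (
                category_map.get(family.lower(), "unknown")
                if category_map
                else "unknown"
            )
            name = None  # domain-only candidates are reported by transcript id
        candidates.append(
            ToxinCandidate(
                transcript_ids=[tid],
                assigned_name=name,
                family=family,
                category=category,
                evidence=ev,
                status=status,
            )
        )
    log.info(
        "integrated %d evidence-bearing transcripts (%d confirmed)",
        len(candidates),
        sum(1 for c in candidates if c.status == "confirmed"),
    )
    return candidates, overlap


def build_report(
    candidates: Sequence[ToxinCandidate],
    outdir: str | Path | None = None,
    overlap: dict[str, int] | None = None,
) -> dict:
    """Partition candidates into similarity-based and domain-only reports.

    Returns a summary dict (and, when ``outdir`` is given, writes the two
    candidate tables, the per-family/category counts and the overlap
    summary there).  Every candidate lands in exactly one table.
    """
    similarity = [c for c in candidates if c.evidence.similarity_hit is not None]
    domain_only = [c for c in candidates if c.evidence.similarity_hit is None]
    per_family: dict[str, int] = {}
    per_category: dict[str, int] = {}
    for c in candidates:
        per_family[c.family] = per_family.get(c.family, 0) + 1
        per_category[c.category] = per_category.get(c.category, 0) + 1
    summary = {
        "n_candidates": len(candidates),
        "n_confirmed": sum(1 for c in candidates if c.status == "confirmed"),
        "n_similarity_based": len(similarity),
        "n_domain_only": len(domain_only),
        "per_family": per_family,
        "per_category": per_category,
    }
    if overlap is not None:
        summary["layer_overlap"] = dict(overlap)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_candidate_table(similarity, outdir / "toxin_candidates_similarity.tsv")
        write_candidate_table(domain_only, outdir / "toxin_candidates_domain_only.tsv")
        with open(outdir / "integration_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
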