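"""Seeded generators for every input the pipeline consumes.

The generators emulate the tentacle/mucus study design with known ground
truth so each stage can be scored without any external download:

* a transcriptome containing toxin transcripts (signal-peptide-like
  prefix + a mature region realising one of the default domain patterns,
  back-translated with uniform codon choice) among housekeeping-like
  decoy ORFs wrapped in random UTRs;
* a matching ToxProt-style reference set (the undiverged template
  proteins with family/taxon annotations);
* a 3 + 3 tentacle/mucus area table with planted fold changes (default
  10-fold), planted all-missing "exclusive" features, and missing cells
  at a configurable rate (default 20%);
* a peptidome with planted P1 (upstream-flank) residue preferences, a
  configurable share of C-terminal fragments, and sprinkled PTMs.

Areas are log-normal: label-free MS areas are positive and right-skewed.
Everything is driven by numpy integer RNG substreams derived from the one
seed, with no iteration-order dependence, so a fixed seed reproduces
byte-identical outputs.  Truth tables carry enough to score every
downstream stage without re-reading this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain_scan import DomainPattern, default_patterns, parse_pattern
from .io_formats import QuantTable, TranscriptRecord
from .peptide_analytics import PeptideObservation
from .similarity_search import ReferenceProtein

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_C = AA20.replace("C", "")

#: Uniform-choice codon table for back-translation (no codon-bias model:
#: codon usage is irrelevant to every downstream stage).
_CODONS: dict[str, list[str]] = {}


def _build_codons() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        for codon, aa in table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


@dataclass(frozen=True)
class ToxinTemplate:
    """One planted toxin family: reference name, family annotation, the
    domain pattern it realises and the fixed inter-cysteine gap lengths."""

    reference_id: str
    family: str
    pattern_name: str
    gaps: tuple[int, ...]


DEFAULT_TEMPLATES = (
    ToxinTemplate(
        "U-actitoxin-Bgr3d",
        "Sea anemone type 3 (BDS) potassium channel toxin",
        "BDS_defensin",
        (1, 14, 9, 6, 0),
    ),
    ToxinTemplate(
        "U-actitoxin-Avd3n",
        "Venom Kunitz type. Sea anemone type 2 potassium channel toxin.",
        "Kunitz",
        (8, 15, 7, 12, 3),
    ),
    ToxinTemplate(
        "Kappa-actitoxin-Bgr1a",
        "Sea anemone type 1 potassium channel toxin",
        "ShKT",
        (3, 4, 6, 4, 3),
    ),
    ToxinTemplate(
        "PI-actitoxin-Avd5a",
        "Kazal-type serine protease inhibitor domain",
        "Kazal",
        (6, 6, 6, 13, 2),
    ),
    ToxinTemplate(
        "U-actitoxin-Avd12a",
        "EGF-domain peptide",
        "EGF",
        (5, 4, 2, 2, 4),
    ),
)


@dataclass
class SimulationConfig:
    """Study-design parameters of the generators (defaults = the 3+3
    tentacle/mucus design with 20% missingness and 10-fold planting)."""

    seed: int = 0
    n_decoy_transcripts: int = 20
    n_toxin_transcripts: int = 12
    toxin_templates: tuple[ToxinTemplate, ...] = DEFAULT_TEMPLATES
    divergence_pct: float = 0.0
    # quantification table
    n_features: int = 300
    fold_change: float = 10.0
    missingness_rate: float = 0.2
    exclusive_fraction: float = 0.05
    layout: dict[str, int] = field(
        default_factory=lambda: {"tentacle": 3, "mucus": 3}
    )
    area_log_mean: float = math.log(1e8)
    area_log_sigma: float = 1.0
    # peptidome
    n_peptides: int = 2000
    cleavage_pref: dict[str, float] = field(
        default_factory=lambda: {"Y": 0.4, "E": 0.2}
    )
    cterm_fraction: float = 0.2
    ptm_rate: float = 0.1
    peptide_len: tuple[int, int] = (8, 25)
    n_precursor_proteins: int = 30
    precursor_len: int = 300

    def __post_init__(self) -> None:
        if not (0 <= self.missingness_rate < 1):
            raise ValueError("missingness_rate must be in [0, 1)")
        if self.fold_change <= 0:
            raise ValueError("fold changes must be > 0")
        if sum(self.cleavage_pref.values()) > 1 + 1e-12:
            raise ValueError("cleavage preference probabilities must sum to <= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _random_residues(rng: np.random.Generator, n: int, alphabet: str = AA_NO_C) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


def _realise_pattern(
    pattern: DomainPattern, gaps: tuple[int, ...], rng: np.random.Generator
) -> str:
    """Build a mature-domain sequence satisfying *pattern* with the given
    fixed gap lengths; gap filler excludes cysteine so the realised
    cysteine spacing is exactly the planted one."""
    elements = parse_pattern(pattern.pattern)
    out = []
    gap_iter = iter(gaps)
    for element in elements:
        if element[0] == "lit":
            out.append(sorted(element[1])[0])
        else:
            _, lo, hi = element
            g = next(gap_iter)
            if not (lo <= g <= hi):
                raise ValueError(
                    f"planted gap {g} outside pattern range ({lo},{hi})"
                )
            out.append(_random_residues(rng, g))
    return "".join(out)


def build_template_proteins(
    cfg: SimulationConfig,
) -> list[tuple[ToxinTemplate, str, tuple[int, int]]]:
    """Template precursor proteins: M + signal-like stretch + mature domain
    + short tail.  Returns (template, protein, domain span) triples;
    deterministic for a fixed seed."""
    rng = cfg.rng(0)
    patterns = {p.name: p for p in default_patterns(include_low_confidence=True)}
    out = []
    for template in cfg.toxin_templates:
        pattern = patterns[template.pattern_name]
        # M + hydrophobic signal-like stretch + propeptide, as in real toxin
        # precursors; also keeps every precursor above the default ORF minimum
        signal = "M" + _random_residues(rng, 14, "AFILVW") + _random_residues(rng, 5)
        propart = _random_residues(rng, 12)
        mature = _realise_pattern(pattern, template.gaps, rng)
        tail = _random_residues(rng, 4)
        protein = signal + propart + mature + tail
        span = (len(signal) + len(propart), len(signal) + len(propart) + len(mature))
        out.append((template, protein, span))
    return out


def simulate_reference_db(cfg: SimulationConfig) -> list[ReferenceProtein]:
    """The ToxProt-style reference set: undiverged template proteins."""
    return [
        ReferenceProtein(
            template.reference_id,
            protein,
            template.family,
            "Cnidaria; sea anemone",
            accession=f"SYN{i:04d}",
        )
        for i, (template, protein, _span) in enumerate(build_template_proteins(cfg))
    ]


def _mutate_protein(
    protein: str, divergence_pct: float, rng: np.random.Generator
) -> str:
    """Point-mutate residues at the given percent rate (the initial Met is
    kept so the ORF still starts at the planted codon)."""
    if divergence_pct <= 0:
        return protein
    out = list(protein)
    for i in range(1, len(out)):
        if rng.random() < divergence_pct / 100.0:
            choices = [aa for aa in AA20 if aa != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = _build_codons()
    return "".join(
        codons[aa][rng.integers(len(codons[aa]))] for aa in protein
    )


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def simulate_transcriptome(
    cfg: SimulationConfig,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Toxin-bearing transcripts plus decoy housekeeping ORFs.

    Each toxin transcript embeds one template protein (possibly point-
    mutated at ``divergence_pct``) back-translated with uniform codon
    choice, guarded by an in-frame stop just before the start codon so
    the planted ORF is exactly recoverable; decoys are random ORFs with a
    housekeeping-like (cysteine-poor) composition inside random UTRs.
    The truth table records the planted family, coordinates, frame and
    domain span.
    """
    rng = cfg.rng(1)
    templates = build_template_proteins(cfg)
    records: list[TranscriptRecord] = []
    rows = []
    counter = 0

    for k in range(cfg.n_toxin_transcripts):
        template, protein, span = templates[k % len(templates)]
        mutated = _mutate_protein(protein, cfg.divergence_pct, rng)
        cds = _back_translate(mutated, rng)
        utr5 = _random_nt(rng, int(rng.integers(9, 31))) + "TAA"
        utr3 = _random_nt(rng, int(rng.integers(10, 41)))
        seq = utr5 + cds + "TGA" + utr3
        counter += 1
        tid = f"TRINITY_DN{counter}_c0_g1_i1"
        records.append(TranscriptRecord(tid, seq))
        rows.append(
            {
                "transcript_id": tid,
                "is_toxin": True,
                "template_id": template.reference_id,
                "family": template.family,
                "pattern": template.pattern_name,
                "frame": len(utr5) % 3 + 1,
                "orf_start": len(utr5),
                "orf_end": len(utr5) + 3 * len(mutated),
                "domain_start": span[0],
                "domain_end": span[1],
                "protein_sequence": mutated,
            }
        )

    for _ in range(cfg.n_decoy_transcripts):
        length = int(rng.integers(60, 201))
        weights = np.full(20, (1 - 0.01) / 19)
        weights[AA20.index("C")] = 0.01
        body = "".join(rng.choice(list(AA20), size=length - 1, p=weights))
        protein = "M" + body
        cds = _back_translate(protein, rng)
        utr5 = _random_nt(rng, int(rng.integers(9, 31))) + "TAA"
        utr3 = _random_nt(rng, int(rng.integers(10, 41)))
        counter += 1
        tid = f"TRINITY_DN{counter}_c0_g1_i1"
        records.append(TranscriptRecord(tid, utr5 + cds + "TGA" + utr3))
        rows.append(
            {
                "transcript_id": tid,
                "is_toxin": False,
                "template_id": "",
                "family": "",
                "pattern": "",
                "frame": len(utr5) % 3 + 1,
                "orf_start": len(utr5),
                "orf_end": len(utr5) + 3 * len(protein),
                "domain_start": -1,
                "domain_end": -1,
                "protein_sequence": protein,
            }
        )

    return records, pd.DataFrame(rows)


def simulate_quant_table(
    cfg: SimulationConfig, feature_ids: list[str] | None = None
) -> tuple[QuantTable, pd.DataFrame]:
    """3+3 area table with planted group enrichment and missingness.

    Feature directions alternate tentacle/mucus; the planted fold change
    multiplies the enriched group's mean.  A configurable fraction of
    features are "exclusive": all cells of the off group are MISSING.
    Remaining cells go missing independently at ``missingness_rate``.
    ``feature_ids`` optionally names the leading features (e.g. transcript
    ids, to tie the table to a simulated transcriptome); the rest get
    synthetic F-numbered ids.
    """
    rng = cfg.rng(2)
    groups = list(cfg.layout)
    columns = pd.MultiIndex.from_tuples(
        [(g, s) for g in groups for s in range(1, cfg.layout[g] + 1)],
        names=["group", "sample"],
    )
    values = np.empty((cfg.n_features, len(columns)))
    truth_rows = []
    index = [f"F{i + 1:04d}" for i in range(cfg.n_features)]
    if feature_ids:
        index[: len(feature_ids)] = feature_ids[: cfg.n_features]
    for i in range(cfg.n_features):
        direction = groups[i % 2]
        off_group = groups[(i + 1) % 2]
        exclusive = rng.random() < cfg.exclusive_fraction
        base = rng.normal(cfg.area_log_mean, 1.0)
        row = []
        for g, _s in columns:
            mu = base + (math.log(cfg.fold_change) if g == direction else 0.0)
            row.append(math.exp(rng.normal(mu, cfg.area_log_sigma)))
        row = np.array(row)
        missing = rng.random(len(columns)) < cfg.missingness_rate
        if exclusive:
            missing = missing | np.array([g == off_group for g, _s in columns])
        row[missing] = np.nan
        values[i] = row
        truth_rows.append(
            {
                "feature_id": index[i],
                "direction": direction,
                "fold_change": cfg.fold_change,
                "exclusive": exclusive,
            }
        )
    table = QuantTable(
        pd.DataFrame(values, index=pd.Index(index, name="feature_id"), columns=columns),
        dict(cfg.layout),
    )
    return table, pd.DataFrame(truth_rows)


def simulate_peptidome(
    cfg: SimulationConfig, proteins: list | None = None
) -> tuple[list[PeptideObservation], pd.DataFrame]:
    """Peptides cut from precursor proteins with planted P1 preferences.

    The upstream flank residue of every generated peptide is drawn from
    ``cleavage_pref`` (stated probabilities; the remaining mass is spread
    uniformly over the unstated residues).  A ``cterm_fraction`` share of
    peptides are C-terminal fragments, whose downstream side is a
    precursor boundary.  PTMs (Met oxidation, else N-terminal
    acetylation) are sprinkled at ``ptm_rate``.
    """
    rng = cfg.rng(3)
    if proteins is None:
        proteins = [
            (
                f"PROT_{i + 1:04d}",
                "".join(rng.choice(list(AA20), size=cfg.precursor_len)),
            )
            for i in range(cfg.n_precursor_proteins)
        ]
    else:
        proteins = [
            (p.protein_id, p.aa_sequence.rstrip("*"))
            if hasattr(p, "aa_sequence")
            else (p[0], p[1])
            for p in proteins
        ]
    if not proteins:
        raise ValueError("precursor protein set is empty")

    pref_residues = sorted(cfg.cleavage_pref)
    pref_probs = [cfg.cleavage_pref[r] for r in pref_residues]
    rest = [aa for aa in AA20 if aa not in cfg.cleavage_pref]
    rest_mass = 1.0 - sum(pref_probs)
    residues = pref_residues + rest
    probs = np.array(pref_probs + [rest_mass / len(rest)] * len(rest))
    probs = probs / probs.sum()

    lmin, lmax = cfg.peptide_len
    peptides: list[PeptideObservation] = []
    truth_rows = []
    attempts_cap = 50
    for _k in range(cfg.n_peptides):
        upstream = residues[int(rng.choice(len(residues), p=probs))]
        cterm = rng.random() < cfg.cterm_fraction
        found = None
        for _a in range(attempts_cap):
            pid, pseq = proteins[int(rng.integers(len(proteins)))]
            if cterm:
                starts = [
                    i + 1
                    for i in range(len(pseq) - lmin)
                    if pseq[i] == upstream and lmin <= len(pseq) - (i + 1) <= lmax
                ]
            else:
                starts = [
                    i + 1
                    for i in range(len(pseq) - lmin - 1)
                    if pseq[i] == upstream
                ]
            if starts:
                start = int(starts[int(rng.integers(len(starts)))])
                if cterm:
                    seq = pseq[start:]
                else:
                    plen = int(rng.integers(lmin, lmax + 1))
                    plen = min(plen, len(pseq) - start - 1)  # keep a downstream flank
                    seq = pseq[start : start + plen]
                found = (pid, pseq, start, seq)
                break
        if found is None:
            continue  # pathological preference/protein combination
        pid, pseq, start, seq = found
        mods: list[tuple[object, str]] = []
        if rng.random() < cfg.ptm_rate:
            if "M" in seq:
                mods.append((seq.index("M"), "oxidation"))
            else:
                mods.append(("N-term", "acetylation"))
        fraction = "tentacle" if rng.random() < 0.5 else "mucus"
        layer = "RA_peptidome" if rng.random() < 0.5 else "NRNA_peptidome"
        area = math.exp(rng.normal(cfg.area_log_mean, cfg.area_log_sigma))
        end = start + len(seq)
        downstream = pseq[end] if end < len(pseq) else "BOUNDARY"
        peptides.append(
            PeptideObservation(
                sequence=seq,
                modifications=mods,
                precursor_ids=[pid],
                fraction=fraction,
                layer=layer,
                areas={(fraction, 1): area},
            )
        )
        truth_rows.append(
            {
                "sequence": seq,
                "protein_id": pid,
                "offset": start,
                "upstream": upstream,
                "downstream": downstream,
                "fraction": fraction,
                "layer": layer,
                "n_mods": len(mods),
            }
        )
    return peptides, pd.DataFrame(truth_rows)
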