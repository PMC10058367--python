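# anemotox

Multi-omic toxin bioprospection for sea anemone tentacle and mucus
tissues.

Sea anemone venoms are rich in short, cysteine-stabilised peptide toxins
(potassium/sodium channel modulators, protease inhibitors,
phospholipases) that are promising pharmacological leads. A practical
way to find them without a genome is to integrate three layers of
evidence: a tentacle transcriptome (what *can* be made), a tentacle and
mucus proteome (what *is* made, and where), and a peptidome of naturally
generated fragments (how precursors are processed). `anemotox`
implements that integration as a tested, reusable pipeline for
bioinformaticians working on cnidarian venom — exercisable end to end on
built-in synthetic data with known ground truth.

## What it computes

* **ORF prediction** — six-frame translation and longest-ORF calling
  with TransDecoder-style completeness classes, plus assembly metrics
  (N50, transcript/gene counts). Default minimum 50 aa, chosen so short
  toxin precursors survive.
* **Similarity search** — exact affine-gap Smith–Waterman (BLOSUM62,
  gap open 11 / extend 1) against a ToxProt-style reference with
  Karlin–Altschul E-values, `E = K·m·n·e^(−λS)` (λ = 0.267, K = 0.041),
  cutoff `E ≤ 1e−4`, and family → category assignment.
* **Domain scanning** — PROSITE-like cysteine-spacing patterns for
  ShKT, Kunitz, Kazal, BDS/defensin, EGF (and optional low-confidence
  F5/8C, C-type lectin, SRCR), plus cysteine-framework extraction
  (`C-1-C-14-C-9-C-6-C-0-C` style).
* **Enrichment** — the PEAKS-export quantitative procedure: `-` vs 0
  missingness coding, floor imputation (1e−2), total-area
  normalization, the ≥ 2-of-3 presence filter, group means with mean
  replacement, and tentacle/mucus enrichment calls.
* **Peptidome analytics** — PTM-aware monoisotopic masses, exact
  peptide-to-precursor mapping (optional I/L equivalence), P1/P1′
  cleavage-site frequency tables, mass histograms.
* **Evidence integration** — cross-omics confirmation (≥ 2 sample-level
  observations across proteome + peptidomes) and actitoxin nomenclature
  (`Κ-actitoxin-Bcs1a` …).
* **Synthetic data** — seeded generators for every input above, with
  truth tables: planted domains, planted 10-fold enrichment with 20%
  missingness, planted P1 preferences.

See `docs/methods.md` for the conventions and the reasoning behind each
default.

## Worked example

Simulate a full input set (12 toxin transcripts over 5 families among
20 decoys, a 3 + 3 tentacle/mucus area table, a 2000-peptide peptidome)
and run every stage:

```bash
anemotox simulate --seed 3 --out sim
anemotox all --indir sim --out run
```

`run/candidates/toxin_candidates_similarity.tsv` then begins:

```text
Toxin	Trinity Code	Transcript (Identity)	E-Value	Toxin Family	Tentacle/Mucus	Omic Approach
U-actitoxin-Bcs12a	TRINITY_DN10_c0_g1_i1	U-actitoxin-Avd12a (100.0%)	1.2E-39	EGF-domain peptide	+/+	Proteome, RA peptidome, NRNA peptidome
U-actitoxin-Bcs12b	TRINITY_DN5_c0_g1_i1	U-actitoxin-Avd12a (100.0%)	1.2E-39	EGF-domain peptide	−/+	Proteome
U-actitoxin-Bcs5a	TRINITY_DN4_c0_g1_i1	PI-actitoxin-Avd5a (100.0%)	1.2E-47	Kazal-type serine protease inhibitor domain	+/+	Proteome, RA peptidome, NRNA peptidome
```

Each row is one candidate: its coined actitoxin name (species code Bcs,
family number inherited from the best hit, isoform letter advancing
a, b, …), the transcript encoding it, the best reference hit with
identity and E-value, the toxin family, the tentacle/mucus presence
pattern (`−/+` = mucus only), and which MS layers support it. The run's
`integration_summary.json` reports, for the same run:

```json
{"layer_overlap": {"both": 5, "proteome_only": 6, "peptidome_only": 0, "neither": 1},
 "n_candidates": 12, "n_confirmed": 11, "n_similarity_based": 12, "n_domain_only": 0}
```

— 12 evidence-bearing transcripts, of which 11 are confirmed by mass
spectrometry in more than one sample; 5 are seen by both proteome and
peptidome, 6 by the proteome alone, and 1 transcript-only candidate
stays `putative_unconfirmed`.

The same stages are available as library functions:

```python
from anemotox import smith_waterman, cysteine_framework

smith_waterman("HEAGAWGHEE", "PAWHEAE").raw_score   # 17 (BLOSUM62, 11/1)
cysteine_framework("GLPCDCHGHTGTYWLNYYSKCPKGYGYTGRCRYLVGSCCYK")
# 'C-1-C-14-C-9-C-6-C-0-C'
```

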