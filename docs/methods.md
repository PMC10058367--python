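# Methods

This note documents the models and procedures implemented in `anemotox`,
the choices made where the underlying protocol was ambiguous, and what
the synthetic-data tests do and do not demonstrate.

## Scope and design

The package re-implements, at desk scale, a multi-omic bioprospection
workflow for sea anemone tentacle/mucus data: transcripts are translated
and ORF-called to build a protein database; predicted proteins are
searched against a ToxProt-style toxin reference and scanned for
venom-associated domains; tentacle-vs-mucus label-free quantification
yields enrichment calls; the peptidome layer contributes masses,
precursor mappings and cleavage-site statistics; and all layers are
integrated into named toxin candidates. Each stage consumes and produces
plain-text files (FASTA, TSV, JSON), so the stages can be run separately
or through the `anemotox` CLI.

## ORF calling

ORFs are called in all six frames. In `met_to_stop` mode each
stop-delimited codon segment contributes its longest Met-initiated run;
`stop_to_stop` keeps the whole segment. Completeness follows the
TransDecoder convention from the two ends of the call: M-start and stop
end = `complete`; stop end only = `5prime_partial`; M-start only =
`3prime_partial`; neither = `internal`. Codons containing N translate to
X. There is no coding-potential (Markov) scoring; the longest-ORF
heuristic is recorded in run provenance.

The default minimum ORF length is **50 aa** rather than TransDecoder's
100 aa: many sea anemone toxin precursors (the BDS-family potassium
channel toxins among them) are shorter than 100 residues, and a 100-aa
floor would silently remove exactly the molecules the pipeline exists to
find. All qualifying ORFs are kept by default (`single_best` off)
because several transcripts can encode one protein.

Assembly N50 is the largest length L such that transcripts of length
≥ L sum to at least half the assembly; gene counts group Trinity ids by
their prefix before the `_i<n>` isoform suffix.

## Similarity search

The search is an exact affine-gap Smith–Waterman (Gotoh) dynamic
program, affordable because desk-scale reference sets hold at most a few
thousand entries; heuristic seeded search is deliberately not
reproduced, so hit counts from heuristic tools are not expected to
match. Conventions:

* gap of length k costs `gap_open + k·gap_extend` (the common
  "open 11, extend 1" convention); defaults BLOSUM62 / 11 / 1;
* E-values are Karlin–Altschul, `E = K·m·n·exp(−λS)`, with the published
  gapped BLOSUM62 constants λ = 0.267, K = 0.041 (overridable); m is the
  query length and n the summed length of the (taxon-filtered) database;
* the significance cutoff defaults to E ≤ 1e−4;
* identity % is computed over alignment columns **including** gap
  columns — one of several conventions in circulation; it is fixed and
  stated so percentages are comparable across runs;
* among equally scoring optimal alignments, the reported one has the
  smallest query start, then smallest subject start; the top hit per
  query is max score, then min E-value, then lexicographic subject id.

Families map to four broad categories (neurotoxin, mixed-function
enzyme, membrane-active, unknown) through an editable TSV; families
absent from the map fall into "unknown" by design, mirroring how
uncharacterised families are reported in practice.

## Domain detection

Domains are detected with PROSITE-like spacing patterns (literal
residues or bracket classes separated by bounded wildcard gaps), not
profile HMMs. Most sea anemone toxin domains are cysteine-stabilised, so
cysteine spacing is a usable signature; it is nonetheless an
approximation, and every report labels the method "pattern-scan
(PFAM-like)". The default set covers ShKT, Kunitz, Kazal, BDS/defensin
and EGF; F5/8C, C-type lectin and SRCR ship as optional patterns flagged
low-confidence because they are not primarily cysteine-stabilised.
Pattern boundaries are validated against synthetic plants only and are
never asserted to equal curated domain boundaries.

Matching is leftmost with greedy gaps; the default scan is
non-overlapping. The cysteine framework of a sequence is reported as
`C-g1-C-g2-…-C` with gi the inter-cysteine residue counts.

## Quantification and enrichment

The quantitative procedure mirrors PEAKS-style exports end to end:

1. `-` (absent) is parsed as MISSING; a numeric 0 means detected with
   low signal. The two states are kept distinct because they are
   replaced differently.
2. Imputation: MISSING → 0, then 0 → floor (default 1e−2), with a
   per-cell provenance flag.
3. Normalization: the upstream protocol says only "standard
   normalization", which is undefined — the default here is total-area
   scaling (each sample scaled so its sum equals the grand mean of
   sample sums), with `none` available; the choice is logged.
   Normalization runs after the floor replacement.
4. Presence filter: a protein enters the comparison when detected
   (non-MISSING and > 0) in ≥ k of n replicates of **either** tissue
   (default 2 of 3), evaluated on the raw table. "Detected" includes
   low-signal zeros being excluded deliberately: presence means a
   positive measured area. The per-group OR reading (rather than pooling
   both tissues) is the natural reading of the design and is the
   implemented one.
5. Group means with mean replacement: the protocol sentence describing
   mean replacement is circular as written; it is disambiguated as —
   per group, the mean is taken over observed (non-imputed) cells and
   every floor-imputed cell is replaced by that mean; a group with no
   observed cell stays at the floor. The step can be disabled by
   skipping it.
6. Enrichment: the tissue with the larger group mean wins; means equal
   within a relative tolerance of 1e−9 (floating-point guard) are a
   tie. "Exclusive" flags the case where the other group was entirely
   imputed.

No significance testing is performed; the comparison is descriptive by
design. Category composition percentages are computed over category
assignments (a multi-category feature counts once per category) and
rounded half-up to one decimal.

## Peptidome analytics

Masses are monoisotopic throughout: standard residue masses (pyteomics
table) + water + fixed PTM deltas. The configured deltas are the
upstream search's variable modifications (oxidation +15.99, acetylation
+42.01, carbamidomethylation +57.02 Da) plus the neuropeptide maturation
marks amidation (−0.98402) and pyroglutamate-from-Gln (−17.02655),
needed for Antho-RFamide/LWamide-style precursors.

Peptides map to precursors by exact substring search; I/L equivalence is
off by default (exact database matching) and switchable, since the two
residues are isobaric. Both the residue upstream of the peptide
N-terminus (P1) and the residue downstream of its C-terminus (P1′) are
cleavage events and are tabulated separately. Peptides flush with a
precursor terminus contribute BOUNDARY on that side; boundary cases are
excluded from the frequency denominators and both denominators are
reported, since C-terminal fragments of processed precursors make the
downstream denominator materially smaller. Multi-mapping peptides count
once via their first mapping in deterministic (protein, offset) order by
default ("all mappings" is available); single-counting avoids inflating
precursors with many copies.

Mass histograms use half-open bins `[origin + k·w, origin + (k+1)·w)`.

## Evidence integration and nomenclature

A transcript with a similarity hit or a domain match becomes a
candidate. *Confirmed* means ≥ 2 sample-level MS observations summed
across the proteome (replicate count) and the two peptidome
preparations (each a pooled sample per tissue fraction, so each
fraction-level detection counts as one observation); the threshold and
the summing-across-layers reading are configurable via `min_samples`.
Reports partition candidates into a similarity-based table and a
domain-only table (domain-only candidates are reported by transcript id,
without a coined name), and tally the proteome/peptidome overlap.

New names follow sea anemone actitoxin nomenclature: activity prefix +
"-actitoxin-" + species code + family number + isoform letter. The
family number is inherited from the best hit's own name when parseable
(…Bgr3d → 3), else the next unused integer — a heuristic, since no
published rule states it. The isoform letter advances past collisions;
more than 26 isoforms in one family is an error. Prefixes are stored as
ASCII tokens (U, Kappa, Pi, Delta, …) and rendered Greek by default or
ASCII on request. The integrator issues the neutral prefix U (unknown
activity) for all new candidates, since no activity assay is in scope.

## Synthetic data

The generators emulate the study design with full ground truth:

* **Transcriptome** — toxin precursors built as M + hydrophobic
  signal-like stretch + propeptide + a mature region realising one of
  the default domain patterns with fixed, family-specific cysteine
  spacings (chosen so no default pattern matches another family's
  plant); back-translated with uniform codon choice; optionally
  point-mutated at a configured percent divergence (the initial Met is
  preserved); wrapped in random UTRs with an in-frame stop immediately
  before the start codon so the planted ORF is exactly recoverable.
  Decoys are random ORFs with a housekeeping-like, cysteine-poor
  (~1% C) composition. The matching reference set is the undiverged
  template proteins with family/taxon annotations.
* **Quantification** — 3 + 3 tentacle/mucus areas, log-normal
  (log-mean ln 1e8, log-sd 1.0 — areas of label-free MS are positive
  and right-skewed), 10-fold planted group differences alternating in
  direction, 20% missing cells, and a 5% share of "exclusive" features
  whose off-group is entirely missing. 300 features by default.
* **Peptidome** — 2000 peptides of 8–25 aa cut from random precursors
  such that each upstream flank is drawn from the planted P1 preference
  (Y 0.4, E 0.2, remainder uniform over the unstated residues); 20% are
  C-terminal fragments; PTMs sprinkled at 10%.

Everything is driven by numpy integer RNG substreams derived from one
seed, with no iteration-order dependence, so a fixed seed reproduces
byte-identical outputs.

What passing these tests shows: the algorithms recover exactly what was
planted under the stated noise model. What they do not show: robustness
to real-data phenomena the generator omits — codon bias, sequencing and
assembly error, shared peptides between paralogous precursors,
intensity-dependent missingness (the generator's missingness is
independent of abundance), retention-time effects, and domain variants
whose cysteine spacing falls outside the default pattern ranges.

## Problem sizes and numerical notes

The test suite and the acceptance script run the oracles at 100 random
alignment pairs (≤ 20 aa), 100 random transcripts (≤ 2 kb), and 200
random pattern strings; parameter recovery uses the generator defaults
above (300 features, 2000 peptides, 10–12 planted toxins). These sizes
keep a full run within a couple of minutes on one core while leaving
the statistical assertions (binomial 99% CI, ≥ 95% direction recovery)
well-powered. Degenerate inputs are errors, not silent results: empty
FASTA records, empty databases, zero-sum samples under total-area
normalization, unmappable peptidomes, out-of-range offsets.

## Known limitations

* Pattern-scan domain detection cannot express profile-HMM emission
  scores; diverged domains with unusual spacing are missed, and no
  E-value is attached to a domain match.
* The exact Smith–Waterman is O(mn) per pair in pure Python; it is
  meant for reference sets up to ~10⁴ entries, not genome-scale search.
* Enrichment calls carry no uncertainty; with 3 + 3 replicates and mean
  replacement, a direction is always produced for retained features.
* The namer does not recognise that a candidate might *be* an already
  described toxin (100% identity hits still receive a new name); the
  report's subject column carries the described toxin for such cases.
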