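"""Independent reference implementations used only by the test suite.

Each oracle is deliberately written with a different algorithmic
structure from the library code it checks (recursion instead of tabular
DP, pair enumeration instead of segment scanning, backtracking instead
of compiled regex) so agreement is meaningful.
"""

from __future__ import annotations

from functools import lru_cache

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = {"TAA", "TAG", "TGA"}

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: Standard monoisotopic residue masses (Da), frozen independently of the
#: mass library the implementation uses.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.0105646863


def peptide_mass_oracle(seq: str, mod_deltas: list[float] = ()) -> float:
    return sum(RESIDUE_MASS[ch] for ch in seq) + WATER + sum(mod_deltas)


# ---------------------------------------------------------------------------
# Affine-gap local alignment score by memoized recursion
# ---------------------------------------------------------------------------


def sw_score_oracle(query: str, subject: str, score_fn, gap_open: float,
                    gap_extend: float) -> float:
    """Best local alignment score; gap of length k costs open + k*extend."""

    @lru_cache(maxsize=None)
    def best_from(i: int, j: int, state: str) -> float:
        opts = [0.0] if state == "M" else [-1e18]
        if i < len(query) and j < len(subject):
            opts.append(score_fn(query[i], subject[j]) + best_from(i + 1, j + 1, "M"))
        if i < len(query):
            cost = gap_extend if state == "I" else gap_open + gap_extend
            opts.append(-cost + best_from(i + 1, j, "I"))
        if j < len(subject):
            cost = gap_extend if state == "D" else gap_open + gap_extend
            opts.append(-cost + best_from(i, j + 1, "D"))
        return max(opts)

    best = 0.0
    for i in range(len(query) + 1):
        for j in range(len(subject) + 1):
            best = max(best, best_from(i, j, "M"))
    best_from.cache_clear()
    return best


# ---------------------------------------------------------------------------
# ORF enumeration by start/stop pair scanning
# ---------------------------------------------------------------------------


def orf_oracle(seq: str, min_len: int, mode: str):
    """Enumerate every qualifying (start, stop) pair in all six frames.

    Returns a sorted list of (frame, start, end, aa, completeness) tuples
    with forward-strand 0-based half-open coordinates, matching the
    library's output contract.
    """
    results = []
    for frame in (1, 2, 3, -1, -2, -3):
        strand = seq.translate(_COMPLEMENT)[::-1] if frame < 0 else seq
        offset = abs(frame) - 1
        codons = [strand[k: k + 3] for k in range(offset, len(strand) - 2, 3)]
        n = len(codons)

        def run_from(c0: int):
            """Scan forward from codon c0 to the first stop (or the end)."""
            aa = []
            for k in range(c0, n):
                if codons[k] in STOP_CODONS:
                    return aa, k, True
                aa.append("X" if "N" in codons[k] else GENETIC_CODE[codons[k]])
            return aa, n, False

        claimed_stops = set()
        if mode == "met_to_stop":
            # every ATG paired with its stop; keep the longest per stop
            pairs = []
            for c0 in range(n):
                if codons[c0] == "ATG":
                    aa, stop, has_stop = run_from(c0)
                    pairs.append((stop, c0, aa, has_stop))
            pairs.sort()
            for stop, c0, aa, has_stop in pairs:
                if stop in claimed_stops:
                    continue
                claimed_stops.add(stop)
                results.append(_record(frame, len(strand), offset, c0, aa,
                                       codons[c0] == "ATG", has_stop))
        else:
            starts = [0] + [k + 1 for k in range(n) if codons[k] in STOP_CODONS]
            for c0 in starts:
                if c0 >= n or codons[c0] in STOP_CODONS:
                    continue
                aa, _stop, has_stop = run_from(c0)
                results.append(_record(frame, len(strand), offset, c0, aa,
                                       codons[c0] == "ATG", has_stop))
    results = [r for r in results if len(r[3]) >= min_len]
    results.sort(key=lambda r: (-len(r[3]), r[0], r[1]))
    return results


def _record(frame, strand_len, offset, c0, aa, starts_m, has_stop):
    s = offset + 3 * c0
    e = s + 3 * len(aa)
    if frame < 0:
        s, e = strand_len - e, strand_len - s
    if starts_m and has_stop:
        completeness = "complete"
    elif has_stop:
        completeness = "5prime_partial"
    elif starts_m:
        completeness = "3prime_partial"
    else:
        completeness = "internal"
    return (frame, s, e, "".join(aa), completeness)


# ---------------------------------------------------------------------------
# Backtracking pattern matcher
# ---------------------------------------------------------------------------


def pattern_match_oracle(seq: str, elements, overlapping: bool = False):
    """Leftmost, greedy-gap matches of a parsed spacing pattern."""

    def match_at(pos: int, k: int):
        if k == len(elements):
            return pos
        element = elements[k]
        if element[0] == "lit":
            if pos < len(seq) and seq[pos] in element[1]:
                return match_at(pos + 1, k + 1)
            return None
        _, lo, hi = element
        for g in range(hi, lo - 1, -1):  # greedy: longest gap first
            if pos + g <= len(seq):
                end = match_at(pos + g, k + 1)
                if end is not None:
                    return end
        return None

    matches = []
    pos = 0
    while pos < len(seq):
        end = match_at(pos, 0)
        if end is not None:
            matches.append((pos, end, seq[pos:end]))
            pos = pos + 1 if overlapping else end
        else:
            pos += 1
    return matches


def n50_oracle(lengths) -> int:
    """Cumulative-sum N50 over descending lengths."""
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    acc = 0
    for length in ordered:
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable for non-empty input")
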