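"""ORF prediction under standard and variant genetic codes.

Several of the viruses this pipeline recovers (sobemo-like and some
mitovirus-like genomes) only show an intact replicase ORF when UGA is
read as tryptophan, as in the yeast/mold/invertebrate mitochondrial
codes (NCBI translation tables 3, 4 and 5).  This module packages those
codon tables, predicts stop-to-stop ORFs on both strands, picks the code
that best explains the replicase homology region, and detects homology
regions that no single ORF can cover — the endogenization signal used by
the triage rules.
"""

from __future__ import annotations

from dataclasses import dataclass

# NCBI translation table 1 (standard), written out codon by codon.
_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

# Differences from the standard table, per NCBI table id.
_TABLE_DIFFS: dict[int, dict[str, str]] = {
    1: {},
    # yeast mitochondrial
    3: {"ATA": "M", "CTT": "T", "CTC": "T", "CTA": "T", "CTG": "T", "TGA": "W"},
    # mold/protozoan/coelenterate mitochondrial
    4: {"TGA": "W"},
    # invertebrate mitochondrial
    5: {"ATA": "M", "AGA": "S", "AGG": "S", "TGA": "W"},
}

SUPPORTED_CODES = tuple(sorted(_TABLE_DIFFS))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon→amino-acid map identified by its NCBI table number."""

    code_id: int
    codon_map: dict  # codon -> aa, stops as "*"

    @property
    def stops(self) -> frozenset:
        return frozenset(c for c, aa in self.codon_map.items() if aa == "*")


def genetic_code(code_id: int) -> GeneticCode:
    if code_id not in _TABLE_DIFFS:
        raise ValueError(
            f"unsupported genetic code {code_id}; supported: {SUPPORTED_CODES}"
        )
    table = dict(_STANDARD_TABLE)
    table.update(_TABLE_DIFFS[code_id])
    return GeneticCode(code_id, table)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(seq: str, code_id: int = 1) -> str:
    """Translate a nucleotide sequence whose length is divisible by 3.

    Stops render as ``*``; any codon containing a non-ACGT character
    (e.g. N) renders as ``X``.
    """
    code = genetic_code(code_id)
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    aas = []
    for i in range(0, len(seq), 3):
        aas.append(code.codon_map.get(seq[i : i + 3], "X"))
    return "".join(aas)


@dataclass(frozen=True)
class OrfPrediction:
    """One predicted ORF, located on the forward strand of its contig.

    ``span`` is 0-based half-open in forward-strand coordinates and
    includes the terminal stop codon when one is present (the protein
    never does), so span length is ``3 * (len(protein) + 1)`` for
    stop-terminated ORFs and ``3 * len(protein)`` at sequence edges.
    ``frame`` is 0–2 relative to the 5' end of the coding strand.
    """

    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    code_id: int
    protein: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length_codons(self) -> int:
        return len(self.protein)


def _scan_strand(seq: str, code: GeneticCode, min_len_codons: int):
    """Yield (frame, start, end, protein, has_stop) in local coordinates."""
    n = len(seq)
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        seg_start_idx = None  # index into codon_starts of first ATG in segment
        for pos in codon_starts:
            codon = seq[pos : pos + 3]
            aa = code.codon_map.get(codon, "X")
            if aa == "*":
                if seg_start_idx is not None:
                    protein = translate(seq[seg_start_idx:pos], code.code_id)
                    if len(protein) >= min_len_codons:
                        yield frame, seg_start_idx, pos + 3, protein, True
                seg_start_idx = None
            elif codon == "ATG" and seg_start_idx is None:
                seg_start_idx = pos
        if seg_start_idx is not None:
            last = frame + 3 * ((n - frame) // 3)
            protein = translate(seq[seg_start_idx:last], code.code_id)
            if len(protein) >= min_len_codons:
                yield frame, seg_start_idx, last, protein, False


def find_orfs(
    seq: str,
    code_id: int = 1,
    min_len_codons: int = 200,
    search_both_strands: bool = True,
    contig_id: str = "",
) -> list[OrfPrediction]:
    """Predict ORFs: first in-frame ATG to the next stop, per frame.

    Every maximal stop-to-stop interval containing an in-frame start and
    yielding at least ``min_len_codons`` sense codons is reported, on
    both strands by default, sorted by protein length descending (ties:
    forward strand first, then ascending start).
    """
    if min_len_codons < 1:
        raise ValueError("min_len_codons must be >= 1")
    seq = seq.upper()
    code = genetic_code(code_id)
    n = len(seq)
    orfs: list[OrfPrediction] = []
    for frame, start, end, protein, _ in _scan_strand(seq, code, min_len_codons):
        orfs.append(OrfPrediction(contig_id, "+", frame, start, end, code_id, protein))
    if search_both_strands:
        rc = reverse_complement(seq)
        for frame, start, end, protein, _ in _scan_strand(rc, code, min_len_codons):
            # map local (rc) coordinates back onto the forward strand
            orfs.append(
                OrfPrediction(
                    contig_id, "-", frame, n - end, n - start, code_id, protein
                )
            )
    orfs.sort(key=lambda o: (-o.length_codons, o.strand != "+", o.start))
    return orfs


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def best_code_for_contig(
    seq: str,
    codes=SUPPORTED_CODES,
    homology_span: tuple[int, int] | None = None,
    min_len_codons: int = 30,
) -> tuple[int, float]:
    """Pick the genetic code whose single longest ORF best covers the
    replicase homology span.

    Returns ``(code_id, coverage)`` where coverage is the largest
    fraction of the homology span covered by any one ORF under that
    code.  Ties (including the no-internal-UGA case, where all codes
    agree) break toward table 1.
    """
    if homology_span is None:
        homology_span = (0, len(seq) - len(seq) % 3)
    h_start, h_end = homology_span
    if not 0 <= h_start <= h_end <= len(seq):
        raise ValueError(f"homology span {homology_span} outside contig")
    span_len = h_end - h_start
    ordered = sorted(codes, key=lambda c: (c != 1, c))
    best_code, best_cov = ordered[0], 0.0
    if span_len == 0:
        return best_code, 0.0
    for code_id in ordered:
        cov = 0.0
        for orf in find_orfs(seq, code_id, min_len_codons=min_len_codons):
            cov = max(cov, _overlap(orf.start, orf.end, h_start, h_end) / span_len)
        if cov > best_cov:
            best_code, best_cov = code_id, cov
    return best_code, best_cov


def detect_interrupted_orf(
    homology_span: tuple[int, int],
    orfs: list[OrfPrediction],
    coverage_threshold: float = 0.9,
) -> tuple[bool, int]:
    """Decide whether the homology region is interrupted (no single ORF
    covers >= ``coverage_threshold`` of it) — the frameshift/premature-stop
    signature of an endogenized viral copy.

    ``n_breaks`` is the number of distinct ORFs a greedy tiling needs to
    reach the threshold, minus one (0 when a single ORF suffices or when
    no ORF overlaps the span at all).
    """
    h_start, h_end = homology_span
    span_len = h_end - h_start
    if span_len <= 0:
        return False, 0
    clipped = []
    for orf in orfs:
        s, e = max(orf.start, h_start), min(orf.end, h_end)
        if e > s:
            clipped.append((s, e))
    if not clipped:
        return True, 0
    best_single = max((e - s) / span_len for s, e in clipped)
    if best_single >= coverage_threshold:
        return False, 0
    # greedy interval cover: add the ORF contributing the most new coverage
    covered: list[tuple[int, int]] = []
    used = 0
    remaining = list(clipped)

    def union_len(intervals):
        total, prev_end = 0, None
        for s, e in sorted(intervals):
            if prev_end is None or s > prev_end:
                total += e - s
                prev_end = e
            elif e > prev_end:
                total += e - prev_end
                prev_end = e
        return total

    current = 0
    while remaining and current / span_len < coverage_threshold:
        gains = [(union_len(covered + [iv]) - current, iv) for iv in remaining]
        gain, best_iv = max(gains, key=lambda g: g[0])
        if gain <= 0:
            break
        covered.append(best_iv)
        remaining.remove(best_iv)
        current = union_len(covered)
        used += 1
    return True, max(0, used - 1)
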