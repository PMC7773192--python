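"""Barcode demultiplexing, full-length read structure, and QC filters.

Demultiplexing scores each 24-nt cell barcode against the first and
last 150 bases of a read (both strands) with a semi-global alignment
(barcode end-to-end, free end gaps in the window) under match +2,
mismatch −2, gap open −3, gap extend −1; a read is assigned to the
best-scoring barcode when that score reaches the cutoff (default 31)
and is unique.

Full-length reads are recognised from the amplicon architecture
(anchor + ATGGG + cDNA + polyA + rc(barcode) + rc(anchor)): the anchor
must be found near both read ends, with the RT end identified by its
adjacent barcode/polyT tract, then the read is oriented to mRNA sense
and trimmed of all adapter sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from scanlong.core_io import ReadRecord, revcomp

DEFAULT_CUTOFF = 31
DEFAULT_WINDOW = 150
ANCHOR_MAX_EDITS = 5
POLY_RUN_MIN = 15
POLY_RUN_NEAR = 10


def _make_aligner(match=2, mismatch=-2, gap_open=-3, gap_extend=-1):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aligner.query_end_gap_score = 0  # free end gaps in the window
    return aligner


_ALIGNER = _make_aligner()


def score_barcode(window: str, barcode: str) -> int:
    """Best semi-global alignment score of a barcode in a window.

    The barcode aligns end-to-end, the window has free end gaps; the
    maximum over the window and its reverse complement is returned. An
    exact match scores 48 (24 matches x +2).
    """
    if len(barcode) != 24:
        raise ValueError(f"barcode length {len(barcode)} != 24")
    if not window:
        raise ValueError("empty window")
    fwd = _ALIGNER.score(window, barcode)
    rev = _ALIGNER.score(window, revcomp(barcode))
    return int(max(fwd, rev))


@dataclass
class BarcodeAssignment:
    read_id: str
    best_barcode: int | None
    best_score: int
    runner_up_score: int
    reason: str  # assigned | below_cutoff | tie

    @property
    def assigned(self) -> bool:
        return self.reason == "assigned"


def demultiplex(
    read: ReadRecord,
    barcodes: Sequence[str],
    cutoff: int = DEFAULT_CUTOFF,
    window: int = DEFAULT_WINDOW,
) -> BarcodeAssignment:
    """Assign a read to a cell by the highest barcode score.

    Scores every barcode over the first and last ``min(window, len)``
    bases (both windows, both strands); assigns the argmax if its score
    reaches ``cutoff`` ("score below 31 discarded" — equality passes)
    and is unique, else reports below_cutoff / tie.
    """
    if not barcodes:
        raise ValueError("no barcodes supplied")
    seq = read.sequence
    w = min(window, len(seq))
    head, tail = seq[:w], seq[-w:]
    windows = [head] if head == tail else [head, tail]
    scores = np.array(
        [max(score_barcode(win, bc) for win in windows) for bc in barcodes]
    )
    order = np.argsort(scores)
    best = int(order[-1])
    best_score = int(scores[best])
    runner_up = int(scores[order[-2]]) if len(scores) > 1 else -(10 ** 9)
    if best_score < cutoff:
        return BarcodeAssignment(read.read_id, None, best_score, runner_up, "below_cutoff")
    if best_score == runner_up:
        return BarcodeAssignment(read.read_id, None, best_score, runner_up, "tie")
    return BarcodeAssignment(read.read_id, best, best_score, runner_up, "assigned")


def filter_reads(
    reads: Iterable[ReadRecord], min_q: float = 7.0, min_len: int = 100
):
    """Discard low-quality (mean qscore < 7) and short (< 100 bp) reads.

    Returns (kept, stats); stats counts discards by reason. Boundary
    values pass (the filters are strict less-than exclusions).
    """
    kept: list[ReadRecord] = []
    stats = {"kept": 0, "low_quality": 0, "short": 0, "input": 0}
    for r in reads:
        stats["input"] += 1
        if r.mean_q < min_q:
            stats["low_quality"] += 1
        elif len(r) < min_len:
            stats["short"] += 1
        else:
            kept.append(r)
            stats["kept"] += 1
    return kept, stats


# ---------------------------------------------------------------------------
# read structure


@dataclass
class AnchorHit:
    start: int
    end: int
    orientation: str  # "+" anchor as-is, "-" reverse complement
    edits: int


@dataclass
class ReadStructure:
    tso_end: AnchorHit | None
    rt_end: AnchorHit | None
    internal_anchor_hits: int
    klass: str  # full_length | tso_only | polyT_only | none | chimeric
    sense: str | None = None  # "+" read is amplicon sense, "-" antisense


def _find_anchor_hits(seq: str, anchor: str, max_edits: int = ANCHOR_MAX_EDITS):
    hits: list[AnchorHit] = []
    for pattern, orient in ((anchor, "+"), (revcomp(anchor), "-")):
        res = edlib.align(pattern, seq, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] < 0:
            continue
        last_end = -1
        for s, e in res["locations"]:
            if s is None:
                s = 0
            if s > last_end:  # keep non-overlapping hits
                hits.append(AnchorHit(s, e + 1, orient, res["editDistance"]))
                last_end = e
    hits.sort(key=lambda h: h.start)
    return hits


def _has_poly_run(segment: str, base: str, min_run: int = POLY_RUN_MIN) -> bool:
    run = 0
    for ch in segment:
        run = run + 1 if ch == base else 0
        if run >= min_run:
            return True
    return False


def find_structure(read: ReadRecord, design) -> ReadStructure:
    """Locate the TSO and RT ends of a read from anchor hits.

    Anchors are matched with <=5 edits over the 25-nt anchor. A terminal
    anchor hit is an RT end when a polyT (read start) or polyA (read
    end) run of >=15 bases lies within barcode distance of it; otherwise
    it is a TSO end. Hits away from both ends are internal; any internal
    hit marks the read chimeric.
    """
    seq = read.sequence
    anchor = design.anchor
    margin = len(anchor) + 24 + POLY_RUN_NEAR + 10
    hits = _find_anchor_hits(seq, anchor)
    start_hit = end_hit = None
    internal = 0
    for h in hits:
        if h.start <= margin and h.orientation == "+" and (start_hit is None or h.edits < start_hit.edits):
            start_hit = h
        elif h.end >= len(seq) - margin and h.orientation == "-" and (end_hit is None or h.edits < end_hit.edits):
            end_hit = h
        else:
            internal += 1
    if internal:
        return ReadStructure(None, None, internal, "chimeric")

    # RT-end signature: polyT right after the start anchor(+barcode), or
    # polyA just before the end anchor(-barcode)
    bc_span = 24 + POLY_RUN_NEAR
    start_is_rt = start_hit is not None and _has_poly_run(
        seq[start_hit.end : start_hit.end + bc_span + POLY_RUN_MIN + 10], "T"
    )
    end_is_rt = end_hit is not None and _has_poly_run(
        seq[max(0, end_hit.start - bc_span - POLY_RUN_MIN - 10) : end_hit.start], "A"
    )

    if start_hit and end_hit:
        if end_is_rt and not start_is_rt:
            return ReadStructure(start_hit, end_hit, 0, "full_length", "+")
        if start_is_rt and not end_is_rt:
            return ReadStructure(end_hit, start_hit, 0, "full_length", "-")
        # both or neither look like RT: ambiguous, not full length
        return ReadStructure(start_hit, end_hit, 0, "none", None)
    if start_hit or end_hit:
        h = start_hit or end_hit
        if (start_hit and start_is_rt) or (end_hit and end_is_rt):
            return ReadStructure(None, h, 0, "polyT_only")
        return ReadStructure(h, None, 0, "tso_only")
    return ReadStructure(None, None, 0, "none")


@dataclass
class FullLengthRead:
    read_id: str
    cell: int | str | None
    oriented_sequence: str  # mRNA sense, adapters and polyA trimmed
    transcribed_strand: str  # strand of the original read carrying the mRNA


def orient_and_trim(
    read: ReadRecord, structure: ReadStructure, assignment=None
) -> FullLengthRead:
    """Orient a full-length read to mRNA sense and strip all adapters.

    Removes the 5' anchor (+ATGGG when present), the polyA tract, the
    barcode and the 3' anchor. transcribed_strand is "+" when the read
    was already in amplicon sense, "-" when it had to be flipped.
    """
    if structure.klass != "full_length":
        raise ValueError(f"read {read.read_id} is not full length ({structure.klass})")
    seq = read.sequence
    if structure.sense == "-":
        n = len(seq)
        seq = revcomp(seq)
        tso = AnchorHit(n - structure.tso_end.end, n - structure.tso_end.start,
                        "+", structure.tso_end.edits)
        rt = AnchorHit(n - structure.rt_end.end, n - structure.rt_end.start,
                       "-", structure.rt_end.edits)
    else:
        tso, rt = structure.tso_end, structure.rt_end
    left = tso.end
    tail = seq[left : left + 8]
    idx = tail.find("ATGGG")
    if idx >= 0:
        left += idx + 5
    # strip rc(barcode) then the maximal polyA run abutting it
    right = rt.start - 24
    while right > left and seq[right - 1] == "A":
        right -= 1
    cell = getattr(assignment, "best_barcode", assignment)
    return FullLengthRead(
        read.read_id, cell, seq[left:right], "+" if structure.sense == "+" else "-"
    )


# ---------------------------------------------------------------------------
# cell-level QC


@dataclass
class CellQC:
    cell: str
    n_full_length_reads: int
    base_mapping_ratio: float
    n_detected_genes: int
    passed: bool


def evaluate_cell_filters(
    n_reads: int,
    mapping_ratio: float,
    n_genes: int,
    min_reads: int = 100_000,
    min_ratio: float = 0.85,
    min_genes: int = 3_000,
) -> bool:
    """Strict less-than exclusions: a cell fails only when a quantity is
    below its threshold; equality passes."""
    return n_reads >= min_reads and mapping_ratio >= min_ratio and n_genes >= min_genes


def compute_cell_qc(
    cell: str,
    full_length_reads: Sequence,
    alignments: Sequence,
    gene_counts: dict[str, float],
    min_reads: int = 100_000,
    min_ratio: float = 0.85,
    min_genes: int = 3_000,
) -> CellQC:
    """Cell filters: full-length read count, base mapping ratio, genes.

    base_mapping_ratio = aligned bases / total read bases over the
    cell's full-length reads; a cell passes when all three quantities
    reach their thresholds (strict less-than exclusions, equality
    passes).
    """
    n_reads = len(full_length_reads)
    total_bases = sum(
        len(getattr(r, "oriented_sequence", None) or getattr(r, "sequence", ""))
        for r in full_length_reads
    )
    aligned = sum(a.aligned_bases for a in alignments)
    ratio = aligned / total_bases if total_bases else 0.0
    ratio = min(ratio, 1.0)
    n_genes = sum(1 for v in gene_counts.values() if v > 0)
    passed = evaluate_cell_filters(n_reads, ratio, n_genes, min_reads, min_ratio, min_genes)
    return CellQC(cell, n_reads, ratio, n_genes, passed)


def length_histogram(reads: Iterable, bin_width: int = 100) -> dict[tuple[int, int], int]:
    """Read-length histogram with fixed-width bins keyed [lo, hi)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    out: dict[tuple[int, int], int] = {}
    for r in reads:
        n = len(getattr(r, "oriented_sequence", None) or getattr(r, "sequence", r))
        lo = (n // bin_width) * bin_width
        key = (lo, lo + bin_width)
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items()))
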