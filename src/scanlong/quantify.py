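"""Transcript assignment, RPG10k/RPT10k matrices, region classes, saturation.

Reads are assigned to annotated transcripts by junction compatibility:
a transcript is a candidate when it lies on the read's chrom and strand,
its junction chain contains the read's chain as a contiguous subchain
(within a +/-5 bp tolerance per junction edge), and its span covers the
read. The read's unit weight is split equally among candidates.
Expression is reported as reads per 10,000 assigned reads per gene
(RPG10k) and per transcript (RPT10k), with raw counts kept alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scanlong.core_io import AlignmentRecord, AnnotationIndex

log = logging.getLogger(__name__)

JUNCTION_TOL = 5


def _chain_suffix_match(read_chain, tx_chain, strand: str, tol: int) -> bool:
    """True iff read_chain matches the mRNA-3'-terminal run of tx_chain,
    each junction edge within +/-tol.

    polyT-primed RT anchors every cDNA at the transcript 3' end, so an
    incomplete read loses junctions only from the mRNA 5' side: on the
    plus strand the read chain must match the *last* n transcript
    junctions, on the minus strand the *first* n (genomic order).
    """
    n, m = len(read_chain), len(tx_chain)
    if n > m:
        return False
    if n == 0:
        return True
    sub = tx_chain[m - n :] if strand == "+" else tx_chain[:n]
    return all(
        abs(rj[0] - tj[0]) <= tol and abs(rj[1] - tj[1]) <= tol
        for rj, tj in zip(read_chain, sub)
    )


def assign_to_transcripts(
    aln: AlignmentRecord, index: AnnotationIndex, tol: int = JUNCTION_TOL
) -> dict[str, float]:
    """Weighted transcript assignment of one primary alignment.

    A transcript is a candidate when it is on the read's chrom and
    strand, its span covers the read blocks, the read's junction chain
    matches its chain at the mRNA 3' terminus (within +/-tol per edge),
    and the read's mRNA-5' block starts inside the corresponding
    transcript exon. The read's unit weight is split equally among
    candidates; no candidate -> unassigned (routed to region
    classification).
    """
    if aln.is_secondary or aln.is_supplementary:
        return {}
    read_chain = aln.junctions
    n = len(read_chain)
    hits = index.exon_overlaps(aln.chrom, aln.start, aln.end)
    tids = {tid for iv in hits for (gid, tid) in [iv.data]}
    candidates = []
    for tid in tids:
        t = index.transcripts[tid]
        if t.strand != aln.strand:
            continue
        if not (t.start - tol <= aln.start and aln.end <= t.end + tol):
            continue
        if not _chain_suffix_match(read_chain, t.junctions, t.strand, tol):
            continue
        # the read's 5'-terminal block must start inside the transcript
        # exon it is matched to (5' truncation stays within that exon)
        m = len(t.junctions)
        if t.strand == "+":
            first_exon = t.exons[m - n]
            if aln.start < first_exon[0] - tol:
                continue
        else:
            first_exon = t.exons[n]
            if aln.end > first_exon[1] + tol:
                continue
        candidates.append(tid)
    if not candidates:
        return {}
    w = 1.0 / len(candidates)
    return {tid: w for tid in sorted(candidates)}


@dataclass
class ExpressionMatrix:
    """Per-cell expression with raw counts and per-10k normalization."""

    gene_counts: pd.DataFrame  # cells x genes, raw (possibly fractional) counts
    transcript_counts: pd.DataFrame  # cells x transcripts
    rpg10k: pd.DataFrame
    rpt10k: pd.DataFrame

    @property
    def cells(self):
        return list(self.gene_counts.index)


def compute_matrix(
    cell_assignments: dict[str, list[dict[str, float]]],
    index: AnnotationIndex,
) -> ExpressionMatrix:
    """Build count and per-10k matrices from per-cell read assignments.

    ``cell_assignments`` maps cell -> list of per-read assignment dicts
    (one dict per assigned read). RPG10k(gene) = 10,000 x count(gene) /
    assigned-read total of the cell; gene counts are the summed weights
    of the gene's transcripts. Cells with zero assigned reads are
    omitted with a warning.
    """
    tx_rows = {}
    for cell, assignments in cell_assignments.items():
        acc: dict[str, float] = {}
        for a in assignments:
            for tid, w in a.items():
                acc[tid] = acc.get(tid, 0.0) + w
        if not acc:
            log.warning("cell %s has no assigned reads; omitted from matrices", cell)
            continue
        tx_rows[cell] = acc
    tx = pd.DataFrame.from_dict(tx_rows, orient="index").fillna(0.0).sort_index(axis=1)
    if tx.empty:
        empty = pd.DataFrame()
        return ExpressionMatrix(empty, empty, empty, empty)
    gene_of = {
        tid: index.transcripts[tid].gene_id if tid in index.transcripts else tid
        for tid in tx.columns
    }
    genes = tx.T.groupby([gene_of[t] for t in tx.columns]).sum().T
    totals = tx.sum(axis=1)
    rpt = tx.mul(10_000.0 / totals, axis=0)
    rpg = genes.mul(10_000.0 / totals, axis=0)
    return ExpressionMatrix(genes, tx, rpg, rpt)


# ---------------------------------------------------------------------------
# region classification


@dataclass
class RegionCounts:
    per_cell: pd.DataFrame  # cells x [exonic, intronic, intergenic]
    labels: dict[str, str]  # read_id -> label


def classify_regions(
    alignments_by_cell: dict[str, list[AlignmentRecord]], index: AnnotationIndex
) -> RegionCounts:
    """Label each read exonic / intronic / intergenic.

    Precedence exon > intron > intergenic: a read is exonic if any block
    overlaps an annotated exon, else intronic if any block overlaps a
    gene span, else intergenic. One label per read_id (primary
    alignments only).
    """
    labels: dict[str, str] = {}
    rows = {}
    for cell, alns in alignments_by_cell.items():
        counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
        for a in alns:
            if a.is_secondary or a.is_supplementary or a.read_id in labels:
                continue
            if any(index.exon_overlaps(a.chrom, s, e) for s, e in a.blocks):
                lab = "exonic"
            elif any(index.gene_overlaps(a.chrom, s, e) for s, e in a.blocks):
                lab = "intronic"
            else:
                lab = "intergenic"
            labels[a.read_id] = lab
            counts[lab] += 1
        rows[cell] = counts
    return RegionCounts(pd.DataFrame.from_dict(rows, orient="index"), labels)


def quantify_lncrna(
    alignments_by_cell: dict[str, list[AlignmentRecord]],
    region_labels: dict[str, str],
    lnc_index: AnnotationIndex,
    tol: int = JUNCTION_TOL,
) -> ExpressionMatrix:
    """Quantify lncRNAs from intergenic reads against a secondary reference.

    Only reads labelled intergenic against the main annotation
    participate; assignment and per-10k normalization follow the same
    rules as for known transcripts, normalized within the lncRNA
    compartment.
    """
    if not lnc_index.transcripts:
        log.warning("empty lncRNA reference; returning empty matrix")
        empty = pd.DataFrame()
        return ExpressionMatrix(empty, empty, empty, empty)
    cell_assignments = {}
    for cell, alns in alignments_by_cell.items():
        per_read = []
        for a in alns:
            if region_labels.get(a.read_id) != "intergenic":
                continue
            asg = assign_to_transcripts(a, lnc_index, tol)
            if asg:
                per_read.append(asg)
        cell_assignments[cell] = per_read
    return compute_matrix(cell_assignments, lnc_index)


# ---------------------------------------------------------------------------
# saturation


def saturation(
    read_assignments: list[dict[str, float]],
    index: AnnotationIndex,
    depths: list[int],
    n_draws: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Detected genes/isoforms vs subsampled read depth.

    For each depth, reads are subsampled without replacement ``n_draws``
    times; mean numbers of genes and transcripts with count > 0 are
    reported. Deterministic given seed.
    """
    total = len(read_assignments)
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total reads {total}")
        g_counts, t_counts = [], []
        for _ in range(n_draws):
            idx = rng.choice(total, size=depth, replace=False) if depth else []
            genes, txs = set(), set()
            for i in idx:
                for tid in read_assignments[int(i)]:
                    txs.add(tid)
                    genes.add(
                        index.transcripts[tid].gene_id
                        if tid in index.transcripts
                        else tid
                    )
            g_counts.append(len(genes))
            t_counts.append(len(txs))
        rows.append(
            {
                "depth": depth,
                "mean_genes": float(np.mean(g_counts)),
                "mean_isoforms": float(np.mean(t_counts)),
            }
        )
    return pd.DataFrame(rows)
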