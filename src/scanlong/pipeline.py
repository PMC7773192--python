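"""End-to-end orchestration helpers shared by the CLI and scripts.

Each function wires together one pipeline stage from the lower-level
modules; nothing here adds behaviour beyond composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from scanlong.core_io import AlignmentRecord, AnnotationIndex, ReadRecord, Transcript
from scanlong.demux import (
    BarcodeAssignment,
    FullLengthRead,
    demultiplex,
    filter_reads,
    find_structure,
    orient_and_trim,
)
from scanlong.isoforms import (
    IsoformCall,
    classify_model,
    cluster_reads,
    collapse_models,
    filter_clusters,
    filter_novel,
    merge_across_cells,
)
from scanlong.quantify import ExpressionMatrix, assign_to_transcripts, compute_matrix


@dataclass
class DemuxResult:
    assignments: list[BarcodeAssignment]
    full_length: dict[int, list[FullLengthRead]]  # barcode index -> reads
    structure_counts: dict[str, int]
    filter_stats: dict[str, int]


def run_demux(
    reads: list[ReadRecord],
    design,
    cutoff: int = 31,
    window: int = 150,
    min_q: float = 7.0,
    min_len: int = 100,
    skip_read_filters: bool = False,
) -> DemuxResult:
    """Read filters -> barcode assignment -> structure -> orientation."""
    if skip_read_filters:
        kept, stats = reads, {"input": len(reads), "kept": len(reads)}
    else:
        kept, stats = filter_reads(reads, min_q=min_q, min_len=min_len)
    assignments = []
    full_length: dict[int, list[FullLengthRead]] = {}
    structure_counts: dict[str, int] = {}
    for r in kept:
        asg = demultiplex(r, design.barcodes, cutoff=cutoff, window=window)
        assignments.append(asg)
        if not asg.assigned:
            continue
        st = find_structure(r, design)
        structure_counts[st.klass] = structure_counts.get(st.klass, 0) + 1
        if st.klass == "full_length":
            fl = orient_and_trim(r, st, asg)
            full_length.setdefault(asg.best_barcode, []).append(fl)
    return DemuxResult(assignments, full_length, structure_counts, stats)


def group_alignments_by_cell(
    alignments: list[AlignmentRecord], cell_of_read: dict[str, str]
) -> dict[str, list[AlignmentRecord]]:
    out: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        cell = cell_of_read.get(a.read_id)
        if cell is not None:
            out.setdefault(cell, []).append(a)
    return out


def quantify_cells(
    alignments_by_cell: dict[str, list[AlignmentRecord]],
    index: AnnotationIndex,
    tol: int = 5,
) -> ExpressionMatrix:
    cell_assignments = {
        cell: [x for x in (assign_to_transcripts(a, index, tol) for a in alns) if x]
        for cell, alns in alignments_by_cell.items()
    }
    return compute_matrix(cell_assignments, index)


def extended_index(index: AnnotationIndex, models) -> AnnotationIndex:
    """Annotation index augmented with discovered models as transcripts
    (gene = host gene when present, else the model id)."""
    txs = list(index.transcripts.values())
    for m in models:
        txs.append(
            Transcript(m.model_id, m.host_gene or m.model_id, m.chrom, m.strand, list(m.exons))
        )
    return AnnotationIndex(txs)


@dataclass
class DiscoveryResult:
    catalogue: list  # all merged models
    calls: list[IsoformCall]  # novel-category calls before expression filters
    retained: list[IsoformCall]  # after RPT10k / share / min-cells filters
    joint: ExpressionMatrix  # expression over known + novel transcripts


def discover_isoforms(
    alignments_by_cell: dict[str, list[AlignmentRecord]],
    index: AnnotationIndex,
    tol: int = 5,
    min_rpt10k: float = 0.1,
    min_share: float = 0.05,
    min_cells: int = 3,
) -> DiscoveryResult:
    """Cluster -> depth filter -> collapse -> merge -> classify -> filter."""
    per_cell = {}
    for cell, alns in sorted(alignments_by_cell.items()):
        models = cluster_reads(alns, index, tol, cell=cell)
        models = filter_clusters(models, index)
        per_cell[cell] = collapse_models(models)
    catalogue, n_cells = merge_across_cells(per_cell)
    calls = []
    novel_models = []
    for m in catalogue:
        cat = classify_model(m, index)
        if cat in {"CJ", "CS", "ME", "IR", "MIR"}:
            calls.append(IsoformCall(m, cat, n_cells_detected=n_cells[m.model_id]))
            novel_models.append(m)
    joint_idx = extended_index(index, novel_models)
    joint = quantify_cells(alignments_by_cell, joint_idx, tol)
    model_gene = {m.model_id: (m.host_gene or m.model_id) for m in novel_models}
    tx_gene = {
        tid: joint_idx.transcripts[tid].gene_id for tid in joint.rpt10k.columns
    } if not joint.rpt10k.empty else {}
    retained = (
        filter_novel(calls, joint.rpt10k, model_gene, tx_gene,
                     min_rpt10k=min_rpt10k, min_share=min_share, min_cells=min_cells)
        if calls and not joint.rpt10k.empty
        else []
    )
    return DiscoveryResult(catalogue, calls, retained, joint)


def calls_table(result: DiscoveryResult) -> pd.DataFrame:
    rows = []
    retained_ids = {c.model.model_id for c in result.retained}
    for c in result.calls:
        rows.append(
            {
                "model_id": c.model.model_id,
                "category": c.category,
                "host_gene": c.model.host_gene,
                "n_cells_detected": c.n_cells_detected,
                "n_supporting_reads": c.model.n_reads,
                "retained": c.model.model_id in retained_ids,
            }
        )
    return pd.DataFrame(rows)
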