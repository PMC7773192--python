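"""Canned simulation scenarios exercising the full pipeline.

These wire the simulator to each analysis stage under fixed study
conditions (library sizes, error rates, barcode counts) and return the
measured quantities; both the test suite and the reproduction script
run them. All randomness derives from the seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scanlong import simlib
from scanlong.allelic import call_reads, dual_map_average, estimate_assignment_error
from scanlong.demux import demultiplex, find_structure, orient_and_trim
from scanlong.quantify import assign_to_transcripts, classify_regions, quantify_lncrna, saturation
from scanlong import pipeline as pl


def _alns_by_cell(lib):
    truth = lib.truth.set_index("read_id")
    out = {}
    for a in lib.truth_alignments:
        out.setdefault(truth.at[a.read_id, "cell"], []).append(a)
    return out


def demux_scenario(
    seed: int,
    n_reads: int = 10_000,
    n_cells: int = 48,
    error_model: simlib.ErrorModel | None = None,
) -> dict:
    """Demultiplex a simulated library and score against truth.

    Returns assignment and accuracy percentages; "non-truncated" reads
    are those that kept their TSO end.
    """
    if error_model is None:
        error_model = simlib.ErrorModel(truncation_prob=0.1)
    ref = simlib.make_reference(n_genes=6, exons_per_gene=5, n_snps_per_kb=0, seed=seed)
    design = simlib.random_design(ref, n_cells, seed=seed)
    lib = simlib.synthesize_reads(ref, design, error_model, n_reads, seed=seed + 1)
    truth = lib.truth.set_index("read_id")
    bc_of_cell = {c.name: c.barcode_index for c in design.cells}
    n_assigned = n_correct = n_cross = 0
    n_nontrunc = n_nontrunc_assigned = 0
    for r in lib.reads:
        a = demultiplex(r, design.barcodes)
        row = truth.loc[r.read_id]
        true_bc = bc_of_cell[row.cell]
        if not row.truncated:
            n_nontrunc += 1
            if a.assigned:
                n_nontrunc_assigned += 1
        if a.assigned:
            n_assigned += 1
            if a.best_barcode == true_bc:
                n_correct += 1
            else:
                n_cross += 1
    return {
        "n_reads": len(lib.reads),
        "pct_assigned": 100.0 * n_assigned / len(lib.reads),
        "pct_assigned_correct": 100.0 * n_correct / n_assigned if n_assigned else float("nan"),
        "n_cross_assigned": n_cross,
        "pct_nontruncated_assigned": 100.0 * n_nontrunc_assigned / n_nontrunc,
    }


def normalization_scenario(seed: int, n_reads: int = 2_000, n_cells: int = 6) -> dict:
    """Max per-cell deviation of the RPG10k row sum from 10,000."""
    ref = simlib.make_reference(n_genes=8, exons_per_gene=4, n_snps_per_kb=0, seed=seed)
    design = simlib.random_design(ref, n_cells, seed=seed)
    lib = simlib.synthesize_reads(ref, design, simlib.ErrorModel(), n_reads, seed=seed + 1)
    mat = pl.quantify_cells(_alns_by_cell(lib), ref.index)
    dev = (mat.rpg10k.sum(axis=1) - 10_000.0).abs().max()
    return {"n_cells": len(mat.cells), "max_rowsum_deviation": float(dev)}


def planted_isoform_scenario(seed: int, n_reads: int = 1_500, n_cells: int = 4) -> dict:
    """Inject one novel isoform per category and run rediscovery.

    Returns {category: recovered category or None} plus the retained
    count; recovery requires surviving clustering, depth filters,
    collapse, and the RPT10k / host-share / min-cells expression
    filters.
    """
    ref = simlib.make_reference(n_genes=6, exons_per_gene=5, n_snps_per_kb=0, seed=seed)
    planted = simlib.plant_novel_isoforms(ref, "G1")
    tids = list(ref.index.transcripts) + [t.transcript_id for t in planted.values()]
    design = simlib.random_design(ref, n_cells, seed=seed, transcripts=tids, uniform=True)
    lib = simlib.synthesize_reads(ref, design, simlib.ErrorModel(), n_reads, seed=seed + 1)
    truth = lib.truth.set_index("read_id")
    res = pl.discover_isoforms(_alns_by_cell(lib), ref.index, min_cells=3)
    recovered: dict[str, str | None] = {cat: None for cat in planted}
    for call in res.retained:
        sources = set(truth.loc[call.model.supporting_read_ids].transcript)
        for cat in planted:
            if f"NOVEL_{cat}" in sources:
                recovered[cat] = call.category
    return {"recovered": recovered, "n_retained": len(res.retained)}


def maternal_fraction_scenario(
    seed: int,
    fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_reads: int = 7_000,
) -> pd.DataFrame:
    """Recover per-cell maternal fractions from zero-error reads.

    One cell per requested fraction; returns truth vs estimate with the
    number of informative (strain-assigned) reads per cell.
    """
    ref = simlib.make_reference(n_genes=6, exons_per_gene=5, n_snps_per_kb=5.0, seed=seed)
    design = simlib.random_design(
        ref, len(fractions), seed=seed, maternal_fraction=list(fractions)
    )
    lib = simlib.synthesize_reads(ref, design, simlib.ErrorModel(), n_reads, seed=seed + 1)
    seqs = {}
    for r in lib.reads:
        st = find_structure(r, design)
        seqs[r.read_id] = orient_and_trim(r, st).oriented_sequence
    by_cell = _alns_by_cell(lib)
    calls = {c: call_reads(v, seqs, ref.index, ref.snps) for c, v in by_cell.items()}
    mat = dual_map_average(calls, calls)
    rows = []
    for cell, m in zip(sorted(calls), fractions):
        n_inf = sum(1 for c in calls[cell] if c.assignment in ("A", "B"))
        rows.append(
            {
                "cell": cell,
                "true_fraction": m,
                "estimated_fraction": float(mat.per_cell_maternal_fraction[cell]),
                "n_informative": n_inf,
            }
        )
    return pd.DataFrame(rows)


def assignment_error_scenario(seed: int, n_reads: int = 1_200) -> dict:
    """Strain-assignment error on pure-strain cells at zero error."""
    ref = simlib.make_reference(n_genes=6, exons_per_gene=5, n_snps_per_kb=5.0, seed=seed)
    design = simlib.random_design(ref, 4, seed=seed, maternal_fraction=[1, 1, 0, 0])
    lib = simlib.synthesize_reads(ref, design, simlib.ErrorModel(), n_reads, seed=seed + 1)
    seqs = {}
    for r in lib.reads:
        st = find_structure(r, design)
        seqs[r.read_id] = orient_and_trim(r, st).oriented_sequence
    calls = {
        c: call_reads(v, seqs, ref.index, ref.snps)
        for c, v in _alns_by_cell(lib).items()
    }
    truth_strain = {"cell00": "A", "cell01": "A", "cell02": "B", "cell03": "B"}
    return estimate_assignment_error(calls, truth_strain)


def saturation_scenario(seed: int, n_reads: int = 600) -> pd.DataFrame:
    """Saturation of detected genes/isoforms on one simulated cell."""
    ref = simlib.make_reference(n_genes=8, exons_per_gene=4, n_snps_per_kb=0, seed=seed)
    design = simlib.random_design(ref, 1, seed=seed)
    lib = simlib.synthesize_reads(ref, design, simlib.ErrorModel(), n_reads, seed=seed + 1)
    alns = next(iter(_alns_by_cell(lib).values()))
    asg = [x for x in (assign_to_transcripts(a, ref.index) for a in alns) if x]
    depths = sorted({0, len(asg) // 8, len(asg) // 4, len(asg) // 2, len(asg)})
    return saturation(asg, ref.index, depths, n_draws=10, seed=seed)


def lncrna_scenario(seed: int, n_reads: int = 1_500, n_cells: int = 3) -> dict:
    """Recover lncRNA counts from intergenic reads vs simulator truth."""
    ref = simlib.make_reference(
        n_genes=6, exons_per_gene=4, n_snps_per_kb=0, seed=seed, n_lnc_genes=3
    )
    tids = list(ref.index.transcripts) + list(ref.lnc_index.transcripts)
    design = simlib.random_design(ref, n_cells, seed=seed, transcripts=tids)
    lib = simlib.synthesize_reads(ref, design, simlib.ErrorModel(), n_reads, seed=seed + 1)
    by_cell = _alns_by_cell(lib)
    rc = classify_regions(by_cell, ref.index)
    mat = quantify_lncrna(by_cell, rc.labels, ref.lnc_index)
    truth = lib.truth.set_index("read_id")
    err = 0.0
    n = 0
    for cell, sub in truth.groupby("cell"):
        for tid in ref.lnc_index.transcripts:
            want = float((sub.transcript == tid).sum())
            got = (
                float(mat.transcript_counts.at[cell, tid])
                if not mat.transcript_counts.empty and tid in mat.transcript_counts.columns
                else 0.0
            )
            err = max(err, abs(got - want))
            n += 1
    return {
        "n_lnc_transcripts": len(ref.lnc_index.transcripts),
        "max_count_error": err,
        "n_intergenic_reads": int(rc.per_cell.intergenic.sum()),
    }
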