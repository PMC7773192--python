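"""Allele-specific expression from strain-specific SNPs.

Reads aligned to both parental reference genomes are genotyped at
strain-specific SNPs and assigned to a strain by two rules: a read with
exactly one informative SNP follows that SNP; a read with several is
assigned only when one strain's SNP count is at least twice the
other's. Reads covering less than 60% of the host gene's shortest
annotated transcript are excluded beforehand. Per-gene maternal and
paternal counts are averaged over the two reference mappings to cancel
reference bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scanlong.core_io import AlignmentRecord, AnnotationIndex, SnpTable, revcomp

MIN_COVERAGE = 0.60

_COMP1 = str.maketrans("ACGTN", "TGCAN")


@dataclass
class AllelicCall:
    read_id: str
    gene: str | None
    coverage_fraction: float
    snp_support_A: int
    snp_support_B: int
    assignment: str  # A | B | unassigned | excluded_low_coverage


def build_alt_genome(genome: dict[str, str], snps: SnpTable) -> dict[str, str]:
    """Substitute the alternate allele at every SNP position.

    Chromosome lengths are preserved (substitutions only) so
    coordinates remain comparable between the two references. Raises if
    a SNP's reference allele does not match the genome.
    """
    out: dict[str, str] = {}
    for chrom, seq in genome.items():
        positions = snps.positions(chrom)
        if not positions:
            out[chrom] = seq
            continue
        arr = bytearray(seq.encode())
        for pos, (ref, alt) in positions.items():
            if chr(arr[pos]).upper() != ref:
                raise ValueError(
                    f"{chrom}:{pos}: genome base {chr(arr[pos])} != SNP ref allele {ref}"
                )
            arr[pos] = ord(alt)
        out[chrom] = arr.decode()
    return out


def genotype_read(
    aln: AlignmentRecord, read_seq: str, snps: SnpTable
) -> tuple[int, int]:
    """Count read bases matching each strain allele at covered SNPs.

    ``read_seq`` is the read in mRNA-sense orientation; for a minus-
    strand alignment the genome-forward base is recovered by
    complementing from the read's far end. Bases matching neither allele
    (sequencing errors) count toward neither strain. Read/genome
    correspondence is colinear within each block, using
    ``block_read_starts`` when the loader provides them.
    """
    positions = snps.positions(aln.chrom)
    if not positions:
        return 0, 0
    a = b = 0
    read_starts = aln.block_read_starts
    if read_starts is None:
        read_starts = []
        off = 0
        for s, e in aln.blocks:
            read_starts.append(off)
            off += e - s
    total = sum(e - s for s, e in aln.blocks)
    for (s, e), roff in zip(aln.blocks, read_starts):
        for pos in range(s, e):
            alleles = positions.get(pos)
            if alleles is None:
                continue
            fwd_offset = roff + (pos - s)
            if aln.strand == "+":
                base = read_seq[fwd_offset] if fwd_offset < len(read_seq) else "N"
            else:
                idx = len(read_seq) - 1 - fwd_offset
                base = read_seq[idx].translate(_COMP1) if 0 <= idx < len(read_seq) else "N"
            if base == alleles[0]:
                a += 1
            elif base == alleles[1]:
                b += 1
    return a, b


def coverage_fraction(
    aln: AlignmentRecord, index: AnnotationIndex, gene: str | None
) -> float:
    """Aligned bases / spliced length of the gene's shortest transcript,
    capped at 1; zero when the read has no host gene."""
    if gene is None:
        return 0.0
    shortest = index.shortest_transcript_length(gene)
    return min(aln.aligned_bases / shortest, 1.0) if shortest else 0.0


def assign_allele(
    read_id: str,
    gene: str | None,
    cov: float,
    supports: tuple[int, int],
    min_cov: float = MIN_COVERAGE,
) -> AllelicCall:
    """Apply the per-read assignment rules.

    Excluded when coverage < min_cov. A single informative SNP decides
    the strain (rule 1); with more, strain X wins only when
    support_X >= 2 * support_Y and support_X >= 1 (rule 2); otherwise
    unassigned.
    """
    a, b = supports
    if cov < min_cov:
        return AllelicCall(read_id, gene, cov, a, b, "excluded_low_coverage")
    if a + b == 1:
        return AllelicCall(read_id, gene, cov, a, b, "A" if a else "B")
    if a >= 1 and a >= 2 * b:
        return AllelicCall(read_id, gene, cov, a, b, "A")
    if b >= 1 and b >= 2 * a:
        return AllelicCall(read_id, gene, cov, a, b, "B")
    return AllelicCall(read_id, gene, cov, a, b, "unassigned")


def call_reads(
    alignments: list[AlignmentRecord],
    read_seqs: dict[str, str],
    index: AnnotationIndex,
    snps: SnpTable,
    min_cov: float = MIN_COVERAGE,
) -> list[AllelicCall]:
    """Genotype and assign every primary alignment of one cell."""
    calls = []
    for aln in alignments:
        if aln.is_secondary or aln.is_supplementary:
            continue
        genes = {}
        for s, e in aln.blocks:
            for iv in index.exon_overlaps(aln.chrom, s, e):
                gid, _ = iv.data
                if index.genes[gid].strand == aln.strand:
                    genes[gid] = genes.get(gid, 0) + min(iv.end, e) - max(iv.begin, s)
        gene = max(sorted(genes), key=lambda g: genes[g]) if genes else None
        cov = coverage_fraction(aln, index, gene)
        supports = genotype_read(aln, read_seqs[aln.read_id], snps)
        calls.append(assign_allele(aln.read_id, gene, cov, supports, min_cov))
    return calls


@dataclass
class AllelicMatrix:
    maternal: pd.DataFrame  # cells x genes, averaged counts
    paternal: pd.DataFrame
    per_cell_maternal_fraction: pd.Series

    @property
    def cells(self):
        return list(self.maternal.index)


def _count_calls(calls_by_cell: dict[str, list[AllelicCall]]):
    rows_a, rows_b = {}, {}
    for cell, calls in calls_by_cell.items():
        ca: dict[str, float] = {}
        cb: dict[str, float] = {}
        for c in calls:
            if c.gene is None:
                continue
            if c.assignment == "A":
                ca[c.gene] = ca.get(c.gene, 0.0) + 1.0
            elif c.assignment == "B":
                cb[c.gene] = cb.get(c.gene, 0.0) + 1.0
        rows_a[cell] = ca
        rows_b[cell] = cb
    a = pd.DataFrame.from_dict(rows_a, orient="index").fillna(0.0)
    b = pd.DataFrame.from_dict(rows_b, orient="index").fillna(0.0)
    cols = sorted(set(a.columns) | set(b.columns))
    return a.reindex(columns=cols, fill_value=0.0), b.reindex(columns=cols, fill_value=0.0)


def dual_map_average(
    calls_ref_A: dict[str, list[AllelicCall]],
    calls_ref_B: dict[str, list[AllelicCall]],
) -> AllelicMatrix:
    """Average per-cell x gene strain counts over the two mappings.

    Both call sets must cover the same cells (they derive from the same
    reads). Maternal (strain A) and paternal (strain B) counts are
    averaged element-wise; per-cell fractions are recomputed from the
    averaged counts.
    """
    if set(calls_ref_A) != set(calls_ref_B):
        missing = set(calls_ref_A) ^ set(calls_ref_B)
        raise ValueError(f"cells present in only one mapping: {sorted(missing)}")
    a1, b1 = _count_calls(calls_ref_A)
    a2, b2 = _count_calls(calls_ref_B)
    cols = sorted(set(a1.columns) | set(a2.columns))
    idx = sorted(calls_ref_A)
    a1, a2, b1, b2 = (
        df.reindex(index=idx, columns=cols, fill_value=0.0) for df in (a1, a2, b1, b2)
    )
    mat = (a1 + a2) / 2.0
    pat = (b1 + b2) / 2.0
    tot = mat.sum(axis=1) + pat.sum(axis=1)
    frac = (mat.sum(axis=1) / tot).where(tot > 0)
    return AllelicMatrix(mat, pat, frac)


def allelic_summary(
    matrix: AllelicMatrix,
    index: AnnotationIndex,
    snps: SnpTable,
    expression: pd.DataFrame | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-cell summary: maternal fraction of assigned reads and the
    fraction of expressed genes carrying >=1 exonic SNP (discriminable).

    ``expression`` is an optional cells x genes count matrix defining
    which genes are expressed per cell (count > 0); without it the
    discriminable fraction is computed over all annotated genes. With
    ``groups`` (cell -> label) per-group means and standard deviations
    are appended as rows labelled ``group:<label>``.
    """
    has_snp = {}
    for gid, g in index.genes.items():
        found = False
        for tid in g.transcripts:
            for s, e in index.transcripts[tid].exons:
                pos = snps.positions(g.chrom)
                if any(s <= p < e for p in pos):
                    found = True
                    break
            if found:
                break
        has_snp[gid] = found
    rows = {}
    for cell in matrix.cells:
        if expression is not None and cell in expression.index:
            expressed = [g for g in expression.columns if expression.at[cell, g] > 0]
        else:
            expressed = list(index.genes)
        n_disc = sum(1 for g in expressed if has_snp.get(g, False))
        rows[cell] = {
            "maternal_fraction": float(matrix.per_cell_maternal_fraction.get(cell, np.nan)),
            "discriminable_gene_fraction": n_disc / len(expressed) if expressed else np.nan,
            "n_expressed_genes": len(expressed),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if groups:
        for label in sorted(set(groups.values())):
            cells = [c for c in out.index if groups.get(c) == label]
            sub = out.loc[cells]
            out.loc[f"group:{label}"] = {
                "maternal_fraction": sub.maternal_fraction.mean(),
                "discriminable_gene_fraction": sub.discriminable_gene_fraction.mean(),
                "n_expressed_genes": sub.n_expressed_genes.mean(),
            }
    return out


def estimate_assignment_error(
    calls_by_cell: dict[str, list[AllelicCall]],
    truth_strain_by_cell: dict[str, str],
) -> dict[str, float | None]:
    """Assignment error on pure-strain cells.

    error(strain) = wrongly assigned informative reads / all assigned
    informative reads, over cells whose true strain is known; None when
    a strain has no assigned reads.
    """
    wrong = {"A": 0, "B": 0}
    total = {"A": 0, "B": 0}
    for cell, calls in calls_by_cell.items():
        truth = truth_strain_by_cell.get(cell)
        if truth not in ("A", "B"):
            continue
        for c in calls:
            if c.assignment in ("A", "B"):
                total[truth] += 1
                if c.assignment != truth:
                    wrong[truth] += 1
    return {
        strain: (wrong[strain] / total[strain] if total[strain] else None)
        for strain in ("A", "B")
    }
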