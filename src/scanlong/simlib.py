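"""Seeded synthetic-library generator.

Builds toy diploid references (genome FASTA + GTF + strain-SNP VCF),
cell designs, and error-bearing barcoded full-length cDNA reads with
complete truth tables. The amplicon architecture emulated is

    anchor + ATGGG + transcript + polyA + rc(barcode) + rc(anchor)

on the sense strand; reads are drawn from either strand, may lack the
5' (TSO) end with a configurable truncation probability, and carry
substitution/insertion/deletion errors with per-base qualities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from scanlong.core_io import (
    AlignmentRecord,
    AnnotationIndex,
    ReadRecord,
    SnpTable,
    Transcript,
    format_blocks,
    revcomp,
    write_fastq,
    write_models_gtf,
    write_truth_alignments,
)

DEFAULT_ANCHOR = "AAGCAGTGGTATCAACGCAGAGTAC"  # 25-nt ISPCR anchor
TSO_TAIL = "ATGGG"
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUTH_COLUMNS = ["read_id", "cell", "transcript", "allele", "strand", "truncated", "blocks"]


# ---------------------------------------------------------------------------
# reference construction


@dataclass
class Reference:
    """A toy diploid reference: genome, annotation, strain SNPs.

    ``extra_transcripts`` holds transcripts that are real in the
    simulation but absent from the main annotation (lncRNA genes, planted
    novel isoforms); the simulator can emit reads for them while the
    analysis side must rediscover them.
    """

    genome: dict[str, str]
    index: AnnotationIndex
    snps: SnpTable
    lnc_index: AnnotationIndex | None = None
    extra_transcripts: dict[str, Transcript] = field(default_factory=dict)
    _alt_genome: dict[str, str] | None = None

    @property
    def alt_genome(self) -> dict[str, str]:
        if self._alt_genome is None:
            from scanlong.allelic import build_alt_genome

            self._alt_genome = build_alt_genome(self.genome, self.snps)
        return self._alt_genome

    def transcript(self, tid: str) -> Transcript:
        if tid in self.index.transcripts:
            return self.index.transcripts[tid]
        if self.lnc_index is not None and tid in self.lnc_index.transcripts:
            return self.lnc_index.transcripts[tid]
        return self.extra_transcripts[tid]

    def transcript_seq(self, tid: str, allele: str = "maternal") -> str:
        """Spliced mRNA-sense sequence of a transcript on one haplotype."""
        t = self.transcript(tid)
        genome = self.genome if allele == "maternal" else self.alt_genome
        seq = "".join(genome[t.chrom][s:e] for s, e in t.exons)
        return seq if t.strand == "+" else revcomp(seq)

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": out / "ref.fa", "gtf": out / "ref.gtf", "vcf": out / "snps.vcf"}
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_models_gtf(self.index.transcripts.values(), paths["gtf"])
        with open(paths["vcf"], "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom, seq in self.genome.items():
                fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for chrom, pos, ref, alt in self.snps.records:
                fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
        if self.lnc_index is not None:
            paths["lnc_gtf"] = out / "lnc.gtf"
            write_models_gtf(self.lnc_index.transcripts.values(), paths["lnc_gtf"])
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


def make_reference(
    n_genes: int = 8,
    exons_per_gene: int = 5,
    n_snps_per_kb: float = 5.0,
    seed: int = 0,
    n_lnc_genes: int = 0,
    exon_len: tuple[int, int] = (150, 400),
    intron_len: tuple[int, int] = (100, 300),
    gap_len: tuple[int, int] = (600, 1500),
) -> Reference:
    """Generate a deterministic toy diploid reference.

    Genes alternate strands along one chromosome; genes with >=3 exons
    get a second annotated transcript skipping their second exon, so some
    splice sites and junctions are shared between transcripts. SNPs are
    placed at exonic positions only, at an expected density of
    ``n_snps_per_kb`` per kb of (union) exonic sequence. lncRNA genes are
    placed in intergenic space and indexed separately, absent from the
    main annotation.
    """
    if n_genes <= 0 or exons_per_gene <= 0 or n_snps_per_kb < 0:
        raise ValueError("n_genes and exons_per_gene must be positive; SNP density >= 0")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    pieces: list[str] = []
    cursor = 0
    transcripts: list[Transcript] = []
    lnc_transcripts: list[Transcript] = []

    def emit(n: int) -> int:
        nonlocal cursor
        pieces.append(_random_seq(rng, n))
        cursor += n
        return cursor

    total_gene_slots = n_genes + n_lnc_genes
    lnc_slots = set(
        rng.choice(total_gene_slots, size=n_lnc_genes, replace=False).tolist()
    ) if n_lnc_genes else set()

    gi = li = 0
    for slot in range(total_gene_slots):
        emit(int(rng.integers(*gap_len)))
        strand = "+" if slot % 2 == 0 else "-"
        is_lnc = slot in lnc_slots
        n_ex = 2 if is_lnc else exons_per_gene
        exons = []
        for k in range(n_ex):
            if k:
                emit(int(rng.integers(*intron_len)))
            s = cursor
            e = emit(int(rng.integers(*exon_len)))
            exons.append((s, e))
        if is_lnc:
            li += 1
            lnc_transcripts.append(
                Transcript(f"LNCT{li}", f"LNC{li}", chrom, strand, exons)
            )
        else:
            gi += 1
            gid = f"G{gi}"
            transcripts.append(Transcript(f"{gid}.T1", gid, chrom, strand, exons))
            if n_ex >= 3:
                # alternative transcript skipping the second exon
                transcripts.append(
                    Transcript(f"{gid}.T2", gid, chrom, strand, exons[:1] + exons[2:])
                )
            if n_ex >= 5:
                # a second alternative skipping the penultimate exon, so the
                # gene owns two distinct skip junctions in different
                # transcripts (enables novel *combinations* of annotated
                # junctions)
                transcripts.append(
                    Transcript(
                        f"{gid}.T3", gid, chrom, strand,
                        exons[: n_ex - 2] + exons[n_ex - 1 :],
                    )
                )
    emit(int(rng.integers(*gap_len)))
    genome_arr = np.frombuffer("".join(pieces).encode(), dtype=np.uint8).copy()

    # pin transcript 3' terminal bases away from A so the synthetic
    # polyA/transcript boundary is unambiguous when trimming
    for t in transcripts + lnc_transcripts:
        if t.strand == "+":
            pos, avoid, repl = t.exons[-1][1] - 1, ord("A"), ord("G")
        else:
            pos, avoid, repl = t.exons[0][0], ord("T"), ord("C")
        if genome_arr[pos] == avoid:
            genome_arr[pos] = repl

    # SNPs at exonic (main-annotation) positions
    exonic = sorted({p for t in transcripts for s, e in t.exons for p in range(s, e)})
    n_snps = int(round(len(exonic) / 1000.0 * n_snps_per_kb))
    if n_snps > len(exonic):
        raise ValueError("requested SNP density exceeds available exonic space")
    snp_records = []
    if n_snps:
        pos_choice = np.sort(rng.choice(len(exonic), size=n_snps, replace=False))
        for i in pos_choice:
            pos = exonic[int(i)]
            ref = chr(genome_arr[pos])
            alt = rng.choice([b for b in "ACGT" if b != ref])
            snp_records.append((chrom, pos, ref, str(alt)))

    genome = {chrom: genome_arr.tobytes().decode()}
    return Reference(
        genome,
        AnnotationIndex(transcripts),
        SnpTable(snp_records),
        AnnotationIndex(lnc_transcripts) if lnc_transcripts else None,
    )


# ---------------------------------------------------------------------------
# library design


@dataclass
class CellProfile:
    name: str
    barcode_index: int
    expression: dict[str, float]  # transcript_id -> probability (sums to 1)
    maternal_fraction: float = 0.5


@dataclass
class LibraryDesign:
    """Barcoded pooled-cell library design (up to 48 cells)."""

    barcodes: list[str]
    cells: list[CellProfile]
    anchor: str = DEFAULT_ANCHOR
    tso_tail: str = TSO_TAIL
    polyT_len: int = 25
    min_barcode_dist: int = 8

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be distinct")
        for bc in self.barcodes:
            if len(bc) != 24:
                raise ValueError(f"barcode {bc} is not 24 nt")
        if not 1 <= len(self.cells) <= 48:
            raise ValueError("1..48 cells per library")
        if self.min_barcode_dist:
            for i, a in enumerate(self.barcodes):
                for b in self.barcodes[i + 1 :]:
                    d = edlib.align(a, b)["editDistance"]
                    if d < self.min_barcode_dist:
                        raise ValueError(
                            f"barcodes {a} and {b} at edit distance {d} < "
                            f"{self.min_barcode_dist}"
                        )
        for c in self.cells:
            if not 0 <= c.barcode_index < len(self.barcodes):
                raise ValueError(f"cell {c.name}: barcode index out of range")
            tot = sum(c.expression.values())
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"cell {c.name}: expression does not sum to 1")
            if not 0.0 <= c.maternal_fraction <= 1.0:
                raise ValueError(f"cell {c.name}: maternal fraction outside [0,1]")


def random_barcodes(n: int, seed: int = 0, min_dist: int = 8, max_tries: int = 100000) -> list[str]:
    """Random 24-nt barcodes with pairwise edit distance >= min_dist.

    Drawn from a stream keyed (seed, "barcodes") so the same seed can be
    reused for the reference without the genome replaying the identical
    random bases as the barcode set.
    """
    rng = np.random.default_rng([seed, 0xBC0DE])
    out: list[str] = []
    for _ in range(max_tries):
        if len(out) == n:
            return out
        cand = _random_seq(rng, 24)
        if all(edlib.align(cand, b)["editDistance"] >= min_dist for b in out):
            out.append(cand)
    raise RuntimeError(f"could not draw {n} separated barcodes")


def random_design(
    reference: Reference,
    n_cells: int,
    seed: int = 0,
    maternal_fraction: float | Sequence[float] = 0.5,
    transcripts: Sequence[str] | None = None,
    uniform: bool = False,
) -> LibraryDesign:
    """A design with random separated barcodes and Dirichlet(1) expression."""
    rng = np.random.default_rng([seed, 0xCE11])
    tids = list(transcripts) if transcripts is not None else list(reference.index.transcripts)
    barcodes = random_barcodes(n_cells, seed=seed)
    if np.isscalar(maternal_fraction):
        mfs = [float(maternal_fraction)] * n_cells
    else:
        mfs = [float(m) for m in maternal_fraction]
    cells = []
    for i in range(n_cells):
        w = np.ones(len(tids)) / len(tids) if uniform else rng.dirichlet(np.ones(len(tids)))
        cells.append(
            CellProfile(f"cell{i:02d}", i, dict(zip(tids, (w / w.sum()).tolist())), mfs[i])
        )
    return LibraryDesign(barcodes, cells)


def make_pure_strain_cells(design: LibraryDesign, strain: str) -> LibraryDesign:
    """Force every cell to a pure strain ('maternal' or 'paternal')."""
    if strain not in {"maternal", "paternal"}:
        raise ValueError(f"unknown strain {strain!r}")
    m = 1.0 if strain == "maternal" else 0.0
    return replace(
        design, cells=[replace(c, maternal_fraction=m) for c in design.cells]
    )


# ---------------------------------------------------------------------------
# error model and read synthesis


@dataclass
class ErrorModel:
    p_sub: float = 0.0
    p_ins: float = 0.0
    p_del: float = 0.0
    truncation_prob: float = 0.0
    q_good: int = 20
    q_err: int = 7

    def __post_init__(self) -> None:
        for p in (self.p_sub, self.p_ins, self.p_del, self.truncation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must lie in [0,1]")


def apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator):
    """Apply per-base substitution/insertion/deletion errors.

    Returns (sequence, qualities): error-free bases get q_good, substituted
    and inserted bases q_err. At most one insertion after each base.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    if n == 0:
        return "", np.empty(0, dtype=np.int32)
    u = rng.random((3, n))
    dels = u[0] < model.p_del
    subs = (~dels) & (u[1] < model.p_sub)
    ins = u[2] < model.p_ins
    if subs.any():
        idx = np.flatnonzero(subs)
        shift = rng.integers(1, 4, idx.size)
        cur = np.searchsorted(BASES, arr[idx])
        arr[idx] = BASES[(cur + shift) % 4]
    quals = np.full(n, model.q_good, dtype=np.int32)
    quals[subs] = model.q_err
    keep = ~dels
    ins_idx = np.flatnonzero(ins)
    if ins_idx.size == 0:
        out = arr[keep]
        return out.tobytes().decode(), quals[keep]
    ins_bases = BASES[rng.integers(0, 4, ins_idx.size)]
    parts_s: list[np.ndarray] = []
    parts_q: list[np.ndarray] = []
    prev = 0
    for j, pos in enumerate(ins_idx):
        stop = pos + 1
        k = keep[prev:stop]
        parts_s.append(arr[prev:stop][k])
        parts_q.append(quals[prev:stop][k])
        parts_s.append(ins_bases[j : j + 1])
        parts_q.append(np.array([model.q_err], dtype=np.int32))
        prev = stop
    k = keep[prev:]
    parts_s.append(arr[prev:][k])
    parts_q.append(quals[prev:][k])
    return np.concatenate(parts_s).tobytes().decode(), np.concatenate(parts_q)


@dataclass
class SimulatedLibrary:
    reads: list[ReadRecord]
    truth: pd.DataFrame  # TRUTH_COLUMNS
    truth_alignments: list[AlignmentRecord]
    design: LibraryDesign

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": out / "reads.fastq",
            "truth": out / "truth.tsv",
            "truth_aln": out / "truth_aln.tsv",
            "barcodes": out / "barcodes.tsv",
        }
        write_fastq(self.reads, paths["fastq"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_truth_alignments(self.truth_alignments, paths["truth_aln"])
        with open(paths["barcodes"], "w") as fh:
            for i, bc in enumerate(self.design.barcodes):
                fh.write(f"BC{i:02d}\t{bc}\n")
        return paths


def _truncated_blocks(t: Transcript, cut: int) -> list[tuple[int, int]]:
    """Genomic blocks after removing `cut` bases from the mRNA 5' end."""
    if cut <= 0:
        return list(t.exons)
    exons = list(t.exons) if t.strand == "+" else list(t.exons)[::-1]
    out = []
    remaining = cut
    for s, e in exons:
        ln = e - s
        if remaining >= ln:
            remaining -= ln
            continue
        if t.strand == "+":
            out.append((s + remaining, e))
        else:
            out.append((s, e - remaining))
        remaining = 0
    if t.strand == "-":
        out = out[::-1]
    return out


def synthesize_reads(
    reference: Reference,
    design: LibraryDesign,
    error_model: ErrorModel,
    n_reads: int,
    seed: int = 0,
) -> SimulatedLibrary:
    """Draw barcoded amplicon reads with full truth labels.

    Each read: a cell is drawn uniformly, a transcript from the cell's
    expression vector, an allele from its maternal fraction, the amplicon
    strand uniformly; with probability ``truncation_prob`` the read loses
    its TSO end together with a uniform fraction of the transcript 5'
    end. Errors are applied last. Truth alignments record the error-free
    genomic blocks of the (possibly truncated) transcript portion.
    """
    rng = np.random.default_rng(seed)
    cells = design.cells
    # transcript sequences cached per (tid, allele)
    seq_cache: dict[tuple[str, str], str] = {}

    def tseq(tid: str, allele: str) -> str:
        key = (tid, allele)
        if key not in seq_cache:
            seq_cache[key] = reference.transcript_seq(tid, allele)
        return seq_cache[key]

    reads: list[ReadRecord] = []
    truth_rows = []
    truth_alns: list[AlignmentRecord] = []
    cell_tids = [list(c.expression) for c in cells]
    cell_probs = [np.array(list(c.expression.values())) for c in cells]
    for i in range(n_reads):
        rid = f"read{i:06d}"
        ci = int(rng.integers(len(cells)))
        cell = cells[ci]
        tid = cell_tids[ci][int(rng.choice(len(cell_tids[ci]), p=cell_probs[ci]))]
        allele = "maternal" if rng.random() < cell.maternal_fraction else "paternal"
        t = reference.transcript(tid)
        seq = tseq(tid, allele)
        truncated = rng.random() < error_model.truncation_prob
        cut = 0
        if truncated:
            cut = int(rng.integers(1, max(2, len(seq) // 2)))
        insert = seq[cut:]
        barcode = design.barcodes[cell.barcode_index]
        tail = "A" * design.polyT_len + revcomp(barcode) + revcomp(design.anchor)
        head = "" if truncated else design.anchor + design.tso_tail
        amplicon = head + insert + tail
        strand = "+" if rng.random() < 0.5 else "-"
        raw = amplicon if strand == "+" else revcomp(amplicon)
        out_seq, quals = apply_errors(raw, error_model, rng)
        reads.append(ReadRecord(rid, out_seq, quals))
        blocks = _truncated_blocks(t, cut)
        truth_rows.append(
            (rid, cell.name, tid, allele, strand, truncated, format_blocks(blocks))
        )
        frac = len(insert) / len(out_seq) if out_seq else 0.0
        truth_alns.append(
            AlignmentRecord(rid, t.chrom, t.strand, blocks, min(frac, 1.0))
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedLibrary(reads, truth, truth_alns, design)


# ---------------------------------------------------------------------------
# planted novel isoforms


def plant_novel_isoforms(reference: Reference, gene_id: str) -> dict[str, Transcript]:
    """Construct one novel isoform per category from an annotated gene.

    Requires a gene whose primary transcript has >= 4 exons. The planted
    models use only annotated splice sites, so they survive a
    novel-splice-site discard rule:

    - CJ: a chain combining annotated junctions in a combination matching
      no single transcript (junction skipped-exon pattern);
    - CS: one junction pairing an annotated donor with an annotated
      acceptor never joined in the annotation;
    - ME: a mono-exon model strictly inside one annotated exon;
    - IR: a multi-exon model retaining one complete annotated intron;
    - MIR: a mono-exon model spanning two exons plus their intervening
      intron.

    The models are registered as extra transcripts of the reference (ids
    ``NOVEL_<CAT>``) so the simulator can emit reads for them.
    """
    g = reference.index.genes[gene_id]
    t1 = reference.index.transcripts[f"{gene_id}.T1"]
    ex = t1.exons
    n = len(ex)
    if n < 5 or f"{gene_id}.T3" not in reference.index.transcripts:
        raise ValueError(
            "planting novel isoforms needs a gene with >= 5 exons and both "
            "skip-variant transcripts"
        )
    chrom, strand = g.chrom, g.strand
    # Annotated junction inventory for this gene: the full ladder J_i from
    # T1, the skip junction K=(end(ex0), start(ex2)) from T2 and the skip
    # junction L=(end(ex[n-3]), start(ex[n-1])) from T3. The chain [K, ...,
    # L] combines the two skips — each junction annotated, the combination
    # matching no single transcript and retaining no intron.
    models = {
        "CJ": Transcript(
            "NOVEL_CJ", gene_id, chrom, strand,
            [ex[0]] + ex[2 : n - 2] + [ex[n - 1]],
        ),
        # junction (end(ex1), start(ex3)): donor and acceptor individually
        # annotated, the pairing never annotated (needs n >= 5)
        "CS": Transcript(
            "NOVEL_CS", gene_id, chrom, strand, [ex[1], ex[3]]
        ),
        # placed in the fourth exon so it cannot overlap-cluster with MIR
        "ME": Transcript(
            "NOVEL_ME", gene_id, chrom, strand,
            [(ex[3][0] + 20, ex[3][1] - 20)],
        ),
        # first intron retained, downstream junction annotated
        "IR": Transcript(
            "NOVEL_IR", gene_id, chrom, strand, [(ex[0][0], ex[1][1]), ex[2]]
        ),
        "MIR": Transcript(
            "NOVEL_MIR", gene_id, chrom, strand, [(ex[1][0], ex[2][1])]
        ),
    }
    if (ex[3][0] + 20) >= (ex[3][1] - 20):
        raise ValueError("fourth exon too short to host a strictly-contained ME model")
    reference.extra_transcripts.update({t.transcript_id: t for t in models.values()})
    return models
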