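"""Readers, writers and the annotation index.

All coordinates are 0-based half-open internally; conversion from the
1-based inclusive GTF/VCF conventions happens only at the format
boundary. Splice junctions are keyed genomically as ``(donor, acceptor)``
with ``donor < acceptor`` — the junction spans the intron
``[donor, acceptor)`` — regardless of strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# read records


@dataclass
class ReadRecord:
    """One raw sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: np.ndarray  # int array, empty for FASTA input

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int32)
        if self.qualities.size and self.qualities.size != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {self.qualities.size}"
            )

    @property
    def mean_q(self) -> float:
        """Phred-scaled mean error probability (undefined for FASTA input)."""
        if not self.qualities.size:
            return math.nan
        return mean_qscore(self.qualities)

    def __len__(self) -> int:
        return len(self.sequence)


def mean_qscore(qualities) -> float:
    """Phred score of the mean per-base error probability.

    ``-10 * log10(mean(10 ** (-q / 10)))`` — the convention used by
    long-read QC tools, which down-weights a read for its worst bases
    rather than averaging Phred values arithmetically.
    """
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("mean_qscore of empty quality vector")
    return float(-10.0 * np.log10(np.mean(np.power(10.0, -q / 10.0))))


def read_sequences(path, fmt: str | None = None) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ or FASTA file.

    ``fmt`` is "fastq" or "fasta"; inferred from the suffix when omitted.
    FASTA records carry empty quality vectors (mean_q is NaN).
    """
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta"} else "fastq"
    fmt = fmt.lower()
    if fmt not in {"fastq", "fasta"}:
        raise ValueError(f"unknown sequence format {fmt!r}")
    with open(path) as fh:
        if fmt == "fasta":
            yield from _iter_fasta(fh)
        else:
            yield from _iter_fastq(fh, str(path))


def _iter_fasta(fh) -> Iterator[ReadRecord]:
    from Bio import SeqIO

    for rec in SeqIO.parse(fh, "fasta"):
        yield ReadRecord(rec.id, str(rec.seq), np.empty(0, dtype=np.int32))


def _iter_fastq(fh, name: str) -> Iterator[ReadRecord]:
    lineno = 0
    while True:
        header = fh.readline()
        if not header:
            return
        lineno += 1
        if not header.startswith("@"):
            raise ValueError(f"{name}:{lineno}: FASTQ header does not start with '@'")
        seq = fh.readline().rstrip("\n")
        plus = fh.readline()
        qual = fh.readline().rstrip("\n")
        if not qual and not plus:
            raise ValueError(f"{name}:{lineno}: truncated FASTQ record")
        lineno += 3
        if not plus.startswith("+"):
            raise ValueError(f"{name}:{lineno - 1}: missing '+' separator line")
        if len(seq) != len(qual):
            raise ValueError(
                f"{name}:{lineno}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        rid = header[1:].split()[0] if len(header) > 1 else ""
        yield ReadRecord(rid, seq, np.frombuffer(qual.encode(), dtype=np.uint8) - 33)


def write_fastq(records: Iterable[ReadRecord], path) -> int:
    """Write ReadRecords as FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            qual = (rec.qualities.astype(np.uint8) + 33).tobytes().decode()
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# annotation


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted, 0-based half-open

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Genomically ordered (donor, acceptor) intron coordinates."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[str] = field(default_factory=list)
    start: int = 0
    end: int = 0


class AnnotationIndex:
    """Genes, transcripts and derived splice-site / junction / interval lookups.

    Built from a GTF (see :func:`load_annotation`) or directly from
    Transcript objects. Splice-site sets are kept genomically: ``left``
    sites are exon ends (intron starts) and ``right`` sites are exon
    starts (intron ends) per (chrom, strand).
    """

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: dict[str, Transcript] = {}
        self.genes: dict[str, Gene] = {}
        self.junctions: dict[tuple[str, str], dict[tuple[int, int], set[str]]] = {}
        self.left_sites: dict[tuple[str, str], set[int]] = {}
        self.right_sites: dict[tuple[str, str], set[int]] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._gene_trees: dict[str, IntervalTree] = {}

        for t in transcripts:
            for (s0, e0), (s1, e1) in zip(t.exons, t.exons[1:]):
                if s1 <= e0:
                    raise ValueError(
                        f"transcript {t.transcript_id}: exons [{s0},{e0}) and "
                        f"[{s1},{e1}) overlap or abut"
                    )
            self.transcripts[t.transcript_id] = t
            g = self.genes.setdefault(
                t.gene_id, Gene(t.gene_id, t.chrom, t.strand, [], t.start, t.end)
            )
            g.transcripts.append(t.transcript_id)
            g.start = min(g.start, t.start)
            g.end = max(g.end, t.end)
            key = (t.chrom, t.strand)
            jmap = self.junctions.setdefault(key, {})
            for j in t.junctions:
                jmap.setdefault(j, set()).add(t.transcript_id)
            ls = self.left_sites.setdefault(key, set())
            rs = self.right_sites.setdefault(key, set())
            for d, a in t.junctions:
                ls.add(d)
                rs.add(a)
            etree = self._exon_trees.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                etree[s:e] = (t.gene_id, t.transcript_id)
        for g in self.genes.values():
            self._gene_trees.setdefault(g.chrom, IntervalTree())[g.start : g.end] = g.gene_id

    # -- lookups ----------------------------------------------------------

    def exon_overlaps(self, chrom: str, start: int, end: int):
        tree = self._exon_trees.get(chrom)
        return set() if tree is None else tree.overlap(start, end)

    def gene_overlaps(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def is_intergenic(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies entirely outside all gene spans."""
        return not self.gene_overlaps(chrom, start, end)

    def intergenic_intervals(self, chrom: str, chrom_len: int) -> list[tuple[int, int]]:
        """Complement of the merged gene spans on one chromosome."""
        tree = self._gene_trees.get(chrom, IntervalTree())
        merged = IntervalTree(tree)
        merged.merge_overlaps()
        out, cursor = [], 0
        for iv in sorted(merged):
            if iv.begin > cursor:
                out.append((cursor, iv.begin))
            cursor = max(cursor, iv.end)
        if cursor < chrom_len:
            out.append((cursor, chrom_len))
        return out

    def gene_junctions(self, gene_id: str) -> set[tuple[int, int]]:
        g = self.genes[gene_id]
        out: set[tuple[int, int]] = set()
        for tid in g.transcripts:
            out.update(self.transcripts[tid].junctions)
        return out

    def gene_sites(self, gene_id: str) -> tuple[set[int], set[int]]:
        """(left, right) splice-site positions of one gene's transcripts."""
        left: set[int] = set()
        right: set[int] = set()
        for j in self.gene_junctions(gene_id):
            left.add(j[0])
            right.add(j[1])
        return left, right

    def shortest_transcript_length(self, gene_id: str) -> int:
        return min(
            self.transcripts[t].spliced_length for t in self.genes[gene_id].transcripts
        )


def load_annotation(gtf_path) -> AnnotationIndex:
    """Build an AnnotationIndex from a GTF file.

    GTF exon rows must carry gene_id and transcript_id attributes;
    1-based inclusive coordinates are shifted to 0-based half-open.
    """
    import pyranges as pr

    gr = pr.read_gtf(str(gtf_path))  # pyranges already converts to 0-based half-open
    df = gr.df if hasattr(gr, "df") else gr
    exons = df[df.Feature == "exon"]
    if "transcript_id" not in exons.columns or exons.transcript_id.isna().any():
        raise ValueError(f"{gtf_path}: exon row without transcript_id")
    transcripts = []
    for (tid,), sub in exons.groupby(["transcript_id"], sort=False):
        sub = sub.sort_values("Start")
        ivs = list(zip(sub.Start.astype(int), sub.End.astype(int)))
        gene_id = str(sub.gene_id.iloc[0])
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(
                    f"{gtf_path}: transcript {tid} has overlapping exons "
                    f"[{s0},{e0}) and [{s1},{e1})"
                )
        transcripts.append(
            Transcript(str(tid), gene_id, str(sub.Chromosome.iloc[0]),
                       str(sub.Strand.iloc[0]), ivs)
        )
    return AnnotationIndex(transcripts)


def write_models_gtf(models, path, source: str = "scanlong") -> None:
    """Write transcript models as GTF (1-based inclusive coordinates).

    Accepts any object with chrom/strand/exons plus either
    model_id/host_gene (discovered models) or transcript_id/gene_id
    (annotated transcripts)."""
    with open(path, "w") as fh:
        for m in models:
            mid = getattr(m, "model_id", None) or m.transcript_id
            gene = getattr(m, "host_gene", None) or getattr(m, "gene_id", None) or mid
            attrs = f'gene_id "{gene}"; transcript_id "{mid}";'
            fh.write(
                "\t".join(
                    [m.chrom, source, "transcript", str(m.exons[0][0] + 1),
                     str(m.exons[-1][1]), ".", m.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in m.exons:
                fh.write(
                    "\t".join(
                        [m.chrom, source, "exon", str(s + 1), str(e), ".",
                         m.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# alignments


@dataclass
class AlignmentRecord:
    """A spliced alignment reduced to its exonic block structure.

    ``blocks`` are genomic intervals (0-based half-open, sorted,
    disjoint); ``block_read_starts`` gives, for each block, the offset of
    its first base in the read sequence *as aligned* (i.e. in the
    orientation that matches the reference), enabling per-base
    read/genome correspondence under a colinear-within-block model.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    aligned_base_fraction: float = 1.0
    is_secondary: bool = False
    is_supplementary: bool = False
    block_read_starts: list[int] | None = None

    def __post_init__(self) -> None:
        for (s0, e0), (s1, e1) in zip(self.blocks, self.blocks[1:]):
            if s1 < e0:
                raise ValueError(f"alignment {self.read_id}: blocks out of order")
        if not 0.0 <= self.aligned_base_fraction <= 1.0 + 1e-9:
            raise ValueError(f"alignment {self.read_id}: aligned_base_fraction out of range")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0]) for i in range(len(self.blocks) - 1)
        )

    @property
    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)


def load_alignments(path, dialect: str | None = None, include_secondary: bool = False):
    """Stream AlignmentRecords from SAM/BAM, PAF or the simulator truth-TSV.

    Secondary/supplementary records are excluded by default (mirroring a
    `--secondary=no` aligner invocation); pass include_secondary=True to
    keep them flagged. Returns (records, stats) where records is a list
    and stats counts skipped categories.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {".sam": "sam", ".bam": "sam", ".paf": "paf"}.get(suffix, "tsv")
    stats = {"unmapped": 0, "secondary": 0, "supplementary": 0}
    records: list[AlignmentRecord] = []
    if dialect == "sam":
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for seg in af:
                if seg.is_unmapped:
                    stats["unmapped"] += 1
                    continue
                if seg.is_secondary:
                    stats["secondary"] += 1
                    if not include_secondary:
                        continue
                if seg.is_supplementary:
                    stats["supplementary"] += 1
                    if not include_secondary:
                        continue
                records.append(_from_pysam(seg))
    elif dialect == "paf":
        records.extend(_iter_paf(path))
    elif dialect == "tsv":
        records.extend(_iter_truth_tsv(path))
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    return records, stats


def _from_pysam(seg) -> AlignmentRecord:
    blocks: list[tuple[int, int]] = []
    read_starts: list[int] = []
    gpos = seg.reference_start
    rpos = 0
    cur_start, cur_rstart = gpos, rpos
    open_block = False
    qlen = seg.infer_read_length() or (len(seg.query_sequence) if seg.query_sequence else 0)
    for op, length in seg.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            if not open_block:
                cur_start, cur_rstart = gpos, rpos
                open_block = True
            gpos += length
            rpos += length
        elif op == 1:  # I
            rpos += length
        elif op == 2:  # D
            gpos += length
        elif op == 3:  # N — close the block
            if open_block:
                blocks.append((cur_start, gpos))
                read_starts.append(cur_rstart)
                open_block = False
            gpos += length
        elif op in (4, 5):  # S/H
            rpos += length if op == 4 else 0
        else:
            raise ValueError(f"{seg.query_name}: unsupported CIGAR op {op}")
    if open_block:
        blocks.append((cur_start, gpos))
        read_starts.append(cur_rstart)
    aligned = sum(e - s for s, e in blocks)
    frac = aligned / qlen if qlen else 0.0
    return AlignmentRecord(
        seg.query_name, seg.reference_name, "-" if seg.is_reverse else "+",
        blocks, min(frac, 1.0), seg.is_secondary, seg.is_supplementary, read_starts,
    )


def _iter_paf(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: PAF row with <12 columns")
            if f[5] == "*":
                continue
            # exon blocks recovered from the cs/CIGAR-free PAF via a bl tag
            # if present, else the whole target span is one block
            blocks = [(int(f[7]), int(f[8]))]
            for tag in f[12:]:
                if tag.startswith("bl:Z:"):
                    blocks = parse_blocks(tag[5:])
            qlen = int(f[1])
            aligned = sum(e - s for s, e in blocks)
            yield AlignmentRecord(
                f[0], f[5], f[4], blocks, min(aligned / qlen, 1.0) if qlen else 0.0
            )


TRUTH_ALN_COLUMNS = ["read_id", "chrom", "strand", "blocks", "aligned_base_fraction"]


def parse_blocks(text: str) -> list[tuple[int, int]]:
    """Parse "s1-e1,s2-e2" block syntax used by truth-TSV and PAF bl tags."""
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def format_blocks(blocks) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks)


def _iter_truth_tsv(path):
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("read_id", "chrom", "strand", "blocks"):
            if name not in idx:
                raise ValueError(f"{path}: truth alignment TSV missing column {name}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            frac = float(f[idx["aligned_base_fraction"]]) if "aligned_base_fraction" in idx else 1.0
            yield AlignmentRecord(
                f[idx["read_id"]], f[idx["chrom"]], f[idx["strand"]],
                parse_blocks(f[idx["blocks"]]), frac,
            )


def write_truth_alignments(records: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_ALN_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.strand}\t{format_blocks(r.blocks)}"
                f"\t{r.aligned_base_fraction:.6f}\n"
            )


# ---------------------------------------------------------------------------
# SNPs


@dataclass
class SnpTable:
    """Biallelic substitution SNPs distinguishing two strains.

    ``ref_strain`` carries the reference-genome allele, ``alt_strain``
    the alternate; positions are 0-based and unique per chromosome.
    """

    records: list[tuple[str, int, str, str]]
    ref_strain: str = "A"
    alt_strain: str = "B"
    n_skipped: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for chrom, pos, ref, alt in self.records:
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"SNP {chrom}:{pos}: not a single-base substitution")
            if (chrom, pos) in seen:
                raise ValueError(f"duplicate SNP position {chrom}:{pos}")
            seen.add((chrom, pos))
        self._by_chrom: dict[str, dict[int, tuple[str, str]]] = {}
        for chrom, pos, ref, alt in self.records:
            self._by_chrom.setdefault(chrom, {})[pos] = (ref, alt)

    def __len__(self) -> int:
        return len(self.records)

    def alleles_at(self, chrom: str, pos: int) -> tuple[str, str] | None:
        return self._by_chrom.get(chrom, {}).get(pos)

    def positions(self, chrom: str) -> dict[int, tuple[str, str]]:
        return self._by_chrom.get(chrom, {})


def load_snps(vcf_path, ref_strain: str = "A", alt_strain: str = "B") -> SnpTable:
    """Load biallelic substitution SNPs from a VCF.

    Indels and multiallelic sites are skipped and counted; positions are
    shifted to 0-based. Records arriving unsorted are sorted internally
    (logged).
    """
    records: list[tuple[str, int, str, str]] = []
    skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            records.append((rec.chrom, rec.pos - 1, rec.ref.upper(), alts[0].upper()))
    if records != sorted(records, key=lambda r: (r[0], r[1])):
        log.info("VCF %s not coordinate-sorted; sorting internally", vcf_path)
        records.sort(key=lambda r: (r[0], r[1]))
    if skipped:
        log.info("VCF %s: skipped %d non-SNP/multiallelic records", vcf_path, skipped)
    return SnpTable(records, ref_strain, alt_strain, n_skipped=skipped)
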