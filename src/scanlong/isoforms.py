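"""Novel-isoform discovery: cluster, depth-filter, collapse, classify, filter.

Transcript models are built per cell from spliced alignments: reads are
grouped by their splice-junction chain (each edge snapped to the nearest
annotated splice site within +/-5 bp), low-depth clusters are removed
(min 2 reads when every splice site and exonic region is annotated, min
5 otherwise), redundant models are collapsed (identical chains merge;
5'-truncated chains merge into their parent), and each surviving model
is classified against the annotation into one of

    known | CJ | CS | ME | IR | MIR | intergenic | discarded

where the five novel categories are: CJ — a new combination of
individually annotated junctions; CS — annotated donor and acceptor
sites joined by a never-annotated junction; ME — a mono-exon model
inside one annotated exon; IR — a complete annotated intron retained
within a model exon; MIR — a mono-exon model spanning annotated exons
plus their flanking introns. Models with any unannotated splice site
after snapping are discarded. Category precedence for multi-exon models
is IR > CJ > CS (retention is the most specific structural event).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median_low

import pandas as pd

from scanlong.core_io import AlignmentRecord, AnnotationIndex

SNAP_TOL = 5


@dataclass
class TranscriptModel:
    model_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    supporting_read_ids: list[str] = field(default_factory=list)
    host_gene: str | None = None

    @property
    def junction_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def n_reads(self) -> int:
        return len(self.supporting_read_ids)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class IsoformCall:
    model: TranscriptModel
    category: str
    n_cells_detected: int = 0
    per_cell_rpt10k: dict[str, float] = field(default_factory=dict)
    per_cell_share: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# clustering


def _snap(value: int, sites: set[int], tol: int) -> int:
    best, bd = value, tol + 1
    for cand in range(value - tol, value + tol + 1):
        if cand in sites and abs(cand - value) < bd:
            best, bd = cand, abs(cand - value)
    return best


def snap_chain(aln: AlignmentRecord, index: AnnotationIndex, tol: int = SNAP_TOL):
    """Snap each junction edge to the nearest annotated splice site
    within +/-tol; unannotated edges are kept as observed."""
    key = (aln.chrom, aln.strand)
    left = index.left_sites.get(key, set())
    right = index.right_sites.get(key, set())
    return tuple((_snap(d, left, tol), _snap(a, right, tol)) for d, a in aln.junctions)


def cluster_reads(
    alignments: list[AlignmentRecord],
    index: AnnotationIndex,
    tol: int = SNAP_TOL,
    cell: str = "",
) -> list[TranscriptModel]:
    """Group one cell's reads into transcript models by junction chain.

    Spliced reads sharing a (chrom, strand, snapped chain) form one
    cluster; residual unannotated edges within +/-tol of each other are
    unified to the cluster-median edge. Mono-exon reads are clustered by
    >=50% reciprocal overlap. Representative exon ends are the medians
    of supporting read ends; junction-internal edges are fixed by the
    chain.
    """
    spliced: dict[tuple, list[AlignmentRecord]] = {}
    mono: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for a in alignments:
        if a.is_secondary or a.is_supplementary:
            continue
        chain = snap_chain(a, index, tol)
        if chain:
            spliced.setdefault((a.chrom, a.strand, chain), []).append(a)
        else:
            mono.setdefault((a.chrom, a.strand), []).append(a)

    # merge spliced clusters whose chains differ only by <=tol at
    # unannotated edges: greedy union onto the first-seen chain
    merged: dict[tuple, list[AlignmentRecord]] = {}
    for key, group in sorted(spliced.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        chrom, strand, chain = key
        target = None
        for mk in merged:
            if mk[0] != chrom or mk[1] != strand or len(mk[2]) != len(chain):
                continue
            if all(
                abs(j1[0] - j2[0]) <= tol and abs(j1[1] - j2[1]) <= tol
                for j1, j2 in zip(chain, mk[2])
            ):
                target = mk
                break
        merged.setdefault(target or key, []).extend(group)

    models: list[TranscriptModel] = []
    n = 0
    for (chrom, strand, chain), group in sorted(merged.items()):
        n += 1
        start = median_low(sorted(a.start for a in group))
        end = median_low(sorted(a.end for a in group))
        exons = _exons_from_chain(start, end, chain)
        models.append(
            TranscriptModel(
                f"{cell or 'M'}.{n:04d}", chrom, strand, exons,
                [a.read_id for a in group],
            )
        )
    for (chrom, strand), group in sorted(mono.items()):
        for cl in _cluster_mono(group):
            n += 1
            start = median_low(sorted(a.start for a in cl))
            end = median_low(sorted(a.end for a in cl))
            models.append(
                TranscriptModel(
                    f"{cell or 'M'}.{n:04d}", chrom, strand, [(start, end)],
                    [a.read_id for a in cl],
                )
            )
    return models


def _exons_from_chain(start: int, end: int, chain) -> list[tuple[int, int]]:
    exons = []
    prev = start
    for d, a in chain:
        exons.append((prev, d))
        prev = a
    exons.append((prev, end))
    return exons


def _cluster_mono(group: list[AlignmentRecord]) -> list[list[AlignmentRecord]]:
    """Greedy >=50% reciprocal-overlap clustering of mono-exon reads."""
    clusters: list[list[AlignmentRecord]] = []
    for a in sorted(group, key=lambda x: (x.start, x.end)):
        placed = False
        for cl in clusters:
            rep = cl[0]
            ov = min(rep.end, a.end) - max(rep.start, a.start)
            if ov > 0 and ov >= 0.5 * (rep.end - rep.start) and ov >= 0.5 * (a.end - a.start):
                cl.append(a)
                placed = True
                break
        if not placed:
            clusters.append([a])
    return clusters


# ---------------------------------------------------------------------------
# depth filter


def _all_annotated(model: TranscriptModel, index: AnnotationIndex) -> bool:
    """True iff every splice site is annotated and every model exon
    overlaps an annotated exon."""
    key = (model.chrom, model.strand)
    left = index.left_sites.get(key, set())
    right = index.right_sites.get(key, set())
    for d, a in model.junction_chain:
        if d not in left or a not in right:
            return False
    for s, e in model.exons:
        if not index.exon_overlaps(model.chrom, s, e):
            return False
    return True


def filter_clusters(
    models: list[TranscriptModel],
    index: AnnotationIndex,
    min_known: int = 2,
    min_novel_region: int = 5,
) -> list[TranscriptModel]:
    """Low-depth cluster removal.

    Clusters whose splice sites are all annotated and whose exons all
    overlap annotated exons need >= 2 reads; clusters touching novel
    exonic space (or with unannotated splice sites) need >= 5. Both are
    strict less-than exclusions: the boundary count passes.
    """
    kept = []
    for m in models:
        need = min_known if _all_annotated(m, index) else min_novel_region
        if m.n_reads >= need:
            kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# collapse


def collapse_models(models: list[TranscriptModel]) -> list[TranscriptModel]:
    """Merge redundant models.

    Models with identical (chrom, strand, chain) merge with pooled
    supports. A multi-exon model whose chain is a 5'-truncated
    contiguous end of another model's chain (same 3' terminus in mRNA
    orientation) merges into the longer model. Mono-exon models are left
    as-is here (their redundancy was handled by overlap clustering).
    """
    by_key: dict[tuple, TranscriptModel] = {}
    passthrough: list[TranscriptModel] = []
    for m in models:
        if not m.junction_chain:
            # mono-exon models share the empty chain; their redundancy was
            # already resolved by reciprocal-overlap clustering
            passthrough.append(m)
            continue
        key = (m.chrom, m.strand, m.junction_chain)
        if key in by_key:
            tgt = by_key[key]
            tgt.supporting_read_ids.extend(m.supporting_read_ids)
            tgt.exons = _merge_ends(tgt.exons, m.exons)
        else:
            by_key[key] = TranscriptModel(
                m.model_id, m.chrom, m.strand, list(m.exons),
                list(m.supporting_read_ids), m.host_gene,
            )
    result = list(by_key.values()) + passthrough
    # 5'-truncation merge: chain A == terminal run of chain B at the 3' end
    absorbed: set[int] = set()
    for i, a in enumerate(result):
        ca = a.junction_chain
        if not ca:
            continue
        for j, b in enumerate(result):
            if i == j or j in absorbed or i in absorbed:
                continue
            cb = b.junction_chain
            if len(cb) <= len(ca) or (a.chrom, a.strand) != (b.chrom, b.strand):
                continue
            if a.strand == "+":
                is_trunc = cb[-len(ca):] == ca
            else:  # mRNA 5' is the genomic right end
                is_trunc = cb[: len(ca)] == ca
            if is_trunc:
                b.supporting_read_ids.extend(a.supporting_read_ids)
                absorbed.add(i)
                break
    return [m for k, m in enumerate(result) if k not in absorbed]


def _merge_ends(e1, e2):
    exons = list(e1)
    exons[0] = (min(e1[0][0], e2[0][0]), e1[0][1])
    exons[-1] = (exons[-1][0], max(e1[-1][1], e2[-1][1]))
    return exons


# ---------------------------------------------------------------------------
# classification


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, cursor = 0, None
    for s, e in sorted(intervals):
        if cursor is None or s > cursor:
            total += e - s
            cursor = e
        elif e > cursor:
            total += e - cursor
            cursor = e
    return total


def _assign_host_gene(model: TranscriptModel, index: AnnotationIndex) -> str | None:
    """Same-strand gene with the largest exonic overlap (union of bases);
    ties broken by gene id."""
    per_gene: dict[str, list[tuple[int, int]]] = {}
    for s, e in model.exons:
        for iv in index.exon_overlaps(model.chrom, s, e):
            gid, _tid = iv.data
            if index.genes[gid].strand != model.strand:
                continue
            per_gene.setdefault(gid, []).append((max(iv.begin, s), min(iv.end, e)))
    if not per_gene:
        return None
    return max(sorted(per_gene), key=lambda g: _union_length(per_gene[g]))


def _is_known(model: TranscriptModel, index: AnnotationIndex) -> bool:
    chain = model.junction_chain
    if not chain:
        # mono-exon: known iff it matches an annotated mono-exon
        # transcript by >=50% reciprocal overlap
        for t in index.transcripts.values():
            if len(t.exons) != 1 or (t.chrom, t.strand) != (model.chrom, model.strand):
                continue
            ov = min(t.end, model.end) - max(t.start, model.start)
            if ov > 0 and ov >= 0.5 * (t.end - t.start) and ov >= 0.5 * (model.end - model.start):
                return True
        return False
    for t in index.transcripts.values():
        if (t.chrom, t.strand) != (model.chrom, model.strand):
            continue
        tc = t.junctions
        if tc == chain:
            return True
        # contiguous-subchain match = truncation, still known; terminal
        # model exons must stay inside the matching transcript exons
        n, m = len(chain), len(tc)
        for off in range(m - n + 1):
            if tc[off : off + n] != chain:
                continue
            first_exon = t.exons[off]
            last_exon = t.exons[off + n]
            if model.start >= first_exon[0] and model.end <= last_exon[1]:
                return True
    return False


def _retained_introns(model: TranscriptModel, introns) -> bool:
    """True iff any complete annotated intron (with a base of each
    flanking exon) lies within one model exon."""
    for s, e in model.exons:
        for d, a in introns:
            if s < d and a < e:
                return True
    return False


def classify_model(model: TranscriptModel, index: AnnotationIndex) -> str:
    """Classify a transcript model against the annotation.

    Returns one of known / CJ / CS / ME / IR / MIR / intergenic /
    discarded; sets ``model.host_gene`` as a side effect when a host is
    found. See the module docstring for category definitions.
    """
    if _is_known(model, index):
        model.host_gene = _assign_host_gene(model, index)
        return "known"
    host = _assign_host_gene(model, index)
    model.host_gene = host
    chain = model.junction_chain

    if not chain:  # mono-exon
        s, e = model.exons[0]
        if not index.gene_overlaps(model.chrom, s, e):
            return "intergenic"
        if host is not None:
            # inside a single annotated exon of the host gene?
            for iv in index.exon_overlaps(model.chrom, s, e):
                gid, tid = iv.data
                if gid == host and iv.begin <= s and e <= iv.end:
                    return "ME"
            if _retained_introns(model, index.gene_junctions(host)):
                return "MIR"
        return "discarded"

    # multi-exon
    if host is None:
        if not any(
            index.gene_overlaps(model.chrom, s, e) for s, e in model.exons
        ):
            return "intergenic"
        return "discarded"
    gene_juncs = index.gene_junctions(host)
    if _retained_introns(model, gene_juncs):
        return "IR"
    if all(j in gene_juncs for j in chain):
        return "CJ"
    key = (model.chrom, model.strand)
    left = index.left_sites.get(key, set())
    right = index.right_sites.get(key, set())
    if all(d in left and a in right for d, a in chain):
        return "CS"
    return "discarded"


# ---------------------------------------------------------------------------
# expression filters and cross-cell merge


def filter_novel(
    calls: list[IsoformCall],
    rpt10k: pd.DataFrame,
    model_gene: dict[str, str],
    tx_gene: dict[str, str],
    min_rpt10k: float = 0.1,
    min_share: float = 0.05,
    min_cells: int = 3,
) -> list[IsoformCall]:
    """Apply the expression filters to novel isoform calls.

    ``rpt10k`` is cells x transcripts computed jointly over known and
    novel transcripts; ``tx_gene`` maps every column to its gene. Per
    cell, a novel transcript is detected iff its RPT10k >= min_rpt10k
    (values below are set to 0) and its share of host-gene transcript
    expression >= min_share; it is retained iff detected in >= min_cells
    cells. All three are strict less-than exclusions.
    """
    expr = rpt10k.where(rpt10k >= min_rpt10k, 0.0)
    gene_sums = expr.T.groupby([tx_gene[c] for c in expr.columns]).sum().T
    kept = []
    for call in calls:
        mid = call.model.model_id
        if mid not in expr.columns:
            continue
        host = model_gene[mid]
        n_det = 0
        for cell in expr.index:
            v = float(expr.at[cell, mid])
            if v <= 0.0:
                continue
            g = float(gene_sums.at[cell, host]) if host in gene_sums.columns else 0.0
            if g <= 0.0:
                raise ValueError(
                    f"model {mid}: host gene {host} has zero expression in "
                    f"cell {cell} but the model is expressed"
                )
            share = v / g
            if share >= min_share:
                n_det += 1
                call.per_cell_rpt10k[cell] = v
                call.per_cell_share[cell] = share
        call.n_cells_detected = n_det
        if n_det >= min_cells:
            kept.append(call)
    return kept


def merge_across_cells(per_cell_models: dict[str, list[TranscriptModel]]):
    """Union per-cell models into a catalogue keyed by identity.

    Spliced models are equal iff (chrom, strand, chain) are equal;
    mono-exon models match by >=50% reciprocal overlap. Representative
    terminal ends are medians across cells. Returns (catalogue,
    n_cells_detected per model_id).
    """
    spliced: dict[tuple, list[tuple[str, TranscriptModel]]] = {}
    mono: list[tuple[str, TranscriptModel]] = []
    for cell, models in sorted(per_cell_models.items()):
        for m in models:
            if m.junction_chain:
                spliced.setdefault((m.chrom, m.strand, m.junction_chain), []).append((cell, m))
            else:
                mono.append((cell, m))
    catalogue: list[TranscriptModel] = []
    n_cells: dict[str, int] = {}
    k = 0
    for (chrom, strand, chain), entries in sorted(spliced.items()):
        k += 1
        start = median_low(sorted(m.start for _, m in entries))
        end = median_low(sorted(m.end for _, m in entries))
        mid = f"CAT.{k:05d}"
        cat = TranscriptModel(
            mid, chrom, strand, _exons_from_chain(start, end, chain),
            [r for _, m in entries for r in m.supporting_read_ids],
            entries[0][1].host_gene,
        )
        catalogue.append(cat)
        n_cells[mid] = len({cell for cell, _ in entries})
    # mono-exon grouping by overlap
    groups: list[list[tuple[str, TranscriptModel]]] = []
    for cell, m in sorted(mono, key=lambda cm: (cm[1].chrom, cm[1].strand, cm[1].start)):
        placed = False
        for grp in groups:
            rep = grp[0][1]
            if (rep.chrom, rep.strand) != (m.chrom, m.strand):
                continue
            ov = min(rep.end, m.end) - max(rep.start, m.start)
            if ov > 0 and ov >= 0.5 * (rep.end - rep.start) and ov >= 0.5 * (m.end - m.start):
                grp.append((cell, m))
                placed = True
                break
        if not placed:
            groups.append([(cell, m)])
    for grp in groups:
        k += 1
        start = median_low(sorted(m.start for _, m in grp))
        end = median_low(sorted(m.end for _, m in grp))
        mid = f"CAT.{k:05d}"
        catalogue.append(
            TranscriptModel(
                mid, grp[0][1].chrom, grp[0][1].strand, [(start, end)],
                [r for _, m in grp for r in m.supporting_read_ids],
                grp[0][1].host_gene,
            )
        )
        n_cells[mid] = len({cell for cell, _ in grp})
    return catalogue, n_cells
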