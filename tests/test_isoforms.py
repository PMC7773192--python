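import numpy as np
import pytest

from scanlong.core_io import AlignmentRecord, AnnotationIndex, Transcript
from scanlong.isoforms import (
    TranscriptModel,
    classify_model,
    cluster_reads,
    collapse_models,
    filter_clusters,
    filter_novel,
    IsoformCall,
    merge_across_cells,
)
from scanlong import pipeline as pl

from oracle_isoforms import oracle_classify


def _aln(blocks, rid, strand="+", chrom="chr1"):
    return AlignmentRecord(rid, chrom, strand, blocks)


def _model(exons, strand="+", chrom="chr1", mid="m", n_reads=5):
    return TranscriptModel(mid, chrom, strand, exons, [f"r{i}" for i in range(n_reads)])


# ---------------------------------------------------------------------------
# clustering


def test_identical_chains_form_one_cluster(toy_index):
    alns = [_aln([(120, 200), (300, 380)], f"r{i}") for i in range(2)]
    models = cluster_reads(alns, toy_index)
    assert len(models) == 1 and models[0].n_reads == 2


def test_near_annotated_edges_snap_into_same_cluster(toy_index):
    a = _aln([(120, 200), (300, 380)], "ra")
    b = _aln([(118, 197), (303, 382)], "rb")  # donor off by 3 near site 200
    models = cluster_reads([a, b], toy_index)
    assert len(models) == 1
    assert models[0].junction_chain == ((200, 300),)


def test_chains_differing_by_a_junction_stay_distinct(toy_index):
    a = _aln([(120, 200), (300, 400), (500, 580)], "ra")
    b = _aln([(120, 200), (400, 680)], "rb")
    models = cluster_reads([a, b], toy_index)
    assert len(models) == 2


def test_mono_exon_reads_cluster_by_reciprocal_overlap(toy_index):
    a = _aln([(300, 400)], "ra")
    b = _aln([(310, 395)], "rb")
    c = _aln([(600, 700)], "rc")
    models = cluster_reads([a, b, c], toy_index)
    sizes = sorted(m.n_reads for m in models)
    assert sizes == [1, 2]


# ---------------------------------------------------------------------------
# depth filter


def test_depth_filter_boundaries(toy_index):
    known2 = _model([(120, 200), (300, 380)], n_reads=2)  # annotated sites
    novel4 = _model([(1000, 1100), (1200, 1300)], n_reads=4)  # novel region
    novel5 = _model([(1000, 1100), (1200, 1300)], n_reads=5)
    kept = filter_clusters([known2, novel4, novel5], toy_index)
    assert known2 in kept and novel5 in kept and novel4 not in kept


def test_depth_filter_single_known_read_removed(toy_index):
    m = _model([(120, 200), (300, 380)], n_reads=1)
    assert filter_clusters([m], toy_index) == []


# ---------------------------------------------------------------------------
# collapse


def test_identical_chain_clusters_merge():
    a = _model([(100, 200), (300, 400)], mid="a", n_reads=3)
    b = _model([(90, 200), (300, 410)], mid="b", n_reads=2)
    merged = collapse_models([a, b])
    assert len(merged) == 1 and merged[0].n_reads == 5
    assert merged[0].exons == [(90, 200), (300, 410)]


def test_truncated_suffix_chain_merges_into_longer_model():
    long = _model([(100, 200), (300, 400), (500, 600)], mid="long", n_reads=3)
    trunc = _model([(320, 400), (500, 600)], mid="trunc", n_reads=2)
    merged = collapse_models([long, trunc])
    assert len(merged) == 1
    assert merged[0].junction_chain == ((200, 300), (400, 500))
    assert merged[0].n_reads == 5


def test_truncated_prefix_merges_on_minus_strand():
    long = _model([(100, 200), (300, 400), (500, 600)], strand="-", mid="long")
    trunc = _model([(100, 200), (300, 380)], strand="-", mid="trunc", n_reads=2)
    merged = collapse_models([long, trunc])
    assert len(merged) == 1 and merged[0].n_reads == 7


def test_unrelated_chains_stay_separate():
    a = _model([(100, 200), (300, 400)], mid="a")
    b = _model([(1000, 1100), (1200, 1300)], mid="b")
    assert len(collapse_models([a, b])) == 2


# ---------------------------------------------------------------------------
# classification: worked examples on the toy annotation
# (GA+: T1 [100,200),[300,400),[500,600) junctions A=(200,300), B=(400,500);
#  T2 [100,200),[400,700),[800,900) junctions C=(200,400), D=(700,800))


@pytest.mark.parametrize(
    "exons,expected",
    [
        ([(100, 200), (300, 400), (500, 600)], "known"),  # exact T1 chain
        # chain [A, B, D] combines annotated junctions of T1 and T2 but
        # matches no single transcript -> CJ
        ([(150, 200), (300, 400), (500, 700), (800, 850)], "CJ"),
        # junction (200,500): donor 200 and acceptor 500 annotated, the
        # pairing never annotated -> CS
        ([(150, 200), (500, 600)], "CS"),
        # intron A=(200,300) retained, junction B known -> IR
        ([(100, 400), (500, 600)], "IR"),
        ([(310, 390)], "ME"),  # inside exon [300,400)
        ([(100, 400)], "MIR"),  # spans exons 1-2 plus intron A
    ],
)
def test_classifier_worked_examples(toy_index, exons, expected):
    assert classify_model(_model(exons), toy_index) == expected


def test_truncated_subchain_is_known_not_novel(toy_index):
    # chain [B] with terminal exons inside T1's exons: a 5' fragment
    assert classify_model(_model([(320, 400), (500, 580)]), toy_index) == "known"


def test_unannotated_splice_site_is_discarded(toy_index):
    assert classify_model(_model([(150, 250), (330, 400)]), toy_index) == "discarded"


def test_intergenic_models(toy_index):
    assert classify_model(_model([(2000, 2200)]), toy_index) == "intergenic"
    assert classify_model(_model([(2000, 2100), (2200, 2300)]), toy_index) == "intergenic"


# ---------------------------------------------------------------------------
# classification: randomized agreement with the brute-force oracle


def _random_case(rng):
    """A random toy annotation plus a random model to classify."""
    chrom = "chr1"
    strand = rng.choice(["+", "-"])
    n_ex = int(rng.integers(3, 7))
    cursor = int(rng.integers(50, 200))
    exons = []
    for _ in range(n_ex):
        length = int(rng.integers(30, 120))
        exons.append((cursor, cursor + length))
        cursor += length + int(rng.integers(20, 100))
    transcripts = [("T1", "G1", chrom, strand, exons)]
    if n_ex >= 3 and rng.random() < 0.8:
        skip = int(rng.integers(1, n_ex - 1))
        transcripts.append(
            ("T2", "G1", chrom, strand, exons[:skip] + exons[skip + 1 :])
        )
    if rng.random() < 0.3:  # occasional annotated mono-exon transcript
        s = cursor + 50
        transcripts.append(("T3", "G2", chrom, strand, [(s, s + 80)]))

    lefts = sorted({e[1] for t in transcripts for e in t[4][:-1]})
    rights = sorted({e[0] for t in transcripts for e in t[4][1:]})

    kind = rng.choice(
        ["exact", "truncate", "retain", "mono_in", "mono_span", "mono_intron",
         "pair_sites", "perturb", "intergenic", "antisense"]
    )
    t = transcripts[int(rng.integers(len(transcripts)))]
    tex = [list(e) for e in t[4]]
    m_strand = t[3]
    if kind == "exact":
        m_exons = [tuple(e) for e in tex]
    elif kind == "truncate" and len(tex) >= 3:
        k = int(rng.integers(1, len(tex) - 1))
        m_exons = [tuple(e) for e in tex[k:]]
        s0, e0 = m_exons[0]
        m_exons[0] = (min(s0 + int(rng.integers(0, max(e0 - s0 - 5, 1))), e0 - 5), e0)
    elif kind == "retain" and len(tex) >= 2:
        k = int(rng.integers(0, len(tex) - 1))
        m_exons = [tuple(e) for e in tex[:k]] + [(tex[k][0], tex[k + 1][1])] + [
            tuple(e) for e in tex[k + 2 :]
        ]
    elif kind == "mono_in":
        s, e = tex[int(rng.integers(len(tex)))]
        pad = int(rng.integers(0, max((e - s) // 3, 1)))
        m_exons = [(s + pad, e - pad)] if e - pad > s + pad else [(s, e)]
    elif kind == "mono_span" and len(tex) >= 2:
        i = int(rng.integers(0, len(tex) - 1))
        m_exons = [(tex[i][0] - int(rng.integers(0, 10)), tex[i + 1][1])]
    elif kind == "mono_intron" and len(tex) >= 2:
        i = int(rng.integers(0, len(tex) - 1))
        gap_s, gap_e = tex[i][1], tex[i + 1][0]
        if gap_e - gap_s >= 10:
            m_exons = [(gap_s + 2, gap_e - 2)]
        else:
            m_exons = [(gap_s, gap_e)]
    elif kind == "pair_sites" and lefts and rights:
        d = int(rng.choice(lefts))
        acc = [r for r in rights if r > d + 5]
        if acc:
            a = int(rng.choice(acc))
            m_exons = [(d - int(rng.integers(10, 40)), d), (a, a + int(rng.integers(10, 40)))]
        else:
            m_exons = [tuple(e) for e in tex]
    elif kind == "perturb" and len(tex) >= 2:
        m_exons = [tuple(e) for e in tex]
        i = int(rng.integers(0, len(m_exons) - 1))
        s, e = m_exons[i]
        m_exons[i] = (s, e + 7)  # novel donor 7 bp off (outside snap range)
    elif kind == "intergenic":
        s = cursor + 500
        if rng.random() < 0.5:
            m_exons = [(s, s + 100)]
        else:
            m_exons = [(s, s + 80), (s + 150, s + 260)]
    elif kind == "antisense":
        m_exons = [tuple(e) for e in tex]
        m_strand = "+" if t[3] == "-" else "-"
    else:
        m_exons = [tuple(e) for e in tex]
    # validity: sorted, disjoint, non-abutting, non-empty
    for (s0, e0), (s1, e1) in zip(m_exons, m_exons[1:]):
        if s1 <= e0:
            return None
    if any(e <= s for s, e in m_exons):
        return None
    return chrom, m_strand, m_exons, transcripts


def test_classifier_agrees_with_brute_force_oracle():
    rng = np.random.default_rng(2024)
    n_checked = 0
    while n_checked < 1000:
        case = _random_case(rng)
        if case is None:
            continue
        chrom, strand, m_exons, transcripts = case
        index = AnnotationIndex(
            [Transcript(tid, gid, c, s, [tuple(e) for e in ex])
             for tid, gid, c, s, ex in transcripts]
        )
        model = TranscriptModel("m", chrom, strand, list(m_exons), ["r0"])
        got = classify_model(model, index)
        want = oracle_classify(chrom, strand, m_exons, transcripts)
        assert got == want, f"{chrom}{strand} {m_exons} vs {transcripts}: {got} != {want}"
        n_checked += 1


# ---------------------------------------------------------------------------
# expression filters


def _make_filter_inputs(rpt_values, share_gene_total=None, n_cells=4):
    """One novel model N hosted by gene g with known transcript K."""
    import pandas as pd

    cells = [f"c{i}" for i in range(n_cells)]
    data = {"N": [], "K": []}
    for i, v in enumerate(rpt_values):
        total = share_gene_total[i] if share_gene_total else 10_000.0
        data["N"].append(v)
        data["K"].append(total - v)
    rpt = pd.DataFrame(data, index=cells[: len(rpt_values)])
    model = TranscriptModel("N", "chr1", "+", [(0, 10)], ["r"], host_gene="g")
    call = IsoformCall(model, "CJ")
    return call, rpt, {"N": "g"}, {"N": "g", "K": "g"}


@pytest.mark.parametrize(
    "rpt,totals,min_cells,retained",
    [
        # RPT10k exactly 0.1, share exactly 5%, 3 cells -> retained
        ([0.1, 0.1, 0.1, 0.0], [2.0, 2.0, 2.0, 2.0], 3, True),
        # RPT10k 0.09 everywhere -> removed
        ([0.09, 0.09, 0.09, 0.09], [2.0, 2.0, 2.0, 2.0], 3, False),
        # share 4.9% -> not detected
        ([0.49, 0.49, 0.49, 0.49], [10.0, 10.0, 10.0, 10.0], 3, False),
        # detected in only 2 cells -> removed
        ([0.1, 0.1, 0.0, 0.0], [2.0, 2.0, 2.0, 2.0], 3, False),
    ],
)
def test_novel_expression_filter_boundaries(rpt, totals, min_cells, retained):
    call, mat, model_gene, tx_gene = _make_filter_inputs(rpt, totals)
    kept = filter_novel([call], mat, model_gene, tx_gene, min_cells=min_cells)
    assert (len(kept) == 1) is retained


def test_min_cells_threshold_is_monotone():
    call, mat, model_gene, tx_gene = _make_filter_inputs(
        [0.5, 0.5, 0.5, 0.0], [2.0, 2.0, 2.0, 2.0]
    )
    counts = []
    for mc in (1, 2, 3, 4, 5):
        call.n_cells_detected = 0
        call.per_cell_rpt10k.clear()
        kept = filter_novel([call], mat, model_gene, tx_gene, min_cells=mc)
        counts.append(len(kept))
    assert counts == sorted(counts, reverse=True)


def test_zero_host_expression_with_novel_expression_raises():
    import pandas as pd

    model = TranscriptModel("N", "chr1", "+", [(0, 10)], ["r"], host_gene="g")
    call = IsoformCall(model, "CJ")
    rpt = pd.DataFrame({"N": [1.0]}, index=["c0"])
    with pytest.raises(ValueError, match="host gene"):
        filter_novel([call], rpt, {"N": "g"}, {"N": "h"})


# ---------------------------------------------------------------------------
# merge across cells


def test_same_chain_across_cells_merges_to_one_entry():
    per_cell = {
        f"cell{i}": [_model([(100, 200), (300, 400)], mid=f"m{i}")] for i in range(5)
    }
    catalogue, n_cells = merge_across_cells(per_cell)
    assert len(catalogue) == 1
    assert n_cells[catalogue[0].model_id] == 5


def test_terminal_length_differences_do_not_split_entries():
    per_cell = {
        "a": [_model([(100, 200), (300, 400)], mid="x")],
        "b": [_model([(80, 200), (300, 460)], mid="y")],
    }
    catalogue, _ = merge_across_cells(per_cell)
    assert len(catalogue) == 1


def test_catalogue_size_equals_distinct_chains():
    per_cell = {
        "a": [_model([(100, 200), (300, 400)], mid="x"),
              _model([(100, 200), (500, 600)], mid="y")],
        "b": [_model([(100, 200), (300, 400)], mid="z")],
    }
    catalogue, _ = merge_across_cells(per_cell)
    assert len(catalogue) == 2


# ---------------------------------------------------------------------------
# planted-isoform recovery through the full stack


def test_planted_isoforms_recovered_with_correct_categories():
    from scanlong import simlib

    ref = simlib.make_reference(n_genes=6, exons_per_gene=5, n_snps_per_kb=0, seed=7)
    planted = simlib.plant_novel_isoforms(ref, "G1")
    tids = list(ref.index.transcripts) + [t.transcript_id for t in planted.values()]
    design = simlib.random_design(ref, 4, seed=1, transcripts=tids, uniform=True)
    lib = simlib.synthesize_reads(ref, design, simlib.ErrorModel(), 1500, seed=3)
    truth = lib.truth.set_index("read_id")
    by_cell = {}
    for a in lib.truth_alignments:
        by_cell.setdefault(truth.at[a.read_id, "cell"], []).append(a)
    res = pl.discover_isoforms(by_cell, ref.index, min_cells=3)
    got = {}
    for call in res.retained:
        reads = call.model.supporting_read_ids
        src = set(truth.loc[reads].transcript) & set(planted)
        plain = {t.replace("NOVEL_", "") for t in set(truth.loc[reads].transcript)}
        for cat in ("CJ", "CS", "ME", "IR", "MIR"):
            if f"NOVEL_{cat}" in set(truth.loc[reads].transcript):
                got[cat] = call.category
    for cat in ("CJ", "CS", "ME", "IR", "MIR"):
        assert got.get(cat) == cat, f"planted {cat} recovered as {got.get(cat)}"
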