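import numpy as np
import pytest

from scanlong import demux, simlib
from scanlong.allelic import (
    allelic_summary,
    assign_allele,
    build_alt_genome,
    call_reads,
    dual_map_average,
    estimate_assignment_error,
    genotype_read,
)
from scanlong.core_io import AlignmentRecord, SnpTable


# ---------------------------------------------------------------------------
# alternate genome


def test_empty_snp_table_is_identity():
    genome = {"chr1": "ACGTACGTAC"}
    assert build_alt_genome(genome, SnpTable([])) == genome


def test_hamming_distance_equals_snp_count():
    genome = {"chr1": "ACGTACGTAC"}
    snps = SnpTable([("chr1", 0, "A", "G"), ("chr1", 4, "A", "T"), ("chr1", 9, "C", "G")])
    alt = build_alt_genome(genome, snps)
    assert len(alt["chr1"]) == len(genome["chr1"])
    assert sum(a != b for a, b in zip(alt["chr1"], genome["chr1"])) == 3


def test_swapped_alleles_invert_the_substitution():
    genome = {"chr1": "ACGTACGTAC"}
    snps = SnpTable([("chr1", 2, "G", "C")])
    alt = build_alt_genome(genome, snps)
    back = build_alt_genome(alt, SnpTable([("chr1", 2, "C", "G")]))
    assert back == genome


def test_ref_allele_mismatch_raises():
    with pytest.raises(ValueError, match="chr1:1"):
        build_alt_genome({"chr1": "ACGT"}, SnpTable([("chr1", 1, "G", "T")]))


# ---------------------------------------------------------------------------
# genotyping


@pytest.fixture()
def snps4():
    return SnpTable(
        [("chr1", 10, "A", "G"), ("chr1", 20, "C", "T"),
         ("chr1", 60, "G", "A"), ("chr1", 70, "T", "C")]
    )


def test_zero_error_maternal_read_supports_all_ref_alleles(snps4):
    genome = "N" * 100
    genome = "".join(
        {10: "A", 20: "C", 60: "G", 70: "T"}.get(i, "C") for i in range(100)
    )
    aln = AlignmentRecord("r", "chr1", "+", [(0, 30), (50, 80)])
    read = genome[0:30] + genome[50:80]
    assert genotype_read(aln, read, snps4) == (4, 0)


def test_read_covering_no_snp_is_uninformative(snps4):
    aln = AlignmentRecord("r", "chr1", "+", [(30, 50)])
    assert genotype_read(aln, "C" * 20, snps4) == (0, 0)


def test_third_base_at_snp_counts_for_neither(snps4):
    aln = AlignmentRecord("r", "chr1", "+", [(0, 15)])
    read = list("C" * 15)
    read[10] = "T"  # neither A (ref) nor G (alt)
    assert genotype_read(aln, "".join(read), snps4) == (0, 0)


def test_minus_strand_read_complements_back_to_genome(snps4):
    # mRNA-sense read of a minus-strand gene: read = revcomp(genome block)
    from scanlong.core_io import revcomp

    genome = "".join(
        {10: "A", 20: "C"}.get(i, "C") for i in range(30)
    )
    aln = AlignmentRecord("r", "chr1", "-", [(0, 30)])
    assert genotype_read(aln, revcomp(genome), snps4) == (2, 0)


# ---------------------------------------------------------------------------
# assignment rules


def _brute_force_rule(cov, a, b, min_cov=0.60):
    """Literal transcription of the two assignment rules."""
    if cov < min_cov:
        return "excluded_low_coverage"
    if a + b == 1:
        return "A" if a == 1 else "B"
    if a > 0 and a >= 2 * b:
        return "A"
    if b > 0 and b >= 2 * a:
        return "B"
    return "unassigned"


def test_assignment_rules_match_brute_force_on_grid():
    for a in range(11):
        for b in range(11):
            for cov in (0.0, 0.59, 0.60, 1.0):
                got = assign_allele("r", "g", cov, (a, b)).assignment
                assert got == _brute_force_rule(cov, a, b), (cov, a, b)


@pytest.mark.parametrize(
    "cov,supports,expected",
    [
        (0.59, (3, 0), "excluded_low_coverage"),
        (0.8, (1, 0), "A"),
        (0.8, (2, 1), "A"),
        (0.8, (3, 2), "unassigned"),
        (0.60, (0, 1), "B"),
        (0.8, (0, 0), "unassigned"),
    ],
)
def test_assignment_worked_examples(cov, supports, expected):
    assert assign_allele("r", "g", cov, supports).assignment == expected


# ---------------------------------------------------------------------------
# dual-mapping average


def _calls(cell_counts):
    """cell -> {gene: (nA, nB)} into call lists."""
    from scanlong.allelic import AllelicCall

    out = {}
    for cell, genes in cell_counts.items():
        calls = []
        for gene, (na, nb) in genes.items():
            calls += [AllelicCall(f"{cell}{gene}a{i}", gene, 1.0, 1, 0, "A") for i in range(na)]
            calls += [AllelicCall(f"{cell}{gene}b{i}", gene, 1.0, 0, 1, "B") for i in range(nb)]
        out[cell] = calls
    return out


def test_dual_average_worked_example():
    a = _calls({"c": {"g": (10, 4)}})
    b = _calls({"c": {"g": (8, 6)}})
    mat = dual_map_average(a, b)
    assert mat.maternal.at["c", "g"] == pytest.approx(9.0)
    assert mat.paternal.at["c", "g"] == pytest.approx(5.0)


def test_dual_average_symmetric_and_idempotent():
    a = _calls({"c": {"g": (10, 4), "h": (0, 3)}})
    b = _calls({"c": {"g": (8, 6)}})
    ab, ba = dual_map_average(a, b), dual_map_average(b, a)
    assert ab.maternal.equals(ba.maternal) and ab.paternal.equals(ba.paternal)
    aa = dual_map_average(a, a)
    assert aa.maternal.at["c", "g"] == 10.0 and aa.paternal.at["c", "h"] == 3.0


def test_dual_average_requires_matching_cells():
    a = _calls({"c1": {"g": (1, 0)}})
    b = _calls({"c2": {"g": (1, 0)}})
    with pytest.raises(ValueError, match="only one mapping"):
        dual_map_average(a, b)


# ---------------------------------------------------------------------------
# end-to-end on simulation


def _allelic_run(reference, maternal_fractions, n_reads, seed):
    design = simlib.random_design(
        reference, len(maternal_fractions), seed=seed,
        maternal_fraction=maternal_fractions,
    )
    lib = simlib.synthesize_reads(reference, design, simlib.ErrorModel(), n_reads, seed=seed + 1)
    truth = lib.truth.set_index("read_id")
    seqs = {}
    for r in lib.reads:
        st = demux.find_structure(r, design)
        seqs[r.read_id] = demux.orient_and_trim(r, st).oriented_sequence
    by_cell = {}
    for a in lib.truth_alignments:
        by_cell.setdefault(truth.at[a.read_id, "cell"], []).append(a)
    calls = {
        c: call_reads(v, seqs, reference.index, reference.snps)
        for c, v in by_cell.items()
    }
    return design, lib, calls


def test_maternal_fraction_recovered_within_binomial_3sigma(reference):
    fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
    design, lib, calls = _allelic_run(reference, fractions, 2500, seed=21)
    mat = dual_map_average(calls, calls)
    for cell, m in zip(sorted(calls), fractions):
        n_inf = sum(1 for c in calls[cell] if c.assignment in "AB")
        est = mat.per_cell_maternal_fraction[cell]
        sigma = np.sqrt(max(m * (1 - m), 0.25 / n_inf) / n_inf)
        assert abs(est - m) <= max(3 * sigma, 1e-12), (cell, m, est)


def test_zero_error_assignment_error_is_zero(reference):
    design, lib, calls = _allelic_run(reference, [1.0, 1.0, 0.0, 0.0], 800, seed=31)
    truth_strain = {"cell00": "A", "cell01": "A", "cell02": "B", "cell03": "B"}
    err = estimate_assignment_error(calls, truth_strain)
    assert err == {"A": 0.0, "B": 0.0}


def test_error_rate_arithmetic_on_constructed_calls():
    calls = _calls({"c": {"g": (987, 13)}})
    err = estimate_assignment_error(calls, {"c": "A"})
    assert err["A"] == pytest.approx(0.013)
    assert err["B"] is None


def test_summary_discriminable_fraction_and_pure_cells(reference):
    design, lib, calls = _allelic_run(reference, [1.0, 1.0], 600, seed=41)
    mat = dual_map_average(calls, calls)
    summary = allelic_summary(mat, reference.index, reference.snps)
    for cell in mat.cells:
        assert summary.at[cell, "maternal_fraction"] == pytest.approx(1.0)
    # every simulated gene carries exonic SNPs at this density or not;
    # the fraction must match a direct truth computation
    expect = np.mean(
        [
            any(
                s <= p < e
                for t in [reference.index.transcripts[tid] for tid in g.transcripts]
                for s, e in t.exons
                for p in reference.snps.positions(g.chrom)
            )
            for g in reference.index.genes.values()
        ]
    )
    assert summary.discriminable_gene_fraction.iloc[0] == pytest.approx(expect)
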