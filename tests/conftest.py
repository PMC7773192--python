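import pytest

from scanlong import simlib
from scanlong.core_io import AnnotationIndex, Transcript


@pytest.fixture(scope="session")
def toy_index():
    """Two-transcript annotation used throughout the classifier tests.

    Gene GA (+): T1 exons [100,200),[300,400),[500,600) with junctions
    A=(200,300), B=(400,500); T2 exons [100,200),[400,700),[800,900)
    with junctions C=(200,400), D=(700,800).
    """
    return AnnotationIndex(
        [
            Transcript("T1", "GA", "chr1", "+", [(100, 200), (300, 400), (500, 600)]),
            Transcript("T2", "GA", "chr1", "+", [(100, 200), (400, 700), (800, 900)]),
        ]
    )


@pytest.fixture(scope="session")
def reference():
    return simlib.make_reference(
        n_genes=6, exons_per_gene=5, n_snps_per_kb=5.0, seed=7, n_lnc_genes=2
    )


@pytest.fixture(scope="session")
def small_library(reference):
    """Zero-error 4-cell library over annotated + lnc transcripts."""
    tids = list(reference.index.transcripts) + list(reference.lnc_index.transcripts)
    design = simlib.random_design(reference, 4, seed=1, transcripts=tids)
    lib = simlib.synthesize_reads(reference, design, simlib.ErrorModel(), 800, seed=3)
    return lib


@pytest.fixture()
def alignments_by_cell(small_library):
    truth = small_library.truth.set_index("read_id")
    out = {}
    for a in small_library.truth_alignments:
        out.setdefault(truth.at[a.read_id, "cell"], []).append(a)
    return out
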