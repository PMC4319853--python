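import pytest

from peony_srna.hairpin import HairpinParams
from peony_srna.synthetic_data import make_references, simulate_libraries

ADAPTOR_3P = "TCGTATGCCGTCTTCTGCTTG"
ADAPTOR_5P = "GTTCAGAGTTCTACAGTCCGACGATC"


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic data set shared across tests:
    references with planted hairpins, conserved families, ncRNAs,
    target sites, plus raw reads for both libraries."""
    transcriptome, catalog, ncrna, truth = make_references(
        seed=11, n_transcripts=8, n_planted_precursors=6,
        n_conserved_families=4, n_ncrna=8, n_target_sites=3)
    reads_ck, reads_tr = simulate_libraries(
        truth, transcriptome, catalog, ncrna, depth_ck=8000, depth_tr=8000)
    return {"transcriptome": transcriptome, "catalog": catalog,
            "ncrna": ncrna, "truth": truth,
            "reads": {"CK": reads_ck, "TR": reads_tr}}


@pytest.fixture(scope="session")
def small_libs(small_sim):
    """Cleaned tag libraries of the small synthetic data set."""
    from peony_srna.sra_io import clean_reads

    libs = {}
    for label in ("CK", "TR"):
        lib, _ = clean_reads(small_sim["reads"][label], ADAPTOR_3P, ADAPTOR_5P,
                             label=label)
        libs[label] = lib
    return libs


@pytest.fixture(scope="session")
def hairpin_params():
    return HairpinParams()
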