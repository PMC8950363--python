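import pytest

from igloci import LocusSpec, annotate_locus, generate_locus, plant_duplication
from igloci.reporting import load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def medium_igh():
    """A mixed-plan heavy locus: F/ORF/P genes, inversions, a duplication,
    planted gaps and unlocalized genes."""
    spec = LocusSpec.demo("IGH", n_v=24, n_subgroups=4, n_d=4, n_j=3, n_c=2,
                          seed=7, n_unlocalized=3, gap_lengths=(120, 60))
    spec = plant_duplication(spec, 5)
    return generate_locus(spec)


@pytest.fixture(scope="session")
def medium_igh_annotated(medium_igh):
    return annotate_locus(
        medium_igh.locus,
        medium_igh.genes,
        directory=medium_igh.directory,
        unlocalized_cores=medium_igh.unlocalized,
    )


@pytest.fixture(scope="session")
def small_igk():
    spec = LocusSpec.demo("IGK", n_v=8, n_subgroups=2, n_j=2, n_c=1, seed=13)
    return generate_locus(spec)


@pytest.fixture(scope="session")
def small_igk_annotated(small_igk):
    return annotate_locus(small_igk.locus, small_igk.genes,
                          directory=small_igk.directory)
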