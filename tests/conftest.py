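import pytest

from screenstat.enrichment_stats import UniformLibraryNull
from screenstat.screen_sim import synthetic_guide_library


@pytest.fixture(scope="session")
def screen_null() -> UniformLibraryNull:
    """The screened library's idealized null: 260 guides x 12 copies."""
    return UniformLibraryNull(m=260, c=12)


@pytest.fixture(scope="session")
def small_null() -> UniformLibraryNull:
    """A pool small enough for exhaustive enumeration (6 clones)."""
    return UniformLibraryNull(m=3, c=2)


@pytest.fixture(scope="session")
def library_52x5():
    return synthetic_guide_library(n_genes=52, guides_per_gene=5, seed=11)


@pytest.fixture()
def guide_table_file(tmp_path, library_52x5):
    path = tmp_path / "guides.csv"
    library_52x5.to_frame().to_csv(path, index=False)
    return path
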