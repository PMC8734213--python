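import numpy as np
import pytest

from scdali import fixtures
from scdali.kernels import linear_factor, standardize_factor


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study: embedding, clusters, time, depths."""
    E, labels, t = fixtures.make_cell_states(400, n_clusters=8, latent_dim=4, seed=42)
    d = fixtures.make_depths(400, 30, 2.0, seed=43)
    return E, labels, t, d


@pytest.fixture(scope="session")
def std_factor(small_study):
    E, *_ = small_study
    return standardize_factor(linear_factor(E))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def read_fixture_files(tmp_path_factory):
    from scdali.fixtures import make_read_fixture

    fx = make_read_fixture(seed=0)
    base = tmp_path_factory.mktemp("reads")
    (base / "reads.sam").write_text(fx.sam_text)
    (base / "vars.vcf").write_text(fx.vcf_text)
    (base / "regions.bed").write_text(fx.bed_text)
    return base, fx
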