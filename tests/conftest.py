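import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import allelic as al

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Small two-allele dataset: 80 genes, 10/10 AI, 8 bootstraps."""
    design = al.SimDesign.desk(
        n_genes=80,
        n_concordant=10,
        n_discordant=10,
        library_size=200_000.0,
        n_bootstraps=8,
    )
    return al.simulate_dataset(design, seed=11)


@pytest.fixture(scope="session")
def desk_sim():
    """Desk-scale benchmark: 2,000 genes, 250/250 AI, B=30."""
    return al.simulate_dataset(al.SimDesign.desk(), seed=101)


@pytest.fixture(scope="session")
def desk_sim50():
    """Desk-scale dataset with 50 bootstrap replicates (coverage grid)."""
    return al.simulate_dataset(al.SimDesign.desk(n_bootstraps=50), seed=202)


@pytest.fixture(scope="session")
def null_sim():
    """Complete-null simulation: both alleles iid, ~5,400 transcripts."""
    design = al.SimDesign.desk(n_genes=1600, n_concordant=0, n_discordant=0)
    return al.simulate_dataset(design, seed=31)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_matrix(counts, bootstraps=None, **kw):
    """AllelicMatrix from a (F, S, 2) array; default bootstraps = counts."""
    counts = np.asarray(counts, dtype=float)
    if bootstraps is None:
        bootstraps = counts[None]
    F, S, _ = counts.shape
    kw.setdefault("feature_ids", [f"f{i}" for i in range(F)])
    kw.setdefault("sample_ids", [f"s{j}" for j in range(S)])
    return al.AllelicMatrix(counts=counts, bootstraps=np.asarray(bootstraps, dtype=float), **kw)
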