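import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vartriage import SimulationConfig, simulate_feature_table, simulate_vcf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def toy_reference():
    """Tiny in-memory contigs with known composition."""
    rng = np.random.default_rng(1234)
    return {
        "ref1": "ACGTACGTAC",
        "rand50": "".join(rng.choice(list("ACGT"), 50)),
        "polyA": "A" * 200,
    }


@pytest.fixture(scope="session")
def cohort():
    """A mid-sized synthetic confirmation cohort (features, labels, truth)."""
    frame, labels, truth = simulate_feature_table(SimulationConfig(n_calls=2500, seed=42))
    return frame, labels, truth


@pytest.fixture(scope="session")
def vcf_bundle(tmp_path_factory):
    """A small realized (FASTA, VCF, features, labels) file set."""
    out = tmp_path_factory.mktemp("simvcf")
    cfg = SimulationConfig(n_calls=400, seed=5)
    paths = simulate_vcf(cfg, out)
    return cfg, paths
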