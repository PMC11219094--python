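import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def neutral_chain():
    """A->T mutation on a 3-residue bead chain (apo phase)."""
    from alchemforge.toys import build_bead_residue_chain, make_bead_residue_chain

    return build_bead_residue_chain(make_bead_residue_chain(3, 1, "A", "T"))


@pytest.fixture(scope="session")
def charge_chain_complex():
    """R->A charge-changing mutation with partner cluster and counterion."""
    from alchemforge.toys import build_bead_residue_chain, make_bead_residue_chain

    return build_bead_residue_chain(
        make_bead_residue_chain(5, 2, "R", "A", phase="complex")
    )


@pytest.fixture(scope="session")
def trio_spec():
    from alchemforge.toys import make_charge_change_trio

    return make_charge_change_trio(seed=0)
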