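import numpy as np
import pytest

import boundarykit as bk


@pytest.fixture(scope="session")
def small_sim():
    """300-bin chromosome with moderate insulation, shared by fast tests."""
    cfg = bk.SimulationConfig(
        n_bins=300, tad_size_range=(30, 60), insulation_depths=(0.3,),
        depth=8e5, seed=11,
    )
    arch = bk.plant_architecture(cfg)
    m = bk.simulate_contact_map(arch)
    return cfg, arch, m


@pytest.fixture(scope="session")
def small_oe(small_sim):
    """Balanced matrix and O/E map of the session simulation."""
    _, _, m = small_sim
    bal = bk.ice_balance(m)
    oe = bk.observed_over_expected(bal, bk.expected_by_distance(bal))
    return bal, oe


@pytest.fixture(scope="session")
def called_tads(small_sim, small_oe):
    """Boundary/TAD calls with insulation scores on the session simulation."""
    _, _, _ = small_sim
    bal, oe = small_oe
    sig = bk.bin_signal(oe, w=5)
    bounds, tads = bk.detect_boundaries(sig, oe, chrom=bal.chrom,
                                       bin_size=bal.bin_size)
    bk.insulation_score(sig, bounds, tads)
    return sig, bounds, tads


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
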