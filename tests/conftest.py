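import numpy as np
import pytest

from cgbesmart import synthetic as syn
from cgbesmart.io_tables import TargetSite


@pytest.fixture(scope="session")
def small_library():
    """100 simulated sites with read tables, shared across tests."""
    cfg = syn.SimConfig(n_sites=100, seed=42, coverage_mean=500)
    sites, truth = syn.simulate_library(cfg)
    tables = syn.simulate_reads(sites, truth, cfg)
    return cfg, sites, truth, tables


@pytest.fixture(scope="session")
def site_map(small_library):
    _, sites, _, _ = small_library
    return {s.site_id: s for s in sites}


def make_site(protospacer: str, site_id: str = "s1", flank: str = "AATTA",
              pam: str = "AGG") -> TargetSite:
    """A valid site with 5-nt flanks around protospacer+PAM."""
    assert len(protospacer) == 20
    return TargetSite(
        site_id=site_id,
        sequence=flank + protospacer + pam + flank[:2],
        protospacer_start=len(flank) + 1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
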