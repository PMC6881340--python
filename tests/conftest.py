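import numpy as np
import pytest

import myotrack as mt


@pytest.fixture(scope="session")
def four_site_traj():
    """10,000-frame trajectory with four transient sites (dwell 100 us)
    placed clear of the detached mode so dwell recovery is not limited
    by binding-position density; detached SD 12.5 nm, bound SD 4.7 nm."""
    sites = [mt.WeakSite(p, 0.25, 100.0) for p in (-36.0, -24.0, 24.0, 36.0)]
    scheme = mt.KineticScheme(sites=sites, encounter_rate=1000.0, duration=400_000.0)
    return mt.simulate_trajectory(scheme, seed=10)


@pytest.fixture(scope="session")
def detached_only_traj():
    scheme = mt.KineticScheme(duration=400_000.0)
    return mt.simulate_trajectory(scheme, seed=99)


@pytest.fixture(scope="session")
def wildtype_scheme():
    """Strong-binding scheme: one site 44 nm forward, ATP-gated dwell at
    2 uM ATP on the fitted rate line."""
    return mt.KineticScheme(
        sites=[mt.WeakSite(44.0, 1.0, 1.0)],
        strong_site_index=0,
        atp_conc=2000.0,
        encounter_rate=10.0,
        duration=400_000.0,
    )
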