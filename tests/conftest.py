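import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from slitwater import synthetic as syn  # noqa: E402


@pytest.fixture(scope="session")
def monolayer_default():
    """Default-condition monolayer toy: populations and orientations."""
    return syn.gen_toy_monolayer(n_molecules=64, n_steps=2500, dt=0.01, seed=101)


@pytest.fixture(scope="session")
def monolayer_events():
    """Detection-condition monolayer toy with planted exchanges and kicks."""
    return syn.gen_toy_monolayer(n_molecules=72, n_steps=4000, dt=0.01, seed=102,
                                 tau_db=1.2, swe_rate=2.0, vacancy_fraction=0.11,
                                 kick_amplitude=0.12)


@pytest.fixture(scope="session")
def monolayer_events_analysis(monolayer_events):
    """Classified bonds, distance shells and filtered segments for the above."""
    import slitwater as sw

    traj, log = monolayer_events
    bonds = sw.classify_bonds(traj)
    shell = sw.shell_series(traj, bonds, mode="distance", r_shell=3.5)
    segments = sw.filter_transients(shell, 0.2)
    return traj, log, bonds, shell, segments


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
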