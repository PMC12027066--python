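import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from midtrace.fixtures import FixtureSpec, make_network, make_peak_table
from midtrace.mid import ExperimentSet, MIDVector, Peak, PeakTable


def random_mid(rng, n_carbons):
    fr = rng.random(n_carbons + 1) + 1e-3
    return MIDVector(fr / fr.sum())


def random_table(rng, n_peaks=12, n_experiments=3, sizes=(1, 2, 3, 4, 5),
                 missing_prob=0.0):
    """Random peak table; every peak keeps at least one experiment."""
    experiments = [f"exp{j}" for j in range(n_experiments)]
    table = PeakTable(ExperimentSet(experiments))
    for i in range(n_peaks):
        n = int(rng.choice(sizes))
        peak = Peak(peak_id=f"pk{i:02d}", n_carbons=n, mz=100.0 + i,
                    rt_seconds=10.0 * i)
        keep = [e for e in experiments if rng.random() >= missing_prob]
        if not keep:
            keep = [experiments[int(rng.integers(n_experiments))]]
        for e in keep:
            peak.set_mid(e, random_mid(rng, n))
        table.add_peak(peak)
    return table


@pytest.fixture(scope="session")
def eval_fixture():
    """Default noiseless evaluation data set (table, truth, labels)."""
    return make_peak_table(FixtureSpec())


@pytest.fixture(scope="session")
def eval_network():
    return make_network(FixtureSpec())
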