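import numpy as np
import pytest

from coevosis import RunConfig
from coevosis.experiment import (
    _child_seeds,
    founder_virus_experiment,
    run_simulation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Factory for reduced-scale configs used in fast integration tests."""

    def make(**kw):
        base = dict(
            M_init=40, K=300, burn_in_steps=40, coevolution_steps=120,
            measurement_interval=30, L=10, mu_hp=0.01,
        )
        base.update(kw)
        return RunConfig(**base)

    return make


@pytest.fixture(scope="session")
def trend_cells():
    """Full-scale replicate runs at low (L=5) and high (L=30) binding
    complexity with the default two founder viruses, for the qualitative
    trend comparisons (transmissibility, targeting unevenness, resistance
    strategy, diversity)."""
    cells = {}
    for L in (5, 30):
        rows = []
        for seed in _child_seeds(4000 + L, 20):
            res = run_simulation(RunConfig(L=L, mu_hp=0.01, seed=seed))
            s = dict(res.summary)
            s["div_start"] = (
                res.records[0]["sequence_div"] if res.records else float("nan")
            )
            s["div_end"] = (
                res.records[-1]["sequence_div"] if res.records else float("nan")
            )
            rows.append(s)
        cells[L] = rows
    return cells


@pytest.fixture(scope="session")
def founder_experiment_tables():
    """Diverse-founder-virus experiment (3 viruses per receptor, 15 total)
    at high and low binding complexity, 20 seeded replicates each."""
    return {
        L: founder_virus_experiment(L=L, mu_hp=0.002, replicates=20, base_seed=1)
        for L in (30, 10)
    }
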