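import numpy as np
import pandas as pd
import pytest

from doms.io_model import ALL_FRACTIONS, AnalysisConfig, ExperimentTable


@pytest.fixture
def cfg():
    return AnalysisConfig()


def make_table(intensity_rows, ms_rows=None, conditions=("control",),
               n_replicates=1, fractions=ALL_FRACTIONS):
    """Build a small ExperimentTable from per-protein dicts of
    {(condition, replicate, fraction): value}."""
    keys = [(c, r, f) for c in conditions
            for r in range(1, n_replicates + 1) for f in fractions]
    columns = pd.MultiIndex.from_tuples(keys, names=["condition", "replicate", "fraction"])
    ids = list(intensity_rows)
    intensity = pd.DataFrame(
        [[intensity_rows[pid].get(k, np.nan) for k in keys] for pid in ids],
        index=ids, columns=columns)
    if ms_rows is None:
        ms = intensity.notna().astype(float) * 5.0
    else:
        ms = pd.DataFrame(
            [[ms_rows[pid].get(k, 0.0) for k in keys] for pid in ids],
            index=ids, columns=columns)
    return ExperimentTable(intensity=intensity, ms_count=ms)


@pytest.fixture
def small_simulation():
    """A small two-condition simulation with planted relocalizers, shared
    across tests (module scope would hide seed bugs; keep it cheap)."""
    from doms.synthetic_data import SimulationConfig, simulate_experiment

    sim = SimulationConfig(n_proteins=300, n_relocalizers=15, seed=11)
    table, truth = simulate_experiment(sim, conditions=("control", "DTT"))
    return table, truth
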