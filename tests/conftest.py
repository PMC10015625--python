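import numpy as np
import pytest

from introland.gio import GenotypeMatrix
from introland import simcoal


@pytest.fixture(scope="session")
def trio_pulse_dataset():
    """Ladder-tree simulation with a recent P3 -> P2 pulse (f = 0.15)."""
    model = simcoal.ladder_model(
        pulses=[simcoal.Pulse(5_000, "P3", "P2", 0.15)])
    windows = simcoal.WindowModel(n_windows=150)
    gm, truth = simcoal.simulate_dataset(
        model, windows, {"P1": 2, "P2": 2, "P3": 2, "P4": 2, "O": 1}, seed=42)
    return gm, truth, model, windows


@pytest.fixture(scope="session")
def ils_only_dataset():
    """Pulse-free ladder-tree simulation (pure incomplete lineage sorting)."""
    model = simcoal.ladder_model()
    windows = simcoal.WindowModel(n_windows=150)
    gm, truth = simcoal.simulate_dataset(
        model, windows, {"P1": 2, "P2": 2, "P3": 2, "P4": 2, "O": 1}, seed=7)
    return gm, truth, model, windows


def make_matrix(dosages, pops, outgroup, chrom=None, pos=None):
    """Hand-built GenotypeMatrix: dosages (n_sites, n_samples), pops per sample."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n_sites,
                       dtype=object),
        pos=np.asarray(pos if pos is not None
                       else np.arange(1, n_sites + 1), dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosages=dosages,
        samples=samples,
        pop_map=dict(zip(samples, pops)),
        outgroup=outgroup,
    )
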