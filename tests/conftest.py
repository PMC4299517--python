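import numpy as np
import pandas as pd
import pytest

from tisfacs import quant, sim


@pytest.fixture(scope="session")
def truth_mono():
    """Purely mononucleotide ground truth (no pairwise terms)."""
    return sim.sample_ground_truth(11, pair_fraction=0.0)


@pytest.fixture(scope="session")
def truth_pairwise():
    """Ground truth with pairwise interactions at the default strength."""
    return sim.sample_ground_truth(12, pair_fraction=0.5)


@pytest.fixture(scope="session")
def small_pipeline(truth_pairwise):
    """A reduced-depth but otherwise standard simulate->gate->read->quantify
    run, shared across tests: (truth, gates, matrix, efficiency table)."""
    pop = sim.simulate_cell_population(
        truth_pairwise, cells_per_tis=40, noise_sigma=0.25, seed=21
    )
    gates, gate_index = sim.assign_gates(pop)
    matrix = sim.simulate_reads(pop, gate_index, reads_per_gate=100_000,
                                seed=22)
    table = quant.quantify(matrix, gates)
    return truth_pairwise, gates, matrix, table


@pytest.fixture()
def tiny_matrix():
    """Hand-sized count matrix over 3 contexts and 4 gates."""
    return pd.DataFrame(
        np.array([[5, 3, 2, 0],
                  [0, 4, 4, 2],
                  [1, 1, 1, 1]]),
        index=pd.Index(["AAAAAAAUGAA", "GCCACCAUGGG", "UUUUUUAUGUU"],
                       name="tis"),
        columns=["gate_01", "gate_02", "gate_03", "gate_04"],
    )
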