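import numpy as np
import pytest

from clonetrace import quantify, synth


@pytest.fixture(scope="session")
def small_library():
    return synth.make_half_library(12, length=18, min_dist=3, seed=11)


@pytest.fixture(scope="session")
def one_mouse_params():
    mice = (synth.MouseSpec("A", (
        synth.LesionSpec("MFP", "MFP"),
        synth.LesionSpec("lung", "lung1", 30),
        synth.LesionSpec("liver", "liver1", 30),
    )),)
    return synth.SimParams(n_cells=5000, p_tic=0.5, mice=mice,
                           reads_per_sample=5000, error_rate=0.0,
                           junk_fraction=0.0)


@pytest.fixture(scope="session")
def noiseless_run(small_library, one_mouse_params):
    """Ground truth, reads and quantified matrix of a noise-free experiment."""
    gt, reads = synth.simulate_experiment(one_mouse_params, small_library,
                                          seed=3)
    records = {s: [quantify.ReadRecord(f"r{i}", seq)
                   for i, seq in enumerate(seqs)]
               for s, seqs in reads.items()}
    matrix = quantify.count_pairs(records, small_library)
    return gt, reads, matrix


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
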