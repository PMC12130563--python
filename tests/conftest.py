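import numpy as np
import pytest

from cccf import consensus as cons
from cccf import de, scoring, synth


@pytest.fixture(scope="session")
def sc_default():
    """Default-scale simulation (2,000 cells) shared across read-only tests."""
    return synth.simulate_sc(synth.SCSimParams(seed=1))


@pytest.fixture(scope="session")
def sc_small():
    """A small, fast simulation for unit tests."""
    params = synth.SCSimParams(
        n_cells_per_condition=250, n_genes=300, n_sig_up=15, n_sig_down=15,
        n_monotone=12, seed=3,
    )
    return synth.simulate_sc(params)


@pytest.fixture(scope="session")
def cccf_chain(sc_default):
    """Normalised matrix, signatures, score tensor and consensus calls for
    the default simulation."""
    adata, truth = sc_default
    norm = de.normalize(adata)
    records = de.sc_de(norm)
    sig = de.extract_signatures(records)
    registry = scoring.build_registry(19)
    tensor = scoring.score_all(norm, sig, registry)
    results = cons.classify(tensor)
    return {
        "adata": adata, "truth": truth, "norm": norm, "signatures": sig,
        "registry": registry, "tensor": tensor, "consensus": results,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
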