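import numpy as np
import pytest

from combilogic.pkn import PriorKnowledgeNetwork
from combilogic.synthetic_data import (CohortSpec, NoiseModel,
                                       make_ground_truth, random_pkn,
                                       simulate_cohort)


@pytest.fixture
def chain_pkn() -> PriorKnowledgeNetwork:
    """S -> A -> B -> M with S stimulus, M readout, A/B unmeasured."""
    pkn = PriorKnowledgeNetwork()
    pkn.add_node("S", role="stimulus")
    pkn.add_node("M", role="readout")
    pkn.add_interaction("S", "A", 1)
    pkn.add_interaction("A", "B", 1)
    pkn.add_interaction("B", "M", -1)
    return pkn


def small_panel(n_stimuli: int = 4, n_readouts: int = 3):
    return (tuple(f"S{i}" for i in range(n_stimuli)),
            tuple(f"M{i}" for i in range(n_readouts)))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Noise-free 3-group cohort on a small random network, with truth."""
    stimuli, readouts = small_panel()
    pkn = random_pkn(stimuli, readouts, n_intermediates=5, seed=7)
    spec = CohortSpec(n_donors_per_group=4,
                      groups=("healthy", "untreated", "FTY"),
                      stimuli=stimuli, readouts=readouts, seed=7)
    truth = make_ground_truth(pkn, spec, n_deregulated=2, seed=7,
                              n_unreverted=1)
    noise = NoiseModel(cv=0.0, donor_variability=0.0)
    cohort = simulate_cohort(truth, spec, noise)
    return pkn, spec, truth, cohort


def random_digraph_edges(n_nodes: int, p: float, rng: np.random.Generator):
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [(a, b) for a in nodes for b in nodes
             if a != b and rng.random() < p]
    return nodes, edges


def transitive_closure_oracle(nodes, edges):
    """Boolean reachability matrix by repeated matrix multiplication."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[idx[a], idx[b]] = True
    closure = adj | np.eye(n, dtype=bool)
    for _ in range(n):
        closure = closure | (closure @ closure)
    return idx, closure
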