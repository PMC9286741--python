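import numpy as np
import pytest

from gxeqtl import (SimulationConfig, assign_environments, compute_kinship,
                    simulate_mosaics, simulate_phenotypes,
                    solve_components_for_pve)


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale DO-like dataset shared across tests: 80 mice, 2 chromosomes."""
    cfg = SimulationConfig(n_mice=80, n_markers=60, n_chromosomes=2, seed=11)
    fp, dm, counts = simulate_mosaics(cfg)
    K = compute_kinship(fp)
    Z = assign_environments(cfg, np.random.default_rng(12))
    return {"cfg": cfg, "fp": fp, "dm": dm, "counts": counts, "K": K, "Z": Z}


@pytest.fixture(scope="session")
def small_phenotype(small_sim):
    cfg = small_sim["cfg"]
    vc = solve_components_for_pve((0.4, 0.4), (1.0, 1.0), small_sim["K"],
                                  small_sim["Z"])
    Y = simulate_phenotypes(vc, small_sim["K"], small_sim["Z"], None, seed=13)
    return {"vc_true": vc, "Y": Y}
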