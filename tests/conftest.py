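import pandas as pd
import pytest

from scrselect.capture_data import StateSpace
from scrselect.evaluation import scaled_down_design
from scrselect.mcmc import ChainConfig, run_chain
from scrselect.simulator import Scenario, build_trap_grid, simulate_dataset


def table3_events(shared_ids: bool = True) -> pd.DataFrame:
    """The worked bilateral example: two fully identified individuals (linked
    through circled simultaneous captures) and one unlinked partial pair,
    over J=3 traps and K=4 occasions."""
    rows = []

    def ev(ind, det, trap, occ, sim=0):
        rows.append((ind, det, trap, occ, sim))

    # fully identified individual 1 (simultaneous capture: trap 2, occasion 4)
    for trap, occs in ((1, [2, 4]), (2, [1, 4]), (3, [3, 4])):
        for o in occs:
            ev("ind1", 1, trap, o, int(trap == 2 and o == 4))
    for trap, occs in ((1, [3]), (2, [4]), (3, [1])):
        for o in occs:
            ev("ind1" if shared_ids else "d2_a", 2, trap, o,
               int(trap == 2 and o == 4))
    # fully identified individual 2 (simultaneous capture: trap 1, occasion 1)
    for trap, occs in ((1, [1]), (2, [4]), (3, [1, 2])):
        for o in occs:
            ev("ind2", 1, trap, o, int(trap == 1 and o == 1))
    for trap, occs in ((1, [1, 2]), (3, [3])):
        for o in occs:
            ev("ind2" if shared_ids else "d2_b", 2, trap, o,
               int(trap == 1 and o == 1))
    # partially identified pair (no simultaneous events, distinct ids)
    for trap, occs in ((1, [1, 4]), (2, [3])):
        for o in occs:
            ev("part1", 1, trap, o)
    for trap, occs in ((1, [3]), (2, [1]), (3, [3])):
        for o in occs:
            ev("part2", 2, trap, o)
    return pd.DataFrame(rows, columns=["individual_id", "detector", "trap_id",
                                       "occasion", "simultaneous"])


@pytest.fixture
def table3():
    return table3_events()


@pytest.fixture
def trap_table3():
    return pd.DataFrame({"trap_id": [1, 2, 3],
                         "x": [0.3, 0.5, 0.7], "y": [0.5, 0.5, 0.5]})


@pytest.fixture(scope="session")
def tiny_setup():
    """A small simulated data set (N=12, M=30, K=8) on a dense grid."""
    space = StateSpace(0.0, 1.4, 0.0, 1.4, buffer=0.2)
    traps = build_trap_grid(5, 5, space)
    scen = Scenario(omega0=0.05, phi=0.9, sigma_m=0.3, sigma_f=0.15,
                    N=12, N_male=5, M=30, K=8)
    data, identity, truth = simulate_dataset(scen, traps, space, seed=11)
    return {"space": space, "traps": traps, "scenario": scen,
            "data": data, "identity": identity, "truth": truth}


@pytest.fixture(scope="session")
def tiny_fit_m3(tiny_setup):
    """An M3 chain on the tiny data set, shared across criterion tests."""
    cfg = ChainConfig(n_iter=1500, burn_in=300, seed=4, latent_thin=10)
    draws = run_chain(tiny_setup["data"], tiny_setup["identity"], "M3", cfg,
                      tiny_setup["traps"], tiny_setup["space"])
    return draws


@pytest.fixture(scope="session")
def sdd():
    return scaled_down_design()
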