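import logging

import numpy as np
import pytest

import oligotraj as ot


@pytest.fixture(autouse=True)
def _quiet_hbond_warnings():
    # noisy frames legitimately detach the occasional amide H; tests that
    # assert on the warning raise the level back locally
    logging.getLogger("oligotraj.contacts").setLevel(logging.ERROR)
    yield
    logging.getLogger("oligotraj.contacts").setLevel(logging.NOTSET)


@pytest.fixture(scope="session")
def ordered_dimer():
    """Noise-free antiparallel dimer, ordered from frame 0."""
    scenario = ot.DimerScenario(
        n_frames=5, transition_frame=0, noise_sigma=0.0, seed=11
    )
    return ot.generate_dimer_trajectory(scenario)


@pytest.fixture(scope="session")
def scripted_dimer():
    """Antiparallel dimer with a transition at frame 30 of 60, 0.1 A noise."""
    scenario = ot.DimerScenario(
        n_frames=60, transition_frame=30, noise_sigma=0.1, seed=12
    )
    return scenario, ot.generate_dimer_trajectory(scenario)


@pytest.fixture
def two_atom_pdb(tmp_path):
    text = (
        "MODEL        1\n"
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C\n"
        "ENDMDL\n"
        "END\n"
    )
    path = tmp_path / "two_atom.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def insulin_like_topology():
    """Chain A with 21 CA atoms, chain B with 30, as in two-chain insulin."""
    topo = []
    for chain, n in (("A", 21), ("B", 30)):
        for i in range(1, n + 1):
            topo.append(
                ot.AtomRecord(
                    atom_name="CA", residue_name="GLY", residue_index=i, chain_id=chain
                )
            )
    return topo
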