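import numpy as np
import pytest

from gpcrdyn import (TorsionModelSpec, ToyReceptorSpec, gen_coupled_torsions,
                     gen_toy_trajectory)


@pytest.fixture(scope="session")
def coupled_pair_series():
    """Coupled torsion pair (km=0, kc=2) at n=1e5, plus an independent pair."""
    spec = TorsionModelSpec(n_residues=4,
                            coupling_edges=[(0, 1, 2.0)],
                            marginal_concentration=0.0,
                            n_runs=5, frames_per_run=20_000, seed=11)
    return gen_coupled_torsions(spec)


@pytest.fixture(scope="session")
def toy_contact_fixture():
    """Toy receptor with scheduled contacts straddling the sustained rule."""
    spec = ToyReceptorSpec(
        helix_count=2, residues_per_helix=5,
        contact_schedule=[(2, "hbond", 0.45), (4, "vdw", 0.41),
                          (7, "vdw", 0.39)],
        per_atom_sigma=0.05, n_runs=5, frames_per_run=200, seed=7)
    return gen_toy_trajectory(spec)


@pytest.fixture(scope="session")
def toy_jitter_fixture():
    """Toy receptor with sigma=0.577 A per-axis jitter at 1e4 pooled frames."""
    spec = ToyReceptorSpec(helix_count=4, residues_per_helix=10,
                           per_atom_sigma=0.577, n_runs=5,
                           frames_per_run=2000, seed=13)
    return gen_toy_trajectory(spec)


@pytest.fixture()
def single_atom_topology():
    from gpcrdyn import Topology
    return Topology(
        atom_names=np.array(["N1"], dtype=object),
        elements=np.array(["N"], dtype=object),
        res_ids=np.array([1]), res_names=np.array(["LIG"], dtype=object),
        chains=np.array(["A"], dtype=object),
        ligand_mask=np.array([True]))
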