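import numpy as np
import pytest

from fretquench import MolecularEnsemble, PhotophysicalParams


@pytest.fixture
def params2d() -> PhotophysicalParams:
    return PhotophysicalParams(quantum_yield=0.33, tau_total=5.0, forster_radius=5.0, dimension=2)


@pytest.fixture
def params3d() -> PhotophysicalParams:
    return PhotophysicalParams(quantum_yield=0.33, tau_total=5.0, forster_radius=5.0, dimension=3)


@pytest.fixture
def time_grid() -> np.ndarray:
    return np.linspace(0.0, 25.0, 501)


@pytest.fixture
def donor_trap_pair() -> MolecularEnsemble:
    """One fluorescent donor and one trap, 3 nm apart, in a 2D box."""
    return MolecularEnsemble(
        dimension=2,
        box_lengths=[100.0, 100.0],
        positions=[[10.0, 10.0], [13.0, 10.0]],
        orientations=[[1.0, 0.0], [0.0, 1.0]],
        trap_mask=[False, True],
        diameter=1.0,
    )


def random_ensemble(dim: int, n: int, seed: int, trap_frac: float = 0.0) -> MolecularEnsemble:
    """Small random ensemble helper for property tests."""
    from fretquench import assign_random_traps, place_molecules

    box = 100.0 if dim == 2 else 20.0
    conc = n / box**dim
    ens = place_molecules(dim, box, conc, rng=seed)
    if trap_frac:
        ens = assign_random_traps(ens, trap_frac, rng=seed + 1)
    return ens
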