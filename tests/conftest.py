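import numpy as np
import pytest

from ionbind.synthetic import LigandSpec, SiteTrajectorySpec, gen_site_trajectory
from ionbind.traj import AnalysisParams


@pytest.fixture
def params():
    return AnalysisParams()


@pytest.fixture
def simple_spec():
    """One ligand, mixed schedule, modest noise, chi + H-bond plants."""
    n = 50
    return SiteTrajectorySpec(
        n_frames=n,
        ligands=(LigandSpec(label="L1", nominal_distance=2.5),),
        shell_schedule={"L1": ("first",) * 30 + ("second",) * 10 + ("none",) * 10},
        chi_schedule=("trans",) * 35 + ("g-",) * 15,
        hbond_schedule={"P1": (True,) * 40 + (False,) * 10},
        water_count=3,
        noise_sd=0.02,
        seed=7,
    )


@pytest.fixture
def simple_traj(simple_spec):
    return gen_site_trajectory(simple_spec)


def random_site_spec(rng: np.random.Generator, n_frames=None, n_ligands=None,
                     noise_sd=None, seed=None):
    """Random-but-valid trajectory spec used for oracle-equivalence sweeps."""
    n = int(rng.integers(5, 60)) if n_frames is None else n_frames
    nl = int(rng.integers(1, 5)) if n_ligands is None else n_ligands
    noise = float(rng.choice([0.0, 0.01, 0.03, 0.05])) if noise_sd is None else noise_sd
    ligands = tuple(
        LigandSpec(
            label=f"L{i}",
            nominal_distance=float(rng.uniform(2.0, 2.8 - 3 * noise - 0.05)),
            second_distance=float(rng.uniform(3.0 + 3 * noise, 5.5 - 9 * noise)),
            none_distance=float(rng.uniform(6.2 + 3 * noise, 9.0)),
        )
        for i in range(nl)
    )
    schedule = {
        lig.label: tuple(rng.choice(["first", "second", "none"], size=n))
        for lig in ligands
    }
    return SiteTrajectorySpec(
        n_frames=n,
        ligands=ligands,
        shell_schedule=schedule,
        water_count=int(rng.integers(0, 5)),
        noise_sd=noise,
        seed=int(rng.integers(0, 2**31)) if seed is None else seed,
    )
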