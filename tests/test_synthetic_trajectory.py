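import numpy as np
import pytest

from ionbind.synthetic import (
    CHI_ATOM_IDS,
    GroundTruth,
    LigandSpec,
    SiteTrajectorySpec,
    gen_site_trajectory,
    hbond_atom_ids,
)
from ionbind.traj import assign_shells, classify_rotamer, hbond_occupancy

from conftest import random_site_spec


def make_spec(schedule, noise=0.0, seed=0, **kwargs):
    return SiteTrajectorySpec(
        n_frames=len(schedule),
        ligands=(LigandSpec(label="L1", nominal_distance=2.5),),
        shell_schedule={"L1": tuple(schedule)},
        noise_sd=noise,
        seed=seed,
        **kwargs,
    )


def test_always_first_occupancy_one():
    traj, truth = gen_site_trajectory(make_spec(["first"] * 10))
    assert truth.first_occupancy["L1"] == 1.0
    assert truth.total_occupancy["L1"] == 1.0
    ion = traj.coords[:, traj.ion_index()]
    lig = traj.coords[:, traj.index_of("L1")]
    assert np.allclose(np.linalg.norm(lig - ion, axis=1), 2.5)


def test_always_out_occupancy_zero():
    spec = SiteTrajectorySpec(
        n_frames=10,
        ligands=(LigandSpec(label="L1", none_distance=7.0),),
        shell_schedule={"L1": ("none",) * 10},
    )
    traj, truth = gen_site_trajectory(spec)
    assert truth.first_occupancy["L1"] == 0.0
    assert truth.total_occupancy["L1"] == 0.0
    a = assign_shells(traj)
    lig = traj.index_of("L1")
    assert not a.first_protein[:, lig].any()
    assert not a.second_protein[:, lig].any()


def test_planted_60_percent_recovered_with_noise():
    # 60/100 frames in the first shell, noise_sd 0.05: downstream shell
    # assignment recovers exactly 60%
    schedule = ["first"] * 60 + ["none"] * 40
    traj, truth = gen_site_trajectory(make_spec(schedule, noise=0.05, seed=11))
    a = assign_shells(traj)
    lig = traj.index_of("L1")
    assert truth.first_occupancy["L1"] == pytest.approx(0.60)
    assert a.first_protein[:, lig].mean() == pytest.approx(0.60)


def test_determinism_same_seed():
    spec = make_spec(["first", "second", "none"] * 5, noise=0.04, seed=42)
    t1, _ = gen_site_trajectory(spec)
    t2, _ = gen_site_trajectory(spec)
    assert np.array_equal(t1.coords, t2.coords)


def test_different_seed_differs():
    s1 = make_spec(["first"] * 5, noise=0.04, seed=1)
    s2 = make_spec(["first"] * 5, noise=0.04, seed=2)
    assert not np.array_equal(gen_site_trajectory(s1)[0].coords,
                              gen_site_trajectory(s2)[0].coords)


def test_inconsistent_first_distance_rejected():
    spec = SiteTrajectorySpec(
        n_frames=3,
        ligands=(LigandSpec(label="L1", nominal_distance=2.79),),
        shell_schedule={"L1": ("first",) * 3},
        noise_sd=0.05,
    )
    with pytest.raises(ValueError, match="L1.*frame 0"):
        gen_site_trajectory(spec)


def test_none_distance_inside_cutoff_rejected():
    spec = SiteTrajectorySpec(
        n_frames=2,
        ligands=(LigandSpec(label="L1", none_distance=5.0),),
        shell_schedule={"L1": ("none", "none")},
    )
    with pytest.raises(ValueError, match="L1"):
        gen_site_trajectory(spec)


def test_schedule_length_mismatch_rejected():
    spec = SiteTrajectorySpec(
        n_frames=5,
        ligands=(LigandSpec(label="L1"),),
        shell_schedule={"L1": ("first",) * 4},
    )
    with pytest.raises(ValueError, match="schedule"):
        gen_site_trajectory(spec)


def test_zero_noise_analysis_equals_truth_exactly():
    rng = np.random.default_rng(5)
    for _ in range(10):
        spec = random_site_spec(rng, noise_sd=0.0)
        traj, truth = gen_site_trajectory(spec)
        a = assign_shells(traj)
        for lig in spec.ligands:
            i = traj.index_of(lig.label)
            assert a.first_protein[:, i].mean() == truth.first_occupancy[lig.label]
            total = (a.first_protein[:, i] | a.second_protein[:, i]).mean()
            assert total == truth.total_occupancy[lig.label]
        assert np.array_equal(a.first_protein.sum(axis=1), truth.protein_first_counts)
        assert np.array_equal(a.second_protein.sum(axis=1), truth.protein_second_counts)
        assert np.array_equal(a.first_water.sum(axis=1), truth.water_first_counts)
        assert np.array_equal(a.second_water.sum(axis=1), truth.water_second_counts)


def test_chi_schedule_recovered():
    spec = make_spec(["first"] * 20, noise=0.03, seed=9,
                     chi_schedule=("trans",) * 14 + ("g-",) * 6)
    traj, truth = gen_site_trajectory(spec)
    series = classify_rotamer(traj, CHI_ATOM_IDS)
    assert tuple(series.labels) == truth.chi_labels
    assert series.fractions() == {"trans": 0.7, "g+": 0.0, "g-": 0.3}


def test_hbond_schedule_recovered():
    spec = make_spec(["first"] * 20, noise=0.03, seed=13,
                     hbond_schedule={"P1": (True,) * 15 + (False,) * 5})
    traj, truth = gen_site_trajectory(spec)
    table = hbond_occupancy([traj], [hbond_atom_ids("P1")])
    occ = table.per_replica.loc[("0", "D_P1->A_P1"), "occupancy_pct"]
    assert occ == pytest.approx(100 * truth.hbond_occupancy["P1"])


def test_high_noise_with_hbonds_rejected():
    spec = SiteTrajectorySpec(
        n_frames=4,
        ligands=(LigandSpec(label="L1", nominal_distance=2.0),),
        shell_schedule={"L1": ("first",) * 4},
        hbond_schedule={"P": (True,) * 4},
        noise_sd=0.2,
        seed=1,
    )
    with pytest.raises(ValueError, match="noise_sd"):
        gen_site_trajectory(spec)


def test_groundtruth_validates_fractions():
    with pytest.raises(ValueError):
        GroundTruth(
            first_occupancy={"L1": 1.5},
            total_occupancy={"L1": 1.0},
            protein_first_counts=np.zeros(1, dtype=int),
            protein_second_counts=np.zeros(1, dtype=int),
            water_first_counts=np.zeros(1, dtype=int),
            water_second_counts=np.zeros(1, dtype=int),
            chi_labels=None,
            hbond_occupancy={},
        )
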