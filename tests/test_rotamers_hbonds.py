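import numpy as np
import pytest

from ionbind.synthetic import CHI_ATOM_IDS, LigandSpec, SiteTrajectorySpec, gen_site_trajectory, hbond_atom_ids
from ionbind.traj import (
    AnalysisParams,
    Atom,
    Trajectory,
    TrajectoryError,
    classify_chi1,
    classify_rotamer,
    dihedral_angles,
    hbond_frame_mask,
    hbond_occupancy,
)
from ionbind.traj.hbonds import HBondPair


# ---------------------------------------------------------------- rotamers

def test_classify_bins():
    assert classify_chi1(np.array([178.0]))[0] == "trans"
    assert classify_chi1(np.array([-150.0]))[0] == "trans"
    assert classify_chi1(np.array([87.0]))[0] == "g+"   # reported g+ geometry
    assert classify_chi1(np.array([60.0]))[0] == "g+"
    assert classify_chi1(np.array([-60.0]))[0] == "g-"
    assert classify_chi1(np.array([-119.0]))[0] == "g-"


def test_dihedral_sign_convention():
    # canonical +60 deg test quadruple (right-handed/IUPAC convention)
    p0 = np.array([[1.0, 1.0, 0.0]])
    p1 = np.array([[0.0, 0.0, 0.0]])
    p2 = np.array([[1.0, 0.0, 0.0]])  # axis along +x from p1
    c, s = np.cos(np.radians(60)), np.sin(np.radians(60))
    p3 = p2 + np.array([[0.0, c, s]])
    ang, defined = dihedral_angles(p0, p1, p2, p3)
    assert defined[0]
    assert ang[0] == pytest.approx(-60.0, abs=1e-9) or ang[0] == pytest.approx(60.0, abs=1e-9)
    # verify against an independent oracle (MDAnalysis)
    from MDAnalysis.lib.distances import calc_dihedrals

    oracle = np.degrees(
        calc_dihedrals(p0.astype(np.float64), p1.astype(np.float64),
                       p2.astype(np.float64), p3.astype(np.float64))
    )
    assert ang[0] == pytest.approx(float(oracle[0]), abs=1e-6)


def test_dihedral_matches_mdanalysis_random():
    from MDAnalysis.lib.distances import calc_dihedrals

    rng = np.random.default_rng(8)
    p = rng.uniform(-5, 5, size=(4, 200, 3))
    ang, defined = dihedral_angles(p[0], p[1], p[2], p[3])
    oracle = np.degrees(calc_dihedrals(p[0], p[1], p[2], p[3]))
    assert defined.all()
    # both wrapped to (-180, 180]; the oracle works in single precision
    diff = np.abs(((ang - oracle) + 180) % 360 - 180)
    assert np.max(diff) < 1e-3


def test_colinear_flagged_not_dropped():
    atoms = tuple(Atom(id=f"A{i}", name="X", role="other") for i in range(4))
    coords = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                       [[1, 1, 0], [0, 0, 0], [1, 0, 0], [1.5, 1, 1]]], dtype=float)
    traj = Trajectory(atoms=atoms, coords=coords, times=np.array([0.0, 1.0]))
    series = classify_rotamer(traj, [f"A{i}" for i in range(4)])
    assert not series.defined[0]
    assert np.isnan(series.chi1[0])
    assert series.labels[0] == ""
    assert series.defined[1]
    assert len(series.chi1) == 2


def test_histogram_fractions_planted():
    spec = SiteTrajectorySpec(
        n_frames=10,
        ligands=(LigandSpec(label="L1"),),
        shell_schedule={"L1": ("first",) * 10},
        chi_schedule=("trans",) * 7 + ("g-",) * 3,
        seed=2,
    )
    traj, _ = gen_site_trajectory(spec)
    series = classify_rotamer(traj, CHI_ATOM_IDS)
    frac = series.fractions()
    assert frac == {"trans": 0.7, "g+": 0.0, "g-": 0.3}
    assert sum(frac.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------- H-bonds

def hb_traj(da_dist, angle_dev_deg, n_frames=1, times=None):
    """Donor at origin, hydrogen at +x, acceptor placed for given D-A distance
    and deviation from linearity at H."""
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    # acceptor direction from H making (180 - dev) with H->D
    dev = np.radians(angle_dev_deg)
    direction = np.array([np.cos(dev), np.sin(dev), 0.0])
    # choose length so that |D-A| = da_dist
    lo, hi = 0.0, 20.0
    for _ in range(80):
        mid = (lo + hi) / 2
        a = h + mid * direction
        if np.linalg.norm(a - d) < da_dist:
            lo = mid
        else:
            hi = mid
    a = h + ((lo + hi) / 2) * direction
    frame = np.stack([d, h, a])
    coords = np.tile(frame, (n_frames, 1, 1))
    atoms = (
        Atom(id="D", name="N", role="donor"),
        Atom(id="H", name="H", role="hydrogen"),
        Atom(id="A", name="O", role="acceptor"),
    )
    t = np.arange(n_frames, dtype=float) if times is None else np.asarray(times, dtype=float)
    return Trajectory(atoms=atoms, coords=coords, times=t)


def test_hbond_present(params):
    traj = hb_traj(3.4, 10.0)
    assert hbond_frame_mask(traj, HBondPair("D", "H", "A"), params)[0]


def test_hbond_distance_fails(params):
    traj = hb_traj(3.6, 0.0)
    assert not hbond_frame_mask(traj, HBondPair("D", "H", "A"), params)[0]


def test_hbond_angle_fails(params):
    traj = hb_traj(3.0, 35.0)
    assert not hbond_frame_mask(traj, HBondPair("D", "H", "A"), params)[0]


def test_pair_without_hydrogen_rejected():
    traj = hb_traj(3.0, 0.0)
    with pytest.raises(TrajectoryError, match="hydrogen"):
        hbond_occupancy([traj], [("D", "A")])


def make_replica(chi_states, hbond_series, replica, seed=0):
    spec = SiteTrajectorySpec(
        n_frames=len(chi_states),
        ligands=(LigandSpec(label="L1"),),
        shell_schedule={"L1": ("first",) * len(chi_states)},
        chi_schedule=tuple(chi_states),
        hbond_schedule={"X": tuple(hbond_series)},
        seed=seed,
    )
    traj, _ = gen_site_trajectory(spec)
    return traj.with_replica(replica)


def test_early_outward_replica_excluded(params):
    n = 100  # frame_interval 1 ns -> times 0..99 ns
    good = make_replica(["trans"] * n, [True] * n, "good", seed=1)
    bad = make_replica(["trans"] * 40 + ["g-"] * 60, [True] * n, "bad", seed=2)
    chi = [classify_rotamer(t, CHI_ATOM_IDS) for t in (good, bad)]
    table = hbond_occupancy([good, bad], [hbond_atom_ids("X")], params, filter_on=chi)
    assert table.excluded_replicas == ("bad",)  # outward switch at 40 ns < 50 ns
    assert list(table.per_replica.index.get_level_values("replica")) == ["good"]


def test_late_outward_frames_dropped_from_denominator(params):
    n = 100
    # outward from 80 ns on; H-bond true on every inward frame
    states = ["trans"] * 80 + ["g-"] * 20
    series = [True] * 80 + [False] * 20
    traj = make_replica(states, series, "r0", seed=3)
    chi = [classify_rotamer(traj, CHI_ATOM_IDS)]
    table = hbond_occupancy([traj], [hbond_atom_ids("X")], params, filter_on=chi)
    assert table.excluded_replicas == ()
    row = table.per_replica.loc[("r0", "D_X->A_X")]
    assert row["n_retained"] == 80
    assert row["occupancy_pct"] == pytest.approx(100.0)


def test_gplus_counts_as_inward(params):
    n = 60
    states = ["trans"] * 30 + ["g+"] * 30
    traj = make_replica(states, [True] * n, "r0", seed=4)
    chi = [classify_rotamer(traj, CHI_ATOM_IDS)]
    table = hbond_occupancy([traj], [hbond_atom_ids("X")], params, filter_on=chi)
    assert table.per_replica.loc[("r0", "D_X->A_X"), "n_retained"] == 60


def test_occupancy_permutation_invariant(params):
    rng = np.random.default_rng(5)
    series = list(rng.random(40) < 0.6)
    t1 = make_replica(["trans"] * 40, series, "a", seed=6)
    perm = list(rng.permutation(40))
    t2 = make_replica(["trans"] * 40, [series[i] for i in perm], "a", seed=6)
    o1 = hbond_occupancy([t1], [hbond_atom_ids("X")], params).pooled["mean_pct"]
    o2 = hbond_occupancy([t2], [hbond_atom_ids("X")], params).pooled["mean_pct"]
    assert np.allclose(o1.to_numpy(), o2.to_numpy())
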