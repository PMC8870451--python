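import numpy as np
import pytest

from ionbind.constants import coulomb_kt
from ionbind.pb import (
    ChargeSystem,
    PBParams,
    SystemMismatchError,
    aggregate_binding,
    binding_energy,
    merge_systems,
    plan_geometry,
    solvation_energy,
)
from ionbind.synthetic import gen_charge_system


def test_eq3_on_fabricated_energies():
    # dG = E(complex) - E(receptor) - E(ion) -> 10 - 6 - 1 = 3
    assert 10.0 - 6.0 - 1.0 == pytest.approx(3.0)
    # and the solver path reproduces the identity on a real system:
    params = PBParams(grid_points=33, scale=1.0)
    receptor = ChargeSystem.from_arrays([[-2.0, 0, 0]], [-1.0], [1.8])
    ion = ChargeSystem.from_arrays([[2.0, 0, 0]], [1.0], [1.2])
    complex_ = merge_systems(receptor, ion)
    from ionbind.pb import build_grids, grid_energy, solve_lpb

    geom = plan_geometry(complex_, params)
    energies = {}
    for key, system in (("c", complex_), ("r", receptor), ("i", ion)):
        grid = build_grids(system, params, geometry=geom)
        energies[key] = grid_energy(solve_lpb(grid), grid)
    dg = binding_energy(complex_, receptor, ion, params, geometry=geom)
    assert dg == pytest.approx(energies["c"] - energies["r"] - energies["i"], abs=1e-10)


def test_mismatch_rejected():
    params = PBParams(grid_points=25, scale=1.0)
    receptor = ChargeSystem.from_arrays([[-2.0, 0, 0]], [-1.0], [1.8])
    ion = ChargeSystem.from_arrays([[2.0, 0, 0]], [1.0], [1.2])
    shifted_ion = ChargeSystem.from_arrays([[2.1, 0, 0]], [1.0], [1.2])
    complex_ = merge_systems(receptor, ion)
    with pytest.raises(SystemMismatchError):
        binding_energy(complex_, receptor, shifted_ion, params)
    with pytest.raises(SystemMismatchError):
        binding_energy(complex_, receptor, merge_systems(ion, ion), params)


def test_far_separated_neutral_receptor_dg_zero():
    # dipolar (net-neutral) receptor and an ion 50 A away in salt water:
    # the interaction is screened to ~0 (within 0.1 kT)
    params = PBParams(eps_in=8.0, eps_out=80.0, ionic_strength=0.15,
                      scale=0.8, grid_points=65)
    receptor = ChargeSystem.from_arrays(
        [[-26.0, 1.0, 0.0], [-26.0, -1.0, 0.0]], [0.5, -0.5], [1.8, 1.8]
    )
    ion = ChargeSystem.from_arrays([[26.0, 0.0, 0.0]], [1.0], [1.2])
    complex_ = merge_systems(receptor, ion)
    dg = binding_energy(complex_, receptor, ion, params)
    assert abs(dg) < 0.1


def test_attractive_pocket_negative_dg():
    params = PBParams(eps_in=8.0, eps_out=80.0, ionic_strength=0.15,
                      scale=1.2, grid_points=49)
    receptor = ChargeSystem.from_arrays([[-1.5, 0, 0]], [-1.0], [2.0])
    ion = ChargeSystem.from_arrays([[1.5, 0, 0]], [1.0], [1.4])
    complex_ = merge_systems(receptor, ion)
    dg_coarse = binding_energy(complex_, receptor, ion, params)
    assert dg_coarse < 0.0
    # second resolution as an independent check of the sign
    params_fine = PBParams(eps_in=8.0, eps_out=80.0, ionic_strength=0.15,
                           scale=1.8, grid_points=73)
    dg_fine = binding_energy(complex_, receptor, ion, params_fine)
    assert dg_fine < 0.0


def test_translation_invariance():
    params = PBParams(grid_points=41, scale=1.0, tolerance=1e-8)
    receptor = ChargeSystem.from_arrays([[-1.5, 0, 0]], [-1.0], [2.0])
    ion = ChargeSystem.from_arrays([[1.5, 0, 0]], [1.0], [1.4])
    complex_ = merge_systems(receptor, ion)
    dg = binding_energy(complex_, receptor, ion, params)
    shift = [1.0 / 3.0, -2.0 / 7.0, 0.123]  # deliberately off-lattice
    dg_shifted = binding_energy(
        complex_.translated(shift), receptor.translated(shift), ion.translated(shift), params
    )
    # grid translates with the solute (geometry is centroid-anchored)
    assert dg_shifted == pytest.approx(dg, abs=0.02 * abs(dg) + 1e-4)


def test_occupancy_warning():
    params = PBParams(grid_points=18, scale=1.0)
    receptor = ChargeSystem.from_arrays([[-4.0, 0, 0]], [-1.0], [2.0])
    ion = ChargeSystem.from_arrays([[4.0, 0, 0]], [1.0], [2.0])
    complex_ = merge_systems(receptor, ion)
    with pytest.warns(UserWarning, match="occup"):
        binding_energy(complex_, receptor, ion, params)


# ---------------------------------------------------------------- born oracle

def test_born_solvation_close_form():
    syn = gen_charge_system("born", q=1.0, radius=2.0, eps_in=2.0, eps_out=80.0)
    C = coulomb_kt()
    assert syn.reference_energy == pytest.approx(-(C / 4.0) * (0.5 - 1.0 / 80.0))
    params = PBParams(eps_in=2.0, eps_out=80.0, ionic_strength=0.0,
                      scale=1.8, grid_points=73, dielectric_model="sharp")
    e = solvation_energy(syn.system, params)
    assert e == pytest.approx(syn.reference_energy, rel=0.05)


def test_born_grid_refinement_monotone():
    syn = gen_charge_system("born", q=1.0, radius=2.0, eps_in=2.0, eps_out=80.0)
    errors = []
    for scale, n in ((1.0, 41), (1.8, 73), (2.6, 105)):
        params = PBParams(eps_in=2.0, eps_out=80.0, ionic_strength=0.0,
                          scale=scale, grid_points=n, dielectric_model="sharp")
        e = solvation_energy(syn.system, params)
        errors.append(abs(e - syn.reference_energy))
    assert errors[0] >= errors[1] >= errors[2]


# ---------------------------------------------------------------- aggregation

def test_aggregate_identical_snapshots():
    report = aggregate_binding([[-3.0] * 5, [-3.0] * 5])
    assert report.median == -3.0
    assert report.q3 - report.q1 == 0.0
    assert report.minimum == report.maximum == -3.0


def test_aggregate_perfect_line_r2_one():
    coords = [1.0, 2.0, 3.0, 4.0]
    energies = [[-1.0 - 0.5 * c] for c in coords]
    report = aggregate_binding(energies, coordination_means=coords)
    assert report.r_squared == pytest.approx(1.0)
    assert report.slope == pytest.approx(-0.5)


def test_aggregate_r2_matches_normal_equations():
    rng = np.random.default_rng(3)
    coords = rng.uniform(1, 4, size=6)
    means = -1.0 - 0.7 * coords + rng.normal(0, 0.2, size=6)
    report = aggregate_binding([[m] for m in means], coordination_means=list(coords))
    # independent closed-form: R^2 = cov^2/(var_x var_y)
    x, y = coords, means
    r2 = float(np.cov(x, y, bias=True)[0, 1] ** 2 / (np.var(x) * np.var(y)))
    assert report.r_squared == pytest.approx(r2, abs=1e-10)


def test_aggregate_single_trajectory_no_r2():
    report = aggregate_binding([[-2.0, -3.0]], coordination_means=[2.5])
    assert report.r_squared is None


def test_aggregate_empty_rejected():
    with pytest.raises(ValueError):
        aggregate_binding([])
    with pytest.raises(ValueError):
        aggregate_binding([[-1.0], []])


def test_aggregate_occupancy_warning():
    with pytest.warns(UserWarning, match="occupancy"):
        aggregate_binding([[-1.0]], grid_occupancies=[0.85])


# ---------------------------------------------------------------- synthetic

def test_point_zero_charge_reference_zero():
    syn = gen_charge_system("point", q=0.0)
    pts = np.array([[1.0, 2.0, 3.0], [0.1, 0.0, 0.0]])
    assert np.all(syn.reference_potential(pts) == 0.0)


def test_two_body_reference_coulomb():
    syn = gen_charge_system("two_body", q=1.0, q2=-1.0, separation=5.0, eps_out=80.0)
    C = coulomb_kt()
    assert syn.reference_energy == pytest.approx(-C / (80.0 * 5.0))


def test_unknown_kind_rejected():
    with pytest.raises(ValueError, match="unknown"):
        gen_charge_system("multipole")


def test_dipole_reference_potential():
    syn = gen_charge_system("dipole", q=1.0, separation=4.0, eps_out=80.0)
    C = coulomb_kt()
    pt = np.array([[0.0, 3.0, 0.0]])  # equidistant: potential 0
    assert syn.reference_potential(pt)[0] == pytest.approx(0.0, abs=1e-12)
    pt2 = np.array([[10.0, 0.0, 0.0]])
    want = C / 80.0 * (1.0 / 12.0 - 1.0 / 8.0)
    assert syn.reference_potential(pt2)[0] == pytest.approx(want)
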