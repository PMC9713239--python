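"""Quasi-static equilibrium solver: oracles, symmetry, determinism."""

import numpy as np
import pytest

from kneeplan import knee_core as kc
from kneeplan.knee_core import (
    LAYOUT,
    FlexionSchedule,
    ImplantPose,
    SolverSettings,
    simulate_squat,
    solve_equilibrium,
    total_energy,
)


def _symmetric_subject():
    """Perfectly medio-laterally symmetric geometry and properties."""
    fem = []
    tib = []
    bundles = kc.BUNDLES
    base_f = dict(kc._BASE_FEM)
    base_t = dict(kc._BASE_TIB)
    # symmetrize: medial bundles mirror lateral counterparts
    pairs = {"deepMCL": "LCL", "supMCL": "PFL", "ACL0": "PCL0", "ACL1": "PCL1"}
    for b in bundles:
        f = np.array(base_f[b], float)
        t = np.array(base_t[b], float)
        fem.append(f)
        tib.append(t)
    fem = np.array(fem)
    tib = np.array(tib)
    # enforce exact mirror symmetry for the collateral pairs and center the rest
    for a, b in [("deepMCL", "LCL"), ("supMCL", "PFL")]:
        ia, ib = bundles.index(a), bundles.index(b)
        fem[ib] = fem[ia] * np.array([-1, 1, 1])
        tib[ib] = tib[ia] * np.array([-1, 1, 1])
    for a, b in [("ACL0", "PCL0"), ("ACL1", "PCL1")]:
        ia, ib = bundles.index(a), bundles.index(b)
        fem[ib] = fem[ia] * np.array([-1, 1, 1])
        tib[ib] = tib[ia] * np.array([-1, 1, 1])
    for b in ("ALL", "PC"):
        i = bundles.index(b)
        fem[i][0] = 0.0
        tib[i][0] = 0.0
    geometry = kc.KneeGeometry(
        fem_attach=fem, tib_attach=tib,
        condyle_centers=np.array([[-22.0, 0, 0], [22.0, 0, 0]]),
        condyle_radii=np.array([24.0, 24.0]),
        dish_centers=np.array([[-22.0, 0, 10.0], [22.0, 0, 10.0]]),
        dish_radii=np.array([34.0, 34.0]),
    )
    props = np.zeros(50)
    for b in bundles:
        props[LAYOUT.index(f"{b}.eps_r")] = 0.01
        props[LAYOUT.index(f"{b}.k")] = 4000.0
    # mirror-match the material parameters of paired bundles
    for a, b in [("deepMCL", "LCL"), ("supMCL", "PFL"), ("ACL0", "PCL0"),
                 ("ACL1", "PCL1")]:
        props[LAYOUT.index(f"{b}.eps_r")] = props[LAYOUT.index(f"{a}.eps_r")]
        props[LAYOUT.index(f"{b}.k")] = props[LAYOUT.index(f"{a}.k")]
    return geometry, props


class TestEquilibrium:
    def test_symmetric_knee_stays_centered(self):
        geometry, props = _symmetric_subject()
        for theta in (20.0, 70.0, 120.0):
            state = solve_equilibrium(geometry, props, None, theta)
            assert state.converged
            assert abs(state.dofs[0]) < 1e-3     # M/L
            assert abs(state.dofs[3]) < 1e-3     # V/V

    def test_slack_ligaments_rest_on_contact(self, subject):
        geometry, props = subject
        slack = props.copy()
        for b in kc.BUNDLES:
            # far below any engagement over the squat (outside the sampling
            # box on purpose: this probes the mechanics, not the prior)
            slack[LAYOUT.index(f"{b}.eps_r")] = -0.45
        state = solve_equilibrium(geometry, slack, None, 70.0)
        assert state.converged
        assert np.all(state.forces == 0.0)
        # contact + envelope rest: all DOFs essentially at the aligned origin
        assert np.all(np.abs(state.dofs) < 0.2)

    def test_two_dof_reduction_matches_grid_search(self, subject):
        geometry, props = subject
        state = solve_equilibrium(geometry, props, None, 70.0,
                                  free_dofs=("ap", "pd"))
        assert state.converged
        # exhaustive lattice over the free DOFs, 0.05 mm spacing
        ap = np.arange(state.dofs[1] - 1.0, state.dofs[1] + 1.0, 0.05)
        pd = np.arange(state.dofs[2] - 1.0, state.dofs[2] + 1.0, 0.05)
        best = (np.inf, None, None)
        for a in ap:
            dofs = np.zeros((len(pd), 5))
            dofs[:, 1] = a
            dofs[:, 2] = pd
            e = np.array([total_energy(geometry, props, None, 70.0, d[None, :])
                          for d in dofs])
            j = int(np.argmin(e))
            if e[j] < best[0]:
                best = (e[j], a, pd[j])
        assert abs(best[1] - state.dofs[1]) <= 0.05 + 1e-9
        assert abs(best[2] - state.dofs[2]) <= 0.05 + 1e-9

    def test_solution_is_local_minimum(self, subject):
        geometry, props = subject
        state = solve_equilibrium(geometry, props, None, 103.33)
        e0 = total_energy(geometry, props, None, 103.33, state.dofs[None, :])
        rng = np.random.default_rng(12)
        for _ in range(100):
            pert = state.dofs + rng.uniform(-0.5, 0.5, 5)
            assert total_energy(geometry, props, None, 103.33,
                                pert[None, :]) >= e0 - 1e-9

    def test_mirrored_problem_mirrors_dof_signs(self, subject):
        geometry, props = subject
        mirrored = geometry.mirrored()
        for theta in (20.0, 86.67):
            a = solve_equilibrium(geometry, props, None, theta)
            b = solve_equilibrium(mirrored, props, None, theta)
            flip = np.array([-1, 1, 1, -1, -1])
            assert np.allclose(b.dofs, flip * a.dofs, atol=1e-5)
            assert np.allclose(np.sort(b.strains), np.sort(a.strains), atol=1e-7)

    def test_zero_attachment_offsets_reproduce_nominal_strains(self, subject):
        geometry, props = subject
        state0 = solve_equilibrium(geometry, props, None, 70.0)
        perturbed = props.copy()
        i = LAYOUT.index("supMCL.fem_y")
        perturbed[i] = 3.0
        state1 = solve_equilibrium(geometry, perturbed, None, 70.0)
        assert not np.allclose(state1.strains, state0.strains)
        perturbed[i] = 0.0
        state2 = solve_equilibrium(geometry, perturbed, None, 70.0)
        assert np.array_equal(state2.strains, state0.strains)

    def test_tension_only_state_invariant(self, subject):
        geometry, props = subject
        state = solve_equilibrium(geometry, props, ImplantPose.zero(), 120.0,
                                  bundles=kc.RETAINED_BUNDLES)
        slack = state.strains <= 0
        assert np.all(state.forces[slack] == 0.0)
        assert np.all(np.isfinite(state.strains))


class TestSquat:
    def test_default_schedule_seven_angles(self, subject):
        geometry, props = subject
        states = simulate_squat(geometry, props, None)
        assert len(states) == 7
        assert states[0].theta == 20.0
        assert states[-1].theta == 120.0

    def test_schedule_spacing(self):
        angles = FlexionSchedule().angles
        assert np.allclose(np.diff(angles), 100.0 / 6.0)
        assert np.diff(angles)[0] == pytest.approx(16.667, abs=1e-3)

    def test_repeat_call_bitwise_identical(self, subject):
        geometry, props = subject
        a = simulate_squat(geometry, props, None)
        b = simulate_squat(geometry, props, None)
        for sa_, sb in zip(a, b):
            assert np.array_equal(sa_.strains, sb.strains)
            assert np.array_equal(sa_.dofs, sb.dofs)

    def test_failure_reports_the_angle(self, subject):
        geometry, props = subject
        starved = SolverSettings(max_iter=1)
        with pytest.raises(RuntimeError, match="20.0"):
            simulate_squat(geometry, props, None, settings=starved)

    def test_schedule_must_increase(self):
        with pytest.raises(ValueError):
            FlexionSchedule(np.array([20.0, 20.0, 40.0]))
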