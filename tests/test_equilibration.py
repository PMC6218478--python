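"""Relaxation to equilibrium and quasistatic tension ramps."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from epifold.builder import build_hex_tissue
from epifold.equilibration import RampProtocol, RelaxationError, relax, run_ramp
from epifold.mechanics import MechanicalParams, total_energy


class TestRelax:
    def test_perturbed_flat_tissue_returns_to_flat(self, small_tissue):
        mesh, params = small_tissue
        W0 = total_energy(mesh, params)
        rng = np.random.default_rng(11)
        pert = mesh.with_positions(
            mesh.positions + rng.uniform(-0.01, 0.01, mesh.positions.shape)
        )
        out, rep = relax(pert, params, tol=1e-7)
        z_apical = out.positions[: out.n_apical, 2]
        assert z_apical.max() - z_apical.min() < 1e-5
        assert rep.energy == pytest.approx(W0, abs=1e-8)

    def test_single_cell_height_matches_1d_oracle(self):
        """Free hexagonal prism with symmetric apical/basal tensions (so the
        relaxed shape stays in the prism family): the 3D relaxation height
        equals a brute-force 1D minimization of W(h) with A = V0/h."""
        from conftest import hexagonal_prism_mesh

        p = MechanicalParams(T_a=1, T_b=1, T_l=2.5, Lambda_a=1, Lambda_b=1, k=0, K_V=2e4)
        mesh = hexagonal_prism_mesh(side=0.35, height=3.0)
        mesh.cells[0].target_volume = 1.5 * np.sqrt(3) * 0.35**2 * 3.0
        V0 = mesh.cells[0].target_volume
        out, _ = relax(mesh, p, tol=1e-7)
        h_relaxed = out.positions[:6, 2].mean() - out.positions[6:, 2].mean()

        def W_of_h(h):
            A = V0 / h  # exact volume; regular hexagon side from area
            s = np.sqrt(A / (1.5 * np.sqrt(3)))
            return (p.T_a + p.T_b) * A + 6 * s * (p.Lambda_a + p.Lambda_b) + p.T_l * 6 * s * h

        res = minimize_scalar(W_of_h, bounds=(0.5, 10.0), method="bounded")
        assert h_relaxed == pytest.approx(res.x, rel=1e-3)

    def test_looser_tolerance_returns_no_lower_energy(self, small_tissue):
        mesh, params = small_tissue
        rng = np.random.default_rng(7)
        pert = mesh.with_positions(
            mesh.positions + 0.02 * rng.standard_normal(mesh.positions.shape)
        )
        _, tight = relax(pert, params, tol=1e-7)
        _, loose = relax(pert, params, tol=1e-5)
        assert loose.energy >= tight.energy - 1e-10

    def test_nonconvergence_raises_with_diagnostics(self, small_tissue):
        mesh, params = small_tissue
        rng = np.random.default_rng(1)
        pert = mesh.with_positions(
            mesh.positions + 0.05 * rng.standard_normal(mesh.positions.shape)
        )
        with pytest.raises(RelaxationError) as err:
            relax(pert, params, tol=1e-13, max_iter=3, n_restarts=1)
        assert err.value.max_force > 0


class TestRampProtocol:
    def test_grid_must_be_monotone(self):
        with pytest.raises(ValueError, match="monotone"):
            RampProtocol("basal_decrease", [-0.1, -0.3, -0.2])

    def test_basal_decrease_requires_negative_delta(self):
        with pytest.raises(ValueError):
            RampProtocol("basal_decrease", [0.1])

    def test_scaling_applies_to_stripe_only(self, small_tissue):
        mesh, params = small_tissue
        proto = RampProtocol("basal_decrease", [-0.5])
        p = proto.apply(params, -0.5)
        arrays = p.cell_arrays(mesh)
        pre = mesh.region_cells("pre_fold")
        neigh = mesh.region_cells("neighbor")
        assert np.allclose(arrays["T_b"][pre], 0.5 * params.T_b)
        assert np.allclose(arrays["T_b"][neigh], params.T_b)
        assert np.allclose(arrays["Lambda_b"][pre], 0.5 * params.Lambda_b)


class TestRunRamp:
    def test_noop_ramp_returns_input_state(self, small_tissue):
        mesh, params = small_tissue
        steps = run_ramp(mesh, params, RampProtocol("basal_decrease", [0.0]))
        assert np.array_equal(steps[0].mesh.positions, mesh.positions)

    def test_basal_decrease_forms_monotone_fold(self, small_tissue):
        """Apical indentation and basal length grow monotonically along the
        quasistatic branch; the fold is wedge-shaped (l_b > l_a)."""
        mesh, params = small_tissue
        proto = RampProtocol.default("basal_decrease", n_steps=8, magnitude=0.6)
        steps = run_ramp(mesh, params, proto, keep_meshes=False)
        d_a = np.array([s.geometry.d_a for s in steps])
        l_b = np.array([s.geometry.l_b for s in steps])
        assert np.all(np.diff(d_a) > -1e-8)
        assert np.all(np.diff(l_b) > -1e-8)
        assert d_a[-1] > 0.3
        g = steps[-1].geometry
        assert g.l_b > g.l_a
        assert all(s.max_volume_violation < 1e-3 for s in steps)

    def test_updown_ramp_is_reversible(self, small_tissue):
        """Quasistatic reversibility at small magnitude: ramping down and
        back up returns the initial equilibrium energy."""
        mesh, params = small_tissue
        W0 = total_energy(mesh, params)
        down = RampProtocol("basal_decrease", np.linspace(-0.02, -0.1, 5))
        steps = run_ramp(mesh, params, down)
        up = RampProtocol("basal_decrease", np.linspace(-0.08, 0.0, 5))
        steps = run_ramp(steps[-1].mesh, params, up, keep_meshes=False)
        assert steps[-1].energy == pytest.approx(W0, abs=1e-6)


class TestFreeParameterSensitivity:
    @pytest.mark.parametrize("lambda_hat,k_hat", [(0.5, 1.0), (2.0, 1.0), (1.0, 0.5), (1.0, 2.0)])
    def test_folding_is_robust_to_free_parameters(self, lambda_hat, k_hat):
        """Varying the two normalized free parameters within a factor of two
        still produces a clear basal-decrease fold."""
        from epifold.builder import assign_stripe

        p = MechanicalParams.from_normalized(lambda_hat=lambda_hat, k_hat=k_hat)
        mesh, params = build_hex_tissue(6, 6, params=p)
        assign_stripe(mesh, 2)
        proto = RampProtocol.default("basal_decrease", n_steps=5, magnitude=0.5)
        steps = run_ramp(mesh, params, proto, keep_meshes=False)
        assert steps[-1].geometry.d_a > 0.1
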