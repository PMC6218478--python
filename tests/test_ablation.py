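"""In-silico ablation, overdamped recoil, and the v0 estimator."""

import numpy as np
import pytest

from epifold.ablation import (
    ablate_element,
    central_edge,
    element_length,
    recoil_velocity,
    simulate_recoil,
)
from epifold.mechanics import energy_and_forces, forces
from epifold.synthetic import gen_recoil_track


class TestAblateElement:
    def test_sets_single_element_tension_to_zero(self, small_tissue):
        mesh, params = small_tissue
        e = central_edge(mesh, "basal")
        p = ablate_element(mesh, params, e, "basal_edge")
        assert p.edge_overrides[("basal", e)] == 0.0
        assert not params.edge_overrides  # original untouched

    def test_unknown_element_rejected(self, small_tissue):
        mesh, params = small_tissue
        with pytest.raises(KeyError):
            ablate_element(mesh, params, 10_000, "apical_edge")
        with pytest.raises(ValueError):
            ablate_element(mesh, params, 0, "bogus")

    def test_zero_tension_edge_gives_zero_released_force(self, small_tissue):
        mesh, params = small_tissue
        p0 = params.copy()
        p0.Lambda_a = 0.0
        # re-relax not needed for the force comparison: the override equals
        # the already-zero shared tension, so forces are identical
        e = central_edge(mesh, "apical")
        p1 = ablate_element(mesh, p0, e, "apical_edge")
        assert np.allclose(forces(mesh, p0), forces(mesh, p1))

    def test_basal_release_stronger_than_apical(self, small_tissue):
        """In the 4x basal:apical tissue, ablating a basal edge releases a
        larger net force on its endpoints than the matched apical edge."""
        mesh, params = small_tissue
        e = central_edge(mesh, "apical")

        def released(kind, edges):
            p = ablate_element(mesh, params, e, kind)
            F = forces(mesh, p)
            i, j = edges[e]
            return np.linalg.norm(F[i]) + np.linalg.norm(F[j])

        assert released("basal_edge", mesh.basal_edges) > 2.5 * released(
            "apical_edge", mesh.apical_edges
        )

    def test_lateral_ablation_leaves_volumes_unchanged(self, small_tissue):
        mesh, params = small_tissue
        p = ablate_element(mesh, params, 0, "lateral_face")
        _, _, _, V0 = energy_and_forces(mesh, params, breakdown=True)
        _, _, _, V1 = energy_and_forces(mesh, p, breakdown=True)
        assert np.array_equal(V0, V1)


class TestSimulateRecoil:
    def test_no_ablation_means_no_recoil(self, small_tissue):
        mesh, params = small_tissue
        e = central_edge(mesh, "apical")
        track = simulate_recoil(mesh, params, e, "apical_edge", n_frames=2,
                                frame_window=1e-3)
        s = track.separation
        assert abs(s[-1] - s[0]) < 1e-8
        assert recoil_velocity(track) == pytest.approx(0.0, abs=1e-6)

    def test_dt_refinement_converges(self, small_tissue):
        mesh, params = small_tissue
        e = central_edge(mesh, "apical")
        p = ablate_element(mesh, params, e, "basal_edge")
        seps = []
        for dt in (2e-5, 1e-5):
            tr = simulate_recoil(mesh, p, e, "basal_edge", dt=dt, n_frames=1,
                                 frame_window=2e-3)
            seps.append(tr.separation[1] - tr.separation[0])
        assert abs(seps[1] - seps[0]) / abs(seps[1]) < 0.01

    def test_symmetric_tensions_give_symmetric_recoil(self):
        from epifold.builder import build_hex_tissue
        from epifold.mechanics import MechanicalParams

        p1 = MechanicalParams.from_normalized(basal_apical_ratio=1.0)
        mesh, params = build_hex_tissue(4, 4, params=p1)
        e = central_edge(mesh, "apical")
        v0 = {}
        for kind in ("apical_edge", "basal_edge"):
            p = ablate_element(mesh, params, e, kind)
            tr = simulate_recoil(mesh, p, e, kind, n_frames=1, frame_window=1e-3)
            v0[kind] = recoil_velocity(tr)
        assert v0["basal_edge"] == pytest.approx(v0["apical_edge"], rel=0.05)

    def test_v0_scales_with_released_tension(self, small_tissue):
        """Recoil velocity is approximately proportional to the ablated
        edge's pre-ablation tension (the premise of recoil velocimetry)."""
        mesh, params = small_tissue
        e = central_edge(mesh, "apical")
        window = 5e-4
        v0s = []
        lams = (0.5, 1.0, 2.0)
        for lam in lams:
            p = params.copy()
            p.Lambda_a = lam
            from epifold.equilibration import relax

            m_eq, _ = relax(mesh, p)
            pa = ablate_element(m_eq, p, e, "apical_edge")
            tr = simulate_recoil(m_eq, pa, e, "apical_edge", n_frames=1,
                                 frame_window=window)
            v0s.append(recoil_velocity(tr))
        ratios = np.array(v0s) / v0s[1]
        assert ratios == pytest.approx(np.array(lams) / lams[1], rel=0.25)

    def test_lateral_face_recoil_tracks_apicobasal_extent(self, small_tissue):
        mesh, params = small_tissue
        p = ablate_element(mesh, params, 3, "lateral_face")
        tr = simulate_recoil(mesh, p, 3, "lateral_face", n_frames=2,
                             frame_window=2e-3)
        # tracked points start at the apical and basal edge midpoints
        quad = mesh.lateral_faces[3]
        mid_ap = mesh.positions[quad[:2]].mean(axis=0)
        assert tr.pos1[0] == pytest.approx(mid_ap, abs=1e-9)
        assert tr.separation[0] == pytest.approx(
            element_length(mesh, 3, "lateral_face"), rel=1e-9
        )


class TestRecoilVelocity:
    def test_first_frame_formula(self):
        track = gen_recoil_track(v_true=0.0, window=0.25, n_frames=2)
        track.pos2[:, 0] = track.pos1[:, 0] + np.array([10.0, 10.5, 11.0])
        assert recoil_velocity(track, window=0.25) == pytest.approx(2.0)

    def test_generator_identity_noise_free(self):
        for v in (0.0, 1.3, 4.0):
            track = gen_recoil_track(v_true=v, window=0.25)
            assert recoil_velocity(track) == pytest.approx(v, abs=1e-12)

    def test_lateral_sampling_window(self):
        track = gen_recoil_track(v_true=2.0, window=1.0)
        assert recoil_velocity(track, window=1.0) == pytest.approx(2.0)

    def test_missing_preablation_sample_rejected(self):
        track = gen_recoil_track(v_true=1.0)
        track.t_ablation = -1.0  # every sample is now post-ablation
        with pytest.raises(ValueError, match="pre-ablation"):
            recoil_velocity(track)
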