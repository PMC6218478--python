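"""Fold-shape readout from cross sections and intensity ratios."""

import numpy as np
import pytest

from epifold.quantify import (
    CrossSection,
    extract_cross_section,
    intensity_ratio,
    measure_fold_geometry,
)
from epifold.synthetic import gen_intensity_table, gen_wedge_cross_section


class TestExtractCrossSection:
    def test_flat_tissue_outlines_are_parallel_planes(self, small_tissue):
        mesh, _ = small_tissue
        from epifold.equilibration import _default_section_offset

        sec = extract_cross_section(mesh, offset=_default_section_offset(mesh))
        h = mesh.positions[: mesh.n_apical, 2].mean() - mesh.positions[mesh.n_apical :, 2].mean()
        assert np.ptp(sec.apical_outline[:, 1]) < 1e-9
        assert np.ptp(sec.basal_outline[:, 1]) < 1e-9
        assert sec.apical_outline[0, 1] - sec.basal_outline[0, 1] == pytest.approx(h, rel=1e-9)

    def test_one_cell_per_row_in_section(self, small_tissue):
        mesh, _ = small_tissue
        from epifold.equilibration import _default_section_offset

        sec = extract_cross_section(mesh, offset=_default_section_offset(mesh))
        assert len(sec.cells) == 6
        assert len(sec.group("fold_center")) == 2

    def test_unsupported_axis_rejected(self, small_tissue):
        mesh, _ = small_tissue
        with pytest.raises(ValueError, match="only sections"):
            extract_cross_section(mesh, axis="z", offset=0.0)

    def test_parallel_offsets_agree_for_uniform_stripe(self, small_tissue):
        """The fold is translation-invariant along the stripe, so two
        parallel section planes give identical geometry."""
        mesh, params = small_tissue
        from epifold.equilibration import RampProtocol, run_ramp

        steps = run_ramp(mesh, params, RampProtocol("basal_decrease", [-0.3]))
        deformed = steps[-1].mesh
        from epifold.equilibration import _default_section_offset

        off = _default_section_offset(mesh)
        dx = mesh.box[0] / mesh.meta["nx"]
        g1 = measure_fold_geometry(extract_cross_section(deformed, offset=off))
        g2 = measure_fold_geometry(extract_cross_section(deformed, offset=off + dx))
        for k, v in g1.as_dict().items():
            assert v == pytest.approx(g2.as_dict()[k], abs=1e-6)


class TestMeasureFoldGeometry:
    def test_flat_section_reads_zero_deformation(self):
        sec = gen_wedge_cross_section(0.0, 0.0, 0.7, 0.7, 1.0)
        g = measure_fold_geometry(sec)
        assert g.d_a == pytest.approx(0.0, abs=1e-12)
        assert g.d_b == pytest.approx(0.0, abs=1e-12)
        assert g.l_a == pytest.approx(0.7)
        assert g.l_b == pytest.approx(0.7)
        assert g.h_tissue == pytest.approx(1.0)
        assert g.l_a_norm == pytest.approx(0.7)

    def test_wedge_fixture_roundtrip_exact(self):
        g = measure_fold_geometry(gen_wedge_cross_section(0.4, 0.1, 1.0, 1.8, 1.0))
        assert (g.d_a, g.d_b, g.l_a, g.l_b, g.h_tissue) == pytest.approx(
            (0.4, 0.1, 1.0, 1.8, 1.0), rel=1e-12
        )

    def test_negative_basal_deformation_sign(self):
        """A basal indentation (basal surface moving toward the apical side)
        reads as negative d_b."""
        g = measure_fold_geometry(gen_wedge_cross_section(0.3, -0.1, 1.0, 1.2, 1.0))
        assert g.d_b == pytest.approx(-0.1, rel=1e-12)

    def test_translation_and_reflection_invariance(self):
        sec = gen_wedge_cross_section(0.4, 0.1, 1.0, 1.8, 1.0)
        g0 = measure_fold_geometry(sec).as_dict()

        moved = gen_wedge_cross_section(0.4, 0.1, 1.0, 1.8, 1.0)
        for c in moved.cells:
            c.apical += np.array([3.7, 0.0])
            c.basal += np.array([3.7, 0.0])
        assert measure_fold_geometry(moved).as_dict() == pytest.approx(g0)

        mirrored = gen_wedge_cross_section(0.4, 0.1, 1.0, 1.8, 1.0)
        for c in mirrored.cells:
            c.apical[:, 0] *= -1
            c.basal[:, 0] *= -1
        assert measure_fold_geometry(mirrored).as_dict() == pytest.approx(g0)

    def test_normalization_is_bookkeeping_identity(self, small_tissue):
        mesh, params = small_tissue
        from epifold.equilibration import RampProtocol, run_ramp

        steps = run_ramp(mesh, params, RampProtocol("basal_decrease", [-0.2]),
                         keep_meshes=False)
        g = steps[-1].geometry
        assert g.d_a_norm == g.d_a / g.h_tissue
        assert g.l_b_norm == g.l_b / g.h_tissue

    def test_requires_fold_cells_and_neighbors(self):
        sec = gen_wedge_cross_section(0.2, 0.0, 1.0, 1.0, 1.0)
        no_fold = CrossSection(cells=[c for c in sec.cells if c.label != "fold_center"])
        with pytest.raises(ValueError, match="fold_center"):
            measure_fold_geometry(no_fold)
        one_sided = CrossSection(
            cells=[c for c in sec.cells if c.apical[:, 0].mean() > -1.2]
        )
        with pytest.raises(ValueError, match="each side"):
            measure_fold_geometry(one_sided)

    def test_impossible_wedge_rejected(self):
        with pytest.raises(ValueError, match="impossible|non-positive"):
            gen_wedge_cross_section(1.5, 0.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="too large"):
            gen_wedge_cross_section(0.9, 0.0, 0.2, 1.0, 1.0, n_fold_cells=2)


class TestIntensityRatio:
    def test_equal_intensities_give_unity(self):
        x = np.ones(10)
        labels = ["fold"] * 5 + ["neighbor"] * 5
        assert intensity_ratio(x, labels) == 1.0

    def test_known_contrast(self):
        x = np.array([0.8] * 4 + [1.0] * 6)
        labels = ["fold"] * 4 + ["neighbor"] * 6
        assert intensity_ratio(x, labels) == pytest.approx(0.8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            intensity_ratio(np.ones(3), ["fold"] * 3)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            intensity_ratio(np.array([-1.0, 1.0]), ["fold", "neighbor"])

    def test_generator_recovery_with_noise(self):
        """Contrast c with multiplicative noise: estimated ratio lies within
        the bootstrap CI of c."""
        ints, labels = gen_intensity_table(200, 200, contrast=0.8, noise_sd=0.1, seed=5)
        ratio, (lo, hi) = intensity_ratio(ints, labels, n_boot=500, seed=6)
        assert lo < 0.8 < hi
        assert ratio == pytest.approx(0.8, abs=0.05)
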