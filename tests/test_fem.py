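import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_plate, solve_plate
from cystfem.fem import (
    LoadCase,
    assemble_and_solve,
    build_model,
    summarize,
    von_mises,
)
from cystfem.geometry import CLASS_CODES, LabelImage
from cystfem.materials import MaterialTable, build_attribute_map

NU = 0.3
# von Mises of the plane-strain uniaxial state (0, -p, nu*(-p)):
# 0.5*[(p)^2 + (p-nu p)^2 + (nu p)^2] = p^2*(1 - nu + nu^2)  ->  factor
# sqrt(1 - 0.3 + 0.09) = sqrt(0.79) = 0.888819...
UNIAXIAL_PLANE_STRAIN_FACTOR = np.sqrt(1.0 - NU + NU**2)


class TestVonMises:
    def test_textbook_identities(self):
        assert von_mises(0.0, 0.0, 0.0, 0.0) == 0.0
        assert von_mises(5.0, 0.0, 0.0, 0.0) == pytest.approx(5.0)
        assert von_mises(0.0, 0.0, 2.0, 0.0) == pytest.approx(np.sqrt(3.0) * 2.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.tuples(*[st.floats(-1e3, 1e3) for _ in range(4)]))
    def test_nonnegative_and_shift_invariant(self, s):
        sx, sy, txy, sz = s
        vm = von_mises(sx, sy, txy, sz)
        assert vm >= 0.0
        # adding a hydrostatic state leaves the deviatoric measure unchanged
        c = 123.0
        assert von_mises(sx + c, sy + c, txy, sz + c) == pytest.approx(vm, abs=1e-6)


class TestPatchTest:
    @pytest.mark.parametrize("formulation", ["plane_strain", "plane_stress"])
    def test_uniaxial_constant_stress_recovered_exactly(self, materials, formulation):
        p = 0.248
        model, field = solve_plate(
            make_plate(20), materials, pressure=p, formulation=formulation
        )
        assert field.sigma[:, 1] == pytest.approx(-p, abs=1e-12)
        assert np.abs(field.sigma[:, 0]).max() < 1e-12
        assert np.abs(field.sigma[:, 2]).max() < 1e-12
        if formulation == "plane_strain":
            assert field.sigma_z == pytest.approx(-NU * p, abs=1e-12)
            assert field.vm == pytest.approx(UNIAXIAL_PLANE_STRAIN_FACTOR * p, abs=1e-12)
            assert field.vm == pytest.approx(0.889 * p, abs=1e-3 * p)
        else:
            assert (field.sigma_z == 0).all()
            assert field.vm == pytest.approx(p, abs=1e-12)

    def test_displacement_scales_with_compliance(self, materials):
        # same plate, soft vs stiff: displacements scale by E ratio
        _, hard = solve_plate(make_plate(10, "cortical"), materials)
        _, soft = solve_plate(make_plate(10, "ligament"), materials)
        ratio = 20_000.0 / 10.0
        assert soft.displacements == pytest.approx(hard.displacements * ratio, rel=1e-9)


class TestBuildModel:
    def test_structured_grid_counts(self, materials):
        img = make_plate(10)
        attrs = build_attribute_map(img, materials)
        model = build_model(img, attrs, LoadCase(70))
        assert model.n_elements == 100
        assert model.n_nodes == 121
        assert model.pressure == pytest.approx(0.248)

    def test_bottom_nodes_all_fixed(self, materials):
        img = make_plate(10)
        attrs = build_attribute_map(img, materials)
        model = build_model(img, attrs, LoadCase(70), bottom_bc="fixed")
        bottom = np.where(np.isclose(model.nodes[:, 1], model.nodes[:, 1].max()))[0]
        fixed = set(model.fixed_dofs.tolist())
        assert all({2 * n, 2 * n + 1} <= fixed for n in bottom)

    def test_consistent_load_equals_pressure_times_width(self, materials):
        img = make_plate(12, pixel_size=0.5)
        attrs = build_attribute_map(img, materials)
        p = 0.318
        model = build_model(img, attrs, LoadCase(pressure_override=p))
        total = model.forces.sum()
        assert total == pytest.approx(p * 12 * 0.5, rel=1e-12)

    def test_disconnected_load_path_rejected(self, materials):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[:4, :] = CLASS_CODES["cortical"]  # floating top slab
        labels[7:, :] = CLASS_CODES["cortical"]  # bottom slab, gap between
        img = LabelImage(labels)
        attrs = build_attribute_map(img, materials)
        with pytest.raises(ValueError, match="load path"):
            build_model(img, attrs, LoadCase(70))

    def test_only_load_path_component_is_meshed(self, materials):
        labels = np.zeros((10, 12), dtype=np.uint8)
        labels[:, 2:6] = CLASS_CODES["cortical"]  # spanning column
        labels[4:6, 9:11] = CLASS_CODES["cortical"]  # floating island
        img = LabelImage(labels)
        attrs = build_attribute_map(img, materials)
        model = build_model(img, attrs, LoadCase(70))
        assert model.n_elements == 40  # island excluded


class TestSolver:
    def test_load_linearity(self, materials):
        img = _inclusion_plate(16)
        attrs = build_attribute_map(img, materials)
        m1 = build_model(img, attrs, LoadCase(pressure_override=0.2))
        m2 = build_model(img, attrs, LoadCase(pressure_override=0.4))
        f1 = assemble_and_solve(m1)
        f2 = assemble_and_solve(m2)
        assert f2.sigma == pytest.approx(2.0 * f1.sigma, rel=1e-9, abs=1e-12)
        assert f2.vm == pytest.approx(2.0 * f1.vm, rel=1e-9, abs=1e-12)

    def test_superposition_of_load_cases(self, materials):
        img = _inclusion_plate(12)
        attrs = build_attribute_map(img, materials)
        ma = build_model(img, attrs, LoadCase(pressure_override=0.1))
        mb = build_model(img, attrs, LoadCase(pressure_override=0.25))
        mc = build_model(img, attrs, LoadCase(pressure_override=0.35))
        ua = assemble_and_solve(ma).displacements
        ub = assemble_and_solve(mb).displacements
        uc = assemble_and_solve(mc).displacements
        assert uc == pytest.approx(ua + ub, rel=1e-9, abs=1e-15)

    def test_sparse_matches_dense_oracle(self, materials):
        img = _inclusion_plate(15)  # 225 elements, < 500 free DOF
        attrs = build_attribute_map(img, materials)
        model = build_model(img, attrs, LoadCase(70))
        sparse = assemble_and_solve(model, method="sparse")
        dense = assemble_and_solve(model, method="dense")
        assert sparse.displacements == pytest.approx(
            dense.displacements, rel=1e-10, abs=1e-15
        )
        assert sparse.vm == pytest.approx(dense.vm, rel=1e-8, abs=1e-12)

    def test_mirrored_geometry_gives_mirrored_field(self, materials):
        img = _inclusion_plate(16, offset=3)  # asymmetric inclusion
        flipped = LabelImage(np.fliplr(img.labels).copy(), img.pixel_size)
        fields = []
        for im in (img, flipped):
            attrs = build_attribute_map(im, materials)
            model = build_model(im, attrs, LoadCase(70))
            fields.append(assemble_and_solve(model))
        n = 16
        vm_a = fields[0].vm.reshape(n, n)
        vm_b = fields[1].vm.reshape(n, n)
        assert vm_b == pytest.approx(np.fliplr(vm_a), rel=1e-8, abs=1e-12)

    def test_solver_residual_is_tiny(self, frontal_image, materials):
        attrs = build_attribute_map(frontal_image, materials)
        model = build_model(frontal_image, attrs, LoadCase(70))
        field = assemble_and_solve(model)
        assert field.residual < 1e-12


class TestInclusionContrast:
    def test_soft_raises_and_stiff_lowers_equator_stress(self, materials):
        # under vertical load the inclusion's influence is strongest at its
        # sides (the equator): a soft inclusion sheds load around itself and
        # raises the flanking stress, a stiff one attracts load and shields
        # its flanks — monotone in the stiffness contrast
        n = 21
        flank = {}
        for cls in ("trabecular", "fluid", "cortical"):  # control, soft, stiff
            img = _inclusion_plate(n, inclusion_cls=cls, base_cls="trabecular")
            attrs = build_attribute_map(img, materials)
            model = build_model(img, attrs, LoadCase(70))
            field = assemble_and_solve(model)
            vm = field.vm.reshape(n, n)
            c = n // 2
            sides = np.r_[vm[c - 2 : c + 2, c - 3], vm[c - 2 : c + 2, c + 2]]
            flank[cls] = sides.mean()
        assert flank["fluid"] > flank["trabecular"] > flank["cortical"]

    def test_mesh_refinement_converges(self, materials):
        # same 8 mm plate with a centred soft inclusion at three pixel sizes;
        # the probe stress increment must shrink as the mesh refines
        probe = []
        for n, h in ((8, 1.0), (16, 0.5), (32, 0.25)):
            labels = np.full((n, n), CLASS_CODES["trabecular"], dtype=np.uint8)
            q = n // 4
            labels[q : 3 * q, q : 3 * q] = CLASS_CODES["fluid"]
            img = LabelImage(labels, pixel_size=h)
            attrs = build_attribute_map(img, materials)
            model = build_model(img, attrs, LoadCase(pressure_override=0.248),
                                bottom_bc="roller")
            field = assemble_and_solve(model)
            # fixed physical probe: mid-height, first column (far from inclusion)
            col0 = np.where(model.element_pixel[:, 1] == 0)[0]
            mid = col0[np.argmin(np.abs(model.element_pixel[col0, 0] - n // 2))]
            probe.append(field.vm[mid])
        d1, d2 = abs(probe[1] - probe[0]), abs(probe[2] - probe[1])
        assert d2 < d1


class TestSummarize:
    def test_constant_field_smax_equals_mean(self, materials):
        _, field = solve_plate(make_plate(20), materials)
        s = summarize(field, boundary_layer=2)
        assert s.smax == pytest.approx(s.mean, rel=1e-12)

    def test_single_element_roi(self, materials):
        model, field = solve_plate(make_plate(10), materials)
        roi = np.zeros(model.n_elements, dtype=bool)
        roi[37] = True
        s = summarize(field, roi=roi)
        assert s.smax == field.vm[37]
        assert s.n_elements == 1

    def test_empty_roi_raises(self, materials):
        model, field = solve_plate(make_plate(10), materials)
        with pytest.raises(ValueError, match="region of interest"):
            summarize(field, roi=np.zeros(model.n_elements, dtype=bool))


def _inclusion_plate(
    n: int,
    inclusion_cls: str = "fluid",
    base_cls: str = "cortical",
    offset: int = 0,
) -> LabelImage:
    labels = np.full((n, n), CLASS_CODES[base_cls], dtype=np.uint8)
    c = n // 2 + offset
    labels[n // 2 - 2 : n // 2 + 2, c - 2 : c + 2] = CLASS_CODES[inclusion_cls]
    return LabelImage(labels, pixel_size=0.5)
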