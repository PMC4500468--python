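"""Phantom generator: rasterization, dipole kernel, forward field, GRE synthesis."""

import numpy as np
import pytest

from canalqsm.phantom import (
    Inclusion,
    PhantomSpec,
    analytic_cylinder_field,
    build_dipole_kernel,
    forward_field,
    inclusion_mask,
    rasterize_susceptibility,
    single_canal_94T,
    synthesize_gre,
    three_canals_94T,
)
from canalqsm.volume_model import (
    AcquisitionParams,
    VoxelGrid,
    make_kspace_grid,
)

B0_Z = (0.0, 0.0, 1.0)


def _spec(grid, inclusions, **kw):
    kw.setdefault("texture_sd", 0.0)
    return PhantomSpec(
        grid=grid,
        acq=AcquisitionParams(field_strength=9.4, echo_time=15e-3),
        inclusions=inclusions,
        **kw,
    )


class TestRasterize:
    def test_cylinder_interior_exterior(self, small_grid):
        inc = Inclusion("cylinder", (0, 0, 0), radius=0.3, delta_chi=0.06, axis=B0_Z)
        spec = _spec(small_grid, [inc], antialias=False)
        chi = rasterize_susceptibility(spec)
        x, y, _ = np.meshgrid(*small_grid.coordinates_mm(), indexing="ij")
        rho = np.sqrt(x**2 + y**2)
        assert np.allclose(chi.values[rho <= 0.25], 0.06)
        assert np.allclose(chi.values[rho >= 0.35], 0.0)

    def test_overlapping_inclusions_add(self, small_grid):
        inc = Inclusion("cylinder", (0, 0, 0), radius=0.3, delta_chi=0.03, axis=B0_Z)
        chi = rasterize_susceptibility(_spec(small_grid, [inc, inc], antialias=False))
        assert chi.values.max() == pytest.approx(0.06)

    def test_sphere_volume_matches_analytic(self):
        grid = VoxelGrid((64, 64, 64), (0.1, 0.1, 0.1))
        r = 0.45  # 4.5 voxels
        inc = Inclusion("sphere", (0, 0, 0), radius=r, delta_chi=1.0)
        chi = rasterize_susceptibility(_spec(grid, [inc]))
        vol = chi.values.sum() * 0.1**3  # antialiased fractions integrate the support
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * r**3, rel=0.05)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            Inclusion("cylinder", (0, 0, 0), radius=0.0, delta_chi=0.06)


class TestDipoleKernel:
    def test_limit_values(self, small_grid):
        kg = make_kspace_grid(small_grid)
        d = build_dipole_kernel(kg, B0_Z).values
        c = kg.dc_index
        # k perpendicular to B0 -> 1/3; k parallel -> -2/3
        assert d[0, c[1], c[2]] == pytest.approx(1.0 / 3.0)
        assert d[c[0], c[1], 0] == pytest.approx(-2.0 / 3.0)
        assert d[c] == 0.0
        off_dc = d[kg.k2 > 0]
        assert off_dc.min() >= -2.0 / 3.0 - 1e-12 and off_dc.max() <= 1.0 / 3.0 + 1e-12

    def test_magic_angle_cone_zero(self):
        # direction with (k.b0)^2 / K^2 = 1/3 exactly: k = (sqrt2, 0, 1)/sqrt3
        grid = VoxelGrid((16, 16, 16), (1.0, 1.0, 1.0))
        kg = make_kspace_grid(grid)
        b0 = (np.sqrt(2.0 / 3.0), 0.0, np.sqrt(1.0 / 3.0))
        d = build_dipole_kernel(kg, b0).values
        k_on_cone = kg.k_dot(b0) ** 2 - kg.k2 / 3.0
        on = (np.abs(k_on_cone) < 1e-12) & (kg.k2 > 0)
        assert on.any()
        assert np.abs(d[on]).max() < 1e-12


class TestForwardField:
    @pytest.mark.parametrize(
        "axis, expected_factor",
        [(B0_Z, 1.0 / 3.0), ((1.0, 0.0, 0.0), -1.0 / 6.0)],
        ids=["parallel", "perpendicular"],
    )
    def test_cylinder_interior_closed_form(self, axis, expected_factor):
        grid = VoxelGrid((96, 96, 96), (0.1, 0.1, 0.1))
        inc = Inclusion("cylinder", (0, 0, 0), radius=0.5, delta_chi=0.06, axis=axis)
        spec = _spec(grid, [inc])
        field = forward_field(rasterize_susceptibility(spec), build_dipole_kernel(make_kspace_grid(grid), B0_Z))
        core = inclusion_mask(spec, dilate_mm=-0.2)
        assert field.values[core.values].mean() == pytest.approx(0.06 * expected_factor, rel=0.05)

    def test_magic_angle_cylinder_interior_near_zero(self):
        grid = VoxelGrid((96, 96, 96), (0.1, 0.1, 0.1))
        theta = np.arccos(np.sqrt(1.0 / 3.0))
        inc = Inclusion(
            "cylinder", (0, 0, 0), radius=0.5, delta_chi=0.06,
            axis=(np.sin(theta), 0.0, np.cos(theta)),
        )
        spec = _spec(grid, [inc])
        field = forward_field(rasterize_susceptibility(spec), build_dipole_kernel(make_kspace_grid(grid), B0_Z))
        core = inclusion_mask(spec, dilate_mm=-0.2)
        assert abs(field.values[core.values].mean()) < 0.05 * 0.06

    def test_sphere_interior_near_zero(self):
        grid = VoxelGrid((96, 96, 96), (0.1, 0.1, 0.1))
        inc = Inclusion("sphere", (0, 0, 0), radius=0.5, delta_chi=0.06)
        spec = _spec(grid, [inc])
        field = forward_field(rasterize_susceptibility(spec), build_dipole_kernel(make_kspace_grid(grid), B0_Z))
        core = inclusion_mask(spec, dilate_mm=-0.2)
        assert abs(field.values[core.values].mean()) < 0.02 * 0.06

    def test_exterior_matches_analytic_cylinder(self):
        grid = VoxelGrid((96, 96, 96), (0.1, 0.1, 0.1))
        inc = Inclusion("cylinder", (0, 0, 0), radius=0.5, delta_chi=0.06, axis=(1.0, 0.0, 0.0))
        spec = _spec(grid, [inc])
        field = forward_field(rasterize_susceptibility(spec), build_dipole_kernel(make_kspace_grid(grid), B0_Z))
        oracle = analytic_cylinder_field(grid, inc, B0_Z)
        _, y, z = np.meshgrid(*grid.coordinates_mm(), indexing="ij")
        ring = (np.sqrt(y**2 + z**2) > 0.8) & (np.sqrt(y**2 + z**2) < 2.0)
        scale = np.abs(oracle.values[ring]).max()
        assert np.abs(field.values - oracle.values)[ring].max() < 0.05 * scale

    def test_volume_mean_is_dc_value_times_mean_chi(self, small_grid):
        inc = Inclusion("cylinder", (0, 0, 0), radius=0.4, delta_chi=0.06, axis=B0_Z)
        spec = _spec(small_grid, [inc])
        field = forward_field(rasterize_susceptibility(spec), build_dipole_kernel(make_kspace_grid(small_grid), B0_Z))
        assert abs(field.values.mean()) < 1e-12  # D(DC) = 0


class TestAnalyticCylinder:
    @pytest.mark.parametrize(
        "axis, expected",
        [
            (B0_Z, 0.06 / 3.0),
            ((1.0, 0.0, 0.0), -0.06 / 6.0),
            ((np.sin(np.arccos(np.sqrt(1 / 3))), 0.0, np.sqrt(1 / 3)), 0.0),
        ],
        ids=["theta0", "theta90", "magic"],
    )
    def test_interior_value(self, small_grid, axis, expected):
        inc = Inclusion("cylinder", (0, 0, 0), radius=0.5, delta_chi=0.06, axis=axis)
        field = analytic_cylinder_field(small_grid, inc, B0_Z)
        c = tuple(n // 2 for n in small_grid.shape)
        assert field.values[c] == pytest.approx(expected, abs=1e-12)


class TestSynthesizeGre:
    def test_quiet_phantom_has_zero_phase(self, small_grid):
        spec = _spec(small_grid, [], noise_sd=0.0)
        vol = synthesize_gre(spec)
        assert np.abs(vol.phase).max() < 1e-12
        assert np.allclose(vol.magnitude, spec.tissue_magnitude)

    def test_paramagnetic_lobes_have_negative_phase(self):
        # cylinder perpendicular to B0: voxels displaced along B0 from the axis
        # sit on the dipole lobes and must show negative phase
        spec = single_canal_94T("perp")
        spec = spec.replace(noise_sd=0.0, texture_sd=0.0, background_field={})
        vol = synthesize_gre(spec)
        c = spec.grid.shape[0] // 2
        lobes = vol.phase[c, c, [c - 3, c - 2, c + 2, c + 3]]
        assert np.all(lobes < 0.0)

    def test_fixed_seed_is_bit_identical(self, small_grid):
        spec = _spec(small_grid, [Inclusion("sphere", (0, 0, 0), radius=0.4, delta_chi=0.06)],
                     noise_sd=0.05, rng_seed=42, texture_sd=0.08)
        a = synthesize_gre(spec)
        b = synthesize_gre(spec)
        assert np.array_equal(a.magnitude, b.magnitude)
        assert np.array_equal(a.phase, b.phase)

    def test_canal_voxels_are_darker(self, small_grid):
        inc = Inclusion("cylinder", (0, 0, 0), radius=0.3, delta_chi=0.06, axis=B0_Z)
        spec = _spec(small_grid, [inc], antialias=False)
        vol = synthesize_gre(spec)
        core = inclusion_mask(spec, dilate_mm=-0.1)
        outside = ~inclusion_mask(spec, dilate_mm=0.2).values
        assert vol.magnitude[core.values].mean() == pytest.approx(
            spec.canal_magnitude_factor * spec.tissue_magnitude, rel=1e-6
        )
        assert vol.magnitude[outside].mean() == pytest.approx(spec.tissue_magnitude, rel=1e-6)


class TestFixtureSpecs:
    def test_yaml_round_trip(self, tmp_path):
        spec = three_canals_94T()
        spec.to_yaml(tmp_path / "spec.yaml")
        back = PhantomSpec.from_yaml(tmp_path / "spec.yaml")
        assert back.grid == spec.grid
        assert back.inclusions == spec.inclusions
        assert back.background_field == spec.background_field
        assert back.rng_seed == spec.rng_seed

    def test_bundled_fixture_loads(self):
        from canalqsm.phantom import load_phantom_spec

        spec = load_phantom_spec("three_canals_94T")
        assert len(spec.inclusions) == 3
        assert spec.acq.field_strength == 9.4

    def test_inclusions_respect_guard_band(self):
        # lateral distance from every cylinder axis to the volume edge >= 25% FOV
        spec = three_canals_94T()
        fov = spec.grid.fov_mm[0]
        for inc in spec.inclusions:
            lateral = [
                abs(c) for c, a in zip(inc.center, inc.axis) if abs(a) < 0.99
            ]
            assert all(fov / 2 - v >= 0.25 * fov for v in lateral)
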