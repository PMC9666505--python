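"""Phantom generator: rod layers, cell target, composition, fill factor."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage, stats

from tpmphantom import (
    CellTargetSpec,
    PhantomSpec,
    RIVolume,
    RodLayerLayout,
    beer_lambert_transmittance,
    build_cell_target,
    compose_phantom,
    compute_fill_factor,
    generate_phantom,
    line_group_layouts,
    rasterize_scattering_cube,
    sample_rod_layouts,
)


@pytest.fixture(scope="module")
def spec():
    return PhantomSpec()


class TestRodLayouts:
    def test_default_cube_has_28_full_layers(self, spec):
        # oracle: layers at rod_height/2 + k*layer_pitch that fit in 40 µm
        layouts = sample_rod_layouts(spec, 1)
        n_expected = 0
        z = spec.rod_height / 2
        while z + spec.rod_height / 2 <= spec.cube_size[2]:
            n_expected += 1
            z += spec.layer_pitch
        assert n_expected == 28
        assert len(layouts) == n_expected

    def test_orientation_alternates(self, spec):
        layouts = sample_rod_layouts(spec, 3)
        for a, b in zip(layouts, layouts[1:]):
            assert a.orientation != b.orientation

    def test_deterministic_for_fixed_seed(self, spec):
        la = sample_rod_layouts(spec, 42)
        lb = sample_rod_layouts(spec, 42)
        for a, b in zip(la, lb):
            assert a.z_center == b.z_center
            np.testing.assert_array_equal(a.rod_positions, b.rod_positions)

    def test_gaps_within_range_and_uniform(self, spec):
        """Edge-to-edge gaps pass a KS test against Uniform(0.7, 3.0)."""
        gaps = []
        seed = 0
        while len(gaps) < 10_000:
            for layer in sample_rod_layouts(spec, seed):
                gaps.extend(np.diff(layer.rod_positions) - spec.rod_width)
            seed += 1
        gaps = np.asarray(gaps)
        lo, hi = spec.rod_gap_range
        assert gaps.min() >= lo and gaps.max() <= hi
        p = stats.kstest(gaps, stats.uniform(lo, hi - lo).cdf).pvalue
        assert p > 0.01

    def test_degenerate_interval_gives_periodic_pitch(self):
        spec = PhantomSpec(rod_gap_range=(1.0, 1.0))
        layouts = sample_rod_layouts(spec, 0)
        for layer in layouts:
            np.testing.assert_allclose(
                np.diff(layer.rod_positions), spec.rod_width + 1.0
            )

    def test_flat_cube_raises(self, spec):
        bad = dataclasses.replace(spec, cube_size=(60.0, 60.0, 1.0))
        with pytest.raises(ValueError, match="degenerate cube"):
            sample_rod_layouts(bad, 0)


class TestRasterize:
    def test_single_rod_cross_section_5_by_18_voxels(self):
        # oracle: voxel centres inside a 0.5 × 1.8 µm rectangle at 0.1 µm
        spec = PhantomSpec(cube_size=(4.0, 4.0, 4.0))
        layer = RodLayerLayout(2.0, "x-aligned", [1.7])
        vol = rasterize_scattering_cube([layer], spec, 0.1)
        occ = vol.values > spec.n_background
        cross = occ[occ.shape[0] // 2]  # (y, z) cross-section
        assert np.count_nonzero(cross.any(axis=1)) == 5
        assert np.count_nonzero(cross.any(axis=0)) == 18
        # rods extend the full cube along their axis
        assert occ.any(axis=(1, 2)).all()

    def test_empty_layout_uniform_background(self, spec):
        vol = rasterize_scattering_cube([], spec, 0.25)
        assert np.all(vol.values == spec.n_background)

    def test_coarse_pitch_rejected(self, spec):
        with pytest.raises(ValueError, match="undersampled"):
            rasterize_scattering_cube([], spec, 0.4)

    def test_ri_range_exact(self, spec):
        vol = rasterize_scattering_cube(sample_rod_layouts(spec, 2), spec, 0.25)
        assert vol.values.min() == spec.n_background
        assert vol.values.max() == spec.polymer_ri_effective

    def test_fill_factor_near_nominal_over_seeds(self):
        """Mean polymer fraction over 20 seeds within [0.20, 0.30]."""
        spec = PhantomSpec(cube_size=(30.0, 30.0, 20.0))
        fills = [
            compute_fill_factor(
                rasterize_scattering_cube(sample_rod_layouts(spec, s), spec, 0.25),
                n_background=spec.n_background,
            )
            for s in range(20)
        ]
        assert 0.20 <= np.mean(fills) <= 0.30


class TestCellTarget:
    def test_finest_line_group_is_1667_lpmm(self, spec):
        cspec = CellTargetSpec()
        groups = line_group_layouts(cspec, spec)
        finest = max(g.frequency_lpmm for g in groups)
        assert finest == 1667.0
        g = [g for g in groups if g.frequency_lpmm == finest][0]
        # oracle: period = 1/(1667 lp/mm) = 0.6 µm, bar width half that
        assert g.period_um == pytest.approx(0.5999, abs=1e-3)
        assert g.bar_width == pytest.approx(0.3, abs=1e-3)

    def test_ellipsoid_bounding_box(self, spec):
        """External dimensions 30 × 25 × 12 µm within one voxel per axis."""
        cspec = CellTargetSpec(truncation=0.0)
        pitch = 0.2
        vol = build_cell_target(cspec, spec, pitch)
        occ = vol.values > spec.n_background
        for axis, size in enumerate(cspec.ellipsoid_size):
            other = tuple(a for a in range(3) if a != axis)
            extent = np.count_nonzero(occ.any(axis=other)) * pitch
            assert abs(extent - size) <= pitch + 1e-9

    def test_no_features_plain_truncated_ellipsoid(self, spec):
        cspec = CellTargetSpec()
        plain = dataclasses.replace(
            cspec,
            line_group_frequencies=(1667.0,),
            bar_length=0.0,
            nucleus_semiaxes=(1e-6, 1e-6, 1e-6),
            nucleoli_radii=(1e-9, 1e-9),
            gradient_size=(1e-9, 1e-9, 1e-9),
        )
        vol = build_cell_target(plain, spec, 0.5)
        inside = vol.values[vol.values > spec.n_background]
        assert np.all(inside == spec.n_background + plain.cytoplasm_offset)

    def test_offset_above_delta_ri_max_rejected(self, spec):
        bad = CellTargetSpec(nucleolus_offset=0.05)
        with pytest.raises(ValueError):
            build_cell_target(bad, spec, 0.5)

    def test_truncation_removes_bottom(self, spec):
        cspec = CellTargetSpec()
        vol = build_cell_target(cspec, spec, 0.2)
        occ = vol.values > spec.n_background
        z = vol.axis_coords(2) - spec.cube_size[2] / 2
        occupied_z = z[occ.any(axis=(0, 1))]
        c = cspec.ellipsoid_size[2] / 2
        assert occupied_z.min() >= -c + cspec.truncation * 2 * c - 0.2


class TestCompose:
    @pytest.fixture(scope="class")
    def small(self):
        spec = PhantomSpec(cube_size=(12.0, 12.0, 10.0))
        cspec = CellTargetSpec(
            ellipsoid_size=(6.0, 5.0, 3.0),
            line_group_frequencies=(1190.0, 1667.0),
            bars_per_group=3,
            bar_length=1.0,
            bar_thickness=0.6,
            line_row_y=-1.2,
            group_margin=0.4,
            nucleus_center=(0.0, 1.2, 0.0),
            nucleus_semiaxes=(1.2, 1.0, 0.8),
            nucleoli_centers=((0.0, 1.2, 0.0),),
            nucleoli_radii=(0.4,),
            gradient_center=(-1.8, 0.0, 0.0),
            gradient_size=(1.2, 1.0, 1.0),
        )
        return spec, cspec

    def test_empty_cell_returns_cube(self, small):
        spec, _ = small
        cube = rasterize_scattering_cube(sample_rod_layouts(spec, 1), spec, 0.25)
        empty = RIVolume(
            np.full_like(cube.values, spec.n_background),
            cube.voxel_pitch,
            cube.origin,
        )
        out = compose_phantom(cube, empty, spec.clearance, spec.n_background)
        np.testing.assert_array_equal(out.values, cube.values)

    def test_clearance_suppresses_rods_near_cell(self, small):
        spec, cspec = small
        cube = rasterize_scattering_cube(sample_rod_layouts(spec, 1), spec, 0.25)
        cell = build_cell_target(cspec, spec, 0.25)
        out = compose_phantom(cube, cell, spec.clearance, spec.n_background)
        cell_mask = cell.values > spec.n_background
        rod_mask = (out.values > spec.n_background) & ~cell_mask
        dist = ndimage.distance_transform_edt(
            ~cell_mask, sampling=tuple(out.voxel_pitch)
        )
        assert np.all(dist[rod_mask] >= spec.clearance)

    def test_zero_clearance_cell_priority(self, small):
        spec, cspec = small
        cube = rasterize_scattering_cube(sample_rod_layouts(spec, 1), spec, 0.25)
        cell = build_cell_target(cspec, spec, 0.25)
        out = compose_phantom(cube, cell, 0.0, spec.n_background)
        cell_mask = cell.values > spec.n_background
        np.testing.assert_array_equal(out.values[cell_mask], cell.values[cell_mask])
        outside = ~cell_mask
        np.testing.assert_array_equal(out.values[outside], cube.values[outside])

    def test_grid_mismatch_raises(self, small):
        spec, _ = small
        cube = rasterize_scattering_cube([], spec, 0.25)
        other = RIVolume(np.full((4, 4, 4), spec.n_background), 0.25, 0.0)
        with pytest.raises(ValueError, match="grid"):
            compose_phantom(cube, other, 0.5)

    def test_composed_ri_range(self, small):
        spec, cspec = small
        vol = generate_phantom(spec, cspec, voxel_pitch=0.25, seed=3)
        assert vol.values.min() == spec.n_background
        assert vol.values.max() - spec.n_background <= spec.delta_ri_max + 1e-15


class TestFillFactor:
    def test_uniform_background_zero(self, spec):
        vol = RIVolume(np.full((8, 8, 8), spec.n_background), 0.5, 0.0)
        assert compute_fill_factor(vol, n_background=spec.n_background) == 0.0

    def test_fully_polymerized_one(self, spec):
        vol = RIVolume(np.full((8, 8, 8), spec.polymer_ri_effective), 0.5, 0.0)
        assert compute_fill_factor(vol, n_background=spec.n_background) == 1.0

    def test_empty_region_raises(self, spec):
        vol = RIVolume(np.full((8, 8, 8), spec.n_background), 0.5, 0.0)
        with pytest.raises(ValueError, match="empty region"):
            compute_fill_factor(vol, region=((9.0, 10.0), (0, 4), (0, 4)))


def test_transmittance_closed_form():
    assert beer_lambert_transmittance(0.1, 40.0) == pytest.approx(
        np.exp(-0.004), rel=1e-12
    )
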