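"""Dose reconstruction, RT Dose round trips and grid operations."""

import numpy as np
import pydicom
import pytest

from protonprep import (
    CopyIdRecord,
    DoseGrid,
    copyids_to_dose_array,
    make_copyid_records,
    median_filter_dose,
    normalize_to_reference,
    read_copyid_records,
    read_rtdose,
    rotate_volume,
    sum_fields,
    write_copyid_records,
    write_rtdose,
)
from protonprep.errors import DomainError, GeometryMismatchError, NormalizationError, StructuralError

from conftest import make_grid
from oracles import brute_force_median, copyid_lookup_table


class TestCopyIds:
    def test_copyid_zero_is_origin_voxel(self):
        grid = copyids_to_dose_array([CopyIdRecord(0, 2.5)], (2, 2, 2))
        assert grid.values[0, 0, 0] == 2.5

    def test_default_ordering_example(self):
        # copyid 5 in a 2x2x2 grid, x fastest: 5 = 1 + 2*(0 + 2*1)
        grid = copyids_to_dose_array([CopyIdRecord(5, 1.0)], (2, 2, 2))
        z, y, x = np.nonzero(grid.values)
        assert (x[0], y[0], z[0]) == (1, 0, 1)

    @pytest.mark.parametrize("ordering", ["xyz", "zyx", "yxz", "xzy", "yzx", "zxy"])
    def test_all_ids_match_nested_loop_oracle(self, ordering):
        dims = (4, 3, 5)
        table = copyid_lookup_table(dims, ordering)
        for cid, (x, y, z) in table.items():
            grid = copyids_to_dose_array([CopyIdRecord(cid, 1.0)], dims, ordering)
            assert grid.values[z, y, x] == 1.0
            assert grid.values.sum() == 1.0

    def test_duplicates_accumulate_and_conserve(self):
        grid = copyids_to_dose_array(
            [CopyIdRecord(3, 1.0), CopyIdRecord(3, 2.0)], (2, 2, 2)
        )
        assert grid.values.ravel()[3] == 3.0
        assert grid.values.sum() == 3.0

    def test_large_record_set_conserves_total(self, rng):
        dims = (20, 25, 20)
        ids = rng.integers(0, np.prod(dims), 10_000)
        doses = rng.uniform(0, 1, 10_000)
        records = [CopyIdRecord(int(i), float(d)) for i, d in zip(ids, doses)]
        grid = copyids_to_dose_array(records, dims)
        assert grid.values.sum() == pytest.approx(doses.sum(), rel=1e-12)

    def test_out_of_range_copyid_names_the_record(self):
        with pytest.raises(IndexError, match="record 1"):
            copyids_to_dose_array([CopyIdRecord(0, 1.0), CopyIdRecord(8, 1.0)], (2, 2, 2))

    def test_empty_records_warn_and_zero_fill(self):
        with pytest.warns(UserWarning):
            grid = copyids_to_dose_array([], (2, 2, 2))
        assert not grid.values.any()

    def test_text_round_trip(self, tmp_path):
        records = [CopyIdRecord(0, 0.125), CopyIdRecord(7, 1.5)]
        path = tmp_path / "scores.csv"
        write_copyid_records(records, path)
        assert read_copyid_records(path) == records

    def test_generator_round_trip_identity(self, rng):
        for ordering in ("xyz", "zyx"):
            vals = np.round(rng.uniform(0, 2, (3, 4, 5)), 6)
            vals[vals < 0.7] = 0.0
            grid = make_grid(vals)
            recs = make_copyid_records(grid, ordering)
            back = copyids_to_dose_array(recs, (5, 4, 3), ordering)
            assert np.array_equal(back.values, grid.values)


class TestRTDose:
    def grid(self, rng, n=(5, 6, 7)):
        return DoseGrid(
            values=rng.uniform(0, 2, n),
            grid_scaling=1.0,
            image_position=np.array([-10.0, -20.0, 5.0]),
            pixel_spacing=np.array([2.0, 2.5]),
            frame_offsets=np.arange(n[0]) * 2.0,
            series_description="MC dose (test)",
        )

    def test_round_trip_integer_quantization(self, rng, tmp_path):
        grid = self.grid(rng)
        path = tmp_path / "dose.dcm"
        write_rtdose(grid, path)
        back = read_rtdose(path)
        assert np.abs(back.physical() - grid.physical()).max() <= 0.5 * back.grid_scaling
        assert np.array_equal(back.frame_offsets, [0, 2, 4, 6, 8])
        assert np.array_equal(back.image_position, grid.image_position)
        assert np.array_equal(back.pixel_spacing, grid.pixel_spacing)
        assert back.series_description == grid.series_description

    def test_round_trip_float_storage_bit_exact(self, rng, tmp_path):
        grid = self.grid(rng)
        grid.values = grid.values.astype(np.float32)
        path = tmp_path / "dose_f.dcm"
        write_rtdose(grid, path, float_storage=True)
        back = read_rtdose(path)
        assert np.array_equal(back.physical(), grid.physical())

    def test_ledger_tags_in_independent_reader(self, rng, tmp_path):
        path = tmp_path / "dose.dcm"
        write_rtdose(self.grid(rng), path)
        ds = pydicom.dcmread(path)
        assert ds.Modality == "RTDOSE"
        assert int(ds.NumberOfFrames) == 5
        assert [float(v) for v in ds.GridFrameOffsetVector] == [0, 2, 4, 6, 8]
        assert ds.Rows == 6 and ds.Columns == 7
        # SimpleITK accepts the file as a DICOM image with the same geometry
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        assert img.GetSize() == (7, 6, 5)
        assert img.GetSpacing()[:2] == (2.5, 2.0)

    def test_wrong_modality_rejected(self, tmp_path, rng):
        path = tmp_path / "notdose.dcm"
        write_rtdose(self.grid(rng), path)
        ds = pydicom.dcmread(path)
        ds.Modality = "CT"
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(StructuralError):
            read_rtdose(path)

    def test_invalid_grid_rejected_before_write(self):
        with pytest.raises(StructuralError):
            DoseGrid(
                values=np.zeros((2, 2, 2)),
                grid_scaling=1.0,
                image_position=np.zeros(3),
                pixel_spacing=np.ones(2),
                frame_offsets=np.array([0.0, 2.0, 4.0]),  # wrong length
            )


class TestNormalization:
    def test_matches_reference_exactly_and_idempotent(self, rng):
        mc = make_grid(rng.uniform(0.5, 1.0, (5, 5, 5)))
        ref = make_grid(rng.uniform(1.0, 2.0, (5, 5, 5)))
        point = np.array([6.0, 6.0, 6.0])
        out = normalize_to_reference(mc, ref, point)
        assert out.sample(point[None])[0] == pytest.approx(ref.sample(point[None])[0], rel=1e-15)
        again = normalize_to_reference(out, ref, point)
        assert again.grid_scaling == pytest.approx(out.grid_scaling, rel=1e-15)
        # stored values untouched, ratio applied to the scaling only
        assert np.array_equal(out.values, mc.values)

    def test_ratio_of_two(self):
        mc = make_grid(np.full((3, 3, 3), 1.0))
        ref = make_grid(np.full((3, 3, 3), 2.0))
        out = normalize_to_reference(mc, ref, [3.0, 3.0, 3.0])
        assert out.grid_scaling == pytest.approx(2.0)

    def test_zero_mc_dose_is_error(self):
        mc = make_grid(np.zeros((3, 3, 3)))
        ref = make_grid(np.ones((3, 3, 3)))
        with pytest.raises(NormalizationError):
            normalize_to_reference(mc, ref, [3.0, 3.0, 3.0])

    def test_point_outside_is_bounds_error(self, rng):
        mc = make_grid(rng.uniform(0.5, 1.0, (3, 3, 3)))
        with pytest.raises(IndexError):
            normalize_to_reference(mc, mc, [100.0, 0.0, 0.0])


class TestMedianFilter:
    def test_constant_grid_unchanged(self):
        grid = make_grid(np.full((4, 4, 4), 3.0))
        assert np.array_equal(median_filter_dose(grid).values, grid.values)

    def test_impulse_removed(self):
        vals = np.ones((5, 5, 5))
        vals[2, 2, 2] = 100.0
        out = median_filter_dose(make_grid(vals), 3)
        assert out.values[2, 2, 2] == 1.0

    def test_matches_brute_force_oracle(self, rng):
        vals = rng.uniform(0, 1, (5, 5, 5))
        out = median_filter_dose(make_grid(vals), 3)
        assert np.allclose(out.values, brute_force_median(vals, (3, 3, 3)))

    def test_non_expansive(self, rng):
        vals = rng.uniform(0, 10, (6, 6, 6))
        out = median_filter_dose(make_grid(vals), (3, 5, 3))
        assert out.values.min() >= vals.min()
        assert out.values.max() <= vals.max()

    def test_even_kernel_rejected(self):
        with pytest.raises(DomainError):
            median_filter_dose(make_grid(np.ones((4, 4, 4))), 2)


class TestSumFields:
    def test_two_identical_fields_double(self, rng):
        g = make_grid(rng.uniform(0, 2, (4, 4, 4)))
        total = sum_fields([g, g])
        assert np.allclose(total.physical(), 2 * g.physical())

    def test_zero_field_is_identity(self, rng):
        g = make_grid(rng.uniform(0, 2, (4, 4, 4)))
        z = make_grid(np.zeros((4, 4, 4)))
        assert np.allclose(sum_fields([g, z]).physical(), g.physical())

    def test_geometry_mismatch_without_resample(self, rng):
        a = make_grid(rng.uniform(0, 1, (4, 4, 4)), spacing=2.0)
        b = make_grid(rng.uniform(0, 1, (4, 4, 4)), spacing=3.0)
        with pytest.raises(GeometryMismatchError):
            sum_fields([a, b])

    def test_resampled_copy_doubles_at_coincident_centers(self, rng):
        # a half-resolution copy shares every other voxel center exactly
        fine_vals = rng.uniform(0.5, 1.5, (9, 9, 9))
        fine = make_grid(fine_vals, spacing=2.0)
        coarse = DoseGrid(
            values=fine_vals[::2, ::2, ::2],
            grid_scaling=1.0,
            image_position=fine.image_position,
            pixel_spacing=fine.pixel_spacing * 2,
            frame_offsets=np.arange(5) * 4.0,
        )
        total = sum_fields([fine, coarse], resample=True)
        assert np.allclose(
            total.physical()[::2, ::2, ::2], 2 * fine.physical()[::2, ::2, ::2], rtol=1e-9
        )


class TestRotateVolume:
    def test_zero_angle_identity(self, rng):
        g = make_grid(rng.uniform(0, 1, (5, 5, 5)))
        out = rotate_volume(g, 0.0, "z")
        assert np.allclose(out.values, g.values)

    def test_quarter_turn_matches_index_permutation(self, rng):
        vals = rng.uniform(0, 1, (7, 7, 7))
        g = make_grid(vals, spacing=2.0)
        out = rotate_volume(g, 90.0, "z")
        # +90 degrees about z maps x->y; the output voxel at (row=r, col=c)
        # samples the source at (x=r, y=-c), i.e. out[i, j] = in[n-1-j, i]
        expected = np.stack([np.rot90(vals[s], k=-1) for s in range(7)])
        assert np.allclose(out.values, expected, atol=1e-9)

    def test_full_turn_identity(self, rng):
        g = make_grid(rng.uniform(0, 1, (6, 6, 6)))
        out = rotate_volume(g, 360.0, "y")
        assert np.allclose(out.values, g.values, atol=1e-9)
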