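import numpy as np
import pytest
from hypothesis import given, strategies as st

from doseqa.dose_model import (
    DoseGrid,
    GridGeometry,
    StructureMask,
    fractional_mask,
    read_mask_nrrd,
    read_nrrd,
    read_rtdose,
    resample_onto,
    write_mask_nrrd,
    write_nrrd,
    write_rtdose,
)
from doseqa.errors import (
    EmptyGridError,
    FormatError,
    GeometryError,
    ParameterError,
    UnsupportedGeometryError,
)
from doseqa import _dicomrt


class TestDoseGrid:
    def test_rejects_negative_dose(self):
        with pytest.raises(GeometryError):
            DoseGrid.from_arrays(np.full((2, 2, 2), -1.0), (0, 0, 0), (1, 1, 1))

    def test_rejects_nan(self):
        values = np.ones((2, 2, 2))
        values[0, 0, 0] = np.nan
        with pytest.raises(GeometryError):
            DoseGrid.from_arrays(values, (0, 0, 0), (1, 1, 1))

    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(GeometryError):
            GridGeometry((0, 0, 0), (1, 0, 1), (2, 2, 2))

    def test_shape_mismatch(self):
        with pytest.raises(GeometryError):
            DoseGrid(np.ones((2, 2, 2)), GridGeometry((0, 0, 0), (1, 1, 1), (3, 3, 3)))

    def test_mask_geometry_must_match(self):
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (2, 2, 2))
        with pytest.raises(GeometryError):
            StructureMask(np.ones((3, 3, 3), dtype=bool), geom)


class TestRTDose:
    def test_round_trip_values_and_geometry(self, tmp_path, rng):
        grid = DoseGrid.from_arrays(
            70.0 * rng.random((4, 5, 6)), (-10.0, 5.0, 2.5), (2.0, 2.5, 3.0)
        )
        path = tmp_path / "dose.dcm"
        write_rtdose(grid, path)
        back = read_rtdose(path)
        assert back.geometry == grid.geometry
        # first write quantizes to the 32-bit scaling grid ...
        np.testing.assert_allclose(back.values, grid.values, atol=grid.max() / 2**31)
        # ... after which the representation round-trips identically
        path2 = tmp_path / "dose2.dcm"
        write_rtdose(back, path2)
        again = read_rtdose(path2)
        assert np.array_equal(again.values, back.values)
        assert again.geometry == back.geometry

    def test_dose_equals_scaling_times_stored(self, tmp_path):
        # file with known scaling s and stored integers v -> dose must be s*v
        stored = np.arange(24, dtype=np.uint32).reshape(2, 3, 4)  # (x, y, z)
        scaling = 0.0125
        path = tmp_path / "scaled.dcm"
        write_rtdose(
            DoseGrid.from_arrays(np.ones((2, 3, 4)), (0, 0, 0), (1, 1, 2)), path
        )
        data = path.read_bytes()
        # splice in our own scaling element payload (same length, 22 chars)
        old = data[data.find(b"\x0e\x00DS", 200) + 6 :][:22]
        new_scaling = f"{scaling:.16e}"[:22].ljust(22).encode()
        data = data.replace(old, new_scaling)
        # and our own pixel data (same byte count: 24 uint32 values)
        data = data[: len(data) - 24 * 4] + np.ascontiguousarray(
            stored.transpose(2, 1, 0).astype("<u4")
        ).tobytes()
        path.write_bytes(data)
        back = read_rtdose(path)
        np.testing.assert_allclose(back.values, scaling * stored, rtol=0, atol=0)

    def test_wrong_modality_rejected(self, tmp_path):
        path = tmp_path / "dose.dcm"
        write_rtdose(
            DoseGrid.from_arrays(np.ones((2, 2, 2)), (0, 0, 0), (1, 1, 1)), path
        )
        data = bytearray(path.read_bytes())
        idx = data.find(b"RTDOSE", 200)  # dataset modality (past file meta UIDs)
        data[idx : idx + 6] = b"CT    "
        bad = tmp_path / "ct.dcm"
        bad.write_bytes(bytes(data))
        with pytest.raises(FormatError):
            read_rtdose(bad)

    def test_tilted_orientation_rejected(self, tmp_path):
        path = tmp_path / "dose.dcm"
        write_rtdose(
            DoseGrid.from_arrays(np.ones((2, 2, 2)), (0, 0, 0), (1, 1, 1)), path
        )
        data = path.read_bytes().replace(b"1\\0\\0\\0\\1\\0", b"0\\1\\0\\1\\0\\0")
        bad = tmp_path / "tilted.dcm"
        bad.write_bytes(data)
        with pytest.raises(UnsupportedGeometryError):
            read_rtdose(bad)

    def test_not_dicom_rejected(self, tmp_path):
        path = tmp_path / "junk.dcm"
        path.write_bytes(b"not a dicom file at all")
        with pytest.raises(FormatError):
            read_rtdose(path)


class TestNRRD:
    @pytest.mark.parametrize("encoding", ["raw", "text"])
    def test_round_trip(self, tmp_path, rng, encoding):
        grid = DoseGrid.from_arrays(
            50.0 * rng.random((3, 4, 5)), (1.0, -2.0, 3.5), (2.5, 2.5, 3.0)
        )
        path = tmp_path / "dose.nrrd"
        write_nrrd(grid, path, encoding=encoding)
        back = read_nrrd(path)
        assert np.array_equal(back.values, grid.values)
        assert back.geometry == grid.geometry

    def test_mask_round_trip(self, tmp_path, rng):
        geom = GridGeometry((0, 0, 0), (2, 2, 2), (4, 4, 4))
        mask = StructureMask(rng.random((4, 4, 4)) > 0.5, geom)
        path = tmp_path / "mask.nrrd"
        write_mask_nrrd(mask, path)
        back = read_mask_nrrd(path)
        assert np.array_equal(back.values, mask.values)
        assert back.geometry == geom

    def test_non_nrrd_rejected(self, tmp_path):
        path = tmp_path / "x.nrrd"
        path.write_bytes(b"hello world\n\n")
        with pytest.raises(FormatError):
            read_nrrd(path)


class TestResample:
    def test_identity(self, rng):
        grid = DoseGrid.from_arrays(rng.random((6, 6, 6)), (0, 0, 0), (2, 2, 2))
        out, oos = resample_onto(grid, grid.geometry)
        np.testing.assert_allclose(out.values, grid.values, atol=1e-12)
        assert not oos.any()

    def test_constant_field_interior(self):
        grid = DoseGrid.from_arrays(np.full((8, 8, 8), 7.0), (0, 0, 0), (2, 2, 2))
        target = GridGeometry((1.0, 1.0, 1.0), (1.7, 1.7, 1.7), (5, 5, 5))
        out, oos = resample_onto(grid, target)
        assert not oos.any()
        np.testing.assert_allclose(out.values, 7.0, atol=1e-12)

    def test_linear_ramp_midpoints(self):
        # d(x) = x along axis 0; trilinear interpolation reproduces it exactly
        x = np.arange(10, dtype=float)
        values = np.broadcast_to(x[:, None, None], (10, 4, 4)).copy()
        grid = DoseGrid.from_arrays(values, (0, 0, 0), (1, 1, 1))
        target = GridGeometry((0.5, 0.0, 0.0), (1.0, 1.0, 1.0), (9, 4, 4))
        out, oos = resample_onto(grid, target)
        assert not oos.any()
        expected = np.broadcast_to((x[:-1] + 0.5)[:, None, None], (9, 4, 4))
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_out_of_support_zero_filled(self):
        grid = DoseGrid.from_arrays(np.full((4, 4, 4), 5.0), (0, 0, 0), (1, 1, 1))
        target = GridGeometry((-2.0, 0.0, 0.0), (1.0, 1.0, 1.0), (4, 4, 4))
        out, oos = resample_onto(grid, target)
        assert oos[:2].all() and not oos[2:].any()
        assert (out.values[:2] == 0).all()
        np.testing.assert_allclose(out.values[2:], 5.0)

    def test_affine_field_reproduced(self, rng):
        # trilinear interpolation is exact for globally affine fields
        axes = [np.arange(n) * s for n, s in zip((7, 6, 5), (2.0, 2.5, 3.0))]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        values = 10.0 + 0.3 * xx + 0.2 * yy + 0.1 * zz
        grid = DoseGrid.from_arrays(values, (0, 0, 0), (2.0, 2.5, 3.0))
        target = GridGeometry((1.1, 2.3, 0.7), (1.3, 1.1, 2.2), (5, 5, 4))
        out, oos = resample_onto(grid, target)
        tx = [target.voxel_centers(a) for a in range(3)]
        gx, gy, gz = np.meshgrid(*tx, indexing="ij")
        expected = 10.0 + 0.3 * gx + 0.2 * gy + 0.1 * gz
        np.testing.assert_allclose(out.values[~oos], expected[~oos], atol=1e-10)


class TestFractionalMask:
    def test_uniform_all_true(self, uniform_grid):
        assert fractional_mask(uniform_grid, 0.05).values.all()

    def test_enumerated_cut(self):
        values = np.array([1.0, 3.0, 100.0]).reshape(3, 1, 1)
        grid = DoseGrid.from_arrays(values, (0, 0, 0), (1, 1, 1))
        mask = fractional_mask(grid, 0.05)  # cut at 5.0
        assert mask.values.ravel().tolist() == [False, False, True]

    def test_two_level_seventy_percent(self):
        values = np.array([60.0, 80.0]).reshape(2, 1, 1)
        grid = DoseGrid.from_arrays(values, (0, 0, 0), (1, 1, 1))
        mask = fractional_mask(grid, 0.70)  # cut at 56: both pass
        assert mask.values.ravel().tolist() == [True, True]

    def test_all_zero_grid_rejected(self):
        grid = DoseGrid.from_arrays(np.zeros((2, 2, 2)), (0, 0, 0), (1, 1, 1))
        with pytest.raises(EmptyGridError):
            fractional_mask(grid, 0.05)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_domain(self, uniform_grid, fraction):
        with pytest.raises(ParameterError):
            fractional_mask(uniform_grid, fraction)

    @given(
        lo=st.floats(0.01, 0.5),
        hi=st.floats(0.5, 0.99),
        seed=st.integers(0, 10_000),
    )
    def test_monotone_in_fraction(self, lo, hi, seed):
        values = np.random.default_rng(seed).random((4, 4, 4)) * 10 + 0.1
        grid = DoseGrid.from_arrays(values, (0, 0, 0), (1, 1, 1))
        mask_lo = fractional_mask(grid, lo).values
        mask_hi = fractional_mask(grid, min(max(hi, lo), 0.99)).values
        assert not np.any(mask_hi & ~mask_lo)
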