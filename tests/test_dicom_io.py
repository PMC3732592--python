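"""DICOM SOP class writers/readers: round trips, integrity, independent parse."""

import hashlib
import subprocess

import numpy as np
import pytest

from mrsikit import dicom_io
from mrsikit.core import Geometry, MetaboliteMap
from mrsikit.dicomlite import DataSet, deterministic_uid, write_file
from mrsikit.errors import CorruptionError, FormatError, IntegrityError

from _dicom_walker import walk_file, find, text


@pytest.fixture(scope="module")
def mrs_file(tmp_path_factory, recon_ds):
    path = tmp_path_factory.mktemp("dicom") / "mrs.dcm"
    dicom_io.write_dicom_mrs(recon_ds, path)
    return path


class TestMrsStorage:
    def test_sop_class_uid(self, mrs_file):
        _, body = walk_file(mrs_file)
        assert text(body, (0x0008, 0x0016)) == "1.2.840.10008.5.1.4.1.1.4.2"

    def test_round_trip_data_within_float32(self, mrs_file, recon_ds):
        back = dicom_io.read_dicom_mrs(mrs_file)
        scale = np.max(np.abs(recon_ds.data))
        assert np.allclose(back.data, recon_ds.data, atol=scale * 1e-6)
        ax_in, ax_out = recon_ds.spectral_axis, back.spectral_axis
        assert ax_out.n_points == ax_in.n_points
        assert ax_out.sweep_width == ax_in.sweep_width
        assert ax_out.transmitter_freq == ax_in.transmitter_freq
        assert ax_out.ppm_ref == ax_in.ppm_ref
        assert ax_out.domain == ax_in.domain

    def test_geometry_survives_exactly(self, mrs_file, recon_ds):
        back = dicom_io.read_dicom_mrs(mrs_file)
        assert back.geometry.origin == recon_ds.geometry.origin
        assert back.geometry.spacing == recon_ds.geometry.spacing
        assert back.geometry.orientation == recon_ds.geometry.orientation

    def test_selection_and_sat_bands_survive(self, mrs_file, recon_ds):
        back = dicom_io.read_dicom_mrs(mrs_file)
        assert np.allclose(back.selection.center, recon_ds.selection.center)
        assert np.allclose(back.selection.size, recon_ds.selection.size)
        assert len(back.sat_bands) == len(recon_ds.sat_bands)
        assert back.sat_bands[0].thickness == recon_ds.sat_bands[0].thickness

    def test_spectroscopy_data_byte_length(self, mrs_file, recon_ds):
        _, body = walk_file(mrs_file)
        payload = find(body, (0x5600, 0x0020))
        nx, ny, nz = recon_ds.dims
        assert len(payload) == 8 * nx * ny * nz * recon_ds.spectral_axis.n_points

    def test_multichannel_input_rejected(self, kspace_ds, tmp_path):
        from mrsikit import recon as R

        multi = kspace_ds.evolve("fake", data=np.repeat(kspace_ds.data, 2, axis=4))
        img = R.spatial_recon(multi)
        with pytest.raises(ValueError, match="coil combination"):
            dicom_io.write_dicom_mrs(img, tmp_path / "x.dcm")

    def test_wrong_sop_class_error_names_found_uid(self, tmp_path, recon_ds):
        mmap = MetaboliteMap(
            values=np.zeros((2, 2, 1)),
            geometry=Geometry(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(2, 2, 1)),
            label="x",
            mask=np.ones((2, 2, 1), bool),
        )
        p = tmp_path / "map.dcm"
        dicom_io.write_metabolite_map_dicom(mmap, p)
        with pytest.raises(FormatError, match="4.1"):
            dicom_io.read_dicom_mrs(p)

    def test_missing_spectroscopy_data_is_corruption(self, tmp_path):
        body = DataSet()
        body.add((0x0008, 0x0016), "UI", dicom_io.MRS_SOP_CLASS)
        body.add((0x0028, 0x0008), "IS", 1)
        body.add((0x0028, 0x0010), "US", 2)
        body.add((0x0028, 0x0011), "US", 2)
        body.add((0x0028, 0x9002), "UL", 8)
        p = write_file(tmp_path / "empty.dcm", dicom_io.MRS_SOP_CLASS, body, deterministic_uid("x"))
        with pytest.raises(CorruptionError, match="5600"):
            dicom_io.read_dicom_mrs(p)


@pytest.fixture(scope="module")
def packed(tmp_path_factory, small_phantom_files):
    d = tmp_path_factory.mktemp("raw")
    out = dicom_io.encapsulate_raw([small_phantom_files[0]], d / "raw.dcm")
    return out, small_phantom_files[0]


class TestRawDataStorage:
    def test_sop_class_uid(self, packed):
        _, body = walk_file(packed[0])
        assert text(body, (0x0008, 0x0016)) == "1.2.840.10008.5.1.4.1.1.66"

    def test_pack_unpack_round_trip_byte_identical(self, packed, tmp_path):
        restored = dicom_io.unencapsulate_raw(packed[0], tmp_path)
        assert restored[0].read_bytes() == packed[1].read_bytes()

    def test_stored_digest_matches_external_sha1(self, packed):
        _, body = walk_file(packed[0])
        seq = find(body, (0x0077, 0x1001))
        stored = text(seq[0], (0x0077, 0x1012))
        # second, independent SHA1 implementation: the sha1sum binary
        external = subprocess.run(
            ["sha1sum", str(packed[1])], capture_output=True, text=True, check=True
        ).stdout.split()[0]
        assert stored == external

    def test_single_bit_flip_detected(self, packed, tmp_path):
        blob = bytearray(packed[0].read_bytes())
        payload = packed[1].read_bytes()
        start = bytes(blob).find(payload)
        assert start > 0
        blob[start + 1000] ^= 0x10
        p = tmp_path / "corrupt.dcm"
        p.write_bytes(bytes(blob))
        with pytest.raises(IntegrityError, match="SHA1"):
            dicom_io.unencapsulate_raw(p, tmp_path / "out")

    def test_empty_payload_member(self, tmp_path):
        empty = tmp_path / "empty.bin"
        empty.write_bytes(b"")
        out = dicom_io.encapsulate_raw([empty], tmp_path / "raw.dcm")
        _, body = walk_file(out)
        seq = find(body, (0x0077, 0x1001))
        assert text(seq[0], (0x0077, 0x1012)) == "da39a3ee5e6b4b0d3255bfef95601890afd80709"
        restored = dicom_io.unencapsulate_raw(out, tmp_path / "restore")
        assert restored[0].read_bytes() == b""

    def test_multiple_members(self, tmp_path):
        a, b = tmp_path / "a.bin", tmp_path / "b.bin"
        a.write_bytes(b"alpha")
        b.write_bytes(b"beta-beta")
        out = dicom_io.encapsulate_raw([a, b], tmp_path / "two.dcm")
        restored = dicom_io.unencapsulate_raw(out, tmp_path / "r")
        assert [p.read_bytes() for p in restored] == [b"alpha", b"beta-beta"]


@pytest.fixture(scope="module")
def a_map():
    rng = np.random.default_rng(5)
    geo = Geometry(origin=(-20, -20, 0), spacing=(5, 5, 8), dims=(6, 5, 3))
    values = rng.uniform(0, 3, size=(6, 5, 3))
    mask = rng.uniform(size=(6, 5, 3)) > 0.2
    return MetaboliteMap(values=values, geometry=geo, label="cho_height", mask=mask)


class TestEnhancedMrImage:
    def test_sop_class_uid(self, a_map, tmp_path):
        p = tmp_path / "m.dcm"
        dicom_io.write_metabolite_map_dicom(a_map, p)
        _, body = walk_file(p)
        assert text(body, (0x0008, 0x0016)) == "1.2.840.10008.5.1.4.1.1.4.1"

    def test_round_trip_within_one_quantization_step(self, a_map, tmp_path):
        p = tmp_path / "m.dcm"
        dicom_io.write_metabolite_map_dicom(a_map, p)
        back = dicom_io.read_metabolite_map_dicom(p)
        vals = a_map.values[a_map.mask]
        step = (vals.max() - vals.min()) / 65535
        assert np.all(np.abs(back.values[a_map.mask] - vals) <= step)
        assert np.array_equal(back.mask, a_map.mask)
        assert back.geometry.origin == a_map.geometry.origin
        assert back.label == "cho_height"

    def test_constant_map_reproduced_exactly(self, tmp_path):
        geo = Geometry(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(3, 3, 2))
        m = MetaboliteMap(np.full((3, 3, 2), 2.5), geo, "const", np.ones((3, 3, 2), bool))
        p = tmp_path / "c.dcm"
        dicom_io.write_metabolite_map_dicom(m, p)
        back = dicom_io.read_metabolite_map_dicom(p)
        assert np.array_equal(back.values, m.values)

    def test_nan_in_unmasked_voxel_rejected(self, tmp_path):
        geo = Geometry(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(2, 2, 1))
        vals = np.array([[[np.nan], [1.0]], [[2.0], [3.0]]])
        m = MetaboliteMap(vals, geo, "bad", np.ones((2, 2, 1), bool))
        with pytest.raises(ValueError, match="NaN"):
            dicom_io.write_metabolite_map_dicom(m, tmp_path / "bad.dcm")

    def test_nan_in_masked_voxel_tolerated(self, tmp_path):
        geo = Geometry(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(2, 2, 1))
        vals = np.array([[[np.nan], [1.0]], [[2.0], [3.0]]])
        mask = np.array([[[False], [True]], [[True], [True]]])
        m = MetaboliteMap(vals, geo, "ok", mask)
        dicom_io.write_metabolite_map_dicom(m, tmp_path / "ok.dcm")


class TestSecondaryCapture:
    def test_series_numbering_and_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        rasters = [rng.integers(0, 255, size=(32, 48, 3), dtype=np.uint8) for _ in range(3)]
        paths = dicom_io.write_secondary_capture(rasters, tmp_path / "sc")
        assert len(paths) == 3
        series_uids = set()
        for i, p in enumerate(paths, start=1):
            _, body = walk_file(p)
            assert text(body, (0x0008, 0x0016)) == "1.2.840.10008.5.1.4.1.1.7"
            assert int(text(body, (0x0020, 0x0013))) == i
            series_uids.add(text(body, (0x0020, 0x000E)))
            assert np.array_equal(dicom_io.read_secondary_capture(p), rasters[i - 1])
        assert len(series_uids) == 1

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="at least one"):
            dicom_io.write_secondary_capture([], tmp_path / "sc")


def test_every_writer_output_parses_with_independent_walker(mrs_file, tmp_path):
    files = [mrs_file]
    files.append(dicom_io.encapsulate_raw([mrs_file], tmp_path / "raw.dcm"))
    geo = Geometry(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(2, 2, 2))
    m = MetaboliteMap(np.arange(8, dtype=float).reshape(2, 2, 2), geo, "m", np.ones((2, 2, 2), bool))
    files.append(dicom_io.write_metabolite_map_dicom(m, tmp_path / "m.dcm"))
    files += dicom_io.write_secondary_capture(
        [np.zeros((16, 16, 3), np.uint8)], tmp_path / "sc"
    )
    for f in files:
        meta, body = walk_file(f)  # raises on any structural inconsistency
        assert text(meta, (0x0002, 0x0010)) == "1.2.840.10008.1.2.1"
        assert find(body, (0x0008, 0x0018)) is not None
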