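"""DICOM encoding of every pipeline product.

Four SOP classes cover the scanner-to-PACS workflow:

* **MR Spectroscopy Storage** (1.2.840.10008.5.1.4.1.1.4.2) — reconstructed
  spectroscopic data.  The complex payload lives in Spectroscopy Data
  (5600,0020) as float32 real/imaginary pairs ordered frame(z) -> row(y) ->
  column(x) -> spectral point; spectral axis metadata in Spectral Width,
  Transmitter Frequency, Chemical Shift Reference and Resonant Nucleus.
* **Raw Data Storage** (1.2.840.10008.5.1.4.1.1.66) — original raw files
  encapsulated verbatim in a documented private block together with their
  SHA1 digests, so integrity can be confirmed when they are unencapsulated.
* **Enhanced MR Image Storage** (1.2.840.10008.5.1.4.1.1.4.1) — 3-D
  metabolite maps, float values linearly mapped onto 16-bit pixels with
  Rescale Slope/Intercept.
* **Secondary Capture Image Storage** (1.2.840.10008.5.1.4.1.1.7) — rendered
  RGB report panels for reading-room review.

A classic single-frame **MR Image Storage** (1.2.840.10008.5.1.4.1.1.4)
writer/reader supports synthetic anatomical reference series.

Geometry is carried in standard plane position/orientation attributes; all
files use Explicit VR Little Endian and deterministic (content-derived) UIDs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .core import Geometry, MrsDataset, MetaboliteMap, SatBand, SelectionBox, SpectralAxis
from .dicomlite import DataSet, deterministic_uid, read_file, write_file
from .errors import CorruptionError, DomainError, FormatError, IntegrityError

__all__ = [
    "MRS_SOP_CLASS",
    "RAW_SOP_CLASS",
    "ENHANCED_MR_SOP_CLASS",
    "SC_SOP_CLASS",
    "MR_IMAGE_SOP_CLASS",
    "write_dicom_mrs",
    "read_dicom_mrs",
    "encapsulate_raw",
    "unencapsulate_raw",
    "write_metabolite_map_dicom",
    "read_metabolite_map_dicom",
    "write_secondary_capture",
    "read_secondary_capture",
    "write_mri_series",
    "read_mri_series",
]

MRS_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.4.2"
RAW_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.66"
ENHANCED_MR_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.4.1"
SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"
MR_IMAGE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.4"

PRIVATE_CREATOR = "MRSIKIT"

# tags used repeatedly
_TAG_SOP_CLASS = (0x0008, 0x0016)
_TAG_SOP_INSTANCE = (0x0008, 0x0018)
_TAG_SPECTRO_DATA = (0x5600, 0x0020)


def _common_elements(
    body: DataSet, sop_class: str, sop_instance: str, modality: str,
    series_uid: str, instance_number: int = 1,
) -> None:
    body.add(_TAG_SOP_CLASS, "UI", sop_class)
    body.add(_TAG_SOP_INSTANCE, "UI", sop_instance)
    body.add((0x0008, 0x0020), "DA", "20130101")  # fixed dates keep files byte-reproducible
    body.add((0x0008, 0x0030), "TM", "000000")
    body.add((0x0008, 0x0060), "CS", modality)
    body.add((0x0010, 0x0010), "PN", "PHANTOM^MRSI")
    body.add((0x0010, 0x0020), "LO", "MRSIKIT-PHANTOM")
    body.add((0x0020, 0x000D), "UI", deterministic_uid("study", series_uid))
    body.add((0x0020, 0x000E), "UI", series_uid)
    body.add((0x0020, 0x0013), "IS", instance_number)


def _geometry_elements(body: DataSet, geo: Geometry) -> None:
    body.add((0x0020, 0x0037), "DS", list(geo.orientation))
    # PixelSpacing is (row spacing, column spacing) = (dy, dx)
    body.add((0x0028, 0x0030), "DS", [geo.spacing[1], geo.spacing[0]])
    body.add((0x0018, 0x0050), "DS", geo.spacing[2])


def _per_frame_positions(body: DataSet, geo: Geometry) -> None:
    items = []
    for z in range(geo.dims[2]):
        pos = geo.voxel_center(0, 0, z)
        plane = DataSet().add((0x0020, 0x0032), "DS", [float(v) for v in pos])
        items.append(DataSet().add((0x0020, 0x9113), "SQ", [plane]))
    body.add((0x5200, 0x9230), "SQ", items)


def _read_frame_geometry(body: DataSet, nx: int, ny: int, nz: int) -> Geometry:
    orient = body.require((0x0020, 0x0037), "Image Orientation (Patient)")
    px = body.require((0x0028, 0x0030), "Pixel Spacing")
    thick = float(body.get((0x0018, 0x0050), 1.0))
    frames = body.get((0x5200, 0x9230), [])
    positions = []
    for item in frames:
        plane_seq = item.get((0x0020, 0x9113))
        if plane_seq:
            positions.append([float(v) for v in plane_seq[0].require((0x0020, 0x0032))])
    if not positions:
        raise CorruptionError("no per-frame plane positions found")
    origin = tuple(positions[0])
    if len(positions) >= 2:
        dz = float(np.linalg.norm(np.array(positions[1]) - np.array(positions[0])))
        if dz > 0:
            thick = dz
    return Geometry(
        origin=origin,
        spacing=(float(px[1]), float(px[0]), thick),
        orientation=tuple(float(v) for v in orient),
        dims=(nx, ny, nz),
    )


# ---------------------------------------------------------------------------
# MR Spectroscopy Storage
# ---------------------------------------------------------------------------

def write_dicom_mrs(ds: MrsDataset, path) -> Path:
    """Encode a single-channel dataset as an MR Spectroscopy Storage instance.

    Preconditions: exactly one channel (combine coils first) and image-space
    spatial axes.  Spectral data may be in either domain; the domain is
    recorded in Signal Domain Columns (0028,9003).
    """
    if ds.channel_count != 1:
        raise ValueError(
            f"MR Spectroscopy export requires a single channel, got {ds.channel_count}; "
            "apply coil combination first"
        )
    if any(d != "image" for d in ds.spatial_domain):
        raise DomainError("MR Spectroscopy export requires image-space spatial axes")
    nx, ny, nz = ds.dims
    axis = ds.spectral_axis

    # frame(z) -> row(y) -> column(x) -> point, real/imag interleaved float32
    cube = np.ascontiguousarray(ds.data[:, :, :, :, 0].transpose(2, 1, 0, 3))
    interleaved = np.empty(cube.size * 2, dtype="<f4")
    interleaved[0::2] = cube.real.ravel()
    interleaved[1::2] = cube.imag.ravel()

    body = DataSet()
    payload = interleaved.tobytes()
    sop_instance = deterministic_uid("mrs", hashlib.sha1(payload).hexdigest())
    _common_elements(body, MRS_SOP_CLASS, sop_instance, "MR",
                     deterministic_uid("mrs-series", sop_instance))
    body.add((0x0018, 0x9052), "FD", axis.sweep_width)
    body.add((0x0018, 0x9053), "FD", axis.ppm_ref)
    body.add((0x0018, 0x9098), "FD", axis.transmitter_freq)
    body.add((0x0018, 0x9100), "CS", "1H")
    body.add((0x0028, 0x0008), "IS", nz)
    body.add((0x0028, 0x0010), "US", ny)
    body.add((0x0028, 0x0011), "US", nx)
    body.add((0x0028, 0x9002), "UL", axis.n_points)
    body.add((0x0028, 0x9003), "CS", "TIME" if axis.domain == "time" else "FREQUENCY")
    _geometry_elements(body, ds.geometry)
    _per_frame_positions(body, ds.geometry)

    if ds.selection is not None:
        slabs = []
        for ax in range(3):
            normal = [0.0, 0.0, 0.0]
            normal[ax] = 1.0
            slab = DataSet()
            slab.add((0x0018, 0x9104), "FD", float(ds.selection.size[ax]))
            slab.add((0x0018, 0x9105), "FD", normal)
            slab.add((0x0018, 0x9106), "FD", [float(v) for v in ds.selection.center])
            slabs.append(slab)
        body.add((0x0018, 0x9126), "SQ", slabs)

    body.add((0x0077, 0x0010), "LO", PRIVATE_CREATOR)
    if ds.sat_bands:
        items = []
        for band in ds.sat_bands:
            item = DataSet()
            item.add((0x0077, 0x1021), "FD", [float(v) for v in band.normal])
            item.add((0x0077, 0x1022), "FD", float(band.distance))
            item.add((0x0077, 0x1023), "FD", float(band.thickness))
            items.append(item)
        body.add((0x0077, 0x1020), "SQ", items)

    body.add(_TAG_SPECTRO_DATA, "OF", payload)
    return write_file(path, MRS_SOP_CLASS, body, sop_instance)


def read_dicom_mrs(path) -> MrsDataset:
    """Decode an MR Spectroscopy Storage instance written by this package."""
    _, body = read_file(path)
    sop = body.get(_TAG_SOP_CLASS)
    if sop != MRS_SOP_CLASS:
        raise FormatError(f"{path}: SOP Class {sop!r} is not MR Spectroscopy Storage")
    nz = int(body.require((0x0028, 0x0008), "Number of Frames"))
    ny = int(body.require((0x0028, 0x0010), "Rows"))
    nx = int(body.require((0x0028, 0x0011), "Columns"))
    n_points = int(body.require((0x0028, 0x9002), "Data Point Columns"))
    raw = body.get(_TAG_SPECTRO_DATA)
    if raw is None:
        raise CorruptionError(f"{path}: missing Spectroscopy Data (5600,0020)")
    expected = 2 * nx * ny * nz * n_points
    floats = np.frombuffer(raw, dtype="<f4")
    if floats.size != expected:
        raise CorruptionError(
            f"{path}: Spectroscopy Data holds {floats.size} floats, expected {expected}"
        )
    cplx = (floats[0::2] + 1j * floats[1::2]).astype(np.complex128)
    data = cplx.reshape(nz, ny, nx, n_points).transpose(2, 1, 0, 3)[..., None]

    sw = float(body.require((0x0018, 0x9052), "Spectral Width"))
    domain = "time" if str(body.get((0x0028, 0x9003), "TIME")).strip() == "TIME" else "frequency"
    axis = SpectralAxis(
        n_points=n_points,
        dwell=1.0 / sw,
        sweep_width=sw,
        transmitter_freq=float(body.require((0x0018, 0x9098), "Transmitter Frequency")),
        ppm_ref=float(body.get((0x0018, 0x9053), 4.7)),
        domain=domain,
    )
    geometry = _read_frame_geometry(body, nx, ny, nz)

    selection = None
    slabs = body.get((0x0018, 0x9126))
    if slabs:
        center = tuple(float(v) for v in slabs[0].require((0x0018, 0x9106)))
        size = [0.0, 0.0, 0.0]
        for slab in slabs:
            normal = np.asarray(slab.require((0x0018, 0x9105)), dtype=float)
            ax = int(np.argmax(np.abs(normal)))
            size[ax] = float(slab.require((0x0018, 0x9104)))
        selection = SelectionBox(center=center, size=tuple(size))

    sat_bands = []
    for item in body.get((0x0077, 0x1020), []) or []:
        sat_bands.append(
            SatBand(
                normal=tuple(float(v) for v in item.require((0x0077, 0x1021))),
                distance=float(item.require((0x0077, 0x1022))),
                thickness=float(item.require((0x0077, 0x1023))),
            )
        )

    ds = MrsDataset(
        data=np.ascontiguousarray(data),
        spectral_axis=axis,
        geometry=geometry,
        spatial_domain=("image", "image", "image"),
        selection=selection,
        sat_bands=sat_bands,
    )
    return ds.evolve("read_dicom_mrs", {"path": str(path)})


# ---------------------------------------------------------------------------
# Raw Data Storage
# ---------------------------------------------------------------------------

def encapsulate_raw(paths: list, out) -> Path:
    """Pack files verbatim into one Raw Data Storage instance.

    Each file becomes a private-sequence item holding its name, the SHA1 hex
    digest of its bytes, the payload (even-padded, pad length recorded), and
    its true byte length.
    """
    paths = [Path(p) for p in paths]
    items = []
    digest_all = hashlib.sha1()
    for p in paths:
        payload = p.read_bytes()
        digest = hashlib.sha1(payload).hexdigest()
        digest_all.update(payload)
        pad = len(payload) % 2
        item = DataSet()
        item.add((0x0077, 0x0010), "LO", PRIVATE_CREATOR)
        item.add((0x0077, 0x1011), "LO", p.name)
        item.add((0x0077, 0x1012), "LO", digest)
        item.add((0x0077, 0x1014), "IS", pad)
        item.add((0x0077, 0x1015), "UL", len(payload))
        item.add((0x0077, 0x1013), "OB", payload)
        items.append(item)

    body = DataSet()
    sop_instance = deterministic_uid("raw", digest_all.hexdigest())
    _common_elements(body, RAW_SOP_CLASS, sop_instance, "OT",
                     deterministic_uid("raw-series", sop_instance))
    body.add((0x0077, 0x0010), "LO", PRIVATE_CREATOR)
    body.add((0x0077, 0x1001), "SQ", items)
    return write_file(out, RAW_SOP_CLASS, body, sop_instance)


def unencapsulate_raw(path, outdir) -> list[Path]:
    """Restore every encapsulated file, verifying each SHA1 digest.

    Raises :class:`IntegrityError` naming the member and both digests on any
    mismatch; nothing is written for a corrupt member.
    """
    _, body = read_file(path)
    sop = body.get(_TAG_SOP_CLASS)
    if sop != RAW_SOP_CLASS:
        raise FormatError(f"{path}: SOP Class {sop!r} is not Raw Data Storage")
    items = body.get((0x0077, 0x1001))
    if items is None:
        raise CorruptionError(f"{path}: missing private raw encapsulation sequence")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    restored = []
    for item in items:
        name = str(item.require((0x0077, 0x1011), "member filename"))
        stored_digest = str(item.require((0x0077, 0x1012), "member digest"))
        pad = int(item.get((0x0077, 0x1014), 0))
        length = item.get((0x0077, 0x1015))
        payload = bytes(item.require((0x0077, 0x1013), "member payload"))
        if length is not None:
            payload = payload[: int(length)]
        elif pad:
            payload = payload[:-pad]
        actual = hashlib.sha1(payload).hexdigest()
        if actual != stored_digest:
            raise IntegrityError(
                f"{path}: member {name!r} failed SHA1 verification: "
                f"stored {stored_digest}, recomputed {actual}"
            )
        dest = outdir / name
        dest.write_bytes(payload)
        restored.append(dest)
    return restored


# ---------------------------------------------------------------------------
# Enhanced MR Image Storage (metabolite maps)
# ---------------------------------------------------------------------------

def write_metabolite_map_dicom(mmap: MetaboliteMap, path) -> Path:
    """Encode a metabolite map as an Enhanced MR Image Storage instance.

    Float values are linearly mapped onto unsigned 16-bit pixels; Rescale
    Slope/Intercept restore them to within one quantization step
    ``(max - min) / 65535``.  Masked-out voxels are written as the minimum.
    """
    values = np.array(mmap.values, dtype=float)
    if not np.all(np.isfinite(values[mmap.mask])):
        raise ValueError("metabolite map contains NaN/Inf in unmasked voxels")
    finite = values[mmap.mask]
    if finite.size == 0:
        vmin, vmax = 0.0, 0.0
    else:
        vmin, vmax = float(finite.min()), float(finite.max())
    values = np.where(mmap.mask, values, vmin)
    slope = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
    intercept = vmin
    pixels = np.round((values - intercept) / slope).astype("<u2")
    nx, ny, nz = mmap.geometry.dims
    pixel_bytes = np.ascontiguousarray(pixels.transpose(2, 1, 0)).tobytes()
    mask_bytes = np.ascontiguousarray(mmap.mask.astype("<u2").transpose(2, 1, 0)).tobytes()

    body = DataSet()
    sop_instance = deterministic_uid("emri", mmap.label, hashlib.sha1(pixel_bytes).hexdigest())
    _common_elements(body, ENHANCED_MR_SOP_CLASS, sop_instance, "MR",
                     deterministic_uid("emri-series", sop_instance))
    body.add((0x0008, 0x103E), "LO", mmap.label)
    body.add((0x0028, 0x0002), "US", 1)
    body.add((0x0028, 0x0004), "CS", "MONOCHROME2")
    body.add((0x0028, 0x0008), "IS", nz)
    body.add((0x0028, 0x0010), "US", ny)
    body.add((0x0028, 0x0011), "US", nx)
    body.add((0x0028, 0x0100), "US", 16)
    body.add((0x0028, 0x0101), "US", 16)
    body.add((0x0028, 0x0102), "US", 15)
    body.add((0x0028, 0x0103), "US", 0)
    body.add((0x0028, 0x1052), "DS", intercept)
    body.add((0x0028, 0x1053), "DS", slope)
    _geometry_elements(body, mmap.geometry)
    _per_frame_positions(body, mmap.geometry)
    body.add((0x0077, 0x0010), "LO", PRIVATE_CREATOR)
    body.add((0x0077, 0x1030), "OW", mask_bytes)  # private: quantification mask
    body.add((0x7FE0, 0x0010), "OW", pixel_bytes)
    return write_file(path, ENHANCED_MR_SOP_CLASS, body, sop_instance)


def read_metabolite_map_dicom(path) -> MetaboliteMap:
    """Inverse of :func:`write_metabolite_map_dicom`."""
    _, body = read_file(path)
    sop = body.get(_TAG_SOP_CLASS)
    if sop != ENHANCED_MR_SOP_CLASS:
        raise FormatError(f"{path}: SOP Class {sop!r} is not Enhanced MR Image Storage")
    nz = int(body.require((0x0028, 0x0008)))
    ny = int(body.require((0x0028, 0x0010)))
    nx = int(body.require((0x0028, 0x0011)))
    slope = float(body.get((0x0028, 0x1053), 1.0))
    intercept = float(body.get((0x0028, 0x1052), 0.0))
    pixels = np.frombuffer(body.require((0x7FE0, 0x0010), "Pixel Data"), dtype="<u2")
    values = (pixels.astype(float) * slope + intercept).reshape(nz, ny, nx).transpose(2, 1, 0)
    mask_raw = body.get((0x0077, 0x1030))
    if mask_raw is not None:
        mask = np.frombuffer(mask_raw, dtype="<u2").reshape(nz, ny, nx).transpose(2, 1, 0).astype(bool)
    else:
        mask = np.ones_like(values, dtype=bool)
    geometry = _read_frame_geometry(body, nx, ny, nz)
    label = str(body.get((0x0008, 0x103E), "map"))
    return MetaboliteMap(values=np.array(values), geometry=geometry, label=label, mask=np.array(mask))


# ---------------------------------------------------------------------------
# Secondary Capture Image Storage (report panels)
# ---------------------------------------------------------------------------

def write_secondary_capture(images: list[np.ndarray], out_stem) -> list[Path]:
    """One SC instance per 8-bit RGB raster, shared series, instances 1..n."""
    if not images:
        raise ValueError("secondary capture requires at least one image")
    shapes = {im.shape for im in images}
    if len(shapes) != 1 or images[0].ndim != 3 or images[0].shape[2] != 3:
        raise ValueError("all rasters must be equal-size (H, W, 3) uint8 arrays")
    out_stem = Path(out_stem)
    out_stem.parent.mkdir(parents=True, exist_ok=True)
    series_digest = hashlib.sha1()
    for im in images:
        series_digest.update(np.ascontiguousarray(im, dtype=np.uint8).tobytes())
    series_uid = deterministic_uid("sc-series", series_digest.hexdigest())
    paths = []
    for i, im in enumerate(images, start=1):
        im = np.ascontiguousarray(im, dtype=np.uint8)
        h, w, _ = im.shape
        body = DataSet()
        sop_instance = deterministic_uid("sc", series_uid, i)
        _common_elements(body, SC_SOP_CLASS, sop_instance, "OT", series_uid, instance_number=i)
        body.add((0x0028, 0x0002), "US", 3)
        body.add((0x0028, 0x0004), "CS", "RGB")
        body.add((0x0028, 0x0006), "US", 0)  # planar configuration: interleaved
        body.add((0x0028, 0x0010), "US", h)
        body.add((0x0028, 0x0011), "US", w)
        body.add((0x0028, 0x0100), "US", 8)
        body.add((0x0028, 0x0101), "US", 8)
        body.add((0x0028, 0x0102), "US", 7)
        body.add((0x0028, 0x0103), "US", 0)
        body.add((0x7FE0, 0x0010), "OB", im.tobytes())
        path = out_stem.parent / f"{out_stem.name}_{i:03d}.dcm"
        write_file(path, SC_SOP_CLASS, body, sop_instance)
        paths.append(path)
    return paths


def read_secondary_capture(path) -> np.ndarray:
    """Decode one SC instance back into an (H, W, 3) uint8 raster."""
    _, body = read_file(path)
    sop = body.get(_TAG_SOP_CLASS)
    if sop != SC_SOP_CLASS:
        raise FormatError(f"{path}: SOP Class {sop!r} is not Secondary Capture")
    h = int(body.require((0x0028, 0x0010)))
    w = int(body.require((0x0028, 0x0011)))
    raw = bytes(body.require((0x7FE0, 0x0010), "Pixel Data"))
    return np.frombuffer(raw[: h * w * 3], dtype=np.uint8).reshape(h, w, 3)


# ---------------------------------------------------------------------------
# MR Image Storage (anatomical reference series)
# ---------------------------------------------------------------------------

def write_mri_series(volume: np.ndarray, geometry: Geometry, out_dir) -> list[Path]:
    """Write a (nx, ny, nz) float volume as one MR Image instance per slice."""
    volume = np.asarray(volume, dtype=float)
    nx, ny, nz = volume.shape
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vmin, vmax = float(volume.min()), float(volume.max())
    slope = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
    pixels = np.round((volume - vmin) / slope).astype("<u2")
    series_uid = deterministic_uid(
        "mri-series", hashlib.sha1(pixels.tobytes()).hexdigest()
    )
    paths = []
    for z in range(nz):
        body = DataSet()
        sop_instance = deterministic_uid("mri", series_uid, z)
        _common_elements(body, MR_IMAGE_SOP_CLASS, sop_instance, "MR",
                         series_uid, instance_number=z + 1)
        body.add((0x0020, 0x0032), "DS", [float(v) for v in geometry.voxel_center(0, 0, z)])
        body.add((0x0020, 0x0037), "DS", list(geometry.orientation))
        body.add((0x0028, 0x0002), "US", 1)
        body.add((0x0028, 0x0004), "CS", "MONOCHROME2")
        body.add((0x0028, 0x0010), "US", ny)
        body.add((0x0028, 0x0011), "US", nx)
        body.add((0x0028, 0x0030), "DS", [geometry.spacing[1], geometry.spacing[0]])
        body.add((0x0018, 0x0050), "DS", geometry.spacing[2])
        body.add((0x0028, 0x0100), "US", 16)
        body.add((0x0028, 0x0101), "US", 16)
        body.add((0x0028, 0x0102), "US", 15)
        body.add((0x0028, 0x0103), "US", 0)
        body.add((0x0028, 0x1052), "DS", vmin)
        body.add((0x0028, 0x1053), "DS", slope)
        body.add((0x7FE0, 0x0010), "OW", np.ascontiguousarray(pixels[:, :, z].T).tobytes())
        path = out_dir / f"mri_{z + 1:03d}.dcm"
        write_file(path, MR_IMAGE_SOP_CLASS, body, sop_instance)
        paths.append(path)
    return paths


def read_mri_series(paths_or_dir) -> tuple[np.ndarray, Geometry]:
    """Read an MR Image series back into a (nx, ny, nz) volume + geometry.

    Slices are sorted by Instance Number.
    """
    p = Path(paths_or_dir) if isinstance(paths_or_dir, (str, Path)) else None
    if p is not None and p.is_dir():
        paths = sorted(p.glob("*.dcm"))
    elif p is not None:
        paths = [p]
    else:
        paths = [Path(q) for q in paths_or_dir]
    if not paths:
        raise FormatError("no MR Image files found")
    slices = []
    for q in paths:
        _, body = read_file(q)
        if body.get(_TAG_SOP_CLASS) != MR_IMAGE_SOP_CLASS:
            raise FormatError(f"{q}: not an MR Image Storage instance")
        n = int(body.get((0x0020, 0x0013), 0))
        slices.append((n, body))
    slices.sort(key=lambda t: t[0])
    bodies = [b for _, b in slices]
    ny = int(bodies[0].require((0x0028, 0x0010)))
    nx = int(bodies[0].require((0x0028, 0x0011)))
    slope = float(bodies[0].get((0x0028, 0x1053), 1.0))
    intercept = float(bodies[0].get((0x0028, 0x1052), 0.0))
    vol = np.empty((nx, ny, len(bodies)))
    for z, body in enumerate(bodies):
        px = np.frombuffer(body.require((0x7FE0, 0x0010)), dtype="<u2")
        vol[:, :, z] = (px.astype(float) * slope + intercept).reshape(ny, nx).T
    orient = bodies[0].require((0x0020, 0x0037))
    spacing_rc = bodies[0].require((0x0028, 0x0030))
    origin = tuple(float(v) for v in bodies[0].require((0x0020, 0x0032)))
    dz = float(bodies[0].get((0x0018, 0x0050), 1.0))
    if len(bodies) >= 2:
        p0 = np.asarray(bodies[0].require((0x0020, 0x0032)), dtype=float)
        p1 = np.asarray(bodies[1].require((0x0020, 0x0032)), dtype=float)
        nrm = float(np.linalg.norm(p1 - p0))
        if nrm > 0:
            dz = nrm
    geometry = Geometry(
        origin=origin,
        spacing=(float(spacing_rc[1]), float(spacing_rc[0]), dz),
        orientation=tuple(float(v) for v in orient),
        dims=(nx, ny, len(bodies)),
    )
    return vol, geometry
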