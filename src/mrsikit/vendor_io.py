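"""Raw-acquisition IO: format sniffing, verbatim parsing, and grid mapping.

The design separates two responsibilities, mirroring how vendor-neutral MRSI
software keeps scanner dialects out of its reconstruction code:

* a *reader* parses a file's bytes into an :class:`Acquisition` without any
  interpretation — samples stay in acquisition order, the header is exposed
  verbatim;
* a *mapper* turns an :class:`Acquisition` into an :class:`MrsDataset` on a
  regular (kx, ky, kz, t, channel) grid ready for Fourier reconstruction.
  Mapping is a pure permutation/reshape: no sample value may change.

A small factory (:func:`sniff_format` / :func:`read_any`) dispatches on magic
bytes so that adding a new dialect means adding a reader + mapper pair, never
touching reconstruction.

MRSRAW1 on-disk layout (little endian throughout)::

    bytes 0-7    magic b"MRSRAW1\\n"
    bytes 8-15   uint64: byte length H of the JSON header
    next H bytes UTF-8 JSON header (dims, n_points, channels, dwell, f0,
                 ppm_ref, geometry, selection, sat_bands, ordering,
                 payload_bytes)
    payload      complex64 pairs (float32 real, float32 imag); loop order
                 channel slowest, kz, ky, kx, spectral fastest (cartesian)
                 or channel, kz, ky, spectral, readout-k fastest (epsi)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Geometry, MrsDataset, SatBand, SelectionBox, SpectralAxis
from .errors import CorruptionError, FormatError

__all__ = [
    "Acquisition",
    "MAGIC",
    "sniff_format",
    "read_raw",
    "write_raw",
    "map_acquisition",
    "read_any",
]

MAGIC = b"MRSRAW1\n"

_DICOM_MRS_UID = "1.2.840.10008.5.1.4.1.1.4.2"
_DICOM_MRI_UID = "1.2.840.10008.5.1.4.1.1.4"


@dataclass
class Acquisition:
    """Parsed-but-uninterpreted raw acquisition: the vendor side of the split."""

    samples: np.ndarray          # complex, acquisition order, 1-D
    header: dict = field(default_factory=dict)

    @property
    def ordering(self) -> dict:
        return self.header.get("ordering", {"kind": "cartesian"})

    def declared_count(self) -> int:
        d = self.header
        nx, ny, nz = d["dims"]
        return nx * ny * nz * d["n_points"] * d["channels"]


def write_raw(path, header: dict, samples: np.ndarray) -> Path:
    """Write an MRSRAW1 file; complex input is stored as complex64 pairs."""
    path = Path(path)
    payload = np.ascontiguousarray(samples, dtype=np.complex64).tobytes()
    header = dict(header)
    header["payload_bytes"] = len(payload)
    blob = json.dumps(header, sort_keys=True, separators=(",", ":")).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(len(blob).to_bytes(8, "little"))
        fh.write(blob)
        fh.write(payload)
    return path


def sniff_format(path) -> str:
    """Identify a file as one of mrsraw / dicom_mrs / dicom_mri / unknown.

    MRSRAW1 is recognized by its magic bytes; DICOM by "DICM" at offset 128,
    then subclassified by the Media Storage SOP Class UID in the file meta
    group.  Sniffing never raises on content — only on unreadable paths.
    """
    path = Path(path)
    if not path.is_file():
        raise OSError(f"not a readable file: {path}")
    with open(path, "rb") as fh:
        head = fh.read(132)
    if head[: len(MAGIC)] == MAGIC:
        return "mrsraw"
    if len(head) >= 132 and head[128:132] == b"DICM":
        from . import dicomlite

        try:
            uid = dicomlite.peek_sop_class(path)
        except Exception:
            return "unknown"
        if uid == _DICOM_MRS_UID:
            return "dicom_mrs"
        if uid == _DICOM_MRI_UID:
            return "dicom_mri"
        return "dicom_other"
    return "unknown"


def read_raw(path) -> Acquisition:
    """Parse an MRSRAW1 file verbatim: no reordering, no scaling.

    Raises :class:`CorruptionError` on truncation or count mismatch and
    :class:`FormatError` on bad magic or malformed JSON.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(len(MAGIC))
        if magic != MAGIC:
            raise FormatError(f"{path}: not an MRSRAW1 file (bad magic {magic!r})")
        hlen = int.from_bytes(fh.read(8), "little")
        blob = fh.read(hlen)
        if len(blob) != hlen:
            raise CorruptionError(f"{path}: truncated header ({len(blob)} of {hlen} bytes)")
        try:
            header = json.loads(blob.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise FormatError(f"{path}: malformed JSON header: {exc}") from exc
        payload = fh.read()
    expected = header.get("payload_bytes")
    if expected is not None and len(payload) != expected:
        raise CorruptionError(
            f"{path}: payload truncated: expected {expected} bytes, got {len(payload)}"
        )
    samples = np.frombuffer(payload, dtype=np.complex64)
    acq = Acquisition(samples=samples, header=header)
    if samples.size != acq.declared_count():
        raise CorruptionError(
            f"{path}: header declares {acq.declared_count()} samples, payload holds {samples.size}"
        )
    return acq


def map_acquisition(acq: Acquisition) -> MrsDataset:
    """Map acquisition-ordered samples onto the regular (x, y, z, t, c) grid.

    A pure permutation: cartesian data is reshaped per the documented loop
    order; EPSI data is additionally de-interleaved (readout k and spectral
    sample swap loop positions) and the per-k delay tau is recorded in
    provenance for the reconstruction stage to consume.  Values are promoted
    to complex128 but never altered.
    """
    h = acq.header
    nx, ny, nz = h["dims"]
    ns, nc = h["n_points"], h["channels"]
    ordering = acq.ordering
    kind = ordering.get("kind", "cartesian")
    if kind == "cartesian":
        grid = acq.samples.reshape(nc, nz, ny, nx, ns).transpose(3, 2, 1, 4, 0)
    elif kind == "epsi":
        if ordering.get("readout_axis", 0) != 0:
            raise FormatError("unsupported acquisition: EPSI readout must be along x")
        grid = acq.samples.reshape(nc, nz, ny, ns, nx).transpose(4, 2, 1, 3, 0)
    else:
        raise FormatError(f"unsupported acquisition ordering {kind!r}")
    data = np.ascontiguousarray(grid, dtype=np.complex128)

    axis = SpectralAxis(
        n_points=ns,
        dwell=h["dwell"],
        sweep_width=1.0 / h["dwell"],
        transmitter_freq=h["f0"],
        ppm_ref=h.get("ppm_ref", 4.7),
        domain="time",
    )
    g = h.get("geometry", {})
    geometry = Geometry(
        origin=tuple(g.get("origin", (0.0, 0.0, 0.0))),
        spacing=tuple(g.get("spacing", (1.0, 1.0, 1.0))),
        orientation=tuple(g.get("orientation", (1, 0, 0, 0, 1, 0))),
        dims=(nx, ny, nz),
    )
    selection = None
    if h.get("selection"):
        selection = SelectionBox(
            center=tuple(h["selection"]["center"]), size=tuple(h["selection"]["size"])
        )
    bands = [
        SatBand(normal=tuple(b["normal"]), distance=b["distance"], thickness=b["thickness"])
        for b in h.get("sat_bands", [])
    ]
    ds = MrsDataset(
        data=data,
        spectral_axis=axis,
        geometry=geometry,
        spatial_domain=("kspace", "kspace", "kspace"),
        selection=selection,
        sat_bands=bands,
    )
    params: dict = {"ordering": kind}
    if kind == "epsi":
        params["readout_axis"] = ordering.get("readout_axis", 0)
        params["tau"] = ordering.get("tau", 0.0)
    return ds.evolve("map_acquisition", params)


def read_any(path) -> MrsDataset:
    """Factory dispatch: sniff, read, map.  The one entry point callers need."""
    fmt = sniff_format(path)
    if fmt == "mrsraw":
        return map_acquisition(read_raw(path))
    if fmt == "dicom_mrs":
        from . import dicom_io

        return dicom_io.read_dicom_mrs(path)
    raise FormatError(
        f"{path}: format {fmt!r} is not a spectroscopy input "
        "(supported: mrsraw, dicom_mrs)"
    )
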