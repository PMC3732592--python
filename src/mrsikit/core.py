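"""Core in-memory model for spectroscopic imaging data.

An MRSI acquisition is at minimum four-dimensional — three spatial axes plus a
spectral axis — and multichannel acquisitions add a coil dimension.  The
central container here, :class:`MrsDataset`, stores the full complex array
indexed ``(x, y, z, spectral, channel)`` together with the spectral axis
bookkeeping (:class:`SpectralAxis`), the spatial geometry in DICOM's LPS
patient coordinate frame (:class:`Geometry`), acquisition annotations
(PRESS selection box, sat bands) and an append-only provenance trail.

Conventions fixed here and relied on everywhere else:

* Frequency-domain spectra are stored fftshifted: the carrier (0 Hz offset)
  sits at index ``floor(N/2)``.
* ppm decreases with increasing spectral index (standard NMR display), so
  ``ppm(i) = ppm_ref + (floor(N/2) - i) * SW / (N * f0)``.
* Voxel indices are 0-based and address voxel centers; ``Geometry.origin`` is
  the LPS position of voxel ``(0, 0, 0)``'s center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import OutOfRangeError

__all__ = [
    "SpectralAxis",
    "Geometry",
    "SelectionBox",
    "SatBand",
    "MrsDataset",
    "MetaboliteMap",
    "ppm_to_index",
    "index_to_ppm",
    "validate_dataset",
]

Domain = Literal["time", "frequency"]
SpatialDomain = Literal["kspace", "image"]


@dataclass(frozen=True)
class SpectralAxis:
    """Spectral sampling parameters and all frequency/ppm/index arithmetic.

    Parameters
    ----------
    n_points : int
        Number of spectral samples N.
    dwell : float
        Seconds per sample (dwell time, Δt).
    sweep_width : float
        Spectral bandwidth SW in Hz; must equal 1/Δt.
    transmitter_freq : float
        Carrier frequency f0 in MHz.
    ppm_ref : float
        Chemical shift assigned to the carrier (0 Hz offset).  Defaults to
        4.7 ppm, the water resonance at body temperature.
    domain : {"time", "frequency"}
        Domain of the data this axis currently describes.
    """

    n_points: int
    dwell: float
    sweep_width: float
    transmitter_freq: float
    ppm_ref: float = 4.7
    domain: Domain = "time"

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError(f"n_points must be >= 1, got {self.n_points}")
        if self.transmitter_freq <= 0:
            raise ValueError("transmitter_freq must be positive (MHz)")
        if not math.isclose(self.sweep_width * self.dwell, 1.0, rel_tol=1e-9):
            raise ValueError(
                f"sweep_width * dwell must equal 1 (got {self.sweep_width * self.dwell!r})"
            )
        if self.domain not in ("time", "frequency"):
            raise ValueError(f"unknown domain {self.domain!r}")

    @property
    def hz_per_bin(self) -> float:
        return self.sweep_width / self.n_points

    @property
    def center_index(self) -> int:
        """Index of the carrier after fftshift: floor(N/2)."""
        return self.n_points // 2

    def bin_offset_hz(self) -> np.ndarray:
        """Frequency offset from the carrier of every bin, Hz, fftshifted order."""
        return (np.arange(self.n_points) - self.center_index) * self.hz_per_bin

    def ppm_span(self) -> tuple[float, float]:
        """(lowest, highest) ppm addressable on this axis at integer indices."""
        lo = index_to_ppm(self, self.n_points - 1)
        hi = index_to_ppm(self, 0)
        return lo, hi

    def with_domain(self, domain: Domain) -> "SpectralAxis":
        return replace(self, domain=domain)

    def times(self) -> np.ndarray:
        """Sample times n*Δt, seconds."""
        return np.arange(self.n_points) * self.dwell


@dataclass(frozen=True)
class Geometry:
    """Axis-aligned voxel grid placement in the LPS patient frame.

    ``orientation`` holds six direction cosines: the unit vector along
    increasing x (column index) followed by the unit vector along increasing
    y (row index), exactly as DICOM's Image Orientation (Patient) does.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    orientation: tuple[float, float, float, float, float, float] = (
        1.0, 0.0, 0.0, 0.0, 1.0, 0.0,
    )
    dims: tuple[int, int, int] = (1, 1, 1)

    @property
    def row_cosines(self) -> np.ndarray:
        return np.asarray(self.orientation[:3], dtype=float)

    @property
    def col_cosines(self) -> np.ndarray:
        return np.asarray(self.orientation[3:], dtype=float)

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.row_cosines, self.col_cosines)

    def violations(self) -> list[str]:
        out: list[str] = []
        r, c = self.row_cosines, self.col_cosines
        if abs(np.linalg.norm(r) - 1) > 1e-6 or abs(np.linalg.norm(c) - 1) > 1e-6:
            out.append("orientation: direction cosines are not unit length")
        elif abs(float(np.dot(r, c))) > 1e-6:
            out.append("orientation: row/column direction cosines are not orthogonal")
        if any(s <= 0 for s in self.spacing):
            out.append("spacing: components must be positive")
        if any(d < 1 for d in self.dims):
            out.append("dims: components must be positive integers")
        return out

    def voxel_center(self, i: int, j: int, k: int) -> np.ndarray:
        """LPS position of the center of voxel (i, j, k)."""
        o = np.asarray(self.origin, dtype=float)
        return (
            o
            + self.row_cosines * self.spacing[0] * i
            + self.col_cosines * self.spacing[1] * j
            + self.normal * self.spacing[2] * k
        )


@dataclass(frozen=True)
class SelectionBox:
    """PRESS volume localization: an axis-aligned excitation box (mm, LPS)."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def violations(self) -> list[str]:
        if any(s <= 0 for s in self.size):
            return ["selection: size components must be positive"]
        return []


@dataclass(frozen=True)
class SatBand:
    """A spatial saturation slab: plane normal, signed distance, thickness (mm)."""

    normal: tuple[float, float, float]
    distance: float
    thickness: float

    def violations(self) -> list[str]:
        out: list[str] = []
        if abs(np.linalg.norm(self.normal) - 1) > 1e-6:
            out.append("sat_band: normal is not unit length")
        if self.thickness <= 0:
            out.append("sat_band: thickness must be positive")
        return out


@dataclass
class MrsDataset:
    """Regular-grid spectroscopic dataset: the object every pipeline stage
    consumes and returns.

    ``data`` is complex, indexed ``(x, y, z, spectral, channel)``.  Operations
    never mutate a dataset in place; they return a copy with exactly one
    record appended to ``provenance``.
    """

    data: np.ndarray
    spectral_axis: SpectralAxis
    geometry: Geometry
    spatial_domain: tuple[SpatialDomain, SpatialDomain, SpatialDomain] = (
        "image", "image", "image",
    )
    selection: SelectionBox | None = None
    sat_bands: list[SatBand] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    @property
    def channel_count(self) -> int:
        return int(self.data.shape[4])

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(d) for d in self.data.shape[:3])  # type: ignore[return-value]

    def evolve(self, op: str, params: dict | None = None, **changes) -> "MrsDataset":
        """Copy of this dataset with ``changes`` applied and one provenance
        record ``{"op": op, "params": params}`` appended."""
        new = MrsDataset(
            data=changes.get("data", self.data),
            spectral_axis=changes.get("spectral_axis", self.spectral_axis),
            geometry=changes.get("geometry", self.geometry),
            spatial_domain=changes.get("spatial_domain", self.spatial_domain),
            selection=changes.get("selection", self.selection),
            sat_bands=list(changes.get("sat_bands", self.sat_bands)),
            provenance=list(self.provenance),
        )
        new.provenance.append({"op": op, "params": dict(params or {})})
        return new


@dataclass
class MetaboliteMap:
    """A real 3-D parameter map sharing the source dataset's spatial geometry."""

    values: np.ndarray
    geometry: Geometry
    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.shape != tuple(self.geometry.dims):
            raise ValueError(
                f"map shape {self.values.shape} / mask {self.mask.shape} must match "
                f"geometry dims {self.geometry.dims}"
            )


def ppm_to_index(axis: SpectralAxis, ppm: float) -> float:
    """Fractional spectral index of a chemical shift.

    Uses the fftshifted display convention ``ppm(i) = ppm_ref +
    (floor(N/2) - i) * SW / (N * f0)``: the carrier sits at floor(N/2) and ppm
    decreases as the index increases.

    Raises
    ------
    OutOfRangeError
        If ``ppm`` lies outside the axis span (the message names the span).
    """
    if axis.domain != "frequency":
        raise_domain("ppm_to_index", axis.domain)
    lo, hi = axis.ppm_span()
    if not (lo <= ppm <= hi):
        raise OutOfRangeError(
            f"ppm {ppm} outside axis range [{lo:.6g}, {hi:.6g}] ppm"
        )
    return axis.center_index - (ppm - axis.ppm_ref) * axis.n_points * axis.transmitter_freq / axis.sweep_width


def index_to_ppm(axis: SpectralAxis, index: float) -> float:
    """Chemical shift of a spectral index (inverse of :func:`ppm_to_index`)."""
    if isinstance(index, (int, np.integer)) and not (0 <= index < axis.n_points):
        raise OutOfRangeError(
            f"index {index} out of bounds for axis of {axis.n_points} points"
        )
    return axis.ppm_ref + (axis.center_index - index) * axis.sweep_width / (
        axis.n_points * axis.transmitter_freq
    )


def raise_domain(op: str, got: str) -> None:
    from .errors import DomainError

    raise DomainError(f"{op}: wrong domain {got!r}")


def validate_dataset(ds: MrsDataset) -> list[str]:
    """Check every container invariant; returns a list of violation strings.

    Violations are data, not exceptions: an empty list means the dataset is
    internally consistent.  The function is side-effect free.
    """
    out: list[str] = []
    if ds.data.ndim != 5:
        out.append(f"shape: data must be 5-D (x, y, z, spectral, channel), got {ds.data.ndim}-D")
        return out
    if tuple(ds.data.shape[:3]) != tuple(ds.geometry.dims):
        out.append(
            f"shape: spatial shape {tuple(ds.data.shape[:3])} != geometry.dims {tuple(ds.geometry.dims)}"
        )
    if ds.data.shape[3] != ds.spectral_axis.n_points:
        out.append(
            f"shape: spectral length {ds.data.shape[3]} != axis n_points {ds.spectral_axis.n_points}"
        )
    if ds.data.shape[4] < 1:
        out.append("shape: channel count must be >= 1")
    if not np.iscomplexobj(ds.data):
        out.append("dtype: data must be complex")
    out.extend(ds.geometry.violations())
    if ds.selection is not None:
        out.extend(ds.selection.violations())
    for band in ds.sat_bands:
        out.extend(band.violations())
    if any(d not in ("kspace", "image") for d in ds.spatial_domain):
        out.append(f"spatial_domain: unknown entries in {ds.spatial_domain}")
    return out
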