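"""Metabolite quantification: peak height / integrated area maps, noise
estimation, and masked ratio maps.

Quantification operates on reconstructed, single-channel, frequency-domain
spectra.  A :class:`PeakWindow` names a chemical-shift interval (e.g. choline
3.12-3.32 ppm) and selects whether the real part (phased spectra) or the
magnitude (after sum-of-squares combination, which discards phase) is
evaluated.  The headline product is the masked Cho/NAA ratio map: voxels
whose denominator fails an SNR gate ``den > k * sigma`` are masked out, which
in practice removes everything outside the PRESS excitation volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MetaboliteMap, MrsDataset, ppm_to_index
from .errors import DomainError, OutOfRangeError

__all__ = [
    "PeakWindow",
    "DEFAULT_WINDOWS",
    "peak_height_map",
    "peak_area_map",
    "estimate_noise",
    "ratio_map",
    "save_nifti",
]


@dataclass(frozen=True)
class PeakWindow:
    """Named ppm interval for peak evaluation; must span >= 2 spectral bins."""

    name: str
    ppm_lo: float
    ppm_hi: float
    mode: str = "real"

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError("require ppm_lo < ppm_hi")
        if self.mode not in ("real", "magnitude"):
            raise ValueError(f"unknown mode {self.mode!r}")


# standard in-vivo 1H windows (0.2 ppm around the textbook singlet shifts)
DEFAULT_WINDOWS = {
    "Cho": PeakWindow("Cho", 3.12, 3.32),
    "Cr": PeakWindow("Cr", 2.93, 3.13),
    "NAA": PeakWindow("NAA", 1.91, 2.11),
}


def _window_bins(ds: MrsDataset, lo_ppm: float, hi_ppm: float) -> tuple[int, int]:
    """Inclusive (first, last) bin index pair covered by a ppm interval.

    Remember ppm decreases with increasing index, so hi_ppm maps to the lower
    index.  Raises if the interval leaves the axis or covers < 2 bins.
    """
    axis = ds.spectral_axis
    i_lo = int(np.ceil(ppm_to_index(axis, hi_ppm)))
    i_hi = int(np.floor(ppm_to_index(axis, lo_ppm)))
    if i_hi - i_lo + 1 < 2:
        raise OutOfRangeError(
            f"ppm window ({lo_ppm}, {hi_ppm}) covers fewer than 2 spectral bins"
        )
    return i_lo, i_hi


def _check_quant_input(ds: MrsDataset, op: str) -> None:
    if ds.spectral_axis.domain != "frequency":
        raise DomainError(f"{op} requires frequency-domain spectra")
    if ds.channel_count != 1:
        raise ValueError(f"{op} requires single-channel data; combine coils first")


def _selected_part(ds: MrsDataset, w: PeakWindow, i_lo: int, i_hi: int) -> np.ndarray:
    block = ds.data[:, :, :, i_lo : i_hi + 1, 0]
    return block.real if w.mode == "real" else np.abs(block)


def peak_height_map(ds: MrsDataset, w: PeakWindow) -> MetaboliteMap:
    """Per-voxel maximum of the selected spectral part over the window."""
    _check_quant_input(ds, "peak_height_map")
    i_lo, i_hi = _window_bins(ds, w.ppm_lo, w.ppm_hi)
    values = _selected_part(ds, w, i_lo, i_hi).max(axis=3)
    return MetaboliteMap(
        values=values,
        geometry=ds.geometry,
        label=f"{w.name}_height",
        mask=np.ones(values.shape, dtype=bool),
    )


def peak_area_map(ds: MrsDataset, w: PeakWindow) -> MetaboliteMap:
    """Per-voxel Riemann sum of the selected part over the window, times the
    bin width in Hz."""
    _check_quant_input(ds, "peak_area_map")
    i_lo, i_hi = _window_bins(ds, w.ppm_lo, w.ppm_hi)
    values = _selected_part(ds, w, i_lo, i_hi).sum(axis=3) * ds.spectral_axis.hz_per_bin
    return MetaboliteMap(
        values=values,
        geometry=ds.geometry,
        label=f"{w.name}_area",
        mask=np.ones(values.shape, dtype=bool),
    )


def estimate_noise(
    ds: MrsDataset,
    region_ppm: tuple[float, float],
    windows: dict[str, PeakWindow] | None = None,
) -> np.ndarray:
    """Per-voxel noise: std of the real part over a signal-free ppm region.

    Refuses regions overlapping any configured metabolite window (default
    Cho/Cr/NAA) — a noise region containing signal would inflate sigma.
    """
    _check_quant_input(ds, "estimate_noise")
    lo, hi = sorted(region_ppm)
    windows = DEFAULT_WINDOWS if windows is None else windows
    for w in windows.values():
        if lo < w.ppm_hi and hi > w.ppm_lo:
            raise ValueError(
                f"noise region ({lo}, {hi}) ppm overlaps the {w.name} window "
                f"({w.ppm_lo}, {w.ppm_hi}) ppm"
            )
    i_lo, i_hi = _window_bins(ds, lo, hi)
    return ds.data[:, :, :, i_lo : i_hi + 1, 0].real.std(axis=3)


def ratio_map(
    numerator: MetaboliteMap,
    denominator: MetaboliteMap,
    noise_sigma,
    k_mask: float = 4.0,
    label: str | None = None,
) -> MetaboliteMap:
    """Masked voxelwise ratio of two maps sharing one geometry.

    A voxel is kept only where the denominator clears ``k_mask * sigma``
    (sigma may be scalar or a per-voxel array) and both inputs are unmasked;
    masked voxels get value 0.  When the inputs are Cho and NAA maps the
    label defaults to ``cho_naa_index``.
    """
    if numerator.geometry != denominator.geometry:
        raise ValueError("ratio_map requires maps with identical geometry")
    sigma = np.asarray(noise_sigma, dtype=float)
    keep = (
        numerator.mask
        & denominator.mask
        & (denominator.values > k_mask * sigma)
    )
    values = np.zeros_like(numerator.values)
    np.divide(numerator.values, denominator.values, out=values, where=keep)
    if label is None:
        is_cho_naa = numerator.label.startswith("Cho") and denominator.label.startswith("NAA")
        label = "cho_naa_index" if is_cho_naa else f"{numerator.label}_over_{denominator.label}"
    return MetaboliteMap(values=values, geometry=numerator.geometry, label=label, mask=keep)


def save_nifti(mmap: MetaboliteMap, path) -> None:
    """Export a map as NIfTI-1 for cross-tool 3-D analysis.

    The affine converts the LPS voxel grid into NIfTI's RAS+ world frame
    (x and y axes negated).
    """
    import nibabel as nib

    geo = mmap.geometry
    lps = np.eye(4)
    lps[:3, 0] = geo.row_cosines * geo.spacing[0]
    lps[:3, 1] = geo.col_cosines * geo.spacing[1]
    lps[:3, 2] = geo.normal * geo.spacing[2]
    lps[:3, 3] = np.asarray(geo.origin)
    ras = np.diag([-1.0, -1.0, 1.0, 1.0]) @ lps
    img = nib.Nifti1Image(mmap.values.astype(np.float32), ras)
    nib.save(img, str(path))
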