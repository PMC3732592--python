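"""Secondary-capture report rendering.

Produces the rasters a radiologist reviews: for each requested slice, an
anatomical grayscale underlay with a semi-transparent metabolite-map color
overlay, the MRSI voxel grid, per-voxel spectrum polylines, the PRESS
selection box outline (pure yellow) and sat band shading (purple), plus two
summary panels referencing the whole acquisition to the anatomy.  Rendering
is pure and deterministic — identical inputs give byte-identical rasters —
so reports can be regenerated and diffed.

Panels are fixed at 1024 x 1024 RGB.  Colors: spectra white, grid mid-gray,
selection box (255, 255, 0), sat bands blended (160, 32, 240).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .core import MetaboliteMap, MrsDataset
from .errors import DomainError

__all__ = ["ReportLayout", "render_slice_panel", "build_report", "save_png"]

PANEL_SIZE = 1024
YELLOW = (255, 255, 0)
PURPLE = (160, 32, 240)
GRID_GRAY = (90, 90, 90)
SPECTRUM_WHITE = (255, 255, 255)
OVERLAY_ALPHA = 0.45
SATBAND_ALPHA = 0.30


@dataclass
class ReportLayout:
    """What to draw: slices, voxel sub-rectangle, overlay, annotation toggles."""

    slices: list[int] = field(default_factory=lambda: [0])
    grid_window: tuple[int, int, int, int] | None = None  # (x_lo, x_hi, y_lo, y_hi) incl.
    overlay: MetaboliteMap | None = None
    overlay_bounds: tuple[float, float] | None = None
    show_selection: bool = True
    show_sat_bands: bool = True


def _heat_lut(t: np.ndarray) -> np.ndarray:
    """Heat-style colormap on t in [0, 1] -> (..., 3) uint8."""
    t = np.clip(t, 0.0, 1.0)
    r = np.clip(3 * t, 0, 1)
    g = np.clip(3 * t - 1, 0, 1)
    b = np.clip(3 * t - 2, 0, 1)
    return (np.stack([r, g, b], axis=-1) * 255).astype(np.uint8)


def _panel_mm_grid(ds: MrsDataset, slice_index: int, size: int):
    """LPS positions (mm) of every panel pixel center on the slice plane."""
    geo = ds.geometry
    nx, ny, _ = geo.dims
    # panel spans the voxel grid's outer edges in x (columns) and y (rows)
    x_mm = geo.origin[0] - geo.spacing[0] / 2 + (np.arange(size) + 0.5) * nx * geo.spacing[0] / size
    y_mm = geo.origin[1] - geo.spacing[1] / 2 + (np.arange(size) + 0.5) * ny * geo.spacing[1] / size
    z_mm = geo.origin[2] + slice_index * geo.spacing[2]
    return x_mm, y_mm, z_mm


def _resample_anatomical(anat_vol, anat_geo, x_mm, y_mm, z_mm) -> np.ndarray:
    """Nearest-neighbor sample of the anatomical volume on the panel grid.

    Assumes axis-aligned geometry (the package's stated processing scope).
    Returns a (ny_panel, nx_panel) float image in [0, 1]; out-of-volume
    pixels are 0.
    """
    ix = np.round((x_mm - anat_geo.origin[0]) / anat_geo.spacing[0]).astype(int)
    iy = np.round((y_mm - anat_geo.origin[1]) / anat_geo.spacing[1]).astype(int)
    iz = int(round((z_mm - anat_geo.origin[2]) / anat_geo.spacing[2]))
    out = np.zeros((y_mm.size, x_mm.size))
    ok_x = (ix >= 0) & (ix < anat_vol.shape[0])
    ok_y = (iy >= 0) & (iy < anat_vol.shape[1])
    if 0 <= iz < anat_vol.shape[2]:
        sub = anat_vol[np.clip(ix, 0, anat_vol.shape[0] - 1)][:, np.clip(iy, 0, anat_vol.shape[1] - 1), iz]
        sub = sub.T  # (ny_panel, nx_panel)
        sub = np.where(ok_y[:, None] & ok_x[None, :], sub, 0.0)
        vmax = sub.max()
        out = sub / vmax if vmax > 0 else sub
    return out


def _voxel_pixel_box(ds: MrsDataset, vx: int, vy: int, size: int) -> tuple[int, int, int, int]:
    """(px_lo, px_hi, py_lo, py_hi) pixel bounds of voxel (vx, vy) on the panel."""
    nx, ny, _ = ds.geometry.dims
    px_lo = int(vx * size / nx)
    px_hi = int((vx + 1) * size / nx)
    py_lo = int(vy * size / ny)
    py_hi = int((vy + 1) * size / ny)
    return px_lo, px_hi, py_lo, py_hi


def render_slice_panel(
    ds: MrsDataset,
    anatomical: tuple[np.ndarray, object] | None,
    layout: ReportLayout,
    slice_index: int,
    size: int = PANEL_SIZE,
) -> np.ndarray:
    """Render one slice to an (size, size, 3) uint8 raster.

    Requires reconstructed single-channel frequency-domain data; raises on a
    slice index outside the volume.
    """
    if ds.spectral_axis.domain != "frequency":
        raise DomainError("render_slice_panel requires frequency-domain spectra")
    if ds.channel_count != 1:
        raise ValueError("render_slice_panel requires single-channel data")
    nx, ny, nz = ds.geometry.dims
    if not (0 <= slice_index < nz):
        raise IndexError(f"slice {slice_index} outside volume of {nz} slices")

    x_mm, y_mm, z_mm = _panel_mm_grid(ds, slice_index, size)
    canvas = np.zeros((size, size, 3), dtype=float)
    if anatomical is not None:
        vol, geo = anatomical
        gray = _resample_anatomical(np.asarray(vol, dtype=float), geo, x_mm, y_mm, z_mm)
        canvas[:] = (gray * 255)[:, :, None]

    # metabolite-map color overlay, blended only inside unmasked voxels
    if layout.overlay is not None:
        ov = layout.overlay
        if layout.overlay_bounds is not None:
            vmin, vmax = layout.overlay_bounds
        else:
            vals = ov.values[ov.mask]
            vmin, vmax = (float(vals.min()), float(vals.max())) if vals.size else (0.0, 1.0)
        span = vmax - vmin if vmax > vmin else 1.0
        for vx in range(nx):
            for vy in range(ny):
                if not ov.mask[vx, vy, slice_index]:
                    continue
                color = _heat_lut(np.array((ov.values[vx, vy, slice_index] - vmin) / span))
                px_lo, px_hi, py_lo, py_hi = _voxel_pixel_box(ds, vx, vy, size)
                block = canvas[py_lo:py_hi, px_lo:px_hi]
                canvas[py_lo:py_hi, px_lo:px_hi] = (
                    (1 - OVERLAY_ALPHA) * block + OVERLAY_ALPHA * color.astype(float)
                )

    # sat band shading: purple wherever a slab intersects the panel plane
    if layout.show_sat_bands and ds.sat_bands:
        xx, yy = np.meshgrid(x_mm, y_mm)  # (size, size), row = y
        for band in ds.sat_bands:
            n = np.asarray(band.normal, dtype=float)
            proj = xx * n[0] + yy * n[1] + z_mm * n[2]
            inside = np.abs(proj - band.distance) <= band.thickness / 2
            canvas[inside] = (
                (1 - SATBAND_ALPHA) * canvas[inside] + SATBAND_ALPHA * np.array(PURPLE, dtype=float)
            )

    img = Image.fromarray(np.clip(canvas, 0, 255).astype(np.uint8))
    draw = ImageDraw.Draw(img)

    win = layout.grid_window or (0, nx - 1, 0, ny - 1)
    x_lo_v, x_hi_v, y_lo_v, y_hi_v = win

    # voxel grid lines over the window
    for vx in range(x_lo_v, x_hi_v + 2):
        px = int(vx * size / nx)
        py0 = int(y_lo_v * size / ny)
        py1 = int((y_hi_v + 1) * size / ny)
        draw.line([(px, py0), (px, py1)], fill=GRID_GRAY, width=1)
    for vy in range(y_lo_v, y_hi_v + 2):
        py = int(vy * size / ny)
        px0 = int(x_lo_v * size / nx)
        px1 = int((x_hi_v + 1) * size / nx)
        draw.line([(px0, py), (px1, py)], fill=GRID_GRAY, width=1)

    # per-voxel spectrum polylines (real part, panel-global scaling)
    spectra = ds.data[x_lo_v : x_hi_v + 1, y_lo_v : y_hi_v + 1, slice_index, :, 0].real
    peak = np.max(np.abs(spectra)) if spectra.size else 0.0
    if peak > 0:
        n_pts = spectra.shape[-1]
        for vx in range(x_lo_v, x_hi_v + 1):
            for vy in range(y_lo_v, y_hi_v + 1):
                px_lo, px_hi, py_lo, py_hi = _voxel_pixel_box(ds, vx, vy, size)
                w = px_hi - px_lo - 2
                h = py_hi - py_lo - 2
                if w < 4 or h < 4:
                    continue
                y_val = spectra[vx - x_lo_v, vy - y_lo_v]
                ys = py_hi - 1 - ((y_val / peak) * 0.5 + 0.5) * h
                xs = px_lo + 1 + np.arange(n_pts) * (w / max(n_pts - 1, 1))
                draw.line(
                    [(float(a), float(b)) for a, b in zip(xs, ys)],
                    fill=SPECTRUM_WHITE,
                    width=1,
                )

    # PRESS selection box outline in pure yellow
    if layout.show_selection and ds.selection is not None:
        geo = ds.geometry
        cz = ds.selection.center[2]
        if abs(z_mm - cz) <= ds.selection.size[2] / 2:
            half = np.asarray(ds.selection.size[:2]) / 2
            lo_mm = np.asarray(ds.selection.center[:2]) - half
            hi_mm = np.asarray(ds.selection.center[:2]) + half
            ext_x = nx * geo.spacing[0]
            ext_y = ny * geo.spacing[1]
            x0 = (lo_mm[0] - (geo.origin[0] - geo.spacing[0] / 2)) / ext_x * size
            x1 = (hi_mm[0] - (geo.origin[0] - geo.spacing[0] / 2)) / ext_x * size
            y0 = (lo_mm[1] - (geo.origin[1] - geo.spacing[1] / 2)) / ext_y * size
            y1 = (hi_mm[1] - (geo.origin[1] - geo.spacing[1] / 2)) / ext_y * size
            draw.rectangle([x0, y0, x1, y1], outline=YELLOW, width=3)

    return np.asarray(img, dtype=np.uint8)


def _montage(panels: list[np.ndarray], size: int = PANEL_SIZE) -> np.ndarray:
    """Tile sub-panels into one size x size raster (row-major)."""
    n = len(panels)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    cell = size // max(cols, rows)
    out = np.zeros((size, size, 3), dtype=np.uint8)
    for i, p in enumerate(panels):
        r, c = divmod(i, cols)
        im = Image.fromarray(p).resize((cell, cell), Image.NEAREST)
        out[r * cell : (r + 1) * cell, c * cell : (c + 1) * cell] = np.asarray(im)
    return out


def build_report(
    ds: MrsDataset,
    anatomical,
    maps: list[MetaboliteMap],
    layout: ReportLayout,
    out_stem,
) -> list:
    """Render the full report and encode it as a Secondary Capture series.

    One panel per requested slice plus two summary panels: an acquisition
    overview (all slices, grid + selection, no overlay) and an overlay
    overview (all slices with the first map).  Returns the written paths —
    len(layout.slices) + 2 instances sharing one series.
    """
    from . import dicom_io

    if not layout.slices:
        raise ValueError("report layout requests no slices")
    panels = [
        render_slice_panel(ds, anatomical, layout, s) for s in layout.slices
    ]
    nz = ds.geometry.dims[2]
    plain = ReportLayout(
        slices=list(range(nz)), overlay=None,
        show_selection=layout.show_selection, show_sat_bands=layout.show_sat_bands,
    )
    overview = _montage([render_slice_panel(ds, anatomical, plain, z) for z in range(nz)])
    with_overlay = ReportLayout(
        slices=list(range(nz)),
        overlay=layout.overlay if layout.overlay is not None else (maps[0] if maps else None),
        overlay_bounds=layout.overlay_bounds,
        show_selection=layout.show_selection,
        show_sat_bands=layout.show_sat_bands,
    )
    overlay_view = _montage(
        [render_slice_panel(ds, anatomical, with_overlay, z) for z in range(nz)]
    )
    rasters = panels + [overview, overlay_view]
    return dicom_io.write_secondary_capture(rasters, out_stem)


def save_png(raster: np.ndarray, path) -> None:
    Image.fromarray(raster).save(str(path), format="PNG")
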