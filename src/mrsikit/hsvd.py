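"""HSVD: Hankel singular value decomposition of FIDs.

Models a time-domain signal as a sum of K damped complex exponentials

    x[n] = sum_k a_k * exp(i*phi_k) * z_k^n,   z_k = exp((i*2*pi*f_k - d_k) * dt)

by exploiting the shift-invariance of the signal subspace of its Hankel
matrix.  The canonical use in proton MRSI is residual-water / baseline
removal: fit components per voxel, then subtract every component whose
frequency falls inside a chemical-shift band (e.g. 4.2-5.2 ppm around water)
from the FID, leaving metabolite resonances untouched.

Algorithm: build the L x (N-L+1) Hankel matrix H[i, j] = x[i+j] with
L = floor(N/2); SVD; keep the top-K left singular vectors U_K; solve the
least-squares shift-invariance equation U_K^top Z = U_K^bottom via
pseudo-inverse; the eigenvalues z_k of Z give frequencies angle(z_k)/(2*pi*dt)
and damping rates -ln|z_k|/dt; complex amplitudes follow from a linear
least-squares fit of x[n] on the z_k^n basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MrsDataset, SpectralAxis
from .errors import OutOfRangeError

__all__ = ["SpectralComponent", "HsvdOptions", "hsvd_fit", "model_fid", "hsvd_filter"]

_ZERO_THRESHOLD = 1e-12  # amplitudes below this fraction of ||x||_inf are dropped


@dataclass(frozen=True)
class SpectralComponent:
    """One damped complex exponential recovered from an FID.

    frequency: Hz offset from the carrier; damping: decay rate in 1/s
    (positive = decaying); amplitude >= 0; phase in (-pi, pi].
    """

    frequency: float
    damping: float
    amplitude: float
    phase: float

    def ppm(self, axis: SpectralAxis) -> float:
        """Chemical shift of this component on the given axis."""
        return axis.ppm_ref - self.frequency / axis.transmitter_freq


@dataclass(frozen=True)
class HsvdOptions:
    model_order: int = 25
    hankel_rows: int | None = None   # default floor(N/2)
    discard_growing: bool = True     # drop |z| > 1 components before subtraction

    def rows_for(self, n: int) -> int:
        return self.hankel_rows if self.hankel_rows is not None else n // 2


def hsvd_fit(
    fid: np.ndarray, axis: SpectralAxis, opts: HsvdOptions = HsvdOptions()
) -> list[SpectralComponent]:
    """Decompose one FID into damped complex exponentials.

    Returns components sorted by descending amplitude.  An (effectively)
    all-zero FID yields an empty list.  Raises ``ValueError`` when the model
    order is too large for the signal length (N must be >= 2K).
    """
    x = np.asarray(fid, dtype=complex).ravel()
    n = x.size
    k_order = opts.model_order
    length = opts.rows_for(n)
    if n < 2 * k_order or k_order > min(length, n - length + 1):
        raise ValueError(
            f"model order {k_order} too large for {n}-point signal "
            f"(need N >= 2K and K <= min(L, N-L+1))"
        )
    scale = float(np.max(np.abs(x))) if n else 0.0
    if scale == 0.0:
        return []

    cols = n - length + 1
    idx = np.arange(length)[:, None] + np.arange(cols)[None, :]
    hankel = x[idx]
    u, s, _ = np.linalg.svd(hankel, full_matrices=False)
    uk = u[:, :k_order]
    # shift invariance: rows 1..L-1 of U_K = rows 0..L-2 of U_K times Z
    z_mat = np.linalg.pinv(uk[:-1, :]) @ uk[1:, :]
    z = np.linalg.eigvals(z_mat)
    z = z[np.abs(z) > _ZERO_THRESHOLD]

    dt = axis.dwell
    powers = z[None, :] ** np.arange(n)[:, None]
    coeff, *_ = np.linalg.lstsq(powers, x, rcond=None)

    comps = []
    for zk, ck in zip(z, coeff):
        amp = abs(ck)
        if amp < _ZERO_THRESHOLD * scale:
            continue
        comps.append(
            SpectralComponent(
                frequency=float(np.angle(zk) / (2 * np.pi * dt)),
                damping=float(-np.log(np.abs(zk)) / dt),
                amplitude=float(amp),
                phase=float(np.angle(ck)),
            )
        )
    comps.sort(key=lambda c: -c.amplitude)
    return comps


def model_fid(components: list[SpectralComponent], axis: SpectralAxis) -> np.ndarray:
    """Time-domain signal of a component list on the axis' sample grid."""
    t = axis.times()
    out = np.zeros(axis.n_points, dtype=complex)
    for c in components:
        out += (
            c.amplitude
            * np.exp(1j * c.phase)
            * np.exp((1j * 2 * np.pi * c.frequency - c.damping) * t)
        )
    return out


def hsvd_filter(
    ds: MrsDataset,
    band_ppm: tuple[float, float],
    opts: HsvdOptions = HsvdOptions(),
) -> MrsDataset:
    """Band-selective removal: subtract fitted components inside a ppm band.

    Operates per voxel and channel on time-domain data.  Growing components
    (|z| > 1) are discarded before subtraction when ``opts.discard_growing``.
    The provenance record carries the removed-component count per voxel.
    """
    from .core import raise_domain

    if ds.spectral_axis.domain != "time":
        raise_domain("hsvd_filter", ds.spectral_axis.domain)
    lo, hi = sorted(band_ppm)
    axis = ds.spectral_axis
    span_lo = axis.ppm_ref - axis.sweep_width / 2 / axis.transmitter_freq
    span_hi = axis.ppm_ref + axis.sweep_width / 2 / axis.transmitter_freq
    if hi < span_lo or lo > span_hi:
        raise OutOfRangeError(
            f"band ({lo}, {hi}) ppm lies outside the axis span "
            f"[{span_lo:.6g}, {span_hi:.6g}] ppm"
        )
    if lo == hi:
        return ds.evolve("hsvd_filter", {"band_ppm": [lo, hi], "removed": []})

    data = np.array(ds.data)
    nx, ny, nz, _, nc = data.shape
    removed = np.zeros((nx, ny, nz, nc), dtype=int)
    fit_axis = axis.with_domain("time")
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                for ic in range(nc):
                    fid = data[ix, iy, iz, :, ic]
                    if not np.any(fid):
                        continue
                    comps = hsvd_fit(fid, fit_axis, opts)
                    if opts.discard_growing:
                        comps = [c for c in comps if c.damping >= 0]
                    inside = [c for c in comps if lo <= c.ppm(axis) <= hi]
                    if inside:
                        data[ix, iy, iz, :, ic] = fid - model_fid(inside, fit_axis)
                        removed[ix, iy, iz, ic] = len(inside)
    return ds.evolve(
        "hsvd_filter",
        {
            "band_ppm": [lo, hi],
            "model_order": opts.model_order,
            "removed_per_voxel": removed.ravel().tolist(),
            "removed_total": int(removed.sum()),
        },
        data=data,
    )
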