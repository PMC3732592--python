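"""Reconstruction and preprocessing chain.

Operations: time-domain apodization and zero filling, centered spatial inverse
DFT, spectral FFT/IFFT, EPSI linear phase (sampling delay) correction, sum-of-
squares coil combination, and zero/first-order phase correction with a simple
automatic zero-order search.

Fixed conventions (the synthetic forward model round-trips exactly under
them):

* spatial reconstruction is ``ifftn(ifftshift(kspace))`` with the usual 1/N
  scaling per axis, so k-space is the centered forward DFT of the image;
* the spectral FFT is ``fftshift(fft(fid))`` — the carrier lands on index
  ``floor(N/2)`` and the bin at index i sits at offset ``(i - floor(N/2)) *
  SW / N`` Hz.

Every operation returns a new dataset with exactly one provenance record
appended and never mutates its input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .core import MrsDataset, ppm_to_index
from .errors import DomainError

__all__ = [
    "PhaseParams",
    "ApodizationSpec",
    "apodize",
    "zero_fill",
    "spatial_recon",
    "spectral_fft",
    "spectral_ifft",
    "epsi_phase_correct",
    "combine_coils",
    "phase_correct",
    "auto_phase0",
]


@dataclass(frozen=True)
class PhaseParams:
    """Zero-order phase phi0 (radians) and first-order phase phi1 (radians
    across the full spectral width), applied about ``pivot``."""

    phi0: float = 0.0
    phi1: float = 0.0
    pivot: int = 0


@dataclass(frozen=True)
class ApodizationSpec:
    """Time-domain line broadening window: shape + broadening L in Hz.

    ``lorentzian`` multiplies the FID by ``exp(-pi*L*t)`` (adds L Hz to a
    Lorentzian FWHM); ``gaussian`` uses ``exp(-(pi*L*t)^2 / (4 ln 2))`` (a
    Gaussian of FWHM L after transform).
    """

    shape: str = "lorentzian"
    broadening: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown apodization shape {self.shape!r}")
        if self.broadening < 0:
            raise ValueError("broadening must be >= 0 Hz")


def _require_spectral(ds: MrsDataset, domain: str, op: str) -> None:
    if ds.spectral_axis.domain != domain:
        raise DomainError(
            f"{op} requires {domain}-domain spectral data, got {ds.spectral_axis.domain!r}"
        )


def apodize(ds: MrsDataset, spec: ApodizationSpec) -> MrsDataset:
    """Multiply every FID by the apodization window (time domain only)."""
    _require_spectral(ds, "time", "apodize")
    t = ds.spectral_axis.times()
    if spec.shape == "lorentzian":
        w = np.exp(-np.pi * spec.broadening * t)
    else:
        w = np.exp(-((np.pi * spec.broadening * t) ** 2) / (4 * math.log(2)))
    data = ds.data * w[None, None, None, :, None]
    return ds.evolve("apodize", {"shape": spec.shape, "broadening": spec.broadening}, data=data)


def zero_fill(ds: MrsDataset, target_points: int) -> MrsDataset:
    """Extend each FID with zeros to ``target_points`` samples.

    Dwell and sweep width are unchanged; only the number of points grows, so
    the spectrum is interpolated onto a finer ppm grid.
    """
    _require_spectral(ds, "time", "zero_fill")
    n = ds.spectral_axis.n_points
    if target_points < n:
        raise ValueError(f"target_points {target_points} < current length {n}")
    shape = list(ds.data.shape)
    shape[3] = target_points
    data = np.zeros(shape, dtype=ds.data.dtype)
    data[:, :, :, :n, :] = ds.data
    axis = ds.spectral_axis.__class__(
        n_points=target_points,
        dwell=ds.spectral_axis.dwell,
        sweep_width=ds.spectral_axis.sweep_width,
        transmitter_freq=ds.spectral_axis.transmitter_freq,
        ppm_ref=ds.spectral_axis.ppm_ref,
        domain="time",
    )
    return ds.evolve("zero_fill", {"target_points": target_points}, data=data, spectral_axis=axis)


def spatial_recon(ds: MrsDataset) -> MrsDataset:
    """Centered inverse spatial DFT: k-space -> image space.

    ``ifftshift`` then ``ifftn`` per spectral sample and channel, 1/N scaling
    per axis; no shift after the transform (voxel 0 is the grid corner).
    """
    if any(d != "kspace" for d in ds.spatial_domain):
        raise DomainError(f"spatial_recon requires all-kspace axes, got {ds.spatial_domain}")
    data = np.fft.ifftn(np.fft.ifftshift(ds.data, axes=(0, 1, 2)), axes=(0, 1, 2))
    return ds.evolve("spatial_recon", {}, data=data, spatial_domain=("image", "image", "image"))


def spectral_fft(ds: MrsDataset, first_point_half: bool = False) -> MrsDataset:
    """Forward spectral FFT with fftshift: time -> frequency domain.

    ``first_point_half`` scales the first FID sample by 0.5 before the
    transform.  The DFT of a one-sided decaying signal carries a flat
    baseline offset of x[0]/2 across every bin; halving the first point is
    the standard correction and matters whenever absolute peak amplitudes
    are quantified.  Off by default so fft/ifft stay exact inverses.
    """
    _require_spectral(ds, "time", "spectral_fft")
    src = ds.data
    if first_point_half:
        src = src.copy()
        src[:, :, :, 0, :] *= 0.5
    data = np.fft.fftshift(np.fft.fft(src, axis=3), axes=3)
    return ds.evolve(
        "spectral_fft",
        {"first_point_half": first_point_half},
        data=data,
        spectral_axis=ds.spectral_axis.with_domain("frequency"),
    )


def spectral_ifft(ds: MrsDataset) -> MrsDataset:
    """Exact inverse of :func:`spectral_fft`: frequency -> time domain."""
    _require_spectral(ds, "frequency", "spectral_ifft")
    data = np.fft.ifft(np.fft.ifftshift(ds.data, axes=3), axis=3)
    return ds.evolve(
        "spectral_ifft", {}, data=data, spectral_axis=ds.spectral_axis.with_domain("time")
    )


def epsi_phase_correct(ds: MrsDataset, axis: int, tau: float) -> MrsDataset:
    """Undo the per-k sampling delay of an echo-planar (EPSI) readout.

    The k-th position along ``axis`` was acquired ``k * tau`` seconds late;
    its spectrum is multiplied by ``exp(+i*2*pi*f*k*tau)`` with f the offset
    frequency of each bin, cancelling the delay-induced linear phase.
    Requires frequency-domain spectra with the EPSI axis still in k-space.
    """
    _require_spectral(ds, "frequency", "epsi_phase_correct")
    if ds.spatial_domain[axis] != "kspace":
        raise DomainError("epsi_phase_correct requires the EPSI axis in k-space")
    sax = ds.spectral_axis
    f = sax.bin_offset_hz()
    nk = ds.data.shape[axis]
    params: dict = {"axis": axis, "tau": tau}
    if abs(tau) * sax.sweep_width * (nk - 1) >= 1.0:
        params["warning"] = "wraparound regime: tau * SW * k_max >= 1"
    k = np.arange(nk)
    ramp = np.exp(1j * 2 * np.pi * np.outer(k, f) * tau)  # (nk, n_points)
    shape = [1, 1, 1, ds.spectral_axis.n_points, 1]
    shape[axis] = nk
    data = ds.data * ramp.reshape(shape)
    return ds.evolve("epsi_phase_correct", params, data=data)


def combine_coils(ds: MrsDataset) -> MrsDataset:
    """Sum-of-squares coil combination: pointwise sqrt(sum_c |v_c|^2).

    Phase-insensitive by construction (invariant to any per-channel phase
    rotation); the output is stored as complex with zero imaginary part and
    flagged magnitude-only in provenance.
    """
    combined = np.sqrt(np.sum(np.abs(ds.data) ** 2, axis=4, keepdims=True))
    data = combined.astype(np.complex128)
    return ds.evolve(
        "combine_coils",
        {"method": "sum_of_squares", "channels_in": ds.channel_count, "phase": "discarded"},
        data=data,
    )


def phase_correct(ds: MrsDataset, p: PhaseParams) -> MrsDataset:
    """Apply zero/first-order phase: S'[i] = S[i] * exp(i*(phi0 + phi1*(i - pivot)/N))."""
    _require_spectral(ds, "frequency", "phase_correct")
    n = ds.spectral_axis.n_points
    if not (0 <= p.pivot < n):
        raise ValueError(f"pivot {p.pivot} outside [0, {n})")
    i = np.arange(n)
    ramp = np.exp(1j * (p.phi0 + p.phi1 * (i - p.pivot) / n))
    data = ds.data * ramp[None, None, None, :, None]
    return ds.evolve(
        "phase_correct", {"phi0": p.phi0, "phi1": p.phi1, "pivot": p.pivot}, data=data
    )


def auto_phase0(ds: MrsDataset, window_ppm: tuple[float, float]) -> PhaseParams:
    """Zero-order phase that maximizes the integrated real part over a window.

    A 1-degree grid scan brackets the optimum, then a bounded scalar search
    refines it to 0.01 degrees.  The result is amplitude-scale invariant.
    Returns PhaseParams with phi1 = 0.
    """
    _require_spectral(ds, "frequency", "auto_phase0")
    lo, hi = sorted(window_ppm)
    axis = ds.spectral_axis
    i_lo = int(np.ceil(ppm_to_index(axis, hi)))
    i_hi = int(np.floor(ppm_to_index(axis, lo)))
    if i_hi < i_lo:
        raise ValueError(f"ppm window ({lo}, {hi}) maps to an empty bin range")
    window = ds.data[:, :, :, i_lo : i_hi + 1, :].sum()

    def score(phi: float) -> float:
        return -float(np.real(window * np.exp(1j * phi)))

    grid = np.deg2rad(np.arange(-180.0, 180.0, 1.0))
    best = grid[int(np.argmin([score(g) for g in grid]))]
    res = minimize_scalar(
        score,
        bounds=(best - np.deg2rad(1.5), best + np.deg2rad(1.5)),
        method="bounded",
        options={"xatol": np.deg2rad(0.01)},
    )
    phi0 = float(np.arctan2(np.sin(res.x), np.cos(res.x)))  # wrap to (-pi, pi]
    return PhaseParams(phi0=phi0, phi1=0.0, pivot=axis.center_index)
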