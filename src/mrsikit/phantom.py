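"""Synthetic multi-voxel, multi-channel MRSI acquisition generator.

The forward model is the standard sum of damped complex exponentials: metabolite
``m`` with chemical shift ``ppm_m``, phase ``phi_m`` and Lorentzian full width
at half maximum ``d_m`` (Hz) contributes

    a_m * exp(i*phi_m) * exp((i*2*pi*f_m - pi*d_m) * n * dt),
    f_m = (ppm_ref - ppm_m) * f0       [Hz offset from the carrier]

to the voxel FID.  Amplitudes vary spatially through ellipsoidal regions with
per-metabolite scale factors, channels apply smooth complex sensitivity
profiles, and each spectral sample is forward-DFT'd to k-space (centered
convention) so a centered inverse DFT recovers the voxel signal exactly.
Optionally the readout axis is echo-planar (EPSI) ordered with a per-k
circular time shift of ``k * epsi_tau`` seconds applied to the FID.  Complex
Gaussian noise of a given standard deviation is added in k-space; a single
integer seed makes the output byte-reproducible.

The on-disk product is the documented MRSRAW1 raw format (see
:mod:`mrsikit.vendor_io`) plus a JSON ground-truth sidecar holding the exact
per-voxel metabolite amplitudes and channel sensitivities.  A matched
anatomical DICOM MR Image series can be produced for spatial referencing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import Geometry, SelectionBox, SatBand, SpectralAxis

__all__ = [
    "MetaboliteSpec",
    "EllipsoidRegion",
    "PhantomConfig",
    "GroundTruth",
    "default_metabolites",
    "default_regions",
    "simulate_voxel_fid",
    "build_phantom_arrays",
    "generate_phantom",
    "generate_anatomical",
]


@dataclass(frozen=True)
class MetaboliteSpec:
    """One spectral line: name, chemical shift, linewidth, amplitude, phase.

    ``damping`` is the Lorentzian FWHM in Hz; the FID component decays as
    ``exp(-pi * damping * t)`` so the magnitude spectrum has exactly that
    full width at half maximum.
    """

    name: str
    ppm: float
    damping: float
    base_amplitude: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.damping <= 0:
            raise ValueError("damping (FWHM, Hz) must be positive")


@dataclass(frozen=True)
class EllipsoidRegion:
    """Ellipsoidal support region in voxel coordinates with per-metabolite scales."""

    name: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    scales: dict[str, float] = field(default_factory=dict)


def default_metabolites() -> list[MetaboliteSpec]:
    """Textbook in-vivo 1H singlets: NAA, Cr, Cho plus residual water."""
    return [
        MetaboliteSpec("NAA", ppm=2.01, damping=1.5, base_amplitude=1.0),
        MetaboliteSpec("Cr", ppm=3.03, damping=1.5, base_amplitude=1.0),
        MetaboliteSpec("Cho", ppm=3.22, damping=1.5, base_amplitude=1.0),
        MetaboliteSpec("water", ppm=4.70, damping=4.0, base_amplitude=5.0),
    ]


def default_regions() -> list[EllipsoidRegion]:
    """Two tissue blocks: 'normal' Cho:NAA = 0.5 and 'tumor' Cho:NAA = 2.0."""
    return [
        EllipsoidRegion(
            "normal",
            center=(4.5, 7.5, 1.5),
            semi_axes=(3.5, 5.5, 1.6),
            scales={"NAA": 2.0, "Cr": 1.0, "Cho": 1.0, "water": 1.0},
        ),
        EllipsoidRegion(
            "tumor",
            center=(11.5, 7.5, 1.5),
            semi_axes=(3.0, 5.0, 1.6),
            scales={"NAA": 1.0, "Cr": 1.2, "Cho": 2.0, "water": 1.0},
        ),
    ]


@dataclass
class PhantomConfig:
    """Everything needed to synthesize one acquisition deterministically."""

    dims: tuple[int, int, int] = (16, 16, 4)
    n_points: int = 512
    dwell: float = 1e-3          # s -> SW = 1000 Hz
    f0: float = 127.7            # MHz (3 T proton)
    ppm_ref: float = 4.7
    metabolites: list[MetaboliteSpec] = field(default_factory=default_metabolites)
    regions: list[EllipsoidRegion] = field(default_factory=default_regions)
    channels: int = 1
    sensitivity_floor: float = 0.3
    sensitivity_width: float = 0.6   # Gaussian sigma as fraction of grid extent
    noise_sigma: float = 0.0
    ordering: str = "cartesian"      # or "epsi"
    epsi_axis: int = 0
    epsi_tau: float = 0.0            # s per k-step
    seed: int = 0
    origin: tuple[float, float, float] = (-75.0, -75.0, -20.0)
    spacing: tuple[float, float, float] = (10.0, 10.0, 10.0)

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must all be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.ordering not in ("cartesian", "epsi"):
            raise ValueError(f"unknown ordering {self.ordering!r}")

    @property
    def sweep_width(self) -> float:
        return 1.0 / self.dwell

    def spectral_axis(self) -> SpectralAxis:
        return SpectralAxis(
            n_points=self.n_points,
            dwell=self.dwell,
            sweep_width=self.sweep_width,
            transmitter_freq=self.f0,
            ppm_ref=self.ppm_ref,
            domain="time",
        )

    def geometry(self) -> Geometry:
        return Geometry(origin=self.origin, spacing=self.spacing, dims=self.dims)

    def selection_box(self) -> SelectionBox:
        """PRESS box covering the central 3/4 of the grid in-plane, full depth."""
        g = self.geometry()
        extent = np.array(self.dims) * np.array(self.spacing)
        center = np.array(self.origin) + (np.array(self.dims) - 1) / 2.0 * np.array(self.spacing)
        size = extent * np.array([0.75, 0.75, 1.0])
        return SelectionBox(center=tuple(center), size=tuple(size))

    def sat_bands(self) -> list[SatBand]:
        ext_x = self.dims[0] * self.spacing[0]
        return [
            SatBand(normal=(1.0, 0.0, 0.0), distance=self.origin[0] + ext_x + 5.0, thickness=20.0),
            SatBand(normal=(-1.0, 0.0, 0.0), distance=-(self.origin[0] - 25.0), thickness=20.0),
        ]


@dataclass
class GroundTruth:
    """Exact forward-model inputs echoed back for recovery tests."""

    amplitudes: np.ndarray        # (x, y, z, n_metabolites)
    metabolite_names: list[str]
    sensitivities: np.ndarray     # (x, y, 1, channels) complex
    region_ratios: dict[str, float]   # region name -> Cho/NAA amplitude ratio
    config: PhantomConfig

    def to_json(self) -> str:
        payload = {
            "metabolite_names": self.metabolite_names,
            "amplitudes": self.amplitudes.tolist(),
            "sensitivities_real": self.sensitivities.real.tolist(),
            "sensitivities_imag": self.sensitivities.imag.tolist(),
            "region_ratios": self.region_ratios,
            "config": _config_dict(self.config),
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        cfgd = d["config"]
        cfg = PhantomConfig(
            dims=tuple(cfgd["dims"]),
            n_points=cfgd["n_points"],
            dwell=cfgd["dwell"],
            f0=cfgd["f0"],
            ppm_ref=cfgd["ppm_ref"],
            metabolites=[MetaboliteSpec(**m) for m in cfgd["metabolites"]],
            regions=[
                EllipsoidRegion(
                    r["name"], tuple(r["center"]), tuple(r["semi_axes"]), r["scales"]
                )
                for r in cfgd["regions"]
            ],
            channels=cfgd["channels"],
            sensitivity_floor=cfgd["sensitivity_floor"],
            sensitivity_width=cfgd["sensitivity_width"],
            noise_sigma=cfgd["noise_sigma"],
            ordering=cfgd["ordering"],
            epsi_axis=cfgd["epsi_axis"],
            epsi_tau=cfgd["epsi_tau"],
            seed=cfgd["seed"],
            origin=tuple(cfgd["origin"]),
            spacing=tuple(cfgd["spacing"]),
        )
        sens = np.asarray(d["sensitivities_real"]) + 1j * np.asarray(d["sensitivities_imag"])
        return cls(
            amplitudes=np.asarray(d["amplitudes"]),
            metabolite_names=d["metabolite_names"],
            sensitivities=sens,
            region_ratios=d["region_ratios"],
            config=cfg,
        )


def _config_dict(cfg: PhantomConfig) -> dict:
    d = asdict(cfg)
    d["dims"] = list(cfg.dims)
    return d


def simulate_voxel_fid(metabolites: list[MetaboliteSpec], axis: SpectralAxis) -> np.ndarray:
    """Time-domain signal of a list of (already region-scaled) metabolites.

    An empty list yields the all-zero series.
    """
    if axis.domain != "time":
        from .core import raise_domain

        raise_domain("simulate_voxel_fid", axis.domain)
    t = axis.times()
    fid = np.zeros(axis.n_points, dtype=complex)
    for m in metabolites:
        f = (axis.ppm_ref - m.ppm) * axis.transmitter_freq  # Hz offset from carrier
        fid += m.base_amplitude * np.exp(1j * m.phase) * np.exp(
            (1j * 2 * np.pi * f - np.pi * m.damping) * t
        )
    return fid


def region_mask(cfg: PhantomConfig, region: EllipsoidRegion) -> np.ndarray:
    """Boolean voxel mask of one ellipsoidal region."""
    ix, iy, iz = np.meshgrid(*(np.arange(n) for n in cfg.dims), indexing="ij")
    cx, cy, cz = region.center
    ax_, ay, az = region.semi_axes
    return (((ix - cx) / ax_) ** 2 + ((iy - cy) / ay) ** 2 + ((iz - cz) / az) ** 2) <= 1.0


def _region_amplitudes(cfg: PhantomConfig) -> tuple[np.ndarray, list[str]]:
    names = [m.name for m in cfg.metabolites]
    nx, ny, nz = cfg.dims
    amps = np.zeros((nx, ny, nz, len(names)))
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    for region in cfg.regions:
        cx, cy, cz = region.center
        ax_, ay, az = region.semi_axes
        inside = (
            ((ix - cx) / ax_) ** 2 + ((iy - cy) / ay) ** 2 + ((iz - cz) / az) ** 2
        ) <= 1.0
        for im, m in enumerate(cfg.metabolites):
            scale = region.scales.get(m.name, 0.0)
            amps[..., im][inside] = m.base_amplitude * scale
    return amps, names


def _channel_sensitivities(cfg: PhantomConfig) -> np.ndarray:
    """Smooth positive in-plane Gaussian profiles with distinct complex phases.

    Shape (nx, ny, 1, channels); constant along z.
    """
    nx, ny, _ = cfg.dims
    c = cfg.channels
    x = (np.arange(nx) + 0.5) / nx
    y = (np.arange(ny) + 0.5) / ny
    xx, yy = np.meshgrid(x, y, indexing="ij")
    sens = np.empty((nx, ny, 1, c), dtype=complex)
    for ci in range(c):
        ang = 2 * np.pi * ci / max(c, 1)
        center = (0.5 + 0.45 * np.cos(ang), 0.5 + 0.45 * np.sin(ang)) if c > 1 else (0.5, 0.5)
        bump = np.exp(
            -(((xx - center[0]) ** 2 + (yy - center[1]) ** 2))
            / (2 * cfg.sensitivity_width**2)
        )
        phase = np.exp(1j * (ang / 2.0)) if c > 1 else 1.0
        sens[:, :, 0, ci] = (cfg.sensitivity_floor + bump) * phase
    return sens


def build_phantom_arrays(cfg: PhantomConfig) -> tuple[np.ndarray, GroundTruth]:
    """Noise-free voxel-domain signal (x, y, z, t, c) plus the ground truth."""
    axis = cfg.spectral_axis()
    amps, names = _region_amplitudes(cfg)
    t = axis.times()
    # per-metabolite time basis, (n_metab, n_points)
    basis = np.empty((len(cfg.metabolites), cfg.n_points), dtype=complex)
    for im, m in enumerate(cfg.metabolites):
        f = (cfg.ppm_ref - m.ppm) * cfg.f0
        basis[im] = np.exp(1j * m.phase) * np.exp((1j * 2 * np.pi * f - np.pi * m.damping) * t)
    voxels = np.tensordot(amps, basis, axes=([3], [0]))  # (x, y, z, t)
    sens = _channel_sensitivities(cfg)
    signal = voxels[..., None] * sens[:, :, :, None, :]  # broadcast z and t
    ratios = {}
    if "Cho" in names and "NAA" in names:
        icho, inaa = names.index("Cho"), names.index("NAA")
        for region in cfg.regions:
            cho = next(m.base_amplitude for m in cfg.metabolites if m.name == "Cho") * region.scales.get("Cho", 0.0)
            naa = next(m.base_amplitude for m in cfg.metabolites if m.name == "NAA") * region.scales.get("NAA", 0.0)
            if naa > 0:
                ratios[region.name] = cho / naa
    truth = GroundTruth(
        amplitudes=amps,
        metabolite_names=names,
        sensitivities=sens,
        region_ratios=ratios,
        config=cfg,
    )
    return signal, truth


def phantom_kspace(cfg: PhantomConfig) -> tuple[np.ndarray, GroundTruth]:
    """K-space samples (kx, ky, kz, t, c): centered forward DFT of the voxel
    signal, EPSI circular time shifts applied if configured, noise added."""
    signal, truth = build_phantom_arrays(cfg)
    k = np.fft.fftshift(np.fft.fftn(signal, axes=(0, 1, 2)), axes=(0, 1, 2))
    if cfg.ordering == "epsi" and cfg.epsi_tau != 0.0:
        k = _apply_epsi_delay(k, cfg.epsi_axis, cfg.epsi_tau, cfg.dwell)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        noise = rng.normal(scale=cfg.noise_sigma, size=k.shape + (2,))
        k = k + noise[..., 0] + 1j * noise[..., 1]
    return k, truth


def _apply_epsi_delay(k: np.ndarray, axis: int, tau: float, dwell: float) -> np.ndarray:
    """Circular (DFT-domain) time shift of kx*tau along the readout axis.

    The k-th readout position's FID is delayed by k*tau: its spectrum is
    multiplied by exp(-i*2*pi*f*k*tau).  Modeled as an exact DFT shift so the
    standard linear phase correction inverts it exactly.
    """
    n_t = k.shape[3]
    f = np.fft.fftfreq(n_t, d=dwell)  # Hz, unshifted order
    out = np.array(k)
    nk = k.shape[axis]
    for ki in range(nk):
        sl = [slice(None)] * k.ndim
        sl[axis] = ki
        spec = np.fft.fft(out[tuple(sl)], axis=2)  # spectral axis is now index 2
        spec *= np.exp(-1j * 2 * np.pi * f * ki * tau)[None, None, :, None]
        out[tuple(sl)] = np.fft.ifft(spec, axis=2)
    return out


def generate_phantom(cfg: PhantomConfig, raw_path, truth_path=None) -> tuple[Path, Path]:
    """Write the MRSRAW1 acquisition file and its ground-truth sidecar.

    Deterministic: identical config (including seed) gives byte-identical files.
    Returns (raw_path, truth_path).
    """
    from . import vendor_io

    raw_path = Path(raw_path)
    if truth_path is None:
        truth_path = raw_path.with_suffix(raw_path.suffix + ".truth.json")
    truth_path = Path(truth_path)

    k, truth = phantom_kspace(cfg)
    samples = _acquisition_order(k, cfg)
    header = {
        "dims": list(cfg.dims),
        "n_points": cfg.n_points,
        "channels": cfg.channels,
        "dwell": cfg.dwell,
        "f0": cfg.f0,
        "ppm_ref": cfg.ppm_ref,
        "geometry": {
            "origin": list(cfg.origin),
            "spacing": list(cfg.spacing),
            "orientation": [1.0, 0.0, 0.0, 0.0, 1.0, 0.0],
        },
        "selection": {
            "center": list(cfg.selection_box().center),
            "size": list(cfg.selection_box().size),
        },
        "sat_bands": [
            {"normal": list(b.normal), "distance": b.distance, "thickness": b.thickness}
            for b in cfg.sat_bands()
        ],
        "ordering": {
            "kind": cfg.ordering,
            "readout_axis": cfg.epsi_axis,
            "tau": cfg.epsi_tau,
        },
    }
    vendor_io.write_raw(raw_path, header, samples)
    truth_path.write_text(truth.to_json())
    return raw_path, truth_path


def _acquisition_order(k: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Flatten (kx, ky, kz, t, c) into the declared acquisition loop order.

    cartesian: channel slowest, then kz, ky, kx, spectral sample fastest.
    epsi: channel, kz, ky, spectral sample, readout k fastest.
    """
    if cfg.ordering == "cartesian":
        return np.ascontiguousarray(k.transpose(4, 2, 1, 0, 3)).ravel()
    if cfg.epsi_axis != 0:
        raise NotImplementedError("EPSI readout is supported along the x axis")
    return np.ascontiguousarray(k.transpose(4, 2, 1, 3, 0)).ravel()


def generate_anatomical(cfg: PhantomConfig, out_dir, upsample: int = 8) -> list[Path]:
    """Matched anatomical DICOM MR Image Storage series.

    One single-frame instance per slice; pixel content is a smooth ellipsoid
    intensity pattern covering the phantom regions, sampled on a grid
    ``upsample`` times finer in-plane than the spectroscopic grid.
    """
    from . import dicom_io

    nx, ny, nz = cfg.dims
    mx, my = nx * upsample, ny * upsample
    x = (np.arange(mx) + 0.5) / upsample - 0.5   # voxel coords of MRSI grid
    y = (np.arange(my) + 0.5) / upsample - 0.5
    xx, yy = np.meshgrid(x, y, indexing="ij")
    vol = np.zeros((mx, my, nz))
    for iz in range(nz):
        for region in cfg.regions:
            cx, cy, cz = region.center
            ax_, ay, az = region.semi_axes
            r2 = ((xx - cx) / ax_) ** 2 + ((yy - cy) / ay) ** 2 + ((iz - cz) / az) ** 2
            vol[:, :, iz] += np.exp(-2.0 * r2)
    vol = vol / vol.max() if vol.max() > 0 else vol
    sp = cfg.spacing
    geo = Geometry(
        origin=(
            cfg.origin[0] - sp[0] / 2 + sp[0] / (2 * upsample),
            cfg.origin[1] - sp[1] / 2 + sp[1] / (2 * upsample),
            cfg.origin[2],
        ),
        spacing=(sp[0] / upsample, sp[1] / upsample, sp[2]),
        dims=(mx, my, nz),
    )
    return dicom_io.write_mri_series(vol, geo, out_dir)
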