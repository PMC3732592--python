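import numpy as np
import pytest

from mrsikit import recon, vendor_io
from mrsikit.phantom import (
    MetaboliteSpec,
    PhantomConfig,
    generate_phantom,
    GroundTruth,
)


@pytest.fixture(scope="session")
def default_cfg():
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_cfg():
    """Fast 8x8x2, 256-point phantom for IO/format tests."""
    return PhantomConfig(dims=(8, 8, 2), n_points=256, seed=11)


@pytest.fixture(scope="session")
def phantom_files(tmp_path_factory, default_cfg):
    d = tmp_path_factory.mktemp("phantom")
    raw, truth = generate_phantom(default_cfg, d / "phantom.raw")
    return raw, truth


@pytest.fixture(scope="session")
def small_phantom_files(tmp_path_factory, small_cfg):
    d = tmp_path_factory.mktemp("small_phantom")
    raw, truth = generate_phantom(small_cfg, d / "phantom.raw")
    return raw, truth


@pytest.fixture(scope="session")
def ground_truth(phantom_files):
    return GroundTruth.from_json(phantom_files[1].read_text())


@pytest.fixture(scope="session")
def kspace_ds(phantom_files):
    return vendor_io.read_any(phantom_files[0])


@pytest.fixture(scope="session")
def recon_ds(kspace_ds):
    """Default noiseless phantom through the standard quantification chain."""
    ds = recon.apodize(kspace_ds, recon.ApodizationSpec("lorentzian", 4.0))
    ds = recon.zero_fill(ds, 2 * ds.spectral_axis.n_points)
    ds = recon.spatial_recon(ds)
    ds = recon.spectral_fft(ds, first_point_half=True)
    ds = recon.phase_correct(ds, recon.PhaseParams())
    return ds


def tiny_cfg(dims=(4, 4, 1), n_points=64, **kw):
    """Small config with one centered region so every grid actually holds signal."""
    from mrsikit.phantom import EllipsoidRegion

    region = EllipsoidRegion(
        "blob",
        center=tuple((d - 1) / 2 for d in dims),
        semi_axes=tuple(max(d / 1.8, 0.6) for d in dims),
        scales={"NAA": 2.0, "Cr": 1.0, "Cho": 1.0, "water": 1.0},
    )
    return PhantomConfig(dims=dims, n_points=n_points, regions=[region], **kw)


def single_voxel_dataset(metabolites, n_points=512, dwell=1e-3, f0=127.7, ppm_ref=4.7):
    """1x1x1 time-domain dataset built from explicit metabolite lines."""
    from mrsikit.core import Geometry, MrsDataset, SpectralAxis
    from mrsikit.phantom import simulate_voxel_fid

    axis = SpectralAxis(n_points, dwell, 1.0 / dwell, f0, ppm_ref, "time")
    fid = simulate_voxel_fid(metabolites, axis)
    return MrsDataset(
        data=fid.reshape(1, 1, 1, n_points, 1),
        spectral_axis=axis,
        geometry=Geometry(origin=(0, 0, 0), spacing=(10, 10, 10), dims=(1, 1, 1)),
        spatial_domain=("image", "image", "image"),
    )


@pytest.fixture()
def water_naa_voxel():
    """Water-dominated voxel for suppression tests.

    The water amplitude (100x NAA) reflects incompletely suppressed in-vivo
    water, the regime band-selective removal exists for; the NAA Lorentzian
    tail leaking into the 4.2-5.2 ppm band is then negligible relative to the
    water energy being removed.
    """
    return single_voxel_dataset(
        [
            MetaboliteSpec("water", 4.7, 4.0, 100.0),
            MetaboliteSpec("NAA", 2.01, 1.5, 1.0),
        ]
    )
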