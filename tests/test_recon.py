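"""Reconstruction operations: windows, transforms, coil combination, phasing."""

import numpy as np
import pytest

from mrsikit import recon
from mrsikit.core import MrsDataset, SpectralAxis, ppm_to_index
from mrsikit.errors import DomainError
from mrsikit.phantom import MetaboliteSpec, PhantomConfig, generate_phantom
from mrsikit.recon import ApodizationSpec, PhaseParams
from mrsikit.vendor_io import read_any

from conftest import single_voxel_dataset


def interpolated_fwhm(spectrum: np.ndarray, hz_per_bin: float) -> float:
    """Numeric FWHM oracle on the absorption (real) part: linear interpolation
    of the half-height crossings."""
    mag = np.asarray(spectrum).real
    peak = np.argmax(mag)
    half = mag[peak] / 2
    left = peak
    while mag[left] > half:
        left -= 1
    right = peak
    while mag[right] > half:
        right += 1
    fl = left + (half - mag[left]) / (mag[left + 1] - mag[left])
    fr = right - (half - mag[right]) / (mag[right - 1] - mag[right])
    return (fr - fl) * hz_per_bin


class TestApodize:
    def test_zero_broadening_is_identity(self, kspace_ds):
        out = recon.apodize(kspace_ds, ApodizationSpec("lorentzian", 0.0))
        assert np.array_equal(out.data, kspace_ds.data)

    def test_lorentzian_window_closed_form(self):
        ds = single_voxel_dataset([MetaboliteSpec("w", 4.7, 1e-6, 1.0)], n_points=256)
        ds.data[:] = 1.0  # constant FID isolates the window itself
        out = recon.apodize(ds, ApodizationSpec("lorentzian", 10.0))
        # w[100] = exp(-pi * 10 Hz * 100 * 1 ms) = exp(-pi)
        assert out.data[0, 0, 0, 100, 0].real == pytest.approx(np.exp(-np.pi), rel=1e-12)

    def test_lorentzian_broadening_adds_to_linewidth(self):
        d, L = 2.0, 8.0
        ds = single_voxel_dataset([MetaboliteSpec("x", 3.0, d, 1.0)], n_points=2048)
        out = recon.apodize(ds, ApodizationSpec("lorentzian", L))
        out = recon.zero_fill(out, 8192)
        spec = recon.spectral_fft(out, first_point_half=True)
        fwhm = interpolated_fwhm(spec.data[0, 0, 0, :, 0], spec.spectral_axis.hz_per_bin)
        assert fwhm == pytest.approx(d + L, rel=0.05)

    def test_gaussian_window_shape(self):
        ds = single_voxel_dataset([MetaboliteSpec("w", 4.7, 1e-6, 1.0)], n_points=256)
        ds.data[:] = 1.0
        out = recon.apodize(ds, ApodizationSpec("gaussian", 10.0))
        t = 100 * 1e-3
        expected = np.exp(-((np.pi * 10.0 * t) ** 2) / (4 * np.log(2)))
        assert out.data[0, 0, 0, 100, 0].real == pytest.approx(expected, rel=1e-12)

    def test_frequency_domain_input_rejected(self, recon_ds):
        with pytest.raises(DomainError):
            recon.apodize(recon_ds, ApodizationSpec("lorentzian", 4.0))


class TestZeroFill:
    def test_target_equal_n_is_identity(self, kspace_ds):
        out = recon.zero_fill(kspace_ds, kspace_ds.spectral_axis.n_points)
        assert np.array_equal(out.data, kspace_ds.data)

    def test_prefix_preserved_suffix_zero(self, kspace_ds):
        n = kspace_ds.spectral_axis.n_points
        out = recon.zero_fill(kspace_ds, 2 * n)
        assert np.array_equal(out.data[:, :, :, :n, :], kspace_ds.data)
        assert not out.data[:, :, :, n:, :].any()
        assert out.spectral_axis.n_points == 2 * n
        assert out.spectral_axis.sweep_width == kspace_ds.spectral_axis.sweep_width

    def test_shrinking_rejected(self, kspace_ds):
        with pytest.raises(ValueError):
            recon.zero_fill(kspace_ds, 16)

    def test_dft_interpolation_preserves_original_bins(self):
        ds = single_voxel_dataset([MetaboliteSpec("x", 3.2, 3.0, 1.0)], n_points=512)
        spec = recon.spectral_fft(ds)
        filled = recon.spectral_fft(recon.zero_fill(ds, 1024))
        # original bin i sits at doubled-grid bin 2i
        assert np.allclose(filled.data[0, 0, 0, ::2, 0], spec.data[0, 0, 0, :, 0], rtol=1e-12)


class TestSpatialRecon:
    def test_round_trips_phantom_voxel_signal(self, kspace_ds, default_cfg):
        from mrsikit.core import MrsDataset
        from mrsikit.phantom import build_phantom_arrays, phantom_kspace

        signal, _ = build_phantom_arrays(default_cfg)
        # exact round trip on the in-memory forward model
        k, _ = phantom_kspace(default_cfg)
        mem = MrsDataset(
            data=k,
            spectral_axis=kspace_ds.spectral_axis,
            geometry=kspace_ds.geometry,
            spatial_domain=("kspace", "kspace", "kspace"),
        )
        img = recon.spatial_recon(mem)
        scale = np.abs(signal).max()
        assert np.allclose(img.data, signal, rtol=1e-9, atol=1e-12 * scale)
        # through the complex64 raw file the error budget is float32 rounding
        img_file = recon.spatial_recon(kspace_ds)
        assert np.allclose(img_file.data, signal, atol=1e-5 * scale)

    def test_centered_delta_gives_constant_image(self):
        axis = SpectralAxis(4, 1e-3, 1000.0, 127.7)
        from mrsikit.core import Geometry

        data = np.zeros((4, 4, 2, 4, 1), complex)
        data[2, 2, 1, :, 0] = 8.0  # delta at the centered k=0 position
        ds = MrsDataset(
            data=data,
            spectral_axis=axis,
            geometry=Geometry(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(4, 4, 2)),
            spatial_domain=("kspace", "kspace", "kspace"),
        )
        img = recon.spatial_recon(ds)
        assert np.allclose(img.data, 8.0 / 32)

    def test_parseval_under_stated_scaling(self, kspace_ds):
        img = recon.spatial_recon(kspace_ds)
        n_spatial = np.prod(kspace_ds.dims)
        assert np.sum(np.abs(img.data) ** 2) * n_spatial == pytest.approx(
            np.sum(np.abs(kspace_ds.data) ** 2), rel=1e-9
        )

    def test_image_domain_input_rejected(self, recon_ds):
        with pytest.raises(DomainError):
            recon.spatial_recon(recon_ds)


class TestSpectralFfts:
    def test_fft_ifft_round_trip(self, kspace_ds):
        out = recon.spectral_ifft(recon.spectral_fft(kspace_ds))
        assert np.allclose(out.data, kspace_ds.data, rtol=1e-12, atol=1e-12)

    def test_on_carrier_phasor_is_delta_at_center(self):
        n = 64
        ds = single_voxel_dataset([], n_points=n)
        ds.data[0, 0, 0, :, 0] = 1.0  # zero-offset, zero-damping phasor
        spec = recon.spectral_fft(ds).data[0, 0, 0, :, 0]
        assert np.argmax(np.abs(spec)) == n // 2
        assert abs(spec[n // 2]) == pytest.approx(n)
        mask = np.ones(n, bool)
        mask[n // 2] = False
        assert np.max(np.abs(spec[mask])) < 1e-9

    def test_singlet_lands_at_its_ppm_index(self):
        ds = single_voxel_dataset([MetaboliteSpec("cho", 3.22, 2.0, 1.0)])
        spec = recon.spectral_fft(ds)
        idx = np.argmax(np.abs(spec.data[0, 0, 0, :, 0]))
        assert idx == round(ppm_to_index(spec.spectral_axis, 3.22))

    def test_wrong_domain_errors(self, recon_ds, kspace_ds):
        with pytest.raises(DomainError):
            recon.spectral_fft(recon_ds)
        with pytest.raises(DomainError):
            recon.spectral_ifft(kspace_ds)


class TestEpsiCorrection:
    def test_zero_tau_is_identity(self, kspace_ds):
        spec = recon.spectral_fft(kspace_ds)
        out = recon.epsi_phase_correct(spec, 0, 0.0)
        assert np.array_equal(out.data, spec.data)

    def test_corrected_epsi_phantom_matches_cartesian_twin(self, tmp_path):
        from conftest import tiny_cfg

        base = dict(dims=(8, 4, 1), n_points=128, seed=21)
        tau = 0.5e-3
        p_c, _ = generate_phantom(tiny_cfg(**base, ordering="cartesian"), tmp_path / "c.raw")
        p_e, _ = generate_phantom(
            tiny_cfg(**base, ordering="epsi", epsi_tau=tau), tmp_path / "e.raw"
        )
        spec_c = recon.spectral_fft(read_any(p_c))
        spec_e = recon.epsi_phase_correct(recon.spectral_fft(read_any(p_e)), 0, tau)
        scale = np.abs(spec_c.data).max()
        assert np.allclose(spec_e.data, spec_c.data, atol=scale * 1e-6)

    def test_tau_then_minus_tau_is_identity(self, kspace_ds):
        spec = recon.spectral_fft(kspace_ds)
        out = recon.epsi_phase_correct(
            recon.epsi_phase_correct(spec, 0, 4e-4), 0, -4e-4
        )
        assert np.allclose(out.data, spec.data, rtol=1e-12, atol=1e-12 * np.abs(spec.data).max())

    def test_wraparound_regime_recorded_in_provenance(self, kspace_ds):
        spec = recon.spectral_fft(kspace_ds)
        out = recon.epsi_phase_correct(spec, 0, 1e-4)  # tau*SW*k_max = 1.5 >= 1
        assert "wraparound" in out.provenance[-1]["params"].get("warning", "")


class TestCombineCoils:
    def test_single_channel_becomes_magnitude(self, recon_ds):
        out = recon.combine_coils(recon_ds)
        assert np.allclose(out.data, np.abs(recon_ds.data))
        assert not out.data.imag.any()

    def test_two_identical_channels_scale_sqrt2(self, kspace_ds):
        doubled = kspace_ds.evolve("dup", data=np.repeat(kspace_ds.data, 2, axis=4))
        out = recon.combine_coils(doubled)
        assert np.allclose(out.data, np.sqrt(2) * np.abs(kspace_ds.data))

    def test_invariant_under_per_channel_phase_rotations(self, tmp_path):
        from conftest import tiny_cfg

        cfg = tiny_cfg(dims=(4, 4, 1), n_points=64, channels=4, seed=13)
        raw, _ = generate_phantom(cfg, tmp_path / "multi.raw")
        ds = read_any(raw)
        reference = recon.combine_coils(ds).data
        rng = np.random.default_rng(2)
        for _ in range(20):
            thetas = rng.uniform(0, 2 * np.pi, size=4)
            rotated = ds.evolve("rot", data=ds.data * np.exp(1j * thetas)[None, None, None, None, :])
            assert np.allclose(recon.combine_coils(rotated).data, reference, rtol=1e-12)


class TestPhaseCorrection:
    def test_zero_phase_is_identity(self, recon_ds):
        out = recon.phase_correct(recon_ds, PhaseParams(0.0, 0.0, 0))
        assert np.array_equal(out.data, recon_ds.data)

    def test_pi_negates_real_part(self, recon_ds):
        out = recon.phase_correct(recon_ds, PhaseParams(np.pi, 0.0, 0))
        assert np.allclose(out.data.real, -recon_ds.data.real, atol=1e-9 * np.abs(recon_ds.data).max())

    def test_dispersive_singlet_rephased_to_absorption(self):
        ds = single_voxel_dataset(
            [MetaboliteSpec("w", 4.7, 2.0, 1.0, phase=np.pi / 2)], n_points=512
        )
        spec = recon.spectral_fft(ds)
        fixed = recon.phase_correct(spec, PhaseParams(-np.pi / 2, 0.0, 0))
        peak = spec.spectral_axis.center_index
        assert abs(fixed.data[0, 0, 0, peak, 0].imag) <= 1e-9 * abs(fixed.data[0, 0, 0, peak, 0])

    def test_first_order_ramp_about_pivot(self):
        ds = single_voxel_dataset([MetaboliteSpec("w", 4.7, 2.0, 1.0)], n_points=64)
        spec = recon.spectral_fft(ds)
        out = recon.phase_correct(spec, PhaseParams(0.0, np.pi, pivot=32))
        # at the pivot the ramp is zero
        assert out.data[0, 0, 0, 32, 0] == pytest.approx(spec.data[0, 0, 0, 32, 0])


class TestAutoPhase0:
    # the search window is symmetric about the singlet so the dispersive part
    # integrates to ~zero and the optimum is the pure phase offset
    def test_absorptive_singlet_needs_no_phase(self):
        ds = single_voxel_dataset([MetaboliteSpec("w", 4.7, 2.0, 1.0)])
        spec = recon.spectral_fft(ds, first_point_half=True)
        p = recon.auto_phase0(spec, (4.5, 4.9))
        assert abs(np.rad2deg(p.phi0)) < 0.1

    @pytest.mark.parametrize("phi", [0.7, -2.2, 3.0])
    def test_recovers_negated_simulated_phase(self, phi):
        ds = single_voxel_dataset([MetaboliteSpec("w", 4.7, 2.0, 1.0, phase=phi)])
        spec = recon.spectral_fft(ds, first_point_half=True)
        p = recon.auto_phase0(spec, (4.5, 4.9))
        delta = np.angle(np.exp(1j * (p.phi0 + phi)))
        assert abs(np.rad2deg(delta)) < 0.1

    def test_invariant_to_amplitude_scaling(self):
        ds = single_voxel_dataset([MetaboliteSpec("w", 4.7, 2.0, 1.0, phase=1.1)])
        spec = recon.spectral_fft(ds, first_point_half=True)
        scaled = spec.evolve("scale", data=spec.data * 37.0)
        assert recon.auto_phase0(spec, (4.5, 4.9)).phi0 == pytest.approx(
            recon.auto_phase0(scaled, (4.5, 4.9)).phi0, abs=np.deg2rad(0.02)
        )


class TestOperationContracts:
    def test_ops_append_one_record_and_do_not_mutate(self, kspace_ds):
        snapshot = kspace_ds.data.copy()
        n0 = len(kspace_ds.provenance)
        stages = [
            lambda d: recon.apodize(d, ApodizationSpec("lorentzian", 4.0)),
            lambda d: recon.zero_fill(d, 2 * d.spectral_axis.n_points),
            recon.spatial_recon,
            recon.spectral_fft,
            recon.combine_coils,
            lambda d: recon.phase_correct(d, PhaseParams()),
        ]
        ds = kspace_ds
        for i, stage in enumerate(stages, start=1):
            ds = stage(ds)
            assert len(ds.provenance) == n0 + i
        assert np.array_equal(kspace_ds.data, snapshot)

    def test_value_linearity_of_linear_ops(self):
        rng = np.random.default_rng(7)
        shape = (4, 4, 2, 64, 1)
        x = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        y = rng.normal(size=shape) + 1j * rng.normal(size=shape)

        def make(d):
            from mrsikit.core import Geometry

            return MrsDataset(
                data=d,
                spectral_axis=SpectralAxis(64, 1e-3, 1000.0, 127.7),
                geometry=Geometry(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(4, 4, 2)),
                spatial_domain=("kspace", "kspace", "kspace"),
            )

        for op in (
            lambda d: recon.apodize(d, ApodizationSpec("lorentzian", 6.0)),
            lambda d: recon.zero_fill(d, 128),
            recon.spatial_recon,
            recon.spectral_fft,
        ):
            lhs = op(make(x + 2 * y)).data
            rhs = op(make(x)).data + 2 * op(make(y)).data
            assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)
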