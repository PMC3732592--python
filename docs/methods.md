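# Methods

This note documents the models, conventions, and numerical choices behind
`mrsikit`, and what the synthetic phantom does and does not establish.

## Data model and conventions

An `MrsDataset` is a complex array indexed `(x, y, z, spectral, channel)` with
a `SpectralAxis` (N points, dwell Δt, sweep width SW = 1/Δt, transmitter
frequency f0 in MHz, and the chemical shift `ppm_ref` assigned to the
carrier), a `Geometry` in DICOM's LPS patient frame (voxel-center addressing,
0-based indices), per-axis spatial-domain flags (k-space vs image), optional
PRESS selection box and sat-band annotations, and an append-only provenance
list — every operation returns a copy with exactly one record added.

Fixed spectral conventions:

* frequency-domain spectra are fftshifted, carrier at index ⌊N/2⌋;
* `ppm(i) = ppm_ref + (⌊N/2⌋ − i)·SW/(N·f0)` — ppm decreases with index
  (standard NMR display); bin i sits at offset `(i − ⌊N/2⌋)·SW/N` Hz;
* `ppm_ref` defaults to 4.7 (water at body temperature), the conventional
  in-vivo ¹H reference.

Spatial transforms: the phantom's forward model is
`kspace = fftshift(fftn(image))` per spectral sample and channel;
reconstruction is the exact inverse `ifftn(ifftshift(kspace))` with 1/N
scaling per axis, so Parseval reads `Σ|image|²·N_spatial = Σ|kspace|²`.

## Synthetic phantom (the stated world)

Each voxel's FID is a sum of damped complex exponentials,

    x[n] = Σ_m a_m e^{iφ_m} exp((i·2π f_m − π d_m)·nΔt),
    f_m = (ppm_ref − ppm_m)·f0,

where `d_m` is the Lorentzian FWHM in Hz (decay rate π·d_m), making
apodization and quantification tests analytic: Lorentzian apodization of L Hz
broadens a line of FWHM d to d+L.

Defaults: 16×16×4 grid, 10 mm isotropic voxels, 512 points, SW 1000 Hz,
f0 127.7 MHz; NAA 2.01, Cr 3.03, Cho 3.22 ppm plus residual water at 4.7 ppm
with 5× metabolite amplitude. Two ellipsoidal regions fix Cho:Cr:NAA at 1:1:2
("normal", Cho/NAA = 0.5) and 2:1.2:1 ("tumor-like", Cho/NAA = 2.0).

**Linewidths are phantom-realistic, not in-vivo-realistic: metabolites 1.5 Hz,
water 4 Hz.** This is deliberate. With the standard chain (4 Hz Lorentzian
apodization, peak-height quantification in 0.2 ppm windows), the Lorentzian
tail of Cr bleeds into the Cho window by ≈ `(d_tot/2Δf)²` of the Cr height
(Δf ≈ 24 Hz separation at 3 T). At in-vivo 5 Hz linewidths that bleed alone
is ~5% and ratio recovery to 2% is physically impossible; at solution-phantom
linewidths the residual systematic is ~0.5–1.5%, which is what the end-to-end
tests measure. Narrow lines emulate the metabolite-solution phantoms used for
scanner validation.

Channels get smooth positive in-plane Gaussian sensitivity profiles with a
constant floor and distinct per-channel phase offsets (exercising the phase
invariance of sum-of-squares combination). Noise is i.i.d. complex Gaussian
in k-space driven by a single integer seed; identical config ⇒ byte-identical
output files.

What a green phantom test does **not** establish: robustness to eddy-current
lineshape distortion, B0 inhomogeneity, macromolecule baselines, J-coupled
multiplets, motion, or chemical-shift displacement — none of which the
generator models.

## EPSI delay model

Echo-planar readouts acquire the k-positions along one axis at staggered
times; position k is delayed by k·τ. The phantom applies this as a *circular*
(DFT-domain) delay — the FID's DFT is multiplied by `exp(−i2πf·kτ)` — and the
reconstruction correction multiplies each spectrum bin by `exp(+i2πf·kτ)`,
its exact inverse (verified to 1e-6 against a cartesian twin). A physically
resampled delay `x(nΔt + kτ)` would additionally scale each component by
`e^{πd·kτ}`, which no pure phase ramp can undo; the circular model is the
idealization under which the standard linear-phase correction is exact. When
`τ·SW·k_max ≥ 1` the ramp wraps; the operation records a wraparound warning
in provenance rather than refusing.

## First-point half-scaling

The DFT of a one-sided decaying signal carries a constant baseline of x[0]/2
across all bins (the sampled step at t = 0). With residual water at 5×
metabolite amplitude this baseline biases peak-height ratios by several
percent. `spectral_fft(ds, first_point_half=True)` halves the first FID
sample before transforming — the standard correction — and is used by the
default quantification pipeline. It is off by default so that
`spectral_ifft(spectral_fft(x)) = x` holds exactly for transform-identity
checks.

## HSVD

`hsvd_fit` builds the L×(N−L+1) Hankel matrix `H[i,j] = x[i+j]` with
L = ⌊N/2⌋ (near-square, the standard conditioning choice), takes the SVD,
truncates to the top K left singular vectors (default K = 25, typical for
water+metabolite ¹H modeling), solves the shift-invariance relation by
pseudo-inverse, and converts the eigenvalues z_k to frequency
`∠z_k/(2πΔt)` and damping `−ln|z_k|/Δt`; amplitudes/phases come from a
linear least-squares fit of x on the z_k^n basis. Components below
1e-12·‖x‖∞ are dropped; growing components (|z| > 1) are discarded before
subtraction by default for residual stability. On noiseless signals of ≤ K/2
components the model matches the FID to < 1e-8 relative RMS and agrees with a
nonlinear-least-squares oracle initialized at truth to 1e-6.

Water removal (`hsvd_filter`) subtracts, per voxel, every fitted component
whose chemical shift lies in the band (default 4.2–5.2 ppm). Note the
residual band energy after removal is bounded below by the *metabolite* tails
that genuinely extend into the band (the dispersive Lorentzian tail falls
only as 1/Δf); the "residual < 1e-6 of original" regime applies when water
dominates the band, as unsuppressed or residual in-vivo water does.

## Quantification

Peak height is the per-voxel maximum of the real part (phased spectra) or
magnitude (after sum-of-squares combination, which discards phase) over a ppm
window; default windows Cho 3.12–3.32, Cr 2.93–3.13, NAA 1.91–2.11 ppm. Peak
area is the Riemann sum over window bins times the Hz-per-bin. Noise is the
per-voxel standard deviation of the real part over a signal-free region
(default 0.9–1.7 ppm; regions overlapping a metabolite window are rejected).
The Cho/NAA map divides voxelwise where the denominator clears `k·σ`
(default k = 4) and masks the rest — in practice this removes everything
outside the excitation volume. This masked ratio is a simplified index: the
published regression-based choline-to-NAA index (CNI) fits per-voxel linear
models over control regions and is *not* implemented here; the map is labeled
`cho_naa_index` and should be read as a plain masked ratio.

Peak-height quantification is grid-limited: a line can fall up to half a bin
off-grid, costing `≈ (Δf_offbin/d_tot)²` of its height. Zero filling
interpolates the spectrum and shrinks this error; the default chain fills ×2.

## DICOM encoding

Only Explicit VR Little Endian is written or read, with defined-length
sequences — strictness is preferred to guessing. UIDs derive
deterministically (SHA1, 2.25 root) from content, and dates are fixed
constants, so identical runs write byte-identical files. The MRS payload in
(5600,0020) is float32 real/imaginary interleaved, ordered frame(z) → row(y)
→ column(x) → spectral point. The selection box is encoded as three
orthogonal slabs in the Volume Localization Sequence (0018,9126); sat bands
and the raw-encapsulation payload (filename, SHA1 hex digest, even-padded
payload with pad length) live in a documented private block under creator
"MRSIKIT" (group 0x0077). Metabolite maps scale float values onto unsigned
16-bit pixels with Rescale Slope/Intercept, exact to one quantization step
`(max−min)/65535`. Multichannel MRS instances and foreign transfer syntaxes
are rejected, not guessed.

The raw on-disk format (`MRSRAW1`) stores a JSON header plus little-endian
complex64 samples; complex64 matches typical scanner raw precision, and all
processing promotes to double. Consequently file round trips are exact at
float32 (~1e-7 relative), while in-memory transform identities hold at double
precision (1e-9 to 1e-12 in the tests).

## Phasing

`phase_correct` applies `S'[i] = S[i]·exp(i(φ0 + φ1·(i − pivot)/N))` with φ1
expressed in radians across the full width about an explicit pivot bin.
`auto_phase0` maximizes the summed real part over a ppm window via a
1° grid scan followed by a bounded scalar refinement to 0.01°; it recovers a
singlet's phase to < 0.1° when the window is symmetric about the peak.
An asymmetric window leaves a genuine dispersive bias (the dispersion
integral no longer cancels), which is a property of the criterion, not of
the optimizer.

## Reports

Panels are 1024×1024 RGB rendered with fixed colors and integer pixel
arithmetic (no fonts, no anti-aliasing dependencies): anatomy underlay by
nearest-neighbor resampling, heat-style overlay (linear ramp LUT) alpha-
blended inside unmasked voxels, voxel grid, per-voxel real-part spectrum
polylines, PRESS box outline in pure yellow (255,255,0), sat bands blended
purple. Rendering is pure and byte-deterministic. A report series is the
requested slice panels plus two summary montages (all slices without and with
overlay), encoded as one Secondary Capture series with instance numbers 1..n.

## Command line

One executable (`mrsikit`) with subcommands `phantom`, `dcmraw pack|unpack`,
`convert`, `recon` (YAML stage list; unknown stages or parameter keys are
rejected), `quant`, and `report`. Exit codes: 0 success, 1 usage error,
2 data/integrity error. Each run writes a JSON manifest with the effective
configuration and SHA1 digests of inputs and outputs; re-running a manifest's
configuration with the same seed reproduces the outputs exactly.
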