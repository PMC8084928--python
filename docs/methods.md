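# Methods

This note documents the models, numerical choices and known limitations of
`cardiofat3d`, in the order the pipeline runs them.

## Digital heart phantom

The phantom emulates a fixed, gadolinium-doped ex vivo heart immersed in a
signal-free perfluoropolyether bath. Geometry is a set of concentric
ellipsoids in normalized coordinates: cavity (radius ≤ 0.35, fat fraction
2 %), myocardium (≤ 0.78, 5 %), epicardial fat rim (≤ 0.92, 90 %), plus
seeded spherical fibro-fatty patches (fat fraction drawn uniformly from
40–70 %) and fibrosis patches that only alter the MTR map. The radii were
chosen so the myocardium holds the plurality of voxels and the PDFF
histogram is water-peak dominated, as in a real heart. The default grid is
32³ at 200 µm — small enough that the full pipeline runs in seconds, large
enough for a 3-level field-map pyramid; all sizes are configurable.

Signal model per coil c and echo n:

    s = C_c · (A_w(tₙ) + A_f(tₙ)·e^{i2πf_F tₙ}) · e^{i2πψ tₙ} + ε,
    A_x(tₙ) = X₀·sinα·(1−E1ₓ)/(1−cosα·E1ₓ)·e^{−tₙ/T2*ₓ},  E1ₓ = e^{−TR/T1ₓ}

with complex Gaussian ε of configurable per-channel SD. Defaults follow
the target acquisition: TR 30 ms, TE 3.08/3.31/3.54 ms, flip 17°. The
fat–water offset defaults to −1361 Hz (−3.4 ppm at a 400.2 MHz proton
frequency, i.e. 9.4 T), fat below water, phase convention
e^{+i2πf_F t}. Relaxation defaults (T1 w/f = 250/150 ms, T2* w/f =
20/15 ms) are plausible for fixed Gd-doped tissue and deliberately
distinct between species; they are placeholders, not literature values.

Coil sensitivities are smooth complex maps for coils ringed around the
volume; their phase offsets stay within ±0.5 rad so the coil-summed signal
cannot cancel destructively.

MT is simulated at the ratio level (the pipeline only ever consumes
MT_on/MT_off): the fine-grid reference signal is the total proton density,
the saturated signal is that reference times mtr_true/100, both are
block-averaged to the coarse MT grid, and Gaussian noise is added. Two
consequences are deliberate: (1) the coarse-grid ground truth at
tissue/background borders is the ratio of block-averaged signals
(signal-weighted), provided by `coarse_mtr_truth`; (2) noise is additive
Gaussian rather than Rician magnitude noise, so the background sample SD
equals the configured SD exactly. Rician bias is likewise not modelled in
the relaxometry series. What passing phantom tests therefore do *not*
show: robustness to Rician floors, multi-peak fat spectra, susceptibility
artefacts, motion, or k-space undersampling.

Voxel-wise relaxometry series use a single effective relaxation rate per
voxel, the fat-fraction-weighted harmonic blend
1/T_eff = (1−ff)/T_w + ff/T_f, because the downstream fits are
mono-exponential.

## Coil combination and phase referencing

Magnitude is the root sum of squares over coils. Two phase conventions are
implemented. `phase_sum` adds the per-voxel phase angles of all coils and
wraps — when every coil sees the same object phase this multiplies the
echo-to-echo phase evolution by the coil count, which provably corrupts
the downstream field map for more than one coil; it is kept because it is
a documented convention for this protocol and it is exact for single-coil
data. `complex_sum`, the pipeline default, takes the phase of the
coil-summed signal, which preserves the object phase for any coil count.
After combination the shortest echo's phase is subtracted (wrapped into
(−π, π]); the solver then works on τₙ = tₙ − t₁ with complex amplitudes
absorbing the echo-1 phase, which is unrecoverable after referencing —
reported W/F maps are magnitudes.

## Water–fat–field-map solver

Per voxel the solver minimizes R(ψ) = ‖Q·D(ψ)s‖² where D demodulates by ψ
and Q projects onto the complement of span{1, e^{i2πf_Fτₙ}} (variable
projection: the amplitudes are eliminated exactly). The ψ update is an
exact Newton step on R (first and second derivatives in closed form),
backtracked to enforce monotone descent, with a deterministic kick off
stationary points of negative curvature. For consistent data this
converges quadratically — noise-free recovery to ~1e−6 Hz in a handful of
iterations — and the backtracking guarantees the iterate stays in the
basin it started in. Defaults: tolerance 0.1 Hz on the ψ step, 30
iterations, single-peak fat model. ψ is reported in
[−1/(2Δτ), +1/(2Δτ)) — ±2174 Hz for 0.23 ms echo spacing.

Branch ambiguity. The three-echo residual has a second minimum with the
species swapped at roughly ψ ± f_F; for near-pure-fat voxels even tiny
model mismatch (the inter-echo T2* decay the 3-point model ignores, or
noise) can make the swapped minimum the *deeper* one, so no residual-only
rule can pick the physical branch. The volume solver therefore relies on
spatial consistency: a dyadic pyramid (complex 2× block averages, down to
8 voxels per axis by default) is solved coarse-to-fine; the coarsest level
starts from ψ = 0 — shimmed acquisitions keep |ψ| well inside the local
capture range of about half the fat–water offset (~±700 Hz here) — and
each finer level starts from the median-filtered (radius 1), trilinearly
upsampled coarser map. Zero-signal voxels carry no field information and
are filled from their nearest signal voxel before filtering. After each
level a consistency pass re-solves voxels whose ψ departs from their
neighborhood median by more than |f_F|/2, starting from that median. An
exhaustive one-period grid search for the coarsest level is available
(`coarse_global_search`) for strongly off-resonant data, with the caveat
above. A brute-force grid oracle (`brute_force_oracle`, step ≤ 1 Hz,
zero-aligned grid, ties broken toward the init) serves as the independent
reference in the tests.

## Relaxometry

Both fits are vectorized two-parameter Levenberg–Marquardt iterations on
(kS₀, rate), with analytic Jacobians. Initialization: saturation recovery
from the half-maximum recovery time (T1 ≈ TR_half/ln 2, interpolated);
decay from a signal-weighted log-linear regression over positive samples.
Convergence: relative step < 1e−12, 200 iterations cap. Voxels below the
signal floor (default 3× background SD in the pipeline), with flat series,
or non-converged fits are flagged invalid (NaN), never silently zeroed.
The fits are magnitude fits without Rician correction, matching the simple
processing the maps are meant to feed; species values for the
proton-density correction are arithmetic ROI means over valid voxels.

## PDFF, mask and thresholds

The proton-density correction inverts the spoiled-gradient-echo weighting
with the species relaxation times; the T2* exponent is positive
(compensating decay) and the reference TE is the first echo (3.08 ms),
because after phase referencing the solver amplitudes are referenced to
echo 1. PDFF = 100·M_f/(M_w+M_f), clipped inputs logged, zero-signal
voxels defined as 0 %, out-of-mask voxels NaN.

The tissue mask thresholds the root sum of squares of the three echo
magnitudes at offset + 3σ, where σ is the sample SD (n−1, no Rician
correction) of a noise-only ROI. The offset defaults to 0 (the plain
3σ rule); the pipeline passes the background mean of the combined image,
because a multi-coil multi-echo RSS background is chi-distributed with a
mean several times its SD and a pure 3σ cut would lie below the floor.
Deterministic refinement replaces interactive editing: morphological
closing (radius-1 cross, on a padded volume so border structures survive),
then the largest 26-connected component; a user-supplied volume of ±1
values can force voxels in or out, and every step is logged.

The histogram model pools masked PDFF values into 1000 equal bins on
[0, 100] % and fits a 4-component Gaussian mixture by weighted EM on the
bin centers (counts as weights; max 500 steps; relative log-likelihood
tolerance 1e−8; components collapsing below one bin width are pruned and
the mixture refitted). Initialization is deterministic: water mean at the
histogram mode, fat mean at the second-highest local maximum at least 10
points away, the two spare components at the 33rd/67th percentiles, equal
weights, SDs = sample SD/4. Because an overparametrized mixture is free to
split an exactly Gaussian peak among overlapping components (the split is
a likelihood plateau, not an artifact of the tolerance), the reported
water and fat Gaussians are *cluster merges*: components whose means lie
within two SDs of the dominant water (fat) component are combined by
moment matching; leftover components are the between-peak residuals and
belong to neither. T_C is μ_w + z·σ_w of the merged water Gaussian with
z = Φ⁻¹(0.9999) = 3.71902, snapped up to the next bin upper edge and
clamped at 100 %; T_D is fixed at 50 %. A voxel exactly at a threshold
counts as water/tissue.

## MTR

Zero-fill interpolation works in the spectral domain: per axis, FFT,
center with fftshift (frequency f at index f + n//2), embed in the larger
spectrum (f at f + m//2), split the Nyquist coefficient of even-length
axes evenly between ±n/2, inverse transform, scale by the factor. This
makes constants exact and preserves samples at original lattice positions
exactly; the imaginary residual is dropped and logged. MTR is computed
where MT_off exceeds the noise floor (default 3× background SD), NaN
elsewhere, and values above 100 % are retained — noise produces them and
clamping would bias statistics.

## Quantification and pipeline

Fat classification uses strict `PDFF > threshold`. Box ROIs are given in
mm from the volume origin (anatomical placement is not automated) and
converted with floor/ceil to half-open voxel intervals; the fat-ratio
denominator is the number of masked voxels in the box, not the full box.
Volumes are voxel counts times the voxel volume, exactly.

`run_pipeline` chains simulate → combine → ideal → relaxometry → pdff →
mtr → quantify on a seeded phantom, writes NIfTI maps, the histogram model
JSON, a CSV report with fixed float formatting (byte-identical across
reruns of the same config and seed), and a run log recording every decided
parameter. Species ROIs for the correction are the phantom's myocardium
and rim compartments — so the "tissue" and "fat" relaxation times are the
effective blended values, mirroring the approximation of fitting ROI means
on real data. Scanner data are processed stage by stage through the CLI
subcommands, which accept NIfTI volumes (complex data as paired
`_real`/`_imag` files).

## Problem sizes used in the tests

Phantom tests run on 32³ grids (64³ for the MT noise-calibration check);
the oracle comparisons use 100 random voxels at a 0.5 Hz grid; the mixture
recovery uses 10⁶ samples; relaxometry Monte-Carlo uses 1000 voxels. These
sizes were chosen so each check is statistically meaningful while the full
suite stays fast.

## Known limitations

Single-peak fat model; no T2*-IDEAL (no joint R2* map); no GRAPPA/k-space
undersampling; no Bloch–McConnell MT model (ratio-level only); no B1/flip
mapping; Rician statistics neither simulated nor corrected; box ROIs are
placed by coordinates, not anatomy. The phantom's relaxation defaults are
placeholders — recovering *configured* values says nothing about the true
relaxation times of fixed human tissue.
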