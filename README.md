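# cardiofat3d

3D post-processing for high-resolution cardiac water–fat and
magnetization-transfer MRI: from multi-coil, multi-echo gradient-echo
volumes to proton-density fat-fraction (PDFF) maps, magnetization-transfer
ratio (MTR) maps, and regional fat/fibrosis quantification — together with
a seeded digital heart phantom that provides ground truth for every stage.

## The problem

Fibro-fatty infiltration of the myocardium — the structural hallmark of
arrhythmogenic right ventricular cardiomyopathy (ARVC) and a substrate for
ventricular arrhythmias — can be imaged ex vivo at very high resolution
(200 µm isotropic at 9.4 T) with two complementary contrasts: chemical-shift
water–fat separation for adipose tissue, and magnetization transfer for
collagen (fibrosis). This package implements the full reconstruction chain
that turns such acquisitions into quantitative maps. Because raw specimen
data of this kind are rarely shareable, the package ships a digital cardiac
phantom (epicardial fat rim, myocardium, fibro-fatty patches, zero-signal
immersion bath, smooth B0 field, coil sensitivities, complex Gaussian noise)
so the whole chain is testable end to end.

## The method

**Coil combination.** Per echo, magnitude = root sum of squares over coils;
phase either as the literal per-coil phase sum or (default in the pipeline)
the phase of the coil-summed complex signal. The shortest echo's phase is
subtracted, so the solver sees effective echo times τₙ = tₙ − t₁.

**IDEAL water–fat separation.** Per voxel, the three-echo signal model

    sₙ = (ρ_w + ρ_f·exp(i2πf_F τₙ))·exp(i2πψ τₙ)

is solved for complex species amplitudes ρ_w, ρ_f and the field map ψ (Hz)
by iterative least squares: demodulate with the current ψ, solve the linear
amplitude problem, update ψ with an exact variable-projection Newton step.
Fat–water swaps (the second minimum at ψ ± f_F) are avoided hierarchically:
a dyadic coarse-to-fine pyramid anchors ψ near zero at the coarsest level
and propagates it with median filtering, trilinear upsampling, and a
neighborhood-median branch-consistency pass. A brute-force ψ-grid oracle is
included for validation.

**Relaxometry and proton-density correction.** Pixel-wise fits
S(TR) = kS₀(1 − e^(−TR/T1)) and S(TE) = kS₀·e^(−TE/T2*) give species
relaxation times from tissue and fat ROIs; W and F are corrected to proton
densities

    M_x = X·(1 − cosα·e^(−TR/T1x)) / (sinα·(1 − e^(−TR/T1x)))·e^(+TE/T2*_x)

and PDFF = 100·M_f/(M_w + M_f).

**Thresholds.** Masked PDFF values are histogrammed (1000 bins on
[0, 100] %) and fitted with a 4-component Gaussian mixture by weighted EM.
The water-only threshold T_C is the 99.99 % point of the water Gaussian
(μ_w + 3.71902·σ_w) snapped up to the next bin edge; the Dixon threshold
T_D is 50 %.

**MTR.** MT_on/MT_off volumes are sinc-interpolated to the PDFF grid by
zero-filling k-space, then MTR = 100·MT_on/MT_off where MT_off exceeds the
noise floor. PDFF-over-MTR composites flag fat, high-MTR-without-fat
(candidate fibrosis), and other tissue.

**Quantification.** Voxels with PDFF above threshold are tagged fat; box
ROIs (in mm) report total/fat/tissue volumes (cm³), fat voxel counts and
fat ratios.

## Worked example

Run the end-to-end phantom pipeline (32³ grid, 200 µm voxels, 4 coils,
per-channel noise SD 0.002):

```python
from cardiofat3d.quantify import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="run", seed=1, noise_sd=0.002,
                     mt_noise_sd=0.05, relaxometry_noise_sd=0.2)
run_pipeline(cfg)
```

The run log records the ROI-fitted species relaxation times
(T1 tissue/fat = 241.9/156.2 ms, T2* = 19.7/15.4 ms — the fat-fraction
weighted effective values of the phantom compartments), the estimated noise
SD (0.0014), a tissue mask of 10 376 voxels (ground truth: 10 344), and the
histogram thresholds T_C = 7.1 %, T_D = 50 %. `report.csv` then reads:

```
roi,total_cm3,fat_cm3,tissue_cm3,fat_voxels,fat_ratio_pct,threshold_pct,voxel_mm3
whole_volume,0.083008,0.032840,0.050168,4105,39.562452,7.100000,0.008000
```

i.e. 4 105 fat voxels → 0.033 cm³ of fat, a whole-volume fat ratio of
39.6 % at the data-driven threshold T_C = 7.1 % — within 0.2 percentage
points of the phantom's ground-truth ratio at that threshold. (T_C sits
just above the 5 % myocardial fat peak here because the noise-free water
peak is very narrow; with the published specimen data the same rule lands
near 40 %.)

The same stages are available from the shell:

```sh
cardiofat3d simulate --seed 1 --out sim/
cardiofat3d combine --in sim/ --mode complex_sum --out comb/
cardiofat3d ideal --in comb/ --out dec/
cardiofat3d all --config cfg.json
```

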