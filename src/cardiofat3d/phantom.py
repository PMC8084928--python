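"""Digital heart phantom with full ground truth.

The phantom emulates a fixed ex vivo heart immersed in a signal-free
perfluoropolyether bath: concentric ellipsoidal compartments for the
ventricular cavity, myocardium and epicardial fat rim, plus seeded
fibro-fatty infiltration patches inside the wall.  It simulates every
acquisition the processing pipeline consumes:

* spoiled-gradient-echo multi-coil multi-echo complex volumes for
  water-fat separation,
* an MT_on / MT_off magnitude pair on a coarser grid for the
  magnetization-transfer ratio,
* saturation-recovery and multi-gradient-echo magnitude series for
  T1 / T2* relaxometry.

All randomness is driven by explicit seeds; identical configuration and
seed produce bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .coilcombine import MultiEchoComplexImage

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "AcquisitionParams",
    "make_truth",
    "simulate_wf_echoes",
    "simulate_mt_pair",
    "simulate_relaxometry_series",
    "block_average",
    "coarse_mtr_truth",
    "spgr_amplitude",
]

#: Default saturation-recovery repetition times (ms).
DEFAULT_SATREC_TR_MS = (200.0, 400.0, 800.0, 1500.0, 5000.0, 10000.0)
#: Default multi-gradient-echo times: 8 echoes from 4 ms, 5 ms spacing (ms).
DEFAULT_MGE_TE_MS = tuple(4.0 + 5.0 * k for k in range(8))


class AcquisitionParams(BaseModel):
    """Spoiled-gradient-echo acquisition parameters for water-fat imaging.

    ``fat_offset_hz`` is the chemical-shift offset of the (single-peak) fat
    resonance relative to water: -3.4 ppm at a 400.2 MHz proton frequency
    (9.4 T) gives about -1361 Hz, fat resonating below water.  The phase
    convention for the fat term is ``exp(+i*2*pi*f_F*t)``.
    """

    tr_ms: float = 30.0
    echo_times_ms: tuple[float, ...] = (3.08, 3.31, 3.54)
    flip_deg: float = 17.0
    fat_offset_hz: float = -1361.0
    n_coils: int = 4
    noise_sd: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "AcquisitionParams":
        te = np.asarray(self.echo_times_ms)
        if len(te) < 3:
            raise ValueError("water-fat simulation needs at least 3 echoes")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if not 0.0 < self.flip_deg <= 90.0:
            raise ValueError("flip angle must be in (0, 90] degrees")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.n_coils < 1:
            raise ValueError("need at least one coil")
        return self


class PhantomConfig(BaseModel):
    """Geometry, composition and field configuration of the phantom.

    Compartment fat fractions are in percent.  ``psi_coeffs_hz`` are the
    coefficients (c0, cx, cy, cz) of an affine field map over normalized
    coordinates in [-1, 1] per axis, in Hz.  Relaxation defaults describe
    formalin-fixed, Gd-doped tissue and are deliberately short; they are
    plausible placeholders, configurable, and distinct between species.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (0.2, 0.2, 0.2)

    cavity_ff: float = 2.0
    myocardium_ff: float = 5.0
    rim_ff: float = 90.0
    patch_ff_range: tuple[float, float] = (40.0, 70.0)
    n_patches: int = 2
    total_density: float = 1.0

    t1w_ms: float = 250.0
    t1f_ms: float = 150.0
    t2sw_ms: float = 20.0
    t2sf_ms: float = 15.0

    psi_coeffs_hz: tuple[float, float, float, float] = (0.0, 60.0, 40.0, 25.0)

    mtr_cavity: float = 75.0
    mtr_myocardium: float = 65.0
    mtr_rim: float = 98.0
    mtr_fibrosis: float = 88.0
    n_fibrosis_patches: int = 2

    n_coils: int = 4
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomConfig":
        if min(self.shape) < 8:
            raise ValueError("phantom grid must be >= 8 voxels per axis "
                             "(the hierarchical field-map solver needs >= 2 levels)")
        for ff in (self.cavity_ff, self.myocardium_ff, self.rim_ff):
            if not 0.0 <= ff <= 100.0:
                raise ValueError("compartment fat fractions must lie in [0, 100]%")
        lo, hi = self.patch_ff_range
        if not (0.0 <= lo <= hi <= 100.0):
            raise ValueError("patch fat-fraction range must be ordered within [0, 100]%")
        return self


@dataclass
class PhantomTruth:
    """Ground-truth maps of the digital heart phantom.

    ``w0``/``f0`` are water/fat proton densities (arbitrary units, >= 0,
    both zero in the background bath).  ``fat_fraction`` is
    ``100*f0/(w0+f0)`` where tissue is present, 0 elsewhere.  ``psi_hz`` is
    the smooth B0 field-inhomogeneity map.  ``coil_sens`` holds one complex
    sensitivity volume per coil.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    w0: np.ndarray
    f0: np.ndarray
    fat_fraction: np.ndarray
    t1w_ms: float
    t1f_ms: float
    t2sw_ms: float
    t2sf_ms: float
    psi_hz: np.ndarray
    mtr_true: np.ndarray
    coil_sens: np.ndarray  # (n_coils, nx, ny, nz) complex
    background: np.ndarray  # bool, True where the signal-free bath is
    labels: np.ndarray = field(default=None)  # 0 bg, 1 cavity, 2 myo, 3 rim, 4 patch

    @property
    def foreground(self) -> np.ndarray:
        return ~self.background


def _normalized_coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def make_truth(config: PhantomConfig) -> PhantomTruth:
    """Build the ground-truth maps for a seeded phantom configuration.

    Geometry: concentric ellipsoids in normalized coordinates — cavity
    (r <= 0.35), myocardium (0.35 < r <= 0.78), epicardial fat rim
    (0.78 < r <= 0.92) — surrounded by a zero-signal bath; the myocardium
    holds the plurality of voxels so the PDFF histogram is water-peak
    dominated, as in a real heart.  Spherical
    fibro-fatty patches (fat fraction drawn from ``patch_ff_range``) and
    fibrosis-MTR patches are placed inside the myocardium at seeded
    positions.
    """
    rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.shape
    ux, uy, uz = _normalized_coords(config.shape)
    # Slightly anisotropic ellipsoid so no axis is degenerate.
    r = np.sqrt((ux / 1.00) ** 2 + (uy / 0.95) ** 2 + (uz / 0.90) ** 2)

    labels = np.zeros(config.shape, dtype=np.int8)
    labels[r <= 0.92] = 3  # fat rim
    labels[r <= 0.78] = 2  # myocardium
    labels[r <= 0.35] = 1  # cavity

    ff = np.zeros(config.shape)
    ff[labels == 1] = config.cavity_ff
    ff[labels == 2] = config.myocardium_ff
    ff[labels == 3] = config.rim_ff

    mtr = np.zeros(config.shape)
    mtr[labels == 1] = config.mtr_cavity
    mtr[labels == 2] = config.mtr_myocardium
    mtr[labels == 3] = config.mtr_rim

    # Fibro-fatty infiltration patches: spheres centred inside the wall.
    def _patch_centers(n: int) -> np.ndarray:
        centers = []
        while len(centers) < n:
            cand = rng.uniform(-0.8, 0.8, size=3)
            rr = np.sqrt((cand[0] / 1.0) ** 2 + (cand[1] / 0.95) ** 2 + (cand[2] / 0.9) ** 2)
            if 0.45 < rr < 0.68:
                centers.append(cand)
        return np.asarray(centers)

    patch_radius = 0.14
    for center in _patch_centers(config.n_patches):
        d = np.sqrt((ux - center[0]) ** 2 + (uy - center[1]) ** 2 + (uz - center[2]) ** 2)
        inside = (d <= patch_radius) & (labels == 2)
        ff[inside] = rng.uniform(*config.patch_ff_range)
        labels[inside] = 4
    for center in _patch_centers(config.n_fibrosis_patches):
        d = np.sqrt((ux - center[0]) ** 2 + (uy - center[1]) ** 2 + (uz - center[2]) ** 2)
        mtr[(d <= patch_radius) & (labels == 2)] = config.mtr_fibrosis

    background = labels == 0
    rho = np.where(background, 0.0, config.total_density)
    f0 = rho * ff / 100.0
    w0 = rho - f0
    fat_fraction = np.where(background, 0.0, ff)

    c0, cx, cy, cz = config.psi_coeffs_hz
    psi = c0 + cx * ux + cy * uy + cz * uz

    coil_sens = _coil_sensitivities(config.shape, config.n_coils, rng)

    return PhantomTruth(
        shape=tuple(config.shape),
        spacing_mm=tuple(config.spacing_mm),
        w0=w0,
        f0=f0,
        fat_fraction=fat_fraction,
        t1w_ms=config.t1w_ms,
        t1f_ms=config.t1f_ms,
        t2sw_ms=config.t2sw_ms,
        t2sf_ms=config.t2sf_ms,
        psi_hz=psi,
        mtr_true=mtr,
        coil_sens=coil_sens,
        background=background,
        labels=labels,
    )


def _coil_sensitivities(shape, n_coils: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth complex sensitivities for coils ringed around the volume.

    Phase offsets are kept within +/- 0.5 rad so the coil-summed signal
    never cancels destructively.
    """
    ux, uy, uz = _normalized_coords(shape)
    sens = np.empty((n_coils, *shape), dtype=np.complex128)
    for c in range(n_coils):
        theta = 2.0 * np.pi * c / n_coils
        cxy = np.array([1.4 * np.cos(theta), 1.4 * np.sin(theta), 0.0])
        d2 = (ux - cxy[0]) ** 2 + (uy - cxy[1]) ** 2 + (uz - cxy[2]) ** 2
        mag = 0.35 + np.exp(-d2 / (2.0 * 1.1**2))
        phase = rng.uniform(-0.4, 0.4) + 0.1 * (np.cos(theta) * ux + np.sin(theta) * uy)
        sens[c] = mag * np.exp(1j * phase)
    return sens


def spgr_amplitude(density: np.ndarray | float, t_ms, tr_ms: float,
                   flip_deg: float, t1_ms: float, t2s_ms: float) -> np.ndarray:
    """Steady-state spoiled-gradient-echo amplitude at echo time ``t_ms``.

    ``density * sin(a) * (1 - E1) / (1 - cos(a) * E1) * exp(-t/T2*)`` with
    ``E1 = exp(-TR/T1)``.
    """
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    return density * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1) * np.exp(-np.asarray(t_ms) / t2s_ms)


def simulate_wf_echoes(truth: PhantomTruth, params: AcquisitionParams) -> MultiEchoComplexImage:
    """Simulate per-coil per-echo complex volumes of the water-fat acquisition.

    Per coil c and echo n the signal is
    ``C_c * (A_w(t_n) + A_f(t_n) * exp(i*2*pi*f_F*t_n)) * exp(i*2*pi*psi*t_n) + eps``
    with the spoiled-gradient-echo amplitudes of :func:`spgr_amplitude` and
    complex Gaussian noise of the configured per-channel SD.
    """
    if truth.shape != truth.w0.shape or truth.coil_sens.shape[1:] != truth.w0.shape:
        raise ValueError("inconsistent truth grids")
    n_coils = truth.coil_sens.shape[0]
    if n_coils != params.n_coils:
        raise ValueError(
            f"truth has {n_coils} coil maps but params request {params.n_coils}")

    te = np.asarray(params.echo_times_ms, dtype=np.float64)
    rng = np.random.default_rng(params.seed)
    data = np.empty((n_coils, len(te), *truth.shape), dtype=np.complex128)
    for n, t in enumerate(te):
        t_s = t * 1e-3
        a_w = spgr_amplitude(truth.w0, t, params.tr_ms, params.flip_deg,
                             truth.t1w_ms, truth.t2sw_ms)
        a_f = spgr_amplitude(truth.f0, t, params.tr_ms, params.flip_deg,
                             truth.t1f_ms, truth.t2sf_ms)
        voxel = (a_w + a_f * np.exp(2j * np.pi * params.fat_offset_hz * t_s)) \
            * np.exp(2j * np.pi * truth.psi_hz * t_s)
        for c in range(n_coils):
            data[c, n] = truth.coil_sens[c] * voxel
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=(*data.shape, 2))
        data = data + noise[..., 0] + 1j * noise[..., 1]
    return MultiEchoComplexImage(data=data, echo_times_ms=te,
                                 spacing_mm=truth.spacing_mm)


def block_average(volume: np.ndarray, factor: int) -> np.ndarray:
    """Average non-overlapping ``factor``-cubed blocks (grid must divide evenly)."""
    if factor == 1:
        return volume.copy()
    shape = volume.shape
    if any(n % factor for n in shape):
        raise ValueError(f"downsample factor {factor} does not divide grid {shape}")
    view = volume.reshape(shape[0] // factor, factor,
                          shape[1] // factor, factor,
                          shape[2] // factor, factor)
    return view.mean(axis=(1, 3, 5))


def simulate_mt_pair(truth: PhantomTruth, noise_sd: float = 0.0,
                     downsample: int = 2, seed: int = 0,
                     signal_scale: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the MT_on / MT_off magnitude pair on the coarse MT grid.

    MT is modelled at the ratio level: the fine-grid reference signal is the
    total proton density, the saturated signal is that reference times
    ``mtr_true/100``, and both are block-averaged to the coarse grid before
    seeded Gaussian noise is added.  Rician magnitude statistics are not
    emulated, so the background sample SD equals the configured SD.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    off_fine = signal_scale * (truth.w0 + truth.f0)
    on_fine = off_fine * truth.mtr_true / 100.0
    mt_off = block_average(off_fine, downsample)
    mt_on = block_average(on_fine, downsample)
    if noise_sd > 0:
        mt_off = mt_off + rng.normal(0.0, noise_sd, mt_off.shape)
        mt_on = mt_on + rng.normal(0.0, noise_sd, mt_on.shape)
    return mt_on, mt_off


def coarse_mtr_truth(truth: PhantomTruth, downsample: int = 2) -> np.ndarray:
    """Signal-weighted ground-truth MTR on the coarse MT grid (NaN where empty).

    Blocks straddling the tissue/background border must be weighted by
    signal, not voxel count: the ratio of block-averaged signals is the
    quantity the MT pair actually encodes there.
    """
    rho = truth.w0 + truth.f0
    num = block_average(rho * truth.mtr_true, downsample)
    den = block_average(rho, downsample)
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out


def effective_relaxation(truth: PhantomTruth) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise effective (T1, T2*) in ms: fat-fraction-weighted harmonic blend.

    The downstream mapping fits mono-exponentials, so each voxel carries a
    single effective relaxation rate ``(1-ff)*R_w + ff*R_f``.
    """
    ff = truth.fat_fraction / 100.0
    r1 = (1.0 - ff) / truth.t1w_ms + ff / truth.t1f_ms
    r2 = (1.0 - ff) / truth.t2sw_ms + ff / truth.t2sf_ms
    return 1.0 / r1, 1.0 / r2


def simulate_relaxometry_series(
    truth: PhantomTruth,
    tr_list_ms=DEFAULT_SATREC_TR_MS,
    te_list_ms=DEFAULT_MGE_TE_MS,
    noise_sd: float = 0.0,
    seed: int = 0,
    signal_scale: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate saturation-recovery and multi-gradient-echo magnitude series.

    Saturation recovery: ``S(TR) = k*S0*(1 - exp(-TR/T1))``; multi-gradient
    echo: ``S(TE) = k*S0*exp(-TE/T2*)`` with voxel-wise effective relaxation
    from :func:`effective_relaxation`.  Returns arrays of shape
    ``(n_TR, *grid)`` and ``(n_TE, *grid)``.
    """
    tr = np.asarray(tr_list_ms, dtype=np.float64)
    te = np.asarray(te_list_ms, dtype=np.float64)
    if tr.size == 0 or te.size == 0:
        raise ValueError("TR and TE lists must be non-empty")
    rng = np.random.default_rng(seed)
    ks0 = signal_scale * (truth.w0 + truth.f0)
    t1, t2s = effective_relaxation(truth)
    satrec = ks0[None] * (1.0 - np.exp(-tr[:, None, None, None] / t1[None]))
    mge = ks0[None] * np.exp(-te[:, None, None, None] / t2s[None])
    if noise_sd > 0:
        satrec = satrec + rng.normal(0.0, noise_sd, satrec.shape)
        mge = mge + rng.normal(0.0, noise_sd, mge.shape)
    return satrec, mge
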