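"""Water-fat-field-map decomposition (IDEAL) with a hierarchical field map.

Per voxel the model for the echo-1-referenced complex signal is

    s_n = (rho_w + rho_f * exp(i*2*pi*f_F*tau_n)) * exp(i*2*pi*psi*tau_n)

with complex species amplitudes rho_w, rho_f (absorbing the echo-1 phase),
the fat chemical-shift offset f_F (Hz) and the field map psi (Hz).  The
per-voxel solver alternates (a) demodulation by the current psi, (b) a
linear least-squares solve for the amplitudes and (c) a linearized
field-map update, which is the classic iterative least-squares scheme for
chemical-shift species separation.

Because the three-echo residual is periodic in psi with period 1/(d tau)
and has a second (swapped) minimum offset by roughly f_F, a per-voxel solve
is only locally convergent — and the residual alone cannot choose the
branch, since for near-pure-fat voxels even tiny model mismatch (inter-echo
T2* decay, noise) can make the swapped minimum the deeper one.  The volume
solver therefore anchors psi at the coarsest pyramid level by a *local*
solve around zero (shimmed acquisitions keep |psi| well inside the capture
range of about half the fat-water offset), propagates it coarse-to-fine
with median filtering and trilinear upsampling, and pulls stragglers back
onto the spatially dominant branch with a neighborhood-median consistency
pass at every level.  An exhaustive one-period grid search remains
available (``coarse_global_search``) for strongly off-resonant data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "IdealSettings",
    "VoxelSolution",
    "WaterFatDecomposition",
    "solve_voxel",
    "brute_force_oracle",
    "solve_volume_hierarchical",
]


@dataclass
class IdealSettings:
    """Solver settings; the defaults are fixed package choices.

    ``fat_offset_hz`` must match the acquisition (fat below water at
    -1361 Hz for 9.4 T by default).  ``coarsest_size`` is the pyramid stop
    size per axis; ``median_radius`` the field-map filter radius between
    levels; ``psi_grid_step_hz`` the coarse-level search step.
    ``n_psi_starts`` > 1 makes the *per-voxel* solver multi-start across
    one aliasing period (global, oracle-equivalent behaviour).
    """

    fat_offset_hz: float = -1361.0
    max_iter: int = 30
    tol_hz: float = 0.1
    coarsest_size: int = 8
    median_radius: int = 1
    n_psi_starts: int = 1
    coarse_global_search: bool = False
    psi_grid_step_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.tol_hz <= 0:
            raise ValueError("tolerance must be positive")
        if self.coarsest_size < 4:
            raise ValueError("coarsest pyramid size must be >= 4")


@dataclass
class VoxelSolution:
    w: float
    f: float
    psi_hz: float
    residual: float
    iterations: int
    converged: bool


@dataclass
class WaterFatDecomposition:
    """Water/fat amplitude maps, field map and fit diagnostics."""

    water: np.ndarray
    fat: np.ndarray
    psi_hz: np.ndarray
    residual: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray
    settings: IdealSettings = field(default_factory=IdealSettings)


def _tau_seconds(tau_ms: np.ndarray) -> np.ndarray:
    tau = np.asarray(tau_ms, dtype=np.float64) * 1e-3
    if tau.size < 3:
        raise ValueError("need >= 3 echoes")
    if abs(tau[0]) > 1e-12:
        raise ValueError("effective echo times must start at tau_1 = 0")
    return tau


def _model_matrices(tau_s: np.ndarray, fat_offset_hz: float):
    """Complex basis, its pseudo-inverse, projector and real basis helpers."""
    c = np.exp(2j * np.pi * fat_offset_hz * tau_s)  # fat phasor per echo
    bc = np.stack([np.ones_like(c), c], axis=1)  # (E, 2)
    pinv = np.linalg.pinv(bc)  # (2, E)
    q = np.eye(len(tau_s)) - bc @ pinv  # residual projector (complex)
    # Real-valued basis for the amplitude perturbations, used to project the
    # field-map derivative out of the amplitude subspace.
    e = len(tau_s)
    b0 = np.zeros((2 * e, 4))
    b0[:e, 0] = 1.0
    b0[e:, 1] = 1.0
    b0[:e, 2], b0[e:, 2] = c.real, c.imag
    b0[:e, 3], b0[e:, 3] = -c.imag, c.real
    b0_pinv = np.linalg.pinv(b0)
    return c, bc, pinv, q, b0, b0_pinv


def principal_period_hz(tau_ms) -> float:
    """Field-map aliasing period 1/(d tau) in Hz for uniform echo spacing."""
    tau_s = _tau_seconds(tau_ms)
    return 1.0 / (tau_s[1] - tau_s[0])


def wrap_psi(psi_hz, period_hz: float):
    """Wrap psi into the half-open principal interval [-period/2, period/2)."""
    return np.mod(np.asarray(psi_hz) + period_hz / 2.0, period_hz) - period_hz / 2.0


def _solve_voxels(signals: np.ndarray, tau_s: np.ndarray, psi_init: np.ndarray,
                  settings: IdealSettings):
    """Vectorized alternating solve for a flat batch of voxels.

    Returns (rho (N,2) complex, psi_hz (N,), residual (N,), iterations (N,),
    converged (N,)).  psi is *not* wrapped here so callers can inspect the
    accumulated value.
    """
    _, bc, pinv, q, _, _ = _model_matrices(tau_s, settings.fat_offset_hz)
    theta = 2.0 * np.pi * tau_s  # d(demodulation phase)/d(psi_Hz) per echo
    period = 1.0 / (tau_s[1] - tau_s[0])
    n = signals.shape[0]
    psi = np.zeros(n, dtype=np.float64) + np.asarray(psi_init, dtype=np.float64)
    iterations = np.zeros(n, dtype=np.int32)
    active = np.ones(n, dtype=bool)
    zero = np.abs(signals).sum(axis=1) == 0.0
    active &= ~zero

    def _amplitudes(sig, psi_vals):
        demod = sig * np.exp(-1j * np.outer(psi_vals, theta))
        rho = demod @ pinv.T
        model = rho @ bc.T
        return demod, rho, model

    # Newton iteration on the variable-projection cost R(psi) = ||Q u(psi)||^2
    # with u = demodulated signal and Q the projector onto the complement of
    # the species subspace: quadratically convergent for consistent data.
    # Steps are backtracked to enforce monotone descent, so the iterate
    # always lands in the minimum nearest (downhill from) its start.
    qt = q.T  # row-vector application: (u @ q.T)[f] = (Q u)[f]

    def _cost(sig, psi_vals):
        u = sig * np.exp(-1j * np.outer(psi_vals, theta))
        qu = u @ qt
        return u, qu, np.einsum("ke,ke->k", qu.conj(), qu).real

    for _ in range(settings.max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        sig = signals[idx]
        u, qu, cost = _cost(sig, psi[idx])
        v = (theta * u) @ qt  # Q(theta*u); u' = -i*theta*u so Qu' = -i*v
        r1 = -2.0 * np.einsum("ke,ke->k", theta * u.conj(), qu).imag
        gn = 2.0 * np.einsum("ke,ke->k", v.conj(), v).real  # ||Qu'||^2 term
        r2 = gn - 2.0 * np.einsum("ke,ke->k", (theta**2) * u.conj(), qu).real
        denom = np.where(r2 > 1e-300, r2, np.maximum(gn, 1e-300))
        dpsi = -r1 / denom
        # Stationary points with negative curvature (maxima/saddles between
        # the two branch minima) would stall the iteration: kick away.
        at_max = (np.abs(dpsi) < settings.tol_hz) & (r2 <= 0) & (gn > 1e-300)
        dpsi = np.where(at_max, np.where(r1 <= 0, 1.0, -1.0) * period / 8.0, dpsi)
        dpsi = np.clip(dpsi, -period / 4.0, period / 4.0)
        for _bt in range(12):
            _, _, cost_new = _cost(sig, psi[idx] + dpsi)
            worse = cost_new > cost * (1.0 + 1e-12) + 1e-300
            if not worse.any():
                break
            dpsi[worse] *= 0.5
        psi[idx] += dpsi
        iterations[idx] += 1
        done = np.abs(dpsi) < settings.tol_hz
        active[idx[done]] = False

    _, rho, model = _amplitudes(signals, psi)
    residual = np.sum(np.abs(signals * np.exp(-1j * np.outer(psi, theta)) - model) ** 2, axis=1)
    rho[zero] = 0.0  # psi stays at its initialization for zero-signal voxels
    residual[zero] = 0.0
    converged = ~active
    return rho, psi, residual, iterations, converged


def _solve_voxels_multistart(signals, tau_s, psi_init, settings):
    """Run the local solver from several psi starts spanning one period.

    Keeps, per voxel, the candidate with the smallest residual; residual
    ties are broken toward the start nearest ``psi_init`` by trying starts
    in order of increasing offset magnitude and requiring strict
    improvement.
    """
    period = 1.0 / (tau_s[1] - tau_s[0])
    k = settings.n_psi_starts
    offsets = (np.arange(k) - k // 2) * (period / k)
    offsets = offsets[np.argsort(np.abs(offsets), kind="stable")]
    best = None
    for off in offsets:
        rho, psi, resid, iters, conv = _solve_voxels(
            signals, tau_s, np.asarray(psi_init, dtype=np.float64) + off, settings)
        if best is None:
            best = [rho, psi, resid, iters, conv]
            continue
        better = resid < best[2] - 1e-15
        for slot, new in zip(best, (rho, psi, resid, iters, conv)):
            slot[better] = new[better]
    return tuple(best)


def solve_voxel(signal, tau_ms, psi_init: float = 0.0,
                settings: IdealSettings | None = None) -> VoxelSolution:
    """Decompose a single voxel's echo-1-referenced complex signal.

    Returns magnitudes ``W = |rho_w|``, ``F = |rho_f|``, the field map
    wrapped into the principal interval, and the least-squares residual.
    An all-zero signal returns W = F = 0, psi = psi_init, residual 0.
    """
    settings = settings or IdealSettings()
    tau_s = _tau_seconds(tau_ms)
    signals = np.asarray(signal, dtype=np.complex128).reshape(1, -1)
    if signals.shape[1] != tau_s.size:
        raise ValueError("signal length must match the number of echoes")
    init = np.array([psi_init], dtype=np.float64)
    if settings.n_psi_starts > 1:
        rho, psi, resid, iters, conv = _solve_voxels_multistart(signals, tau_s, init, settings)
    else:
        rho, psi, resid, iters, conv = _solve_voxels(signals, tau_s, init, settings)
    period = 1.0 / (tau_s[1] - tau_s[0])
    psi_out = float(psi[0]) if np.abs(signals).sum() == 0 else float(wrap_psi(psi[0], period))
    return VoxelSolution(w=float(np.abs(rho[0, 0])), f=float(np.abs(rho[0, 1])),
                         psi_hz=psi_out, residual=float(resid[0]),
                         iterations=int(iters[0]), converged=bool(conv[0]))


def brute_force_oracle(signal, tau_ms, settings: IdealSettings | None = None,
                       grid_step_hz: float = 0.5, psi_init: float = 0.0) -> VoxelSolution:
    """Exhaustive field-map grid search over one aliasing period.

    For every psi on the grid the linear amplitude problem is solved
    exactly; the global residual minimizer is returned (ties broken toward
    the grid point closest to ``psi_init``).  This is the independent
    reference the iterative solver is validated against.
    """
    settings = settings or IdealSettings()
    tau_s = _tau_seconds(tau_ms)
    if grid_step_hz > 1.0:
        raise ValueError("oracle grid step must be <= 1 Hz")
    sig = np.asarray(signal, dtype=np.complex128).reshape(-1)
    _, bc, pinv, q, _, _ = _model_matrices(tau_s, settings.fat_offset_hz)
    period = 1.0 / (tau_s[1] - tau_s[0])
    grid = _psi_grid(period, grid_step_hz)
    theta = 2.0 * np.pi * tau_s
    demod = sig[None, :] * np.exp(-1j * np.outer(grid, theta))
    resid = np.sum(np.abs(demod @ q.T) ** 2, axis=1)
    rmin = resid.min()
    ties = np.nonzero(resid <= rmin + 1e-12 * (1.0 + rmin))[0]
    dist = np.abs(wrap_psi(grid[ties] - psi_init, period))
    best = ties[np.argmin(dist)]
    rho = demod[best] @ pinv.T
    return VoxelSolution(w=float(np.abs(rho[0])), f=float(np.abs(rho[1])),
                         psi_hz=float(grid[best]), residual=float(resid[best]),
                         iterations=0, converged=True)


def _psi_grid(period: float, step: float) -> np.ndarray:
    """Zero-aligned grid of multiples of ``step`` spanning one period."""
    half = int(np.floor((period / 2.0) / step))
    n = int(np.ceil(period / step))
    return (np.arange(n) - half) * step


def _coarse_grid_search(signals: np.ndarray, tau_s: np.ndarray,
                        settings: IdealSettings) -> np.ndarray:
    """Vectorized one-period grid search returning psi (Hz) per voxel."""
    _, _, _, q, _, _ = _model_matrices(tau_s, settings.fat_offset_hz)
    period = 1.0 / (tau_s[1] - tau_s[0])
    grid = _psi_grid(period, settings.psi_grid_step_hz)
    theta = 2.0 * np.pi * tau_s
    phasor = np.exp(-1j * np.outer(grid, theta))  # (G, E)
    psi = np.zeros(signals.shape[0])
    chunk = 4096
    for lo in range(0, signals.shape[0], chunk):
        s = signals[lo:lo + chunk]
        demod = s[:, None, :] * phasor[None, :, :]
        resid = np.sum(np.abs(np.einsum("vge,fe->vgf", demod, q)) ** 2, axis=2)
        psi[lo:lo + chunk] = grid[np.argmin(resid, axis=1)]
    psi[np.abs(signals).sum(axis=1) == 0.0] = 0.0  # flat residual: no information
    return psi


def _pad_to_even(vol: np.ndarray) -> np.ndarray:
    pads = [(0, n % 2) for n in vol.shape[-3:]]
    if not any(p[1] for p in pads):
        return vol
    pads = [(0, 0)] * (vol.ndim - 3) + pads
    return np.pad(vol, pads, mode="edge")


def _block_average_echoes(echoes: np.ndarray) -> np.ndarray:
    """Complex 2x block average of an (E, nx, ny, nz) stack, edge-padding odd axes."""
    e = _pad_to_even(echoes)
    _, nx, ny, nz = e.shape
    view = e.reshape(e.shape[0], nx // 2, 2, ny // 2, 2, nz // 2, 2)
    return view.mean(axis=(2, 4, 6))


def _fill_from_foreground(psi: np.ndarray, foreground: np.ndarray) -> np.ndarray:
    """Replace signal-free voxels by the nearest signal voxel's field value.

    Zero-signal voxels carry no field information; left at an arbitrary
    value they would corrupt the median filter and the coarse-to-fine
    initialization near tissue borders.
    """
    if foreground.all() or not foreground.any():
        return psi
    idx = ndimage.distance_transform_edt(~foreground, return_distances=False,
                                         return_indices=True)
    return psi[tuple(idx)]


def _median_filter_psi(psi: np.ndarray, radius: int) -> np.ndarray:
    if radius < 1:
        return psi
    return ndimage.median_filter(psi, size=2 * radius + 1, mode="nearest")


def _branch_consistency(psi: np.ndarray, flat: np.ndarray, tau_s: np.ndarray,
                        foreground: np.ndarray, settings: IdealSettings,
                        passes: int = 4) -> np.ndarray:
    """Pull field-map outliers back onto the spatially dominant branch.

    A voxel whose psi differs from its neighborhood median by more than
    half the fat-water offset sits on the swapped branch (the residual
    alone cannot distinguish the branches for near-pure-fat voxels); it is
    re-solved locally starting from that median.
    """
    cut = abs(settings.fat_offset_hz) / 2.0
    psi = psi.copy()
    for _ in range(passes):
        med = _median_filter_psi(_fill_from_foreground(psi, foreground),
                                 max(settings.median_radius, 1))
        bad = (np.abs(psi - med) > cut) & foreground
        if not bad.any():
            break
        sel = bad.ravel()
        _, p, _, _, _ = _solve_voxels(flat[sel], tau_s, med.ravel()[sel], settings)
        psi.ravel()[sel] = p
    return psi


def solve_volume_hierarchical(combined, settings: IdealSettings | None = None) -> WaterFatDecomposition:
    """Hierarchical coarse-to-fine water-fat decomposition of a volume.

    A dyadic pyramid is built by complex block-averaging the referenced
    echo images; the coarsest level's field map is anchored by a local
    solve from psi_init = 0 (or an exhaustive one-period grid search when
    ``coarse_global_search`` is on), then each finer level is initialized
    with the median-filtered, trilinearly upsampled coarser field map, and
    a neighborhood-median consistency pass repairs fat-water branch
    outliers at every level.
    """
    settings = settings or IdealSettings()
    if combined.relative_phase is None:
        from .coilcombine import reference_to_first_echo
        combined = reference_to_first_echo(combined)
    echoes = combined.complex_referenced()
    tau_s = _tau_seconds(combined.tau_ms)

    pyramid = [echoes]
    while min(pyramid[-1].shape[1:]) > settings.coarsest_size:
        pyramid.append(_block_average_echoes(pyramid[-1]))
    pyramid = pyramid[::-1]  # coarsest first

    psi = None
    for vol in pyramid:
        shape = vol.shape[1:]
        flat = vol.reshape(vol.shape[0], -1).T  # (N, E)
        foreground = (np.abs(flat).sum(axis=1) > 0.0).reshape(shape)
        if psi is None:
            if settings.coarse_global_search:
                init = _coarse_grid_search(flat, tau_s, settings)
            else:
                init = np.zeros(flat.shape[0])
            init = _fill_from_foreground(init.reshape(shape), foreground)
            init = _median_filter_psi(init, settings.median_radius).ravel()
        else:
            psi_f = _median_filter_psi(psi, settings.median_radius)
            zoom = [t / s for t, s in zip(shape, psi_f.shape)]
            init = ndimage.zoom(psi_f, zoom, order=1, mode="nearest",
                                grid_mode=True).ravel()
        rho, psi_flat, resid, iters, conv = _solve_voxels(flat, tau_s, init, settings)
        psi = _branch_consistency(psi_flat.reshape(shape), flat, tau_s,
                                  foreground, settings)
        # Re-solve amplitudes wherever the consistency pass moved psi.
        moved = (psi.ravel() != psi_flat) & foreground.ravel()
        if moved.any():
            rho_m, psi_m, resid_m, iters_m, conv_m = _solve_voxels(
                flat[moved], tau_s, psi.ravel()[moved], settings)
            rho[moved], resid[moved] = rho_m, resid_m
            iters[moved] += iters_m
            conv[moved] = conv_m
            psi.ravel()[moved] = psi_m
        psi = _fill_from_foreground(psi, foreground)

    period = 1.0 / (tau_s[1] - tau_s[0])
    shape = echoes.shape[1:]
    return WaterFatDecomposition(
        water=np.abs(rho[:, 0]).reshape(shape),
        fat=np.abs(rho[:, 1]).reshape(shape),
        psi_hz=np.asarray(wrap_psi(psi, period)),
        residual=resid.reshape(shape),
        iterations=iters.reshape(shape),
        converged=conv.reshape(shape),
        settings=settings,
    )
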