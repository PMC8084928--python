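"""Pixel-wise T1 (saturation recovery) and T2* (multi-gradient-echo) mapping.

Both fits are mono-exponential, two-parameter nonlinear least squares:

    S(TR) = k*S0 * (1 - exp(-TR/T1))
    S(TE) = k*S0 * exp(-TE/T2*)

solved voxel-wise with a vectorized Levenberg-Marquardt iteration on the
rate parametrization (k, R = 1/T).  Initialization: the saturation-recovery
fit starts from the half-maximum recovery time, the decay fit from a
signal-weighted log-linear regression.  Voxels below the signal floor or
with degenerate series are flagged invalid rather than silently zeroed.
Magnitude (Rician) noise bias is not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RelaxationMaps",
    "SpeciesRelaxation",
    "fit_t1_map",
    "fit_t2star_map",
    "roi_mean",
]


@dataclass
class RelaxationMaps:
    """Voxel-wise relaxation fit results; invalid voxels carry NaN and valid=False."""

    t1_ms: np.ndarray | None
    t2star_ms: np.ndarray | None
    ks0: np.ndarray
    residual_norm: np.ndarray
    valid: np.ndarray

    @property
    def time_constant_ms(self) -> np.ndarray:
        return self.t1_ms if self.t1_ms is not None else self.t2star_ms


@dataclass
class SpeciesRelaxation:
    """ROI-mean relaxation times for the two species (cardiac tissue, fat), ms."""

    t1w_ms: float
    t1f_ms: float
    t2sw_ms: float
    t2sf_ms: float

    def __post_init__(self) -> None:
        for name in ("t1w_ms", "t1f_ms", "t2sw_ms", "t2sf_ms"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


def _lm_fit(series: np.ndarray, x: np.ndarray, model, jac, p0: np.ndarray,
            max_iter: int = 200, tol: float = 1e-12):
    """Vectorized Levenberg-Marquardt for a batch of 2-parameter fits.

    ``series`` is (N, M), ``p0`` is (N, 2); ``model(x, p)`` and
    ``jac(x, p)`` return (N, M) and (N, M, 2).  Returns (p, cost, converged).
    """
    p = p0.copy()
    lam = np.full(p.shape[0], 1e-3)
    resid = series - model(x, p)
    cost = np.einsum("nm,nm->n", resid, resid)
    converged = np.zeros(p.shape[0], dtype=bool)
    for _ in range(max_iter):
        if converged.all():
            break
        j = jac(x, p)
        a = np.einsum("nmi,nmj->nij", j, j)
        g = np.einsum("nmi,nm->ni", j, resid)
        diag = np.maximum(np.einsum("nii->ni", a), 1e-300)
        aa = a.copy()
        aa[:, 0, 0] += lam * diag[:, 0]
        aa[:, 1, 1] += lam * diag[:, 1]
        det = aa[:, 0, 0] * aa[:, 1, 1] - aa[:, 0, 1] * aa[:, 1, 0]
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step = np.empty_like(g)
        step[:, 0] = (aa[:, 1, 1] * g[:, 0] - aa[:, 0, 1] * g[:, 1]) / det
        step[:, 1] = (aa[:, 0, 0] * g[:, 1] - aa[:, 1, 0] * g[:, 0]) / det
        p_new = p + step
        p_new[:, 1] = np.maximum(p_new[:, 1], 1e-12)  # rates stay positive
        resid_new = series - model(x, p_new)
        cost_new = np.einsum("nm,nm->n", resid_new, resid_new)
        improved = cost_new <= cost
        p[improved] = p_new[improved]
        resid[improved] = resid_new[improved]
        lam = np.where(improved, lam / 3.0, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e12)
        small_step = np.max(np.abs(step) / (np.abs(p) + 1e-30), axis=1) < tol
        converged |= improved & small_step
        cost = np.where(improved, cost_new, cost)
    return p, cost, converged


def _satrec_model(tr, p):
    return p[:, 0:1] * (1.0 - np.exp(-tr[None, :] * p[:, 1:2]))


def _satrec_jac(tr, p):
    e = np.exp(-tr[None, :] * p[:, 1:2])
    j = np.empty((p.shape[0], tr.size, 2))
    j[:, :, 0] = 1.0 - e
    j[:, :, 1] = p[:, 0:1] * tr[None, :] * e
    return j


def _decay_model(te, p):
    return p[:, 0:1] * np.exp(-te[None, :] * p[:, 1:2])


def _decay_jac(te, p):
    e = np.exp(-te[None, :] * p[:, 1:2])
    j = np.empty((p.shape[0], te.size, 2))
    j[:, :, 0] = e
    j[:, :, 1] = -p[:, 0:1] * te[None, :] * e
    return j


def _flatten_series(series: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    series = np.asarray(series, dtype=np.float64)
    spatial = series.shape[1:]
    return series.reshape(series.shape[0], -1).T, spatial


def fit_t1_map(series: np.ndarray, tr_list_ms, signal_floor: float = 0.0) -> RelaxationMaps:
    """Fit ``S(TR) = k*S0*(1 - exp(-TR/T1))`` voxel-wise.

    ``series`` is (n_TR, ...spatial...) magnitude data at strictly
    increasing repetition times.  kS0 is initialized at the maximum signal
    and T1 at the half-maximum recovery time (linear interpolation between
    the bracketing TRs).  Voxels at/below ``signal_floor`` or with a
    degenerate (flat) series are invalid.
    """
    tr = np.asarray(tr_list_ms, dtype=np.float64)
    if tr.size < 3:
        raise ValueError("need >= 3 TR points for a T1 fit")
    if np.any(np.diff(tr) <= 0):
        raise ValueError("TR values must be strictly increasing")
    data, spatial = _flatten_series(series)
    if data.shape[1] != tr.size:
        raise ValueError("series length does not match TR list")

    smax = data.max(axis=1)
    fittable = (smax > signal_floor) & (smax - data.min(axis=1) > 1e-12 * np.maximum(smax, 1.0))

    # Half-maximum recovery time -> T1 = TR_half / ln 2.
    half = 0.5 * smax
    above = data >= half[:, None]
    first = np.argmax(above, axis=1)
    tr_half = tr[first].astype(np.float64)
    has_prev = first > 0
    idx = np.nonzero(has_prev)[0]
    if idx.size:
        i1 = first[idx]
        s0, s1 = data[idx, i1 - 1], data[idx, i1]
        frac = np.where(s1 > s0, (half[idx] - s0) / np.maximum(s1 - s0, 1e-30), 0.0)
        tr_half[idx] = tr[i1 - 1] + frac * (tr[i1] - tr[i1 - 1])
    t1_init = np.clip(tr_half / np.log(2.0), tr[0] * 0.05, tr[-1] * 10.0)

    p0 = np.stack([smax, 1.0 / t1_init], axis=1)
    t1 = np.full(data.shape[0], np.nan)
    ks0 = np.full(data.shape[0], np.nan)
    rnorm = np.full(data.shape[0], np.nan)
    valid = np.zeros(data.shape[0], dtype=bool)
    if fittable.any():
        sel = np.nonzero(fittable)[0]
        p, cost, conv = _lm_fit(data[sel], tr, _satrec_model, _satrec_jac, p0[sel])
        ok = conv & (p[:, 1] > 0) & np.isfinite(cost)
        t1[sel] = np.where(ok, 1.0 / p[:, 1], np.nan)
        ks0[sel] = np.where(ok, p[:, 0], np.nan)
        rnorm[sel] = np.sqrt(cost)
        valid[sel] = ok
    return RelaxationMaps(t1_ms=t1.reshape(spatial), t2star_ms=None,
                          ks0=ks0.reshape(spatial),
                          residual_norm=rnorm.reshape(spatial),
                          valid=valid.reshape(spatial))


def fit_t2star_map(series: np.ndarray, te_list_ms, signal_floor: float = 0.0) -> RelaxationMaps:
    """Fit ``S(TE) = k*S0*exp(-TE/T2*)`` voxel-wise.

    Initialization is a signal-weighted log-linear regression over the
    strictly positive samples, refined by Levenberg-Marquardt; voxels with
    fewer than two positive samples, at/below ``signal_floor``, or with a
    flat series are invalid.
    """
    te = np.asarray(te_list_ms, dtype=np.float64)
    if te.size < 3:
        raise ValueError("need >= 3 echoes for a T2* fit")
    data, spatial = _flatten_series(series)
    if data.shape[1] != te.size:
        raise ValueError("series length does not match TE list")

    smax = data.max(axis=1)
    pos = data > 0
    npos = pos.sum(axis=1)
    fittable = (smax > signal_floor) & (npos >= 2) & \
        (smax - data.min(axis=1) > 1e-12 * np.maximum(smax, 1.0))

    # Weighted log-linear init: ln S = ln k - TE * R2, weights S^2.
    w = np.where(pos, data, 0.0) ** 2
    logs = np.where(pos, np.log(np.maximum(data, 1e-300)), 0.0)
    sw = w.sum(axis=1) + 1e-300
    mx = (w * te[None, :]).sum(axis=1) / sw
    my = (w * logs).sum(axis=1) / sw
    sxx = (w * (te[None, :] - mx[:, None]) ** 2).sum(axis=1) + 1e-300
    sxy = (w * (te[None, :] - mx[:, None]) * (logs - my[:, None])).sum(axis=1)
    r2_init = np.clip(-sxy / sxx, 1e-6, 1e3)
    k_init = np.exp(my + mx * r2_init)

    p0 = np.stack([k_init, r2_init], axis=1)
    t2s = np.full(data.shape[0], np.nan)
    ks0 = np.full(data.shape[0], np.nan)
    rnorm = np.full(data.shape[0], np.nan)
    valid = np.zeros(data.shape[0], dtype=bool)
    if fittable.any():
        sel = np.nonzero(fittable)[0]
        p, cost, conv = _lm_fit(data[sel], te, _decay_model, _decay_jac, p0[sel])
        ok = conv & (p[:, 1] > 0) & np.isfinite(cost)
        t2s[sel] = np.where(ok, 1.0 / p[:, 1], np.nan)
        ks0[sel] = np.where(ok, p[:, 0], np.nan)
        rnorm[sel] = np.sqrt(cost)
        valid[sel] = ok
    return RelaxationMaps(t1_ms=None, t2star_ms=t2s.reshape(spatial),
                          ks0=ks0.reshape(spatial),
                          residual_norm=rnorm.reshape(spatial),
                          valid=valid.reshape(spatial))


def roi_mean(volume: np.ndarray, roi: np.ndarray, valid: np.ndarray | None = None,
             name: str = "ROI") -> tuple[float, int]:
    """Arithmetic mean of ``volume`` over the boolean ``roi``.

    Voxels flagged invalid (``valid`` False, or NaN values) are excluded;
    returns (mean, number of voxels used).
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != np.asarray(volume).shape:
        raise ValueError(f"{name}: ROI shape does not match the volume")
    if not roi.any():
        raise ValueError(f"{name}: ROI is empty")
    use = roi & np.isfinite(volume)
    if valid is not None:
        use &= np.asarray(valid, dtype=bool)
    n = int(use.sum())
    if n == 0:
        raise ValueError(f"{name}: all ROI voxels are invalid")
    return float(np.mean(np.asarray(volume)[use])), n
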