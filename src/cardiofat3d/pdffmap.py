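"""Proton-density fat fraction: relaxation correction, masking, histogram model.

The water/fat amplitudes of a spoiled-gradient-echo acquisition carry T1
saturation and T2* decay weighting.  The proton-density correction removes
both with species-specific relaxation times,

    M_x = X * (1 - cos(a)*E1x) / (sin(a) * (1 - E1x)) * exp(+TE_ref/T2*_x),

(the positive exponent compensates the decay accrued at the reference
echo), after which PDFF = 100 * M_f / (M_w + M_f).

Voxel classification thresholds come from the pooled PDFF histogram of
masked voxels (1000 bins on [0, 100]%): a 4-component Gaussian mixture is
fitted by weighted EM, the water component is the one at the histogram
mode, and the water-only threshold T_C is the 99.99% point of that
Gaussian snapped up to the next bin edge.  The Dixon threshold T_D is
fixed at 50%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .relaxometry import SpeciesRelaxation

__all__ = [
    "PDFFMap",
    "TissueMask",
    "HistogramModel",
    "correct_proton_density",
    "compute_pdff",
    "estimate_noise_sd",
    "build_tissue_mask",
    "fit_histogram_gmm",
    "select_thresholds",
]

logger = logging.getLogger(__name__)

#: Standard-normal quantile at 0.9999, the water-Gaussian cut for T_C.
Z_9999 = float(stats.norm.ppf(0.9999))


@dataclass
class PDFFMap:
    """Fat-fraction volume in percent; voxels outside the mask are NaN."""

    values: np.ndarray
    mask_applied: bool
    te_ref_ms: float
    n_clipped: int = 0


@dataclass
class TissueMask:
    """Boolean tissue mask with the parameters that reproduce it."""

    mask: np.ndarray
    noise_sd: float
    k: float
    provenance: list = field(default_factory=list)


@dataclass
class HistogramModel:
    """PDFF histogram with its fitted Gaussian mixture and thresholds.

    ``water_mu``/``water_sd`` (and the fat counterparts) are the
    moment-matched Gaussian of the water (fat) *cluster* of mixture
    components: an overparametrized mixture is free to split a perfectly
    Gaussian peak among several overlapping components, so thresholds are
    derived from the merged cluster moments, which are stable against that
    splitting, rather than from a single component.
    """

    bin_edges: np.ndarray  # 1001 edges over [0, 100]
    counts: np.ndarray
    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K,) percent
    sds: np.ndarray  # (K,) percent
    water_idx: int
    fat_idx: int
    water_mu: float = np.nan
    water_sd: float = np.nan
    fat_mu: float = np.nan
    fat_sd: float = np.nan
    t_c: float | None = None
    t_d: float = 50.0

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def correct_proton_density(w: np.ndarray, f: np.ndarray, flip_deg: float,
                           tr_ms: float, te_ref_ms: float,
                           species: SpeciesRelaxation) -> tuple[np.ndarray, np.ndarray]:
    """Convert W/F signal amplitudes into proton-density images (M_w, M_f)."""
    a = np.deg2rad(flip_deg)
    if np.sin(a) == 0.0:
        raise ValueError("flip angle of 0 degrees makes the correction undefined")

    def factor(t1_ms: float, t2s_ms: float) -> float:
        e1 = np.exp(-tr_ms / t1_ms)
        return (1.0 - np.cos(a) * e1) / (np.sin(a) * (1.0 - e1)) * np.exp(te_ref_ms / t2s_ms)

    m_w = np.asarray(w, dtype=np.float64) * factor(species.t1w_ms, species.t2sw_ms)
    m_f = np.asarray(f, dtype=np.float64) * factor(species.t1f_ms, species.t2sf_ms)
    return m_w, m_f


def compute_pdff(m_w: np.ndarray, m_f: np.ndarray,
                 mask: TissueMask | None = None,
                 te_ref_ms: float = 3.08) -> PDFFMap:
    """PDFF = 100 * M_f / (M_w + M_f); zero-signal voxels map to 0%.

    Negative inputs are clipped to zero (count logged); voxels outside the
    mask are set to NaN.
    """
    m_w = np.asarray(m_w, dtype=np.float64)
    m_f = np.asarray(m_f, dtype=np.float64)
    if m_w.shape != m_f.shape:
        raise ValueError("M_w / M_f shape mismatch")
    n_clipped = int((m_w < 0).sum() + (m_f < 0).sum())
    if n_clipped:
        logger.info("clipped %d negative proton-density values to 0", n_clipped)
    m_w = np.clip(m_w, 0.0, None)
    m_f = np.clip(m_f, 0.0, None)
    denom = m_w + m_f
    pdff = np.zeros_like(denom)
    np.divide(100.0 * m_f, denom, out=pdff, where=denom > 0)
    applied = mask is not None
    if applied:
        if mask.mask.shape != pdff.shape:
            raise ValueError("mask shape mismatch")
        pdff = np.where(mask.mask, pdff, np.nan)
    return PDFFMap(values=pdff, mask_applied=applied, te_ref_ms=te_ref_ms,
                   n_clipped=n_clipped)


def estimate_noise_sd(magnitude: np.ndarray, roi: np.ndarray) -> float:
    """Sample SD (n-1) of magnitude values in a noise-only ROI.

    No Rician correction is applied.  The ROI must lie outside the object;
    a warning is raised when it looks signal-contaminated.
    """
    roi = np.asarray(roi, dtype=bool)
    vals = np.asarray(magnitude, dtype=np.float64)[roi].ravel()
    if vals.size < 10:
        raise ValueError(f"noise ROI has only {vals.size} voxels (need >= 10)")
    if vals.size < 100:
        warnings.warn(f"noise ROI has only {vals.size} voxels; SD estimate is coarse")
    sd = float(np.std(vals, ddof=1))
    if sd > 0 and float(vals.mean()) > 5.0 * sd:
        warnings.warn("noise ROI mean exceeds 5x its SD; it may contain signal")
    return sd


def build_tissue_mask(echo_magnitudes: np.ndarray, sigma: float, k: float = 3.0,
                      user_mask: np.ndarray | None = None,
                      offset: float = 0.0) -> TissueMask:
    """Threshold the root-sum-of-squares of the echo magnitudes at
    ``offset + k*sigma``.

    ``offset`` defaults to 0 (the plain 3-sigma rule); for multi-coil,
    multi-echo root-sum-of-squares data the background floor is
    chi-distributed with a nonzero mean, which callers should pass as
    ``offset`` so the threshold sits above the floor.

    The initial threshold mask is refined deterministically (replacing the
    interactive segmentation a human operator would do): morphological
    closing with a radius-1 cross-shaped element, then retention of the
    largest 26-connected component.  An optional ``user_mask`` volume with
    values +1 (force include) / -1 (force exclude) is applied last.
    """
    if sigma < 0:
        raise ValueError("noise SD must be non-negative")
    mags = np.asarray(echo_magnitudes, dtype=np.float64)
    combined = np.sqrt(np.sum(mags**2, axis=0))
    if sigma == 0.0 and k > 0:
        warnings.warn("sigma = 0: mask keeps all strictly positive voxels")
    provenance = [{"step": "threshold", "k": k, "sigma": sigma, "offset": offset}]
    mask = combined > offset + k * sigma

    structure = ndimage.generate_binary_structure(3, 1)
    # Pad before closing: the default zero border would erode structures
    # touching the volume edge.
    padded = np.pad(mask, 1)
    mask = ndimage.binary_closing(padded, structure=structure)[1:-1, 1:-1, 1:-1]
    provenance.append({"step": "binary_closing", "radius": 1})

    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + int(np.argmax(counts)))
    provenance.append({"step": "largest_26_connected_component", "n_components": int(n)})

    if user_mask is not None:
        user_mask = np.asarray(user_mask)
        mask = mask | (user_mask > 0)
        mask = mask & ~(user_mask < 0)
        provenance.append({"step": "user_mask",
                           "added": int((user_mask > 0).sum()),
                           "removed": int((user_mask < 0).sum())})
    return TissueMask(mask=mask, noise_sd=sigma, k=k, provenance=provenance)


def _weighted_em(x: np.ndarray, w: np.ndarray, means: np.ndarray, sds: np.ndarray,
                 weights: np.ndarray, bin_width: float, max_iter: int = 500,
                 tol: float = 1e-8):
    """EM for a 1D Gaussian mixture on weighted points (histogram bin centers).

    Components whose SD collapses below the bin width are pruned and the
    remaining mixture is refitted.  Returns (weights, means, sds, loglik).
    """
    means, sds, weights = means.copy(), sds.copy(), weights.copy()
    wsum = w.sum()
    ll_old = -np.inf
    it = 0
    while it < max_iter:
        it += 1
        comp = weights[:, None] * stats.norm.pdf(x[None, :], means[:, None],
                                                 np.maximum(sds[:, None], 1e-12))
        total = comp.sum(axis=0)
        total = np.maximum(total, 1e-300)
        ll = float(np.sum(w * np.log(total)))
        resp = comp / total[None, :]
        nk = (resp * w[None, :]).sum(axis=1)
        ok = nk > 1e-12 * wsum
        weights = nk / wsum
        means = np.where(ok, (resp * w[None, :] * x[None, :]).sum(axis=1) / np.maximum(nk, 1e-300), means)
        var = (resp * w[None, :] * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / np.maximum(nk, 1e-300)
        sds = np.where(ok, np.sqrt(np.maximum(var, 0.0)), sds)

        degenerate = (sds < bin_width) | ~ok
        if degenerate.any() and (~degenerate).sum() >= 1 and degenerate.sum() < len(means):
            keep = ~degenerate
            logger.info("pruning %d degenerate mixture component(s)", int(degenerate.sum()))
            means, sds = means[keep], sds[keep]
            weights = weights[keep] / weights[keep].sum()
            ll_old = -np.inf
            continue
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    weights = weights / weights.sum()
    return weights, means, sds, ll


def fit_histogram_gmm(pdff: PDFFMap, mask: TissueMask | None = None,
                      bins: int = 1000, components: int = 4,
                      seed: int = 0) -> HistogramModel:
    """Histogram the masked PDFF values and fit a Gaussian mixture by EM.

    The pooled histogram (1000 equal bins on [0, 100]%) is fitted on its
    bin centers with counts as weights.  Initialization: water mean at the
    global histogram mode, fat mean at the second-highest local maximum at
    least 10 percentage points away, the two spare components at the
    33rd/67th percentiles; equal weights; SDs = sample SD / 4.  ``seed`` is
    accepted for interface stability (the deterministic initialization
    uses no randomness).
    """
    del seed  # initialization is deterministic
    values = pdff.values[mask.mask] if mask is not None else pdff.values.ravel()
    values = values[np.isfinite(values)]
    if values.size < 10**4:
        warnings.warn(f"histogram built from only {values.size} voxels "
                      "(statistics below the intended operating range)")
    if values.size == 0:
        raise ValueError("no masked PDFF values to histogram")
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 100.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]

    sample_sd = float(np.std(values))
    if sample_sd == 0.0:
        # All masked voxels identical: single surviving component.
        value = float(values[0])
        model = HistogramModel(bin_edges=edges, counts=counts,
                               weights=np.array([1.0]), means=np.array([value]),
                               sds=np.array([0.0]), water_idx=0, fat_idx=0,
                               water_mu=value, water_sd=0.0,
                               fat_mu=value, fat_sd=0.0)
        return model

    mode = centers[int(np.argmax(counts))]
    sep = max(int(round(10.0 / bin_width)), 1)  # >= 10 pp peak separation
    from scipy.signal import find_peaks

    peaks, props = find_peaks(counts, distance=sep)
    if peaks.size:
        order = np.argsort(counts[peaks])[::-1]
        water_init = centers[peaks[order[0]]]
        fat_init = centers[peaks[order[1]]] if order.size > 1 else None
    else:
        water_init, fat_init = mode, None
    if fat_init is None:
        fat_init = float(np.clip(water_init + 4.0 * sample_sd, 0.0, 100.0))

    p33, p67 = np.percentile(values, [33.0, 67.0])
    means0 = np.array([water_init, fat_init, p33, p67], dtype=np.float64)[:components]
    sds0 = np.full(components, sample_sd / 4.0)
    weights0 = np.full(components, 1.0 / components)

    w, m, s, _ = _weighted_em(centers, counts.astype(np.float64), means0, sds0,
                              weights0, bin_width)
    water_idx = int(np.argmin(np.abs(m - mode)))
    fat_idx = int(np.argmin(np.abs(m - fat_init))) if len(m) > 1 else water_idx
    if fat_idx == water_idx and len(m) > 1:
        fat_idx = int(np.argmax(m))

    # Report moment-matched cluster Gaussians for the water and fat peaks.
    # Spare components whose mean falls within two SDs of a peak's dominant
    # component are co-modelling that peak (EM freely splits a Gaussian
    # peak among overlapping components) and are merged into it; the rest
    # are the between-peak "residuals" and belong to neither.
    def _merge(sel: np.ndarray) -> tuple[float, float]:
        wt = w[sel].sum()
        mu = float((w[sel] * m[sel]).sum() / wt)
        var = float((w[sel] * (s[sel] ** 2 + m[sel] ** 2)).sum() / wt - mu**2)
        return mu, float(np.sqrt(max(var, 0.0)))

    water_sel = np.abs(m - m[water_idx]) <= 2.0 * s[water_idx]
    fat_sel = np.abs(m - m[fat_idx]) <= 2.0 * s[fat_idx]
    both = water_sel & fat_sel
    if both.any():  # resolve overlaps toward the nearer peak
        nearer_water = np.abs(m - m[water_idx]) <= np.abs(m - m[fat_idx])
        water_sel &= ~both | nearer_water
        fat_sel &= ~both | ~nearer_water
    water_sel[water_idx] = True
    fat_sel[fat_idx] = fat_idx != water_idx
    if not fat_sel.any():
        fat_sel = np.arange(len(m)) == int(np.argmax(m))
    water_mu, water_sd = _merge(water_sel)
    fat_mu, fat_sd = _merge(fat_sel)
    if water_mu > fat_mu:
        warnings.warn("water peak mean exceeds fat peak mean: the histogram "
                      "mode is fat-dominated; check the mask and data")
    return HistogramModel(bin_edges=edges, counts=counts, weights=w, means=m,
                          sds=s, water_idx=water_idx, fat_idx=fat_idx,
                          water_mu=water_mu, water_sd=water_sd,
                          fat_mu=fat_mu, fat_sd=fat_sd)


def select_thresholds(model: HistogramModel) -> tuple[float, float]:
    """Water-only threshold T_C and Dixon threshold T_D (= 50%).

    T_C is the smallest histogram bin upper edge at or above
    ``mu_w + z * sigma_w`` with z the 0.9999 standard-normal quantile
    (3.71902), using the merged water-cluster Gaussian; a degenerate water
    SD of 0 yields the first edge above the water mean.  Values beyond
    100% are clamped (with a warning).
    """
    mu = float(model.water_mu)
    sd = float(model.water_sd)
    if not np.isfinite(mu):
        mu = float(model.means[model.water_idx])
        sd = float(model.sds[model.water_idx])
    upper_edges = model.bin_edges[1:]
    if sd == 0.0:
        idx = int(np.searchsorted(upper_edges, mu, side="right"))
    else:
        x = mu + Z_9999 * sd
        if x > upper_edges[-1]:
            warnings.warn("water Gaussian 99.99% point exceeds 100%; clamping T_C")
            model.t_c = float(upper_edges[-1])
            return model.t_c, model.t_d
        idx = int(np.searchsorted(upper_edges, x, side="left"))
    idx = min(idx, len(upper_edges) - 1)
    model.t_c = float(upper_edges[idx])
    return model.t_c, model.t_d
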