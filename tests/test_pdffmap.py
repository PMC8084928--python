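import numpy as np
import pytest
from scipy import stats

from cardiofat3d.pdffmap import (HistogramModel, PDFFMap, TissueMask, Z_9999,
                                 build_tissue_mask, compute_pdff,
                                 correct_proton_density, estimate_noise_sd,
                                 fit_histogram_gmm, select_thresholds)
from cardiofat3d.relaxometry import SpeciesRelaxation


def _species(**kw):
    base = dict(t1w_ms=250.0, t1f_ms=150.0, t2sw_ms=20.0, t2sf_ms=15.0)
    base.update(kw)
    return SpeciesRelaxation(**base)


def test_correction_limit_is_identity():
    """alpha=90 deg, TR >> T1, TE_ref=0: the correction factor is 1."""
    w = np.array([[[2.0]]])
    species = _species(t1w_ms=10.0, t2sw_ms=30.8)
    m_w, _ = correct_proton_density(w, w, 90.0, 5000.0, 0.0, species)
    assert m_w[0, 0, 0] == pytest.approx(2.0, rel=1e-12)


def test_correction_t2star_compensation_value():
    w = np.array([[[1.0]]])
    species = _species(t1w_ms=1e-3, t2sw_ms=30.8)
    m_w, _ = correct_proton_density(w, w, 90.0, 1000.0, 3.08, species)
    assert m_w[0, 0, 0] == pytest.approx(np.e**0.1, rel=1e-9)


def test_correction_inverts_simulator_amplitude(default_truth):
    """Applying the correction with the generating parameters recovers the
    proton densities up to one global constant."""
    from cardiofat3d.phantom import spgr_amplitude

    t = default_truth
    te_ref = 3.08
    w_sig = spgr_amplitude(t.w0, te_ref, 30.0, 17.0, t.t1w_ms, t.t2sw_ms)
    f_sig = spgr_amplitude(t.f0, te_ref, 30.0, 17.0, t.t1f_ms, t.t2sf_ms)
    species = SpeciesRelaxation(t.t1w_ms, t.t1f_ms, t.t2sw_ms, t.t2sf_ms)
    m_w, m_f = correct_proton_density(w_sig, f_sig, 17.0, 30.0, te_ref, species)
    fg = t.foreground & (t.w0 > 0)
    ratio = m_w[fg] / t.w0[fg]
    assert np.ptp(ratio) / ratio.mean() < 1e-9
    fgf = t.foreground & (t.f0 > 0)
    ratio_f = m_f[fgf] / t.f0[fgf]
    assert abs(ratio_f.mean() - ratio.mean()) / ratio.mean() < 1e-9


def test_correction_rejects_zero_flip():
    with pytest.raises(ValueError):
        correct_proton_density(np.ones((1, 1, 1)), np.ones((1, 1, 1)), 0.0,
                               30.0, 3.08, _species())


def test_pdff_arithmetic():
    m_w = np.array([1.0, 1.0, 0.2, 0.0]).reshape(4, 1, 1)
    m_f = np.array([0.0, 1.0, 0.8, 0.0]).reshape(4, 1, 1)
    pdff = compute_pdff(m_w, m_f)
    np.testing.assert_allclose(pdff.values.ravel(), [0.0, 50.0, 80.0, 0.0])
    assert pdff.n_clipped == 0


def test_pdff_clips_negative_inputs():
    pdff = compute_pdff(np.array([[[-0.5]]]), np.array([[[1.0]]]))
    assert pdff.values[0, 0, 0] == 100.0
    assert pdff.n_clipped == 1


def test_pdff_mask_marks_outside_invalid():
    mask = TissueMask(mask=np.array([[[True, False]]]), noise_sd=0.0, k=3.0)
    pdff = compute_pdff(np.ones((1, 1, 2)), np.ones((1, 1, 2)), mask)
    assert pdff.values[0, 0, 0] == 50.0
    assert np.isnan(pdff.values[0, 0, 1])


def test_noise_sd_examples():
    vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 20).reshape(10, 10, 1)
    roi = np.ones_like(vals, dtype=bool)
    assert estimate_noise_sd(vals, roi) == pytest.approx(np.std(vals, ddof=1))
    flat = np.full((5, 5, 5), 3.3)
    assert estimate_noise_sd(flat, np.ones_like(flat, bool)) == pytest.approx(0.0, abs=1e-12)
    five = np.array([1.0, 2.0, 3.0, 4.0, 5.0]).reshape(5, 1, 1)
    with pytest.warns(UserWarning, match="coarse"):
        sd = estimate_noise_sd(np.tile(five, (10, 1, 1)), np.ones((50, 1, 1), bool))
    assert sd == pytest.approx(np.std(np.tile([1, 2, 3, 4, 5], 10), ddof=1))
    assert np.std([1, 2, 3, 4, 5], ddof=1) == pytest.approx(1.5811, abs=1e-4)


def test_noise_sd_roi_size_errors():
    vals = np.zeros((2, 2, 2))
    with pytest.raises(ValueError):
        estimate_noise_sd(vals, np.ones_like(vals, bool))


def test_mask_single_hot_voxel():
    mags = np.zeros((3, 3, 3, 1))
    mags[:, 1, 1, 0] = 10.0 / np.sqrt(3.0)
    mags[:, [0, 0, 2, 2], [0, 2, 0, 2], 0] = 0.1
    mask = build_tissue_mask(mags, sigma=0.1, k=3.0)
    assert mask.mask.sum() == 1
    assert mask.mask[1, 1, 0]


def test_mask_threshold_monotonic_in_k():
    rng = np.random.default_rng(0)
    mags = rng.rayleigh(1.0, (3, 8, 8, 8))
    combined = np.sqrt((mags**2).sum(axis=0))
    small = combined > 2.0 * 1.0
    large = combined > 4.0 * 1.0
    assert np.all(large <= small)


def test_mask_recovers_phantom_foreground(default_truth, noisefree_combined):
    """At high SNR the masked voxel count matches the true tissue count
    within 2%."""
    from cardiofat3d.phantom import AcquisitionParams, simulate_wf_echoes
    from cardiofat3d.coilcombine import combine_coils, reference_to_first_echo

    scale = np.abs(noisefree_combined.magnitude[0][default_truth.foreground]).mean()
    params = AcquisitionParams(n_coils=default_truth.coil_sens.shape[0],
                               noise_sd=float(scale / 80.0), seed=3)
    multi = simulate_wf_echoes(default_truth, params)
    combined = combine_coils(multi, mode="complex_sum")
    rss3 = np.sqrt((combined.magnitude**2).sum(axis=0))
    bg_roi = np.zeros(default_truth.w0.shape, bool)
    bg_roi[:6, :6, :6] = True
    sigma = estimate_noise_sd(rss3, bg_roi)
    mask = build_tissue_mask(combined.magnitude, sigma, k=3.0,
                             offset=float(rss3[bg_roi].mean()))
    true_count = default_truth.foreground.sum()
    assert abs(int(mask.mask.sum()) - true_count) / true_count < 0.02


def test_mask_user_overrides():
    mags = np.ones((3, 4, 4, 4))
    user = np.zeros((4, 4, 4), dtype=np.int8)
    user[0, 0, 0] = -1
    user[3, 3, 3] = 1
    mask = build_tissue_mask(mags, sigma=10.0, k=3.0, user_mask=user)
    assert not mask.mask[0, 0, 0]
    assert mask.mask[3, 3, 3]
    assert any(p["step"] == "user_mask" for p in mask.provenance)


def _pdff_from_samples(samples):
    return PDFFMap(values=np.asarray(samples, dtype=float), mask_applied=False,
                   te_ref_ms=3.08)


def test_gmm_known_mixture_recovery():
    """0.8 N(20,5^2) + 0.2 N(90,3^2): merged water Gaussian within 0.1."""
    rng = np.random.default_rng(7)
    n = 10**6
    samples = np.where(rng.random(n) < 0.8, rng.normal(20, 5, n),
                       rng.normal(90, 3, n))
    model = fit_histogram_gmm(_pdff_from_samples(np.clip(samples, 0, 100)))
    assert model.water_mu == pytest.approx(20.0, abs=0.1)
    assert model.water_sd == pytest.approx(5.0, abs=0.1)
    assert model.fat_mu == pytest.approx(90.0, abs=0.1)
    assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert model.water_mu < model.fat_mu


def test_gmm_order_invariance():
    rng = np.random.default_rng(8)
    samples = np.clip(rng.normal(30, 8, 20000), 0, 100)
    with pytest.warns(UserWarning):
        a = fit_histogram_gmm(_pdff_from_samples(samples))
    with pytest.warns(UserWarning):
        b = fit_histogram_gmm(_pdff_from_samples(rng.permutation(samples)))
    np.testing.assert_array_equal(a.counts, b.counts)
    np.testing.assert_allclose(a.means, b.means)
    np.testing.assert_allclose(a.sds, b.sds)


def test_gmm_all_zero_degenerate():
    with pytest.warns(UserWarning):
        model = fit_histogram_gmm(_pdff_from_samples(np.zeros(5000)))
    assert len(model.means) == 1
    assert model.water_mu == 0.0 and model.water_sd == 0.0
    t_c, t_d = select_thresholds(model)
    assert t_c == pytest.approx(0.1)
    assert t_d == 50.0


def test_select_thresholds_worked_examples():
    edges = np.linspace(0.0, 100.0, 1001)

    def model_with(mu, sd):
        return HistogramModel(bin_edges=edges, counts=np.zeros(1000),
                              weights=np.array([1.0]), means=np.array([mu]),
                              sds=np.array([sd]), water_idx=0, fat_idx=0,
                              water_mu=mu, water_sd=sd, fat_mu=95.0, fat_sd=1.0)

    t_c, t_d = select_thresholds(model_with(0.0, 1.0))
    assert t_c == pytest.approx(3.8)
    t_c, _ = select_thresholds(model_with(21.0, 5.0))
    assert t_c == pytest.approx(39.6)
    t_c, _ = select_thresholds(model_with(10.0, 0.0))
    assert t_c == pytest.approx(10.1)
    with pytest.warns(UserWarning):
        t_c, _ = select_thresholds(model_with(99.0, 5.0))
    assert t_c == 100.0


def test_t_c_matches_numeric_cdf_inversion():
    """T_C agrees within one bin with a direct numeric inversion of the
    fitted water Gaussian's CDF at 0.9999."""
    rng = np.random.default_rng(9)
    n = 200000
    samples = np.where(rng.random(n) < 0.75, rng.normal(25, 4, n),
                       rng.normal(85, 3, n))
    model = fit_histogram_gmm(_pdff_from_samples(np.clip(samples, 0, 100)))
    t_c, _ = select_thresholds(model)
    numeric = stats.norm.ppf(0.9999, loc=model.water_mu, scale=model.water_sd)
    assert abs(t_c - numeric) <= model.bin_width + 1e-12
    assert Z_9999 == pytest.approx(3.71902, abs=1e-5)
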