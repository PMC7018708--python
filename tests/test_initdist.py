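"""Mixture fitting, cross-density imputation, and initial-condition sampling."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from qlmac.initdist import (MixtureModel, TransformSpec, _apply_transform,
                            build_initial_ensemble, fit_gmm2,
                            impute_cross_density, sample_initials)


def _mix_samples(rng, n, w_high=0.7, mu=(0.0, 2.0), sd=(0.3, 0.3)):
    hi = rng.random(n) < w_high
    return np.where(hi, rng.normal(mu[1], sd[1], n), rng.normal(mu[0], sd[0], n))


def test_gmm_recovery():
    """Simulate-and-refit: weights within 0.03, means within 0.05."""
    rng = np.random.default_rng(0)
    z = _mix_samples(rng, 10_000)
    m = fit_gmm2(z)
    assert m.w_high == pytest.approx(0.7, abs=0.03)
    assert m.mu_low == pytest.approx(0.0, abs=0.05)
    assert m.mu_high == pytest.approx(2.0, abs=0.05)


def test_gmm_symmetric_mixture():
    rng = np.random.default_rng(1)
    z = _mix_samples(rng, 10_000, w_high=0.5, mu=(-1.0, 1.0))
    m = fit_gmm2(z)
    assert m.mu_low == pytest.approx(-m.mu_high, abs=0.05)


def test_gmm_single_gaussian_flags_degenerate():
    rng = np.random.default_rng(2)
    z = rng.normal(1.0, 0.4, 5000)
    m = fit_gmm2(z)
    assert m.degenerate


def test_gmm_rejects_small_or_nonfinite():
    with pytest.raises(ValueError):
        fit_gmm2(np.zeros(10) + np.arange(10))
    bad = np.r_[np.random.default_rng(3).normal(size=100), np.nan]
    with pytest.raises(ValueError):
        fit_gmm2(bad)


def test_impute_identity():
    rng = np.random.default_rng(4)
    z = _mix_samples(rng, 8000)
    spec, _ = impute_cross_density(z, z.copy())
    assert spec.delta == pytest.approx(0.0, abs=0.02)
    assert spec.w_high == pytest.approx(fit_gmm2(z).w_high, abs=0.02)


def test_impute_known_transform_recovery():
    rng = np.random.default_rng(5)
    z = _mix_samples(rng, 8000)
    true = TransformSpec(delta=-0.6, w_high=0.3)
    src = fit_gmm2(z)
    target = _apply_transform(z, src.responsibility_high(z), true,
                              np.random.default_rng(77))
    spec, imputed = impute_cross_density(z, target)
    assert spec.delta == pytest.approx(true.delta, abs=0.05)
    assert spec.w_high == pytest.approx(true.w_high, abs=0.03)
    from scipy.stats import ks_2samp
    assert ks_2samp(imputed, target).statistic < 0.05


def test_impute_round_trip():
    """impute(A->B) then impute(B->A): deltas cancel, weights recovered."""
    rng = np.random.default_rng(6)
    a = _mix_samples(rng, 8000)
    src = fit_gmm2(a)
    fwd = TransformSpec(delta=-0.5, w_high=0.25)
    b = _apply_transform(a, src.responsibility_high(a), fwd,
                         np.random.default_rng(8))
    s_ab, _ = impute_cross_density(a, b)
    s_ba, _ = impute_cross_density(b, a)
    assert s_ab.delta + s_ba.delta == pytest.approx(0.0, abs=0.05)
    assert s_ba.w_high == pytest.approx(src.w_high, abs=0.03)


def test_impute_unimodal_target_warns():
    rng = np.random.default_rng(7)
    z = _mix_samples(rng, 6000)
    target = rng.normal(2.0, 0.3, 6000)
    with pytest.warns(UserWarning, match="unimodal"):
        spec, _ = impute_cross_density(z, target)
    assert spec.w_high == pytest.approx(1.0, abs=0.05)


def test_sampling_determinism_and_limits():
    mix = MixtureModel(0.3, 0.7, 0.0, 2.0, 0.3, 0.3)
    a = sample_initials(mix, 30, seed=9)
    b = sample_initials(mix, 30, seed=9)
    assert a.equals(b)
    with pytest.raises(ValueError):
        sample_initials(mix, 0, seed=0)
    # noise-free limit: all cells collapse onto the mean cell
    tight = MixtureModel(1e-9, 1.0 - 1e-9, 1.0, 1.0 + 1e-9, 1e-6, 1e-6)
    t = sample_initials(tight, 10, seed=0)
    assert np.allclose(t.factor_complex, 1.0, atol=1e-4)


def test_sample_mean_matches_mixture_mean():
    mix = MixtureModel(0.3, 0.7, 0.0, 2.0, 0.3, 0.3)
    t = sample_initials(mix, 10_000, seed=10)
    se = t.latent.std() / np.sqrt(len(t))
    assert abs(t.latent.mean() - mix.mean) < 3 * se


def test_initials_positive_and_fully_correlated(params):
    mix = MixtureModel(0.25, 0.75, 0.0, 2.5, 0.5, 0.6)
    initials, k_rela0, table = build_initial_ensemble(mix, 50, params, seed=11)
    complexes = np.array([c.nfkb_ikb_c for c in initials])
    assert np.all(complexes > 0) and np.all(k_rela0 > 0)
    rho = spearmanr(complexes, k_rela0).statistic
    assert rho == pytest.approx(1.0)
    # population mean complex anchored to the mean cell's basal complex
    from qlmac.model import basal_state
    anchor = basal_state(params).nfkb_ikb_c
    assert complexes.mean() == pytest.approx(anchor, rel=0.15)


def test_latent_drives_cumulative_response(params):
    """Noise-free downstream check: cumulative 24 hps total reporter is
    increasing in the latent initial value (Spearman rho > 0.9)."""
    from qlmac.perturbations import PerturbationSpec
    from qlmac.population import simulate_population
    mix = MixtureModel(0.25, 0.75, 0.0, 2.5, 0.5, 0.6)
    initials, k_rela0, table = build_initial_ensemble(mix, 20, params, seed=12)
    ens = simulate_population(initials, params, PerturbationSpec(lps=100.0),
                              k_rela0=k_rela0)
    tot = ens.observable("total_reporter")
    cum = np.trapezoid(tot[ens.times >= 0], ens.times[ens.times >= 0], axis=0)
    rho = spearmanr(table.latent, cum).statistic
    assert rho > 0.9


def test_mixture_validation():
    with pytest.raises(ValueError):
        MixtureModel(0.5, 0.6, 0.0, 1.0, 0.3, 0.3)
    with pytest.raises(ValueError):
        MixtureModel(0.5, 0.5, 1.0, 0.0, 0.3, 0.3)
    with pytest.raises(ValueError):
        TransformSpec(delta=0.0, w_high=1.2)
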