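"""Analysis statistics: thresholding, CV, permutation tests, readouts."""

import itertools
import math

import numpy as np
import pytest

from qlmac.model import N_SPECIES, SPECIES, ParameterSet
from qlmac.perturbations import PerturbationSpec
from qlmac.population import EnsembleResult
from qlmac.stats import (classify_activation, cv_timecourse, nadir_threshold,
                         r2_permutation, readouts_12hps)

_IDX = {s: i for i, s in enumerate(SPECIES)}


def _fake_ensemble(times, per_cell: dict) -> EnsembleResult:
    """Build an EnsembleResult from per-cell species timecourses."""
    n_t = len(times)
    n_c = len(next(iter(per_cell.values())))
    states = np.zeros((n_t, n_c, N_SPECIES))
    for name, cells in per_cell.items():
        for j, y in enumerate(cells):
            states[:, j, _IDX[name]] = y
    return EnsembleResult(times=np.asarray(times, float), states=states,
                          medium=np.zeros((n_t, 3)), density=np.ones(n_t),
                          spec=PerturbationSpec(), params=ParameterSet())


# ---------------------------------------------------------------------------
# nadir threshold
# ---------------------------------------------------------------------------

def test_nadir_symmetric_mixture():
    rng = np.random.default_rng(0)
    z = np.r_[rng.normal(0, 0.5, 5000), rng.normal(4, 0.5, 5000)]
    res = nadir_threshold(z)
    assert not res.unimodal
    assert res.threshold == pytest.approx(2.0, abs=0.2)
    assert res.fraction_high == pytest.approx(0.5, abs=0.02)


def test_nadir_weighted_mixture():
    rng = np.random.default_rng(1)
    n = 10_000
    hi = rng.random(n) < 0.8
    z = np.where(hi, rng.normal(4, 0.5, n), rng.normal(0, 0.5, n))
    res = nadir_threshold(z)
    assert res.fraction_high == pytest.approx(0.8, abs=0.03)


def test_nadir_unimodal_flag():
    rng = np.random.default_rng(2)
    res = nadir_threshold(rng.normal(1.0, 0.5, 5000))
    assert res.unimodal
    assert math.isnan(res.threshold)


def test_fraction_high_invariant_to_monotone_rescale():
    rng = np.random.default_rng(3)
    z = np.r_[rng.normal(0, 0.5, 4000), rng.normal(4, 0.5, 6000)]
    a = nadir_threshold(z).fraction_high
    b = nadir_threshold(2.5 * z - 7.0).fraction_high
    assert a == pytest.approx(b, abs=0.01)


# ---------------------------------------------------------------------------
# CV timecourse
# ---------------------------------------------------------------------------

def test_cv_identical_cells_zero():
    t = np.linspace(0, 24, 50)
    y = np.sin(t / 10) + 2
    ens = _fake_ensemble(t, {"mch_mat": [y, y, y]})
    assert np.allclose(cv_timecourse(ens, "mch_mat"), 0.0)


def test_cv_hand_arithmetic():
    t = np.array([0.0, 1.0])
    ens = _fake_ensemble(t, {"mch_mat": [np.array([1.0, 1.0]),
                                         np.array([3.0, 3.0])]})
    assert np.allclose(cv_timecourse(ens, "mch_mat"), 0.5)


def test_cv_lognormal_scaling_closed_form():
    """Cells = c(t) * lognormal latent: CV is constant in t and equals
    sqrt(exp(sigma^2) - 1)."""
    rng = np.random.default_rng(4)
    sigma = 0.4
    latent = rng.lognormal(0.0, sigma, 10_000)
    t = np.linspace(0, 10, 5)
    c = 1.0 + t
    ens = _fake_ensemble(t, {"mch_mat": [c * f for f in latent]})
    cv = cv_timecourse(ens, "mch_mat")
    expected = math.sqrt(math.exp(sigma ** 2) - 1.0)
    assert np.allclose(cv, expected, rtol=0.05)
    assert np.ptp(cv) < 1e-9


# ---------------------------------------------------------------------------
# permutation R^2
# ---------------------------------------------------------------------------

def test_r2_perfect_fit_lower_bound():
    x = np.arange(10.0)
    res = r2_permutation(x, 2 * x, B=999, seed=0)
    assert res.r2 == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 1000)


def test_r2_exhaustive_matches_monte_carlo():
    """n=5 toy set: exhaustive 120-permutation p vs large-B Monte Carlo."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([1.1, 2.3, 2.9, 3.5, 5.2])
    exact = r2_permutation(x, y, B=999, seed=0)
    assert exact.exhaustive and exact.n_perm == 120

    # independent Monte-Carlo oracle at B = 1e5
    rng = np.random.default_rng(5)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    obs = np.mean(xs * ys) ** 2
    hits = sum(np.mean(xs * rng.permutation(ys)) ** 2 >= obs - 1e-15
               for _ in range(100_000))
    p_mc = (1 + hits) / 100_001
    assert abs(p_mc - exact.p_value) < 0.01


def test_r2_type_i_error_calibration():
    """Independent x, y at n=30: p is uniform, so P(p < 0.05) ~ 0.05."""
    rng = np.random.default_rng(6)
    hits = 0
    reps = 500
    for i in range(reps):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        if r2_permutation(x, y, B=999, seed=i).p_value < 0.05:
            hits += 1
    assert hits / reps == pytest.approx(0.05, abs=0.02)


def test_r2_p_floor_and_errors():
    x = np.arange(20.0)
    res = r2_permutation(x, x ** 2, B=999, seed=0)
    assert res.p_value >= 1 / 1000
    with pytest.raises(ValueError):
        r2_permutation(x, np.zeros(20), B=999)
    with pytest.raises(ValueError):
        r2_permutation(x[:2], x[:2], B=999)


# ---------------------------------------------------------------------------
# 12 hps readouts
# ---------------------------------------------------------------------------

def test_readouts_constant_and_ramp():
    t = np.round(np.arange(0.0, 24.01, 0.1), 10)
    const = np.full_like(t, 2.0)
    ramp = 3.0 * t
    cum = 0.5 * t  # cumulative flux as a state
    ens = _fake_ensemble(t, {
        "nfkb_ikb_c": [const, np.zeros_like(t)],
        "mch_mat": [ramp, const],
        "cum_secreted": [cum, cum],
    })
    r = readouts_12hps(ens)
    assert r.integ_total_reporter[0] == pytest.approx(24.0)   # 12 x 2
    assert r.integ_mcherry[0] == pytest.approx(3 * 72.0, rel=1e-6)  # a t^2/2
    assert r.integ_mcherry[1] == pytest.approx(24.0)
    assert r.cum_secreted_tnf[0] == pytest.approx(6.0)


def test_readouts_require_12h_window():
    t = np.linspace(0, 6, 20)
    ens = _fake_ensemble(t, {"mch_mat": [t]})
    with pytest.raises(ValueError):
        readouts_12hps(ens)


# ---------------------------------------------------------------------------
# activation classification
# ---------------------------------------------------------------------------

def test_classify_planted_partition():
    rng = np.random.default_rng(7)
    lo = np.exp(rng.normal(0.0, 0.3, 60))
    hi = np.exp(rng.normal(4.0, 0.3, 140))
    cum = np.r_[lo, hi]
    labels = classify_activation(cum)
    assert np.array_equal(labels, np.r_[np.zeros(60), np.ones(140)].astype(bool))


def test_classify_invariant_to_order():
    rng = np.random.default_rng(8)
    cum = np.r_[np.exp(rng.normal(0, 0.3, 80)), np.exp(rng.normal(4, 0.3, 120))]
    perm = rng.permutation(len(cum))
    assert np.array_equal(classify_activation(cum)[perm],
                          classify_activation(cum[perm]))


def test_classify_identical_cells_rejected():
    with pytest.raises(ValueError):
        classify_activation(np.ones(50))
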