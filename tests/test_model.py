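"""Single-cell ODE model: derivatives, simulation, and basal equilibration."""

import math

import numpy as np
import pytest

from qlmac.model import (CellState, ParameterSet, SPECIES, basal_state,
                         derivatives, simulate_cell)
from qlmac.perturbations import PerturbationSpec, build_schedule, configure_params


def test_frozen_system_has_zero_derivatives(zero_params):
    p = ParameterSet(**zero_params)
    state = CellState(nfkb_ikb_c=1.0, nfkb_n=0.3, tnf_intra=2.0)
    d = derivatives(state, p)
    assert np.allclose(d, 0.0)


def test_no_stimulus_no_basal_tnf_production(params, basal):
    """Without LPS there is no detectable TNF production: at the resting
    state tnf_mrna ~ 0, so d(tnf_intra)/dt ~ 0."""
    d = derivatives(basal, params)
    i_tnf = SPECIES.index("tnf_intra")
    assert basal.tnf_mrna < 1e-5
    assert abs(d[i_tnf]) < 1e-4


@pytest.mark.parametrize("x0", [1.0, 10.0, 0.0])
def test_pure_decay_derivative(zero_params, x0):
    p = ParameterSet(**dict(zero_params, d_pest=0.7))
    state = CellState(nfkb_ikb_c=0.0, ikb=0.0, rela_mrna=0.0, mch_mat=x0)
    d = derivatives(state, p)
    i = SPECIES.index("mch_mat")
    assert d[i] == pytest.approx(-0.7 * x0)
    others = np.delete(d, i)
    assert np.allclose(others, 0.0)


def test_derivatives_rejects_nonfinite_state(params):
    state = CellState(nfkb_n=math.nan)
    with pytest.raises(ValueError, match="nfkb_n"):
        derivatives(state, params)


def test_derivatives_rejects_negative_parameter():
    with pytest.raises(ValueError, match="k_rel"):
        ParameterSet(k_rel=-1.0).validate()


def test_ode_matches_exponential_decay(zero_params):
    """Decoupled decay sub-case agrees with the closed form to 1e-6."""
    p = ParameterSet(**dict(zero_params, d_pest=math.log(2)))
    init = CellState(nfkb_ikb_c=0.0, ikb=0.0, rela_mrna=0.0, mch_mat=1.0)
    t = np.round(np.arange(0.0, 24.05, 0.1), 10)
    traj = simulate_cell(init, p, t_grid=t)
    assert traj.species("mch_mat")[t == 1.0][0] == pytest.approx(0.5, abs=1e-6)
    assert np.allclose(traj.species("mch_mat"), 0.5 ** t, atol=1e-6)


def test_trajectory_nonnegative_and_fractions_bounded(params, basal_lps):
    spec = PerturbationSpec(lps=100.0, stnfr=1.0)
    p = configure_params(params, spec)
    traj = simulate_cell(basal_lps, p, schedule=build_schedule(spec, p))
    assert traj.states.min() >= 0.0
    for s in ("a_tlr4", "a_tnfr", "a_il10r", "ikk", "sr", "dsr"):
        assert traj.species(s).max() <= 1.0 + 1e-9


def test_bfa_accumulates_intracellular_tnf(params, basal_lps):
    """With secretion blocked from 1 hps, intracellular TNF at 3 hps
    exceeds the matched no-BFA run."""
    p = configure_params(params, PerturbationSpec(lps=100.0))
    t = np.round(np.arange(0.0, 24.05, 0.1), 10)
    runs = {}
    for bfa in (None, 1.0):
        spec = PerturbationSpec(lps=100.0, bfa_at=bfa)
        traj = simulate_cell(basal_lps, p, schedule=build_schedule(spec, p),
                             t_grid=t)
        runs[bfa] = traj
    i3 = np.flatnonzero(t == 3.0)[0]
    assert runs[1.0].species("tnf_intra")[i3] > runs[None].species("tnf_intra")[i3]
    # matched times up to 3 hps: BFA run is never below the no-BFA run
    upto = t <= 3.0
    assert np.all(runs[1.0].species("tnf_intra")[upto]
                  >= runs[None].species("tnf_intra")[upto] - 1e-9)
    # cumulative secreted flux is frozen exactly once BFA is active
    cum = runs[1.0].species("cum_secreted")
    after = t >= 1.0
    assert np.all(np.diff(cum[after]) == 0.0)


def test_fbd_shapes_total_reporter(params, basal, basal_lps):
    """FBD off: total reporter stays within 5% of its initial value for
    24 h.  FBD on with LPS: total rises then declines (interior max)."""
    spec = PerturbationSpec(lps=100.0, stnfr=1.0)
    t = np.round(np.arange(-1.0, 24.05, 0.1), 10)
    p_off = configure_params(params, spec).replace(fbd_on=False)
    traj_off = simulate_cell(basal, p_off, schedule=build_schedule(spec, p_off),
                             t_grid=t)
    tot_off = traj_off.observable("total_reporter")
    assert abs(tot_off[-1] - tot_off[0]) / tot_off[0] < 0.05

    p_on = configure_params(params, spec)
    assert p_on.fbd_on
    traj_on = simulate_cell(basal_lps, p_on, schedule=build_schedule(spec, p_on),
                            t_grid=t)
    tot_on = traj_on.observable("total_reporter")
    i_max = int(np.argmax(tot_on))
    assert 0 < i_max < len(t) - 1
    assert tot_on[i_max] > tot_on[0] * 1.2
    assert tot_on[-1] < tot_on[i_max]


def test_unit_multipliers_reproduce_base_bitwise(params, basal_lps):
    spec1 = PerturbationSpec(lps=100.0)
    spec2 = PerturbationSpec(lps=100.0, mech_multipliers=(1.0,) * 6)
    p1 = configure_params(params, spec1)
    p2 = configure_params(params, spec2)
    t = np.round(np.arange(0.0, 12.05, 0.1), 10)
    a = simulate_cell(basal_lps, p1, schedule=build_schedule(spec1, p1), t_grid=t)
    b = simulate_cell(basal_lps, p2, schedule=build_schedule(spec2, p2), t_grid=t)
    assert np.array_equal(a.states, b.states)


def test_basal_state_properties(params):
    """Resting cell: NF-kB sequestered in the cytoplasmic complex, nuclear
    pool small, inducible genes off."""
    b = basal_state(configure_params(params, PerturbationSpec()))
    assert b.nfkb_ikb_c > 0.9 * b.total_reporter  # sequestered in the complex
    assert b.nfkb_n < 0.1 * b.nfkb_ikb_c
    assert b.tnf_mrna < 1e-5 and b.tnf_intra < 1e-3


def test_basal_state_zero_synthesis(zero_params):
    p = ParameterSet(**dict(zero_params, d_rela=0.1, d_rela_m=1.0, d_ikb=0.1,
                            d_mch_m=0.3, d_pest=0.3, d_m=1.0, d_tnf=0.3,
                            k_ikk_off=0.5, k_tlr4_off=0.3, k_tnfr_off=0.3,
                            k_il10r_off=0.3, k_sr_off=0.5, k_dsr_off=0.5))
    b = basal_state(p)
    assert np.allclose(b.to_array(), 0.0, atol=1e-6)


def test_basal_state_two_start_consistency(params):
    p = configure_params(params, PerturbationSpec())
    b1 = basal_state(p)
    guess = CellState(nfkb_ikb_c=5.0, ikb=2.0, rela_mrna=1.0, nfkb_n=0.5)
    b2 = basal_state(p, initial_guess=guess)
    x1, x2 = b1.to_array(), b2.to_array()
    scale = np.maximum(np.abs(x1), 1e-6)
    assert np.all(np.abs(x1 - x2) / scale < 1e-3)


def test_mcherry_maturation_lag(zero_params):
    """Mature mCherry lags a transcript step by the maturation stage.

    Closed-form oracle for the linear chain
    imm' = k_trl*mrna - (k_mat + d)*imm, mat' = k_mat*imm - d*mat with a
    unit mrna step: the half-rise time of mat/mat_ss is computed from the
    analytic solution and compared against the simulated half-rise (1%),
    and the lag relative to a maturation-free reporter is about 1 h.
    """
    k, d = math.log(2), math.log(2)
    p = ParameterSet(**dict(zero_params, k_trl_mch=1.0, k_mat=k, d_pest=d))
    init = CellState(nfkb_ikb_c=0.0, ikb=0.0, rela_mrna=0.0, mch_mrna=1.0)
    t = np.round(np.arange(0.0, 24.005, 0.01), 10)
    traj = simulate_cell(init, p, t_grid=t)
    y = traj.species("mch_mat")
    t_half_sim = float(np.interp(0.5, y / y[-1], t))

    # analytic: mat(t)/mat_ss for the two-stage chain
    lam = k + d
    mat = (k / (d * lam)
           + np.exp(-lam * t) * (k / (lam * (lam - d)))
           - np.exp(-d * t) * (k / (d * (lam - d))))
    mat_ss = k / (d * lam)
    t_half_exact = float(np.interp(0.5, mat / mat_ss, t))
    assert t_half_sim == pytest.approx(t_half_exact, rel=0.01)

    t_half_ref = math.log(2) / d  # one-stage reporter, same decay
    assert 0.5 < t_half_sim - t_half_ref < 1.5  # ~1 h maturation delay


def test_cellstate_total_reporter_identity():
    s = CellState(nfkb_ikb_c=0.7, nfkb_c=0.2, nfkb_n=0.1)
    assert s.total_reporter == pytest.approx(1.0)


def test_parameterset_json_roundtrip(tmp_path, params):
    path = tmp_path / "p.json"
    params.to_json(path)
    loaded = ParameterSet.from_json(path)
    assert loaded == params
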