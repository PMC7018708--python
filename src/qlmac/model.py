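"""Single-cell reaction network of LPS-induced NF-kB/TNF signaling.

The model describes one macrophage as a deterministic ODE system in
arbitrary fluorescence-anchored units (concentrations in a.u., time in
hours).  Receptor activation (TLR4, TNFR, IL-10R) is reversible two-state
binding; IKK integrates the TLR4/PKC/TNFR arms; IKK frees NF-kB from the
cytoplasmic NF-kB:IkB complex; free NF-kB shuttles to the nucleus where it
induces IkB (negative feedback), the Tnf/mCherry promoter, and - above an
LPS dose threshold - transcription of its own RelA subunit (the
feedback-dominance, FBD, positive loop).  Tnf mRNA is additionally subject
to stabilizing (SR) and destabilizing (DSR) post-transcriptional
regulation and to IL-10; TNF protein is secreted unless brefeldin A (BFA)
blocks secretion.  mCherry reports Tnf-promoter activity through an
explicit ~1 h chromophore maturation step.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "OBSERVABLES",
    "CellState",
    "ParameterSet",
    "CellTrajectory",
    "derivatives",
    "simulate_cell",
    "basal_state",
    "DEFAULT_SOLVER_OPTS",
]

# ---------------------------------------------------------------------------
# Species layout
# ---------------------------------------------------------------------------

#: Ordered per-cell state vector.  ``cum_secreted`` is carried as an extra
#: integrated state so the cumulative secreted-TNF flux is exact (and exactly
#: flat while BFA is active) rather than post-hoc quadrature.
SPECIES = (
    "a_tlr4",      # active TLR4 fraction, 0..1
    "a_tnfr",      # active TNFR fraction, 0..1
    "a_il10r",     # active IL-10R fraction, 0..1
    "ikk",         # active IKK fraction, 0..1
    "nfkb_ikb_c",  # cytoplasmic NF-kB:IkB complex, a.u.
    "nfkb_c",      # free cytoplasmic NF-kB, a.u.
    "nfkb_n",      # nuclear NF-kB, a.u.
    "ikb",         # free IkB, a.u.
    "rela_mrna",   # Rela transcript, a.u.
    "tnf_mrna",    # Tnf transcript, a.u.
    "tnf_intra",   # intracellular TNF protein, a.u.
    "mch_mrna",    # mCherry transcript, a.u.
    "mch_imm",     # immature (dark) mCherry, a.u.
    "mch_mat",     # mature mCherry, a.u.
    "sr",          # stabilizing-regulation activity, 0..1
    "dsr",         # destabilizing-regulation activity, 0..1
    "cum_secreted",  # cumulative secreted TNF per cell, a.u.
)
N_SPECIES = len(SPECIES)
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: Derived per-cell observables reported alongside raw species.
OBSERVABLES = ("total_reporter", "nuclear", "cytoplasmic", "mch_mat",
               "tnf_intra", "cum_secreted")

_FRACTION_SPECIES = ("a_tlr4", "a_tnfr", "a_il10r", "ikk", "sr", "dsr")


@dataclass
class CellState:
    """Molecular state of one cell at one instant (a.u.; fractions 0..1)."""

    a_tlr4: float = 0.0
    a_tnfr: float = 0.0
    a_il10r: float = 0.0
    ikk: float = 0.0
    nfkb_ikb_c: float = 1.0
    nfkb_c: float = 0.0
    nfkb_n: float = 0.0
    ikb: float = 0.1
    rela_mrna: float = 0.1
    tnf_mrna: float = 0.0
    tnf_intra: float = 0.0
    mch_mrna: float = 0.0
    mch_imm: float = 0.0
    mch_mat: float = 0.0
    sr: float = 0.0
    dsr: float = 0.0
    cum_secreted: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "CellState":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_SPECIES,):
            raise ValueError(f"expected {N_SPECIES} species, got shape {x.shape}")
        return cls(**{s: float(x[i]) for i, s in enumerate(SPECIES)})

    @property
    def total_reporter(self) -> float:
        """Total NF-kB reporter signal: complex + free cytoplasmic + nuclear."""
        return self.nfkb_ikb_c + self.nfkb_c + self.nfkb_n

    def validate(self, tol: float = 1e-9) -> None:
        for s in SPECIES:
            v = getattr(self, s)
            if not math.isfinite(v):
                raise ValueError(f"non-finite value for species {s!r}: {v}")
            if v < -tol:
                raise ValueError(f"negative value for species {s!r}: {v}")
        for s in _FRACTION_SPECIES:
            if getattr(self, s) > 1.0 + 1e-9:
                raise ValueError(f"fraction {s!r} exceeds 1: {getattr(self, s)}")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """Kinetic constants of the network (rates per h, levels in a.u.).

    Defaults are the round-2 calibrated values for the RAW 264.7 reporter
    line; mechanism multipliers ``m1..m6`` rescale (1) TLR4->IKK transduction,
    (2) NF-kB-induced transcription, (3) SR, (4) DSR, (5) TNFR signaling
    (IKK arm and translational enhancement), and (6) FBD, and default to 1.
    """

    # receptor two-state kinetics
    k_tlr4_on: float = 0.604       # per h (at saturating ligand drive)
    k_tlr4_off: float = 0.255      # per h
    k_tnfr_on: float = 1.5       # per a.u. h
    k_tnfr_off: float = 1.2      # per h
    k_il10r_on: float = 2.0      # per h
    k_il10r_off: float = 0.2     # per h
    K_lps: float = 10.0          # ng/ml, half-max ligand drive
    K_pma: float = 30.0          # ng/ml
    K_il10: float = 2.0          # ng/ml
    k_adapt: float = 0.356        # per h, TLR4/PKC signal attenuation (tolerance)

    # IKK
    w0: float = 0.0005           # basal IKK drive, per h
    w_tlr4: float = 0.977         # per h, scaled by m1
    w_pkc: float = 0.36          # per h
    w_tnfr: float = 0.121          # per h, scaled by m5
    k_ikk_off: float = 0.344      # per h
    gamma_il10: float = 7.73      # IKK inhibition weight of active IL-10R

    # NF-kB core
    k_rel: float = 8.62           # IkB release by IKK, per (a.u. fraction) h
    k_imp: float = 2.23           # nuclear import, per h
    k_exp: float = 1.91           # IkB-mediated nuclear rebinding/export, per a.u. h
    k_cbind: float = 3.0         # cytoplasmic NF-kB:IkB rebinding, per a.u. h

    # IkB expression
    k_ikb0: float = 0.01        # basal synthesis, a.u./h
    k_ikb_ind: float = 3.71      # NF-kB-induced synthesis, a.u./h
    K_ikb: float = 0.309          # a.u.
    h_ikb: float = 2.0
    d_ikb: float = 0.0572          # per h

    # RelA expression (FBD)
    k_rela0: float = 0.1         # basal Rela transcription, a.u./h (extrinsic, per cell)
    k_fbd: float = 0.284          # FBD-induced Rela transcription, a.u./h, scaled by m6
    K_fbd: float = 0.0682          # a.u.
    h_fbd: float = 4.0
    d_rela_m: float = 1.0        # Rela mRNA decay, per h
    k_trl_rela: float = 1.0      # RelA translation, per h
    d_rela: float = 0.208          # NF-kB protein turnover, per h (all pools)

    # Tnf / mCherry promoter (shared)
    k_txn: float = 2.2           # a.u./h, scaled by m2
    K_txn: float = 0.592          # a.u.
    h_txn: float = 3.0

    # Tnf mRNA stability
    d_m: float = 1.2             # per h, baseline
    alpha_sr: float = 4.0        # SR stabilization weight, scaled by m3
    alpha_dsr: float = 7.0       # DSR destabilization weight, scaled by m4
    beta_dsr: float = 3.0        # DSR translational inhibition, scaled by m4
    alpha_il10: float = 4.0      # IL-10 destabilization weight

    # TNF protein
    k_trl: float = 6.0           # translation, per h
    beta_tnfr: float = 1.0       # TNFR translational enhancement, scaled by m5
    beta_il10: float = 4.0       # IL-10 translational inhibition
    k_sec: float = 1.8           # secretion, per h
    d_tnf: float = 0.25          # intracellular decay, per h

    # mCherry
    k_trl_mch: float = 1.0       # per h
    d_mch_m: float = 0.868        # mRNA decay, per h
    k_mat: float = math.log(2) / 1.0   # maturation, per h (~1 h half-time)
    d_pest: float = 0.243         # PEST-tagged protein decay, per h

    # SR / DSR dynamics (SR fast-on/fast-off; DSR slow-on)
    k_sr_on: float = 4.0         # per h
    k_sr_off: float = 1.2        # per h
    k_dsr_on: float = 0.6       # per h
    k_dsr_off: float = 0.05      # per h

    # extracellular medium
    d_ext: float = 0.3           # extracellular TNF decay, per h
    k_bind: float = 50.0         # sTNFR binding of TNF, per a.u. h
    k_upt: float = 3.0           # density-scaled cellular TNF uptake, per h

    # population growth (logistic)
    growth_rate: float = math.log(2) / 18.0  # per h (~18 h doubling)
    capacity_fold: float = 4.0   # carrying capacity as fold of plating density

    # mechanism multipliers and FBD flag
    m1: float = 1.0
    m2: float = 1.0
    m3: float = 1.0
    m4: float = 1.0
    m5: float = 1.0
    m6: float = 1.0
    fbd_on: bool = False

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "fbd_on":
                continue
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} is not finite: {v}")
            if f.name.startswith("m") and f.name[1:].isdigit():
                if v < 0:
                    raise ValueError(f"multiplier {f.name!r} must be >= 0, got {v}")
            elif v < 0:
                raise ValueError(f"parameter {f.name!r} must be >= 0, got {v}")

    def replace(self, **kw) -> "ParameterSet":
        return dataclasses.replace(self, **kw)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fbd_on"] = bool(self.fbd_on)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_json(self, path, metadata: dict | None = None) -> None:
        payload = {"metadata": metadata or {"units": "a.u., hours"},
                   "parameters": self.to_dict()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls.from_dict(payload.get("parameters", payload))


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

class _ZeroInputs:
    """No stimulus, no pretreatment, no extracellular TNF."""

    def lps_drive(self, t):
        return 0.0

    def pma_drive(self, t):
        return 0.0

    def il10_drive(self, t):
        return 0.0

    def bfa(self, t):
        return 0.0


def _hill(x, K, h):
    xh = np.power(np.maximum(x, 0.0), h)
    return xh / (K ** h + xh)


def rhs_cells(t: float, states: np.ndarray, p: ParameterSet, inputs,
              tnf_ext: float | np.ndarray) -> np.ndarray:
    """Vectorized RHS for ``states`` of shape (n_cells, N_SPECIES).

    ``inputs`` provides time-dependent drives (see :class:`_ZeroInputs` for
    the interface); ``tnf_ext`` is the shared extracellular TNF level.
    """
    s = states
    a_tlr4 = s[:, 0]
    a_tnfr = s[:, 1]
    a_il10r = s[:, 2]
    ikk = s[:, 3]
    C = s[:, 4]
    nc = s[:, 5]
    nn = s[:, 6]
    ikb = s[:, 7]
    rm = s[:, 8]
    tm = s[:, 9]
    tp = s[:, 10]
    mm = s[:, 11]
    mi = s[:, 12]
    ma = s[:, 13]
    sr = s[:, 14]
    dsr = s[:, 15]

    L = inputs.lps_drive(t)
    P = inputs.pma_drive(t)
    IL = inputs.il10_drive(t)
    bfa = inputs.bfa(t)

    d = np.empty_like(s)

    d[:, 0] = p.k_tlr4_on * L * (1.0 - a_tlr4) - p.k_tlr4_off * a_tlr4
    d[:, 1] = p.k_tnfr_on * tnf_ext * (1.0 - a_tnfr) - p.k_tnfr_off * a_tnfr
    d[:, 2] = p.k_il10r_on * IL * (1.0 - a_il10r) - p.k_il10r_off * a_il10r

    ikk_drive = (p.w0 + p.m1 * p.w_tlr4 * a_tlr4 + p.w_pkc * P
                 + p.m5 * p.w_tnfr * a_tnfr) / (1.0 + p.gamma_il10 * a_il10r)
    d[:, 3] = ikk_drive * (1.0 - ikk) - p.k_ikk_off * ikk

    release = p.k_rel * ikk * C
    cbind = p.k_cbind * ikb * nc
    nexport = p.k_exp * ikb * nn
    # per-cell basal Rela transcription may be an array (extrinsic noise)
    k_rela0 = getattr(inputs, "k_rela0", None)
    if k_rela0 is None:
        k_rela0 = p.k_rela0
    # FBD: dose-gated switch (fbd_on), driven by TLR4 activity through a
    # sharp Hill so it is insensitive to moderate signaling-magnitude
    # changes once the switch is engaged
    fbd = (p.m6 * p.k_fbd * _hill(a_tlr4, p.K_fbd, p.h_fbd)) if p.fbd_on else 0.0

    d[:, 4] = cbind + nexport + p.k_trl_rela * rm - release - p.d_rela * C
    d[:, 5] = release - p.k_imp * nc - cbind - p.d_rela * nc
    d[:, 6] = p.k_imp * nc - nexport - p.d_rela * nn
    d[:, 7] = (p.k_ikb0 + p.k_ikb_ind * _hill(nn, p.K_ikb, p.h_ikb)
               - cbind - nexport - p.d_ikb * ikb - p.k_rel * ikk * ikb)
    d[:, 8] = k_rela0 + fbd - p.d_rela_m * rm

    txn = p.m2 * p.k_txn * _hill(nn, p.K_txn, p.h_txn)
    dm_eff = p.d_m * (1.0 + p.m4 * p.alpha_dsr * dsr
                      + p.alpha_il10 * a_il10r) / (1.0 + p.m3 * p.alpha_sr * sr)
    d[:, 9] = txn - dm_eff * tm

    trl_eff = (p.k_trl * (1.0 + p.m5 * p.beta_tnfr * a_tnfr)
               / ((1.0 + p.beta_il10 * a_il10r) * (1.0 + p.m4 * p.beta_dsr * dsr)))
    sec_flux = p.k_sec * (1.0 - bfa) * tp
    d[:, 10] = trl_eff * tm - sec_flux - p.d_tnf * tp

    d[:, 11] = txn - p.d_mch_m * mm
    d[:, 12] = p.k_trl_mch * mm - p.k_mat * mi - p.d_pest * mi
    d[:, 13] = p.k_mat * mi - p.d_pest * ma

    d[:, 14] = p.k_sr_on * a_tlr4 * (1.0 - sr) - p.k_sr_off * sr
    d[:, 15] = p.k_dsr_on * a_tlr4 * (1.0 - dsr) - p.k_dsr_off * dsr
    d[:, 16] = sec_flux
    return d


def derivatives(state: CellState, params: ParameterSet,
                inputs=None, tnf_ext: float = 0.0) -> np.ndarray:
    """Rate of change of every species for a single cell.

    ``inputs`` is an object with ``lps_drive/pma_drive/il10_drive/bfa``
    callables of time (defaults to no stimulus, evaluated at t=0).
    """
    x = state.to_array()
    if not np.all(np.isfinite(x)):
        bad = [s for s, v in zip(SPECIES, x) if not math.isfinite(v)]
        raise ValueError(f"non-finite state in species {bad}")
    params.validate()
    if inputs is None:
        inputs = _ZeroInputs()
    return rhs_cells(0.0 if not hasattr(inputs, "t0") else inputs.t0,
                     x[None, :], params, inputs, tnf_ext)[0]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

DEFAULT_SOLVER_OPTS = {"method": "LSODA", "rtol": 1e-6, "atol": 1e-9}
#: Output grid spacing, h
OUTPUT_DT = 0.1


@dataclass
class CellTrajectory:
    """Solution of one cell on an output grid (times in h post-stimulus)."""

    times: np.ndarray
    states: np.ndarray          # (n_times, N_SPECIES)

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name]]

    def observable(self, name: str) -> np.ndarray:
        if name == "total_reporter":
            return (self.species("nfkb_ikb_c") + self.species("nfkb_c")
                    + self.species("nfkb_n"))
        if name == "nuclear":
            return self.species("nfkb_n")
        if name == "cytoplasmic":
            return self.species("nfkb_ikb_c") + self.species("nfkb_c")
        return self.species(name)

    def state_at(self, t: float) -> CellState:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise ValueError(f"time {t} not on output grid")
        return CellState.from_array(self.states[i])


def _integrate(x0: np.ndarray, params: ParameterSet, inputs, t_span,
               t_eval, tnf_ext=0.0, solver_opts=None) -> np.ndarray:
    opts = dict(DEFAULT_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    n = x0.shape[0] if x0.ndim == 2 else 1
    flat0 = np.ravel(x0)

    def f(t, y):
        return rhs_cells(t, y.reshape(n, N_SPECIES), params, inputs,
                         tnf_ext).ravel()

    sol = solve_ivp(f, t_span, flat0, t_eval=t_eval, **opts)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message} "
                           f"(t={sol.t[-1] if len(sol.t) else t_span[0]:.3f})")
    return sol.y.T.reshape(len(sol.t), n, N_SPECIES)


def simulate_cell(initial: CellState, params: ParameterSet, schedule=None,
                  t_grid: np.ndarray | None = None,
                  solver_opts: dict | None = None) -> CellTrajectory:
    """Simulate one decoupled cell (no extracellular TNF feedback).

    ``schedule`` is a :class:`qlmac.perturbations.Schedule` (or any object
    with the drive callables); ``t_grid`` defaults to [t_start, 24] h at
    0.1 h spacing, where t_start is the schedule's earliest event (<= 0).
    """
    initial.validate()
    params.validate()
    if schedule is None:
        schedule = _ZeroInputs()
    t_start = float(getattr(schedule, "t_start", 0.0))
    if t_grid is None:
        t_grid = np.round(np.arange(t_start, 24.0 + OUTPUT_DT / 2, OUTPUT_DT), 10)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] > t_start:
        raise ValueError("t_grid must span the schedule (start at or before "
                         f"{t_start})")
    x0 = initial.to_array()[None, :].copy()
    # sTNFR without medium coupling has no effect in a decoupled cell
    y = _integrate(x0, params, schedule, (t_grid[0], t_grid[-1]), t_grid,
                   tnf_ext=0.0, solver_opts=solver_opts)
    states = np.clip(y[:, 0, :], 0.0, None)
    _check_nonneg(y[:, 0, :])
    return CellTrajectory(times=t_grid, states=states)


def _check_nonneg(states: np.ndarray, tol: float = 1e-6) -> None:
    m = states.min()
    if m < -tol:
        i = np.unravel_index(np.argmin(states), states.shape)
        raise RuntimeError(
            f"species {SPECIES[i[-1]]!r} went negative ({m:.3e}) beyond tolerance")


def basal_state(params: ParameterSet, density_context=None,
                t_eq: float = 400.0, tol: float = 1e-6,
                initial_guess: CellState | None = None) -> CellState:
    """Pre-stimulus resting state, found by equilibrating without ligand.

    Integrates the unstimulated system until every species changes by less
    than ``tol`` (relative) per hour.  ``density_context`` is accepted for
    interface symmetry; the resting single cell does not sense the medium.
    """
    params.validate()
    guess = initial_guess if initial_guess is not None else CellState(
        nfkb_ikb_c=params.k_trl_rela * params.k_rela0 / (params.d_rela_m * params.d_rela),
        rela_mrna=params.k_rela0 / params.d_rela_m,
        ikb=params.k_ikb0 / max(params.d_ikb, 1e-12) if params.d_ikb > 0 else 0.1,
    )
    x = guess.to_array()[None, :]
    x[0, _IDX["cum_secreted"]] = 0.0
    inputs = _ZeroInputs()
    last = None
    for _ in range(6):
        y = _integrate(x, params, inputs, (0.0, t_eq), np.array([0.0, t_eq - 1.0, t_eq]))
        x = y[-1][None, :].copy()
        rate = np.abs(y[-1, 0] - y[-2, 0]) / 1.0  # per-hour change
        scale = np.maximum(np.abs(y[-1, 0]), 1e-9)
        rel = rate / scale
        rel[_IDX["cum_secreted"]] = 0.0  # running integral, not a level
        if np.all(rel < tol):
            out = np.clip(y[-1, 0], 0.0, None)
            out[_IDX["cum_secreted"]] = 0.0
            return CellState.from_array(out)
        if last is not None and np.allclose(last, y[-1, 0], rtol=1e-10, atol=1e-12):
            break
        last = y[-1, 0].copy()
    raise RuntimeError(
        "basal equilibration did not converge; last two iterates: "
        f"{last} vs {y[-1, 0]}")
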