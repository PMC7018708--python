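"""Population of heterogeneous cells coupled through a shared medium.

N simulated cells stand in for the culture: each cell secretes TNF into a
single well-mixed extracellular compartment, whose TNF concentration every
cell senses through TNFR.  Secretion into the medium is the per-capita
mean flux scaled by cell density (relative to the high-density plating
reference), so density acts as one dimensionless coupling knob.  The
medium also carries free soluble TNF receptor (sTNFR) and the TNF:sTNFR
complex; their sum is conserved.  Density grows logistically.

For large ensembles (histogram-scale N) the medium is computed from a
density-quantile-representative subset under full coupling, and the
remaining cells are then integrated independently against that medium
trajectory (mean-field decoupling); trajectory-scale ensembles (N <= 64)
are integrated fully coupled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (N_SPECIES, OBSERVABLES, SPECIES, CellState, CellTrajectory,
                    DEFAULT_SOLVER_OPTS, OUTPUT_DT, ParameterSet, rhs_cells)
from .perturbations import (PerturbationSpec, RHO_REF, Schedule, build_schedule,
                            configure_params)

__all__ = ["MediumState", "EnsembleResult", "simulate_population",
           "grow_density", "snapshot"]

_IDX = {name: i for i, name in enumerate(SPECIES)}
#: Above this N, the mean-field two-pass scheme replaces full coupling.
FULL_COUPLING_MAX_N = 64
#: Size of the representative subset used for the medium in the two-pass scheme.
N_MEDIUM_REP = 48


@dataclass
class MediumState:
    """Extracellular compartment (a.u.)."""

    tnf_ext: float = 0.0
    stnfr_free: float = 0.0
    tnf_stnfr: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.tnf_ext, self.stnfr_free, self.tnf_stnfr])


def grow_density(density0: float, t: float | np.ndarray, growth_params) -> np.ndarray:
    """Logistic cell density at time ``t`` hours after anchoring.

    ``growth_params`` needs ``growth_rate`` (per h) and ``capacity_fold``
    (carrying capacity as a fold of ``density0``); a :class:`ParameterSet`
    qualifies.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if density0 <= 0:
        raise ValueError("density0 must be > 0")
    r = growth_params.growth_rate
    K = growth_params.capacity_fold * density0
    if r == 0 or K == density0:
        return np.broadcast_to(np.float64(density0), t.shape).copy() if t.ndim else np.float64(density0)
    e = np.exp(r * t)
    return K * density0 * e / (K + density0 * (e - 1.0))


class _EnsembleInputs:
    """Schedule plus per-cell basal Rela transcription rates."""

    def __init__(self, schedule: Schedule, k_rela0: np.ndarray | None):
        self._s = schedule
        self.k_rela0 = k_rela0

    def lps_drive(self, t):
        return self._s.lps_drive(t)

    def pma_drive(self, t):
        return self._s.pma_drive(t)

    def il10_drive(self, t):
        return self._s.il10_drive(t)

    def bfa(self, t):
        return self._s.bfa(t)


@dataclass
class EnsembleResult:
    """Simulated population: per-cell states, medium, and density over time."""

    times: np.ndarray               # (n_t,), h post-stimulus
    states: np.ndarray              # (n_t, n_cells, N_SPECIES)
    medium: np.ndarray              # (n_t, 3): tnf_ext, stnfr_free, tnf_stnfr
    density: np.ndarray             # (n_t,), cells/ml
    spec: PerturbationSpec
    params: ParameterSet

    @property
    def n_cells(self) -> int:
        return self.states.shape[1]

    def cell(self, i: int) -> CellTrajectory:
        return CellTrajectory(times=self.times, states=self.states[:, i, :])

    def observable(self, name: str) -> np.ndarray:
        """(n_t, n_cells) array of the named observable."""
        if name == "total_reporter":
            return (self.states[:, :, _IDX["nfkb_ikb_c"]]
                    + self.states[:, :, _IDX["nfkb_c"]]
                    + self.states[:, :, _IDX["nfkb_n"]])
        if name == "nuclear":
            return self.states[:, :, _IDX["nfkb_n"]]
        if name == "cytoplasmic":
            return (self.states[:, :, _IDX["nfkb_ikb_c"]]
                    + self.states[:, :, _IDX["nfkb_c"]])
        return self.states[:, :, _IDX[name]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cell trajectory table (cell_id, time_h, observables)."""
        n_t, n_c = self.states.shape[:2]
        cols = {"cell_id": np.repeat(np.arange(n_c), n_t),
                "time_h": np.tile(self.times, n_c)}
        for name in OBSERVABLES:
            cols[name] = self.observable(name).T.ravel()
        return pd.DataFrame(cols)

    def medium_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times,
                             "tnf_ext": self.medium[:, 0],
                             "stnfr_free": self.medium[:, 1],
                             "tnf_stnfr": self.medium[:, 2],
                             "density": self.density})


def _medium_rhs(t, tnf_ext, stnfr, p, mean_sec_flux, rho_rel):
    bind = p.k_bind * stnfr * tnf_ext
    d_tnf = (rho_rel * mean_sec_flux - p.d_ext * tnf_ext - bind
             - p.k_upt * rho_rel * tnf_ext)
    return d_tnf, -bind, bind


def _simulate_coupled(x0: np.ndarray, k_rela0, p: ParameterSet,
                      schedule: Schedule, t_grid, solver_opts) -> tuple:
    """Fully coupled cells + medium integration."""
    n = x0.shape[0]
    inputs = _EnsembleInputs(schedule, k_rela0)
    t_start = t_grid[0]
    med0 = np.array([0.0, 0.0, 0.0])
    rho0 = schedule.spec.density0

    def rho_rel(t):
        return float(grow_density(rho0, max(t - t_start, 0.0), p)) / RHO_REF

    def f(t, y):
        cells = y[: n * N_SPECIES].reshape(n, N_SPECIES)
        tnf_ext, stnfr = y[-3], y[-2]
        dc = rhs_cells(t, cells, p, inputs, max(tnf_ext, 0.0))
        sec = p.k_sec * (1.0 - inputs.bfa(t)) * np.maximum(
            cells[:, _IDX["tnf_intra"]], 0.0)
        dm = _medium_rhs(t, max(tnf_ext, 0.0), max(stnfr, 0.0), p,
                         float(np.mean(sec)), rho_rel(t))
        return np.concatenate([dc.ravel(), dm])

    y0 = np.concatenate([x0.ravel(), med0])
    opts = dict(DEFAULT_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    # sTNFR appears in the medium at its pretreatment time
    segs = []
    if schedule.stnfr0 > 0 and t_start < -1.0:
        segs = [(t_start, -1.0), (-1.0, t_grid[-1])]
    else:
        segs = [(t_start, t_grid[-1])]
        if schedule.stnfr0 > 0:
            y0[-2] = schedule.stnfr0
    ts, ys = [], []
    y = y0
    for (a, b) in segs:
        mask = (t_grid >= a - 1e-12) & (t_grid <= b + 1e-12)
        t_eval = t_grid[mask]
        sol = solve_ivp(f, (a, b), y, t_eval=t_eval, **opts)
        if not sol.success:
            raise RuntimeError(f"population solver failed: {sol.message}")
        keep = np.ones(len(sol.t), dtype=bool)
        if ts and len(sol.t) and sol.t[0] <= ts[-1][-1] + 1e-12:
            keep[0] = False
        ts.append(sol.t[keep])
        ys.append(sol.y.T[keep])
        y = sol.y[:, -1].copy()
        if b == -1.0:
            y[-2] += schedule.stnfr0
    t_out = np.concatenate(ts)
    y_out = np.concatenate(ys, axis=0)
    states = y_out[:, : n * N_SPECIES].reshape(len(t_out), n, N_SPECIES)
    medium = y_out[:, -3:]
    return t_out, np.clip(states, 0.0, None), np.clip(medium, 0.0, None)


def _simulate_driven(x0: np.ndarray, k_rela0, p: ParameterSet,
                     schedule: Schedule, t_grid, tnf_ext_of_t,
                     chunk: int = 64) -> np.ndarray:
    """Integrate decoupled cells against a fixed medium trajectory."""
    n = x0.shape[0]
    out = np.empty((len(t_grid), n, N_SPECIES))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        sub = x0[lo:hi]
        kr = None if k_rela0 is None else k_rela0[lo:hi]
        inputs = _EnsembleInputs(schedule, kr)
        m = hi - lo

        def f(t, y):
            return rhs_cells(t, y.reshape(m, N_SPECIES), p, inputs,
                             float(tnf_ext_of_t(t))).ravel()

        sol = solve_ivp(f, (t_grid[0], t_grid[-1]), sub.ravel(),
                        t_eval=t_grid, method="RK45", rtol=1e-6, atol=1e-9)
        if not sol.success:
            raise RuntimeError(f"driven-cell solver failed: {sol.message}")
        out[:, lo:hi, :] = sol.y.T.reshape(len(t_grid), m, N_SPECIES)
    return np.clip(out, 0.0, None)


def simulate_population(initials, params: ParameterSet, spec: PerturbationSpec,
                        t_grid: np.ndarray | None = None,
                        k_rela0: np.ndarray | None = None,
                        solver_opts: dict | None = None) -> EnsembleResult:
    """Simulate N cells sharing one medium under a perturbation condition.

    ``initials`` is a list of :class:`CellState` (or an (N, N_SPECIES)
    array); ``k_rela0`` optionally gives each cell its own basal Rela
    transcription rate (extrinsic noise).  The perturbation's mechanism
    multipliers and FBD flag are applied to ``params`` internally.
    """
    if isinstance(initials, np.ndarray):
        x0 = np.array(initials, dtype=float)
    else:
        initials = list(initials)
        if len(initials) == 0:
            raise ValueError("need at least one cell")
        x0 = np.stack([c.to_array() for c in initials])
    if x0.ndim != 2 or x0.shape[1] != N_SPECIES:
        raise ValueError(f"initials must be (N, {N_SPECIES})")
    n = x0.shape[0]
    if n < 1:
        raise ValueError("need at least one cell")
    if k_rela0 is not None:
        k_rela0 = np.asarray(k_rela0, dtype=float)
        if k_rela0.shape != (n,):
            raise ValueError("k_rela0 must have one entry per cell")
    p = configure_params(params, spec)
    p.validate()
    schedule = build_schedule(spec, p)
    if t_grid is None:
        t_grid = np.round(np.arange(schedule.t_start, 24.0 + OUTPUT_DT / 2,
                                    OUTPUT_DT), 10)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] > schedule.t_start:
        raise ValueError("t_grid must start at or before the first scheduled event")

    if n <= FULL_COUPLING_MAX_N:
        t_out, states, medium = _simulate_coupled(x0, k_rela0, p, schedule,
                                                  t_grid, solver_opts)
    else:
        # representative subset spanning the initial-state distribution
        order = np.argsort(x0[:, _IDX["nfkb_ikb_c"]], kind="stable")
        pick = order[np.round(np.linspace(0, n - 1, N_MEDIUM_REP)).astype(int)]
        kr_rep = None if k_rela0 is None else k_rela0[pick]
        t_out, _, medium = _simulate_coupled(x0[pick], kr_rep, p, schedule,
                                             t_grid, solver_opts)
        from scipy.interpolate import interp1d
        tnf_of_t = interp1d(t_out, medium[:, 0], kind="linear",
                            bounds_error=False,
                            fill_value=(medium[0, 0], medium[-1, 0]))
        states = _simulate_driven(x0, k_rela0, p, schedule, t_out, tnf_of_t)

    rho = np.asarray(grow_density(spec.density0,
                                  np.maximum(t_out - t_out[0], 0.0), p))
    return EnsembleResult(times=t_out, states=states, medium=medium,
                          density=rho, spec=spec, params=p)


def snapshot(ensemble: EnsembleResult, t: float) -> pd.DataFrame:
    """Per-cell observable table at one simulated time (no extrapolation)."""
    i = int(np.argmin(np.abs(ensemble.times - t)))
    if abs(ensemble.times[i] - t) > 1e-6:
        raise ValueError(f"t={t} h is not on the simulated grid")
    rows = {"cell_id": np.arange(ensemble.n_cells)}
    for name in OBSERVABLES:
        rows[name] = ensemble.observable(name)[i]
    return pd.DataFrame(rows)
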