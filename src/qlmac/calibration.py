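"""Two-round calibration of the model to trajectory summary statistics.

The training data are summary statistics of mean reporter trajectories
(peak times, peak amplitude ratio, rise durations) under a panel of
perturbation conditions.  Fitting follows a two-round scheme on the
homogeneous mean cell:

* round 1 - the cell-intrinsic NF-kB arm (TLR4 signaling, IKK,
  nucleocytoplasmic shuttling, IkB feedback, FBD), trained on the
  sTNFR + LPS condition where intercellular TNF feedback is blocked.
  A multi-objective evolutionary search returns a Pareto family of
  parameter subsets with similar outcomes.
* round 2 - the full model (Tnf promoter and post-transcriptional
  regulation, mCherry expression, IL-10 effects, secretion) across all
  conditions, with the round-1 subset constrained to family members and
  the remaining parameters searched freely.

Objectives are squared residuals normalized by the target SDs, so a value
of 1 means "one SD away".  The evolutionary engine is an NSGA-II-style
nondominated sorting GA with SBX crossover and polynomial mutation on
log-scaled parameters.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .model import CellTrajectory, ParameterSet, basal_state
from .perturbations import PerturbationSpec, configure_params
from .population import EnsembleResult, simulate_population

__all__ = ["TrajectorySummary", "FitObjective", "ParameterFamily", "FitConfig",
           "summarize_trajectory", "fit_round1", "fit_round2",
           "ROUND1_FREE", "ROUND2_FREE", "printed_round1_objective",
           "printed_round2_objectives", "nsga2"]


# ---------------------------------------------------------------------------
# Trajectory summaries
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySummary:
    """Peak statistics of one (mean) trajectory, times in hps."""

    peak_time_total: float
    peak_amp_total: float
    peak_time_nuclear: float
    peak_amp_nuclear: float
    peak_time_cytoplasmic: float
    peak_amp_cytoplasmic: float
    peak_time_mcherry: float
    peak_amp_mcherry: float
    ratio_cyt_nuc: float
    rise_duration_mcherry: float
    integral_total_12: float
    integral_mcherry_12: float
    flagged_monotone: tuple = ()

    def get(self, name: str) -> float:
        return getattr(self, name)


def _interp_peak(t: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Argmax refined by quadratic interpolation; flags end-of-window peaks."""
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i]), True
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if abs(denom) < 1e-300:
        return float(t1), float(y1), False
    dt = t1 - t0
    off = 0.5 * (y0 - y2) / denom
    off = min(max(off, -1.0), 1.0)
    tp = t1 + off * dt
    yp = y1 - 0.25 * (y0 - y2) * off
    return float(tp), float(yp), False


def summarize_trajectory(traj) -> TrajectorySummary:
    """Summary statistics of a trajectory's post-stimulus window.

    ``traj`` is a :class:`CellTrajectory` or an :class:`EnsembleResult`
    (summarized on the across-cell mean).  Peaks use quadratic
    interpolation on the output grid; integrals are trapezoid over
    [0, 12] hps.  A monotone observable (no interior peak) reports the
    window end as its peak time and is listed in ``flagged_monotone``.
    """
    if isinstance(traj, EnsembleResult):
        t = traj.times
        get = lambda nm: traj.observable(nm).mean(axis=1)
    else:
        t = traj.times
        get = traj.observable
    if t[-1] < 24.0 - 1e-9:
        raise ValueError("trajectory must cover at least 24 h post-stimulus")
    m = t >= 0.0
    tm = t[m]
    vals = {}
    flagged = []
    for key, obs in [("total", "total_reporter"), ("nuclear", "nuclear"),
                     ("cytoplasmic", "cytoplasmic"), ("mcherry", "mch_mat")]:
        tp, yp, flag = _interp_peak(tm, get(obs)[m])
        vals[f"peak_time_{key}"] = tp
        vals[f"peak_amp_{key}"] = yp
        if flag:
            flagged.append(key)
    m12 = (t >= 0.0) & (t <= 12.0 + 1e-9)
    return TrajectorySummary(
        ratio_cyt_nuc=vals["peak_amp_cytoplasmic"] / vals["peak_amp_nuclear"],
        rise_duration_mcherry=vals["peak_time_mcherry"],
        integral_total_12=float(np.trapezoid(get("total_reporter")[m12], t[m12])),
        integral_mcherry_12=float(np.trapezoid(get("mch_mat")[m12], t[m12])),
        flagged_monotone=tuple(flagged),
        **vals,
    )


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

@dataclass
class FitObjective:
    """Targets for one condition: summary-field -> (value, sd), with weight."""

    condition: PerturbationSpec
    targets: dict
    weight: float = 1.0

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if not self.targets:
            raise ValueError("objective needs at least one target")

    def residuals(self, summary: TrajectorySummary) -> np.ndarray:
        """Squared SD-normalized residuals, one per target."""
        out = []
        for name, (val, sd) in self.targets.items():
            out.append(((summary.get(name) - val) / sd) ** 2)
        return self.weight * np.asarray(out)


def printed_round1_objective() -> FitObjective:
    """Round-1 targets: NF-kB reporter peak statistics under sTNFR + LPS."""
    return FitObjective(
        condition=PerturbationSpec(lps=100.0, stnfr=1.0, density="high"),
        targets={"peak_time_total": (14.0, 4.0),
                 "peak_time_nuclear": (10.0, 6.0),
                 "peak_time_cytoplasmic": (15.0, 4.0),
                 "ratio_cyt_nuc": (1.4, 0.4)},
    )


def printed_round2_objectives() -> list[FitObjective]:
    """Round-2 targets across conditions, including mCherry dynamics."""
    return [
        FitObjective(
            condition=PerturbationSpec(lps=100.0, stnfr=1.0, density="high"),
            targets={"peak_time_total": (14.0, 4.0),
                     "peak_time_nuclear": (10.0, 6.0),
                     "peak_time_cytoplasmic": (15.0, 4.0),
                     "ratio_cyt_nuc": (1.4, 0.4),
                     "peak_time_mcherry": (18.0, 5.0)}),
        FitObjective(
            condition=PerturbationSpec(lps=100.0, density="high"),
            targets={"rise_duration_mcherry": (16.0, 2.0)}),
        FitObjective(
            condition=PerturbationSpec(lps=100.0, il10=10.0, density="high"),
            targets={"rise_duration_mcherry": (12.0, 3.0)}),
        FitObjective(
            condition=PerturbationSpec(density="high"),
            targets={"peak_amp_mcherry": (0.0, 0.2)}),   # unstimulated: basal
    ]


def evaluate_conditions(params: ParameterSet, objectives) -> list[np.ndarray]:
    """Mean-cell residual vectors, one array per objective/condition."""
    out = []
    for obj in objectives:
        p = configure_params(params, obj.condition)
        b = basal_state(p)
        ens = simulate_population([b], params, obj.condition)
        out.append(obj.residuals(summarize_trajectory(ens)))
    return out


# ---------------------------------------------------------------------------
# NSGA-II engine
# ---------------------------------------------------------------------------

def _nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    n = len(F)
    dominates = np.zeros((n, n), dtype=bool)
    for i in range(n):
        dominates[i] = np.all(F[i] <= F, axis=1) & np.any(F[i] < F, axis=1)
    # dominates[i, j] True when j dominates... careful: row i vs all rows
    dom_count = dominates.sum(axis=0)  # times each i is dominated
    fronts = []
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        front = np.where((dom_count == 0) & ~assigned)[0]
        if len(front) == 0:  # numerical tie fallback
            front = np.where(~assigned)[0]
        fronts.append(front)
        assigned[front] = True
        dom_count = dom_count - dominates[front].sum(axis=0)
    return fronts


def _crowding(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j])
        span = F[order[-1], j] - F[order[0], j]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0 and n > 2:
            d[order[1:-1]] += (F[order[2:], j] - F[order[:-2], j]) / span
    return d


def nsga2(eval_fn, n_var: int, pop_size: int, n_gen: int, seed: int,
          x_init: np.ndarray | None = None):
    """Minimal NSGA-II over the unit cube; returns (X, F) final population.

    ``eval_fn(x)`` maps a genome in [0,1]^n_var to an objective vector.
    Deterministic given ``seed``.  ``x_init`` seeds part of the initial
    population (e.g. centre points from parameter sweeps).
    """
    rng = np.random.default_rng(seed)
    X = rng.random((pop_size, n_var))
    if x_init is not None:
        x_init = np.atleast_2d(x_init)
        X[: len(x_init)] = np.clip(x_init, 0.0, 1.0)
    F = np.array([eval_fn(x) for x in X], dtype=float)

    def tournament(rank, crowd):
        a, b = rng.integers(0, pop_size, 2)
        if rank[a] != rank[b]:
            return a if rank[a] < rank[b] else b
        return a if crowd[a] >= crowd[b] else b

    eta_c, eta_m = 15.0, 20.0
    pm = 1.0 / n_var
    for _ in range(n_gen):
        fronts = _nondominated_sort(F)
        rank = np.empty(pop_size, dtype=int)
        crowd = np.empty(pop_size)
        for r, fr in enumerate(fronts):
            rank[fr] = r
            crowd[fr] = _crowding(F[fr]) if len(fr) > 1 else np.inf
        children = []
        while len(children) < pop_size:
            p1, p2 = tournament(rank, crowd), tournament(rank, crowd)
            c1, c2 = X[p1].copy(), X[p2].copy()
            # SBX crossover
            do = rng.random(n_var) < 0.9
            u = rng.random(n_var)
            beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta_c + 1)),
                            (1 / (2 * (1 - u))) ** (1 / (eta_c + 1)))
            c1[do], c2[do] = (0.5 * ((1 + beta) * X[p1] + (1 - beta) * X[p2]))[do], \
                             (0.5 * ((1 - beta) * X[p1] + (1 + beta) * X[p2]))[do]
            for c in (c1, c2):
                mut = rng.random(n_var) < pm
                u2 = rng.random(n_var)
                delta = np.where(u2 < 0.5,
                                 (2 * u2) ** (1 / (eta_m + 1)) - 1,
                                 1 - (2 * (1 - u2)) ** (1 / (eta_m + 1)))
                c[mut] = c[mut] + delta[mut]
                np.clip(c, 0.0, 1.0, out=c)
                children.append(c)
        Xc = np.array(children[:pop_size])
        Fc = np.array([eval_fn(x) for x in Xc], dtype=float)
        X_all = np.vstack([X, Xc])
        F_all = np.vstack([F, Fc])
        fronts = _nondominated_sort(F_all)
        keep = []
        for fr in fronts:
            if len(keep) + len(fr) <= pop_size:
                keep.extend(fr)
            else:
                cd = _crowding(F_all[fr]) if len(fr) > 1 else np.array([np.inf])
                order = fr[np.argsort(-cd)]
                keep.extend(order[: pop_size - len(keep)])
                break
        keep = np.asarray(keep)
        X, F = X_all[keep], F_all[keep]
    return X, F


# ---------------------------------------------------------------------------
# Parameter encoding and the two rounds
# ---------------------------------------------------------------------------

ROUND1_FREE = ("k_tlr4_on", "k_tlr4_off", "k_adapt", "w_tlr4", "k_ikk_off",
               "k_rel", "k_imp", "k_exp", "k_ikb_ind", "K_ikb", "d_ikb",
               "k_fbd", "K_fbd", "d_rela")
ROUND2_FREE = ("K_txn", "k_txn", "d_mch_m", "d_pest", "gamma_il10",
               "beta_il10", "alpha_il10", "k_dsr_on", "k_dsr_off",
               "beta_dsr", "alpha_dsr")


@dataclass
class FitConfig:
    """Evolutionary-search settings.

    ``bounds_scale`` sets log-uniform bounds [v/s, v*s] around each free
    parameter's value in ``base`` (sweep-derived centre); narrow it for
    fast smoke fits, widen for thorough searches.
    """

    pop_size: int = 32
    n_gen: int = 20
    bounds_scale: float = 30.0
    free: tuple = ROUND1_FREE
    base: ParameterSet = field(default_factory=ParameterSet)
    min_family: int = 4
    seed_centre: bool = True

    def bounds(self) -> dict:
        s = self.bounds_scale
        return {nm: (getattr(self.base, nm) / s, getattr(self.base, nm) * s)
                for nm in self.free}


def _decode(x: np.ndarray, free, bounds) -> dict:
    out = {}
    for xi, nm in zip(x, free):
        lo, hi = bounds[nm]
        out[nm] = lo * (hi / lo) ** float(xi)
    return out


def _encode_centre(free, bounds, base) -> np.ndarray:
    x = []
    for nm in free:
        lo, hi = bounds[nm]
        v = min(max(getattr(base, nm), lo), hi)
        x.append(math.log(v / lo) / math.log(hi / lo))
    return np.array(x)


@dataclass
class ParameterFamily:
    """Pareto-nondominated parameter subsets with their objective vectors."""

    members: list            # list of dicts (name -> value)
    objectives: np.ndarray   # (n_members, n_objectives)

    def __post_init__(self):
        self.objectives = np.atleast_2d(np.asarray(self.objectives, float))
        if len(self.members) != len(self.objectives):
            raise ValueError("members and objectives must align")
        if len(self.members) == 0:
            raise ValueError("family must be non-empty")

    def __len__(self):
        return len(self.members)

    def check_nondominated(self) -> bool:
        F = self.objectives
        for i in range(len(F)):
            dominated = np.all(F <= F[i], axis=1) & np.any(F < F[i], axis=1)
            if dominated.any():
                return False
        return True


def _safe_eval(params, objectives, n_obj):
    try:
        res = evaluate_conditions(params, objectives)
        return np.concatenate(res)
    except (RuntimeError, ValueError):
        return np.full(n_obj, 1e6)


def fit_round1(objective: FitObjective | None = None,
               config: FitConfig | None = None, seed: int = 0) -> ParameterFamily:
    """Round 1: fit the cell-intrinsic NF-kB arm to sTNFR + LPS targets.

    Returns the Pareto family over the SD-normalized target residuals.
    Reproducible given ``seed``.
    """
    objective = objective or printed_round1_objective()
    if objective.condition.stnfr <= 0:
        raise ValueError("round 1 trains on the sTNFR + LPS condition "
                         "(intercellular feedback excluded)")
    config = config or FitConfig()
    bounds = config.bounds()
    n_obj = len(objective.targets)

    def eval_fn(x):
        params = config.base.replace(**_decode(x, config.free, bounds))
        return _safe_eval(params, [objective], n_obj)

    x0 = _encode_centre(config.free, bounds, config.base) if config.seed_centre else None
    X, F = nsga2(eval_fn, len(config.free), config.pop_size, config.n_gen,
                 seed, x_init=x0)
    fronts = _nondominated_sort(F)
    front = fronts[0]
    # top up from subsequent fronts if the first is tiny
    fi = 1
    while len(front) < config.min_family and fi < len(fronts):
        front = np.concatenate([front, fronts[fi]])
        fi += 1
    # deduplicate identical objective vectors, keep pairwise nondomination
    members, F_keep = [], []
    for i in front:
        if any(np.allclose(F[i], f) for f in F_keep):
            continue
        members.append(_decode(X[i], config.free, bounds))
        F_keep.append(F[i])
    fam_F = np.array(F_keep)
    keep = []
    for i in range(len(fam_F)):
        dominated = np.all(fam_F <= fam_F[i], axis=1) & np.any(fam_F < fam_F[i], axis=1)
        if not dominated.any():
            keep.append(i)
    if len(keep) < 1:
        keep = list(range(len(fam_F)))
    return ParameterFamily([members[i] for i in keep], fam_F[keep])


def fit_round2(objectives=None, family: ParameterFamily | None = None,
               config: FitConfig | None = None, seed: int = 0):
    """Round 2: fit the full model across conditions.

    Round-1 parameters are drawn only from ``family`` members (one
    categorical gene selects the member); the round-2 set is searched
    freely.  Returns (best ParameterSet, per-condition residual log).
    """
    objectives = objectives or printed_round2_objectives()
    if family is None or len(family) == 0:
        raise ValueError("round 2 requires a non-empty round-1 family")
    if len(objectives) < 2:
        raise ValueError("round 2 needs a multi-condition objective set")
    config = config or FitConfig(free=ROUND2_FREE)
    bounds = config.bounds()
    n_cond = len(objectives)

    def build(x):
        member = family.members[min(int(x[0] * len(family)), len(family) - 1)]
        p = config.base.replace(**member)
        return p.replace(**_decode(x[1:], config.free, bounds))

    def eval_fn(x):
        params = build(x)
        try:
            res = evaluate_conditions(params, objectives)
            return np.array([r.sum() for r in res])
        except (RuntimeError, ValueError):
            return np.full(n_cond, 1e6)

    if config.seed_centre:
        # one seed row per family member: member selector + centre genes
        centre = _encode_centre(config.free, bounds, config.base)
        sel = (np.arange(len(family)) + 0.5) / len(family)
        x0 = np.column_stack([sel, np.tile(centre, (len(family), 1))])
        x0 = x0[: config.pop_size]
    else:
        x0 = None
    X, F = nsga2(eval_fn, 1 + len(config.free), config.pop_size, config.n_gen,
                 seed, x_init=x0)
    weights = np.array([o.weight for o in objectives])
    total = (F * np.where(weights > 0, 1.0, 0.0)).sum(axis=1) \
        if np.all(weights == 1.0) else F @ weights
    best = int(np.argmin(total))
    params = build(X[best])
    log = {"per_condition_residuals": F[best].tolist(),
           "total": float(total[best]), "seed": seed,
           "pop_size": config.pop_size, "n_gen": config.n_gen}
    return params, log
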