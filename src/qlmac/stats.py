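"""Quantification and in-silico experiments on simulated populations.

Covers the analysis layer: nadir thresholding of bimodal distributions
(licensed fraction), CV timecourses, permutation-tested R^2 between
per-cell scalars, 12 hps integrated readouts, one-at-a-time mechanism
sweeps, parameter-robustness sweeps, and the heterogeneous-vs-homogeneous
population comparison.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm

from .initdist import MixtureModel, build_initial_ensemble
from .model import ParameterSet
from .perturbations import PerturbationSpec, apply_mechanism_scaling
from .population import EnsembleResult, simulate_population

__all__ = ["NadirResult", "nadir_threshold", "cv_timecourse",
           "r2_permutation", "readouts_12hps", "mechanism_sweep",
           "robustness_cv_sweep", "hetero_vs_homo", "classify_activation"]


# ---------------------------------------------------------------------------
# Bimodality thresholding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NadirResult:
    """Threshold at the density nadir between two modes (log scale)."""

    threshold: float
    fraction_high: float
    unimodal: bool

    def __iter__(self):
        return iter((self.threshold, self.fraction_high))


def nadir_threshold(samples: np.ndarray, grid_size: int = 512) -> NadirResult:
    """Find the antimode between the two dominant modes of a log-scale KDE.

    Uses a Gaussian KDE with Silverman bandwidth; the threshold is the
    density minimum between the two highest local maxima, and
    ``fraction_high`` is the share of samples above it.  A unimodal
    density returns a flagged sentinel (NaN threshold).
    """
    z = np.asarray(samples, dtype=float).ravel()
    if z.size < 100:
        raise ValueError("need >= 100 samples for a stable antimode estimate")
    if not np.all(np.isfinite(z)):
        raise ValueError("samples must be finite")
    kde = gaussian_kde(z, bw_method="silverman")
    pad = 0.5 * z.std()
    grid = np.linspace(z.min() - pad, z.max() + pad, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(interior)[0] + 1
    if len(peaks) < 2:
        return NadirResult(math.nan, math.nan, unimodal=True)
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = sorted(top2)
    nadir = lo + int(np.argmin(dens[lo:hi + 1]))
    thr = float(grid[nadir])
    return NadirResult(thr, float(np.mean(z > thr)), unimodal=False)


def classify_activation(cum_mcherry: np.ndarray) -> np.ndarray:
    """Post-hoc high/low activation labels from log cumulative mCherry.

    Splits at the nadir threshold; if the distribution is unimodal, falls
    back to a two-means split on the log scale.  Returns a boolean array
    (True = high).  All-identical input raises (single group).
    """
    c = np.asarray(cum_mcherry, dtype=float).ravel()
    if np.ptp(c) == 0:
        raise ValueError("all cells identical: single activation group")
    z = np.log(np.maximum(c, 1e-12))
    if z.size >= 100:
        res = nadir_threshold(z)
        if not res.unimodal:
            return z > res.threshold
    # two-means on the log scale (deterministic Lloyd iteration)
    lo, hi = z.min(), z.max()
    for _ in range(100):
        thr = (lo + hi) / 2.0
        g = z > thr
        if g.all() or (~g).all():
            break
        lo_new, hi_new = z[~g].mean(), z[g].mean()
        if np.isclose(lo_new, lo) and np.isclose(hi_new, hi):
            break
        lo, hi = lo_new, hi_new
    return z > (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Dispersion and correlation statistics
# ---------------------------------------------------------------------------

def cv_timecourse(ensemble: EnsembleResult, observable: str,
                  mean_floor: float = 1e-9) -> np.ndarray:
    """Coefficient of variation across cells at each output time.

    Returns CV(t) with NaN where the population mean is below
    ``mean_floor`` (CV undefined).  Population (ddof=0) SD convention.
    """
    y = ensemble.observable(observable)
    if y.shape[1] < 2:
        raise ValueError("CV needs at least two cells")
    mean = y.mean(axis=1)
    sd = y.std(axis=1, ddof=0)
    cv = np.full_like(mean, np.nan)
    ok = mean > mean_floor
    cv[ok] = sd[ok] / mean[ok]
    return cv


@dataclass(frozen=True)
class R2PermResult:
    r2: float
    p_value: float          # permutation p (add-one correction; exact if exhaustive)
    p_gauss: float          # Gaussian-tail approximation of the permutation null
    exhaustive: bool
    n_perm: int


def r2_permutation(x: np.ndarray, y: np.ndarray, B: int = 9999,
                   seed: int = 0) -> R2PermResult:
    """One-tailed permutation test of the least-squares R^2 between x and y.

    Permutes y against x.  For n <= 7 the full n! permutation set is
    enumerated (exact p); otherwise B Monte-Carlo permutations with the
    add-one correction p = (1 + #{R2_perm >= R2_obs}) / (B + 1).  The
    Gaussian-tail value approximates the far tail that a finite B cannot
    resolve and is reported separately.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be equal length, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    if B < 999:
        raise ValueError("B must be >= 999")

    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    n = x.size

    def r2_of(perm_y):
        return float(np.mean(xs * perm_y) ** 2)

    obs = r2_of(ys)
    if n <= 7:
        vals = np.array([r2_of(ys[list(p)])
                         for p in itertools.permutations(range(n))])
        p_perm = float(np.mean(vals >= obs - 1e-15))
        exhaustive, n_perm = True, len(vals)
    else:
        rng = np.random.default_rng(seed)
        vals = np.empty(B)
        perm = np.arange(n)
        for b in range(B):
            rng.shuffle(perm)
            vals[b] = r2_of(ys[perm])
        p_perm = (1.0 + float(np.sum(vals >= obs - 1e-15))) / (B + 1.0)
        exhaustive, n_perm = False, B
    mu, sd = float(vals.mean()), float(vals.std(ddof=1))
    p_gauss = float(norm.sf(obs, loc=mu, scale=max(sd, 1e-300)))
    return R2PermResult(r2=obs, p_value=p_perm, p_gauss=p_gauss,
                        exhaustive=exhaustive, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Integrated readouts
# ---------------------------------------------------------------------------

def readouts_12hps(ensemble: EnsembleResult) -> pd.DataFrame:
    """Per-cell 12 hps readout triple.

    Trapezoid integrals of total reporter and mature mCherry over
    [0, 12] hps, and the cumulative secreted TNF flux accrued on that
    window (a.u. per cell).
    """
    t = ensemble.times
    if t[-1] < 12.0 - 1e-9:
        raise ValueError("simulation must span at least 12 hps")
    m = (t >= 0.0) & (t <= 12.0 + 1e-9)
    tw = t[m]
    tot = ensemble.observable("total_reporter")[m]
    mch = ensemble.observable("mch_mat")[m]
    cum = ensemble.observable("cum_secreted")
    i0 = int(np.argmin(np.abs(t - 0.0)))
    i12 = int(np.argmin(np.abs(t - 12.0)))
    return pd.DataFrame({
        "cell_id": np.arange(ensemble.n_cells),
        "integ_total_reporter": np.trapezoid(tot, tw, axis=0),
        "integ_mcherry": np.trapezoid(mch, tw, axis=0),
        "cum_secreted_tnf": cum[i12] - cum[i0],
    })


_READOUT_COLS = ("integ_total_reporter", "integ_mcherry", "cum_secreted_tnf")


def _mean_readouts(params: ParameterSet, spec: PerturbationSpec,
                   initials, k_rela0=None) -> np.ndarray:
    ens = simulate_population(initials, params, spec, k_rela0=k_rela0)
    r = readouts_12hps(ens)
    return r[list(_READOUT_COLS)].mean().to_numpy()


# ---------------------------------------------------------------------------
# Mechanism and robustness sweeps
# ---------------------------------------------------------------------------

def default_multiplier_grid(n: int = 7) -> np.ndarray:
    """Log2-spaced one-at-a-time multiplier grid over 1/8x..8x (incl. 1x)."""
    return np.power(2.0, np.linspace(-3, 3, n))


def mechanism_sweep(base: ParameterSet, grid: np.ndarray | None = None,
                    condition: PerturbationSpec | None = None,
                    initials=None, k_rela0=None) -> pd.DataFrame:
    """One-at-a-time sweep of mechanism magnitudes m1..m6.

    For each mechanism the multiplier runs over ``grid`` with the other
    five held at 1x; readouts are the mean 12 hps triple.  Default
    condition: high density, LPS 100 ng/ml.  ``initials`` defaults to the
    single mean cell (equilibrated basal state).
    """
    from .model import basal_state
    from .perturbations import configure_params
    grid = default_multiplier_grid() if grid is None else np.asarray(grid, float)
    if not np.any(np.isclose(grid, 1.0)):
        raise ValueError("multiplier grid must include the 1x base point")
    condition = condition or PerturbationSpec(lps=100.0)
    if initials is None:
        initials = [basal_state(configure_params(base, condition))]
    rows = []
    for mech in range(1, 7):
        for m in grid:
            mult = [1.0] * 6
            mult[mech - 1] = float(m)
            spec = dataclasses.replace(condition, mech_multipliers=tuple(mult))
            vals = _mean_readouts(base, spec, initials, k_rela0)
            rows.append({"mechanism": mech, "multiplier": float(m),
                         **dict(zip(_READOUT_COLS, vals))})
    return pd.DataFrame(rows)


#: Parameters held fixed in the robustness sweep: structural knobs
#: (multipliers, Hill exponents, flags, dose scales) rather than kinetic rates.
_ROBUSTNESS_EXCLUDE = {"m1", "m2", "m3", "m4", "m5", "m6", "fbd_on",
                       "h_ikb", "h_fbd", "h_txn", "K_lps", "K_pma", "K_il10",
                       "capacity_fold"}


def robustness_cv_sweep(base: ParameterSet, cv_list, n_samples: int,
                        seed: int, condition: PerturbationSpec | None = None,
                        initials=None) -> pd.DataFrame:
    """Global parameter-variation robustness.

    For each CV, every kinetic parameter is drawn lognormally with median
    at its fitted value and log-SD set so the linear CV matches; the
    divergence metric is the median (over draws) of the mean absolute
    relative deviation of the 12 hps readout triple from the base run.
    """
    cv_list = list(cv_list)
    if len(cv_list) < 2:
        raise ValueError("need at least two CV values")
    if n_samples < 20:
        raise ValueError("need at least 20 samples per CV")
    from .model import basal_state
    from .perturbations import configure_params
    condition = condition or PerturbationSpec(lps=100.0)
    if initials is None:
        initials = [basal_state(configure_params(base, condition))]
    base_vals = _mean_readouts(base, condition, initials)
    names = [f.name for f in dataclasses.fields(base)
             if f.name not in _ROBUSTNESS_EXCLUDE
             and getattr(base, f.name) > 0]
    rng = np.random.default_rng(seed)
    rows = []
    for cv in cv_list:
        sigma = math.sqrt(math.log(1.0 + cv ** 2))
        devs = []
        for _ in range(n_samples):
            if cv == 0:
                p = base
            else:
                draw = {nm: getattr(base, nm) * rng.lognormal(0.0, sigma)
                        for nm in names}
                p = base.replace(**draw)
            try:
                vals = _mean_readouts(p, condition, initials)
            except RuntimeError:
                continue
            devs.append(np.mean(np.abs(vals - base_vals)
                                / np.maximum(base_vals, 1e-12)))
        rows.append({"cv": float(cv),
                     "divergence": float(np.median(devs)),
                     "n_ok": len(devs)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Heterogeneous vs homogeneous populations
# ---------------------------------------------------------------------------

def hetero_vs_homo(params: ParameterSet, mix_high: MixtureModel,
                   mix_low: MixtureModel, seed: int, n_cells: int = 30,
                   lps: float = 100.0) -> tuple[pd.DataFrame, dict]:
    """Compare heterogeneous vs homogeneous populations across scenarios.

    Scenarios are {density low/high} x {initial distribution low/high}.
    Homogeneous cells carry the mean (on the linear scale) of the matching
    heterogeneous distribution; both initial distributions are normalized
    against the high-density mixture so their levels are comparable.
    Readouts are normalized to the heterogeneous low-density/low-initials
    scenario (= 1x).  ``total_secreted`` folds in cell number (density).

    The coupling metric compares the total-TNF fold change when density
    and initial state move together against the product of the two
    single-factor fold changes.
    """
    anchor = mix_high.mean_exp()
    rows = []
    for pop_kind in ("heterogeneous", "homogeneous"):
        for dens in ("low", "high"):
            for init in ("low", "high"):
                mix = mix_high if init == "high" else mix_low
                spec = PerturbationSpec(lps=lps, density=dens)
                if pop_kind == "heterogeneous":
                    initials, k_rela0, _ = build_initial_ensemble(
                        mix, n_cells, params, seed, norm=anchor)
                else:
                    f = mix.mean_exp() / anchor
                    initials, k_rela0, _ = build_initial_ensemble(
                        mix, 1, params, seed, norm=anchor, factor_override=f)
                vals = _mean_readouts(params, spec, initials, k_rela0)
                dens_rel = spec.density0 / PerturbationSpec(density="high").density0
                rows.append({"population": pop_kind, "density": dens,
                             "initials": init,
                             **dict(zip(_READOUT_COLS, vals)),
                             "total_secreted": vals[2] * dens_rel})
    df = pd.DataFrame(rows)
    ref = df[(df.population == "heterogeneous") & (df.density == "low")
             & (df.initials == "low")].iloc[0]
    for c in list(_READOUT_COLS) + ["total_secreted"]:
        df[c + "_fold"] = df[c] / ref[c]

    het = df[df.population == "heterogeneous"].set_index(["density", "initials"])
    coupled = het.loc[("high", "high"), "total_secreted_fold"]
    f_density = het.loc[("high", "low"), "total_secreted_fold"]
    f_initial = het.loc[("low", "high"), "total_secreted_fold"]
    coupling = {"coupled_fold": float(coupled),
                "density_fold": float(f_density),
                "initial_fold": float(f_initial),
                "independent_product": float(f_density * f_initial),
                "synergy": float(coupled / (f_density * f_initial))}
    return df, coupling
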