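"""Pre-stimulus reporter distributions: mixture fits, cross-density
imputation, and correlated initial-condition sampling.

Pre-stimulus EGFP-RelA fluorescence is bimodal (licensed high-state cells
vs low-state cells) and its shape depends on cell-density history.  The
high- and low-density measurements are acquired in non-comparable units,
so the low-density distribution is *imputed* from the high-density one by
a transform - a shift in log-fluorescence plus a reweighting of the two
mixture components - chosen to match the observed low-density shape
(Kolmogorov-Smirnov distance).  Cells are then initialized by drawing one
latent log-fluorescence per cell and mapping it monotonically onto the
initial NF-kB:IkB complex, the basal Rela transcription rate, and the
initial Rela mRNA level (fully correlated extrinsic noise).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import ks_2samp
from sklearn.mixture import GaussianMixture

from .model import CellState, ParameterSet, basal_state

__all__ = ["MixtureModel", "TransformSpec", "fit_gmm2",
           "impute_cross_density", "sample_initials", "build_initial_ensemble"]

MIN_SAMPLES = 50


@dataclass(frozen=True)
class MixtureModel:
    """Two-component Gaussian mixture in log-fluorescence space.

    Components are ordered so ``mu_low < mu_high``; ``w_low + w_high = 1``.
    """

    w_low: float
    w_high: float
    mu_low: float
    mu_high: float
    sd_low: float
    sd_high: float

    def __post_init__(self):
        if not (0.0 < self.w_low < 1.0 and 0.0 < self.w_high < 1.0):
            raise ValueError("weights must lie in (0, 1)")
        if abs(self.w_low + self.w_high - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.sd_low <= 0 or self.sd_high <= 0:
            raise ValueError("component SDs must be > 0")
        if self.mu_low > self.mu_high:
            raise ValueError("components must be ordered by mean")

    @property
    def ashman_d(self) -> float:
        """Ashman's bimodality separation D; D > 2 indicates two clean modes."""
        return math.sqrt(2.0) * (self.mu_high - self.mu_low) / math.sqrt(
            self.sd_low ** 2 + self.sd_high ** 2)

    @property
    def degenerate(self) -> bool:
        """True when the fit collapsed to (nearly) a single Gaussian: a
        vanishing component, coincident means, or unresolvable overlap."""
        return self.w_low < 0.02 or self.w_high < 0.02 \
            or (self.mu_high - self.mu_low) < 0.1 or self.ashman_d < 2.0

    @property
    def mean(self) -> float:
        return self.w_low * self.mu_low + self.w_high * self.mu_high

    def mean_exp(self) -> float:
        """E[exp(Z)] for a latent Z drawn from the mixture."""
        return (self.w_low * np.exp(self.mu_low + self.sd_low ** 2 / 2)
                + self.w_high * np.exp(self.mu_high + self.sd_high ** 2 / 2))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.random(n) < self.w_high
        z = np.where(comp,
                     rng.normal(self.mu_high, self.sd_high, n),
                     rng.normal(self.mu_low, self.sd_low, n))
        return z

    def responsibility_high(self, z: np.ndarray) -> np.ndarray:
        """Posterior probability that each sample came from the high mode."""
        from scipy.stats import norm
        lo = self.w_low * norm.pdf(z, self.mu_low, self.sd_low)
        hi = self.w_high * norm.pdf(z, self.mu_high, self.sd_high)
        return hi / np.maximum(lo + hi, 1e-300)

    def to_dict(self) -> dict:
        return {"w_low": self.w_low, "w_high": self.w_high,
                "mu_low": self.mu_low, "mu_high": self.mu_high,
                "sd_low": self.sd_low, "sd_high": self.sd_high}

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(**{k: float(d[k]) for k in
                      ("w_low", "w_high", "mu_low", "mu_high", "sd_low", "sd_high")})


@dataclass(frozen=True)
class TransformSpec:
    """Cross-density transform: log-shift plus target high-mode weight."""

    delta: float
    w_high: float

    def __post_init__(self):
        if not (0.0 <= self.w_high <= 1.0):
            raise ValueError("target high-mode weight must lie in [0, 1]")


def fit_gmm2(samples: np.ndarray, seed: int = 0, n_init: int = 8) -> MixtureModel:
    """Maximum-likelihood two-component Gaussian fit (multi-start EM).

    ``samples`` are log-fluorescence values; requires at least 50 finite
    points.  Components are relabeled so the low-mean mode comes first.
    """
    z = np.asarray(samples, dtype=float).ravel()
    if not np.all(np.isfinite(z)):
        raise ValueError("samples must be finite")
    if z.size < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {z.size}")
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         n_init=n_init, random_state=seed, reg_covar=1e-6)
    gm.fit(z[:, None])
    sds = np.sqrt(gm.covariances_.ravel())
    floor = 1e-3 * max(z.std(), 1e-12)
    if np.any(sds < floor):
        raise ValueError(
            f"degenerate EM solution: component SD {sds.min():.3g} below "
            f"floor {floor:.3g}")
    order = np.argsort(gm.means_.ravel())
    w = gm.weights_.ravel()[order]
    mu = gm.means_.ravel()[order]
    sd = sds[order]
    return MixtureModel(w_low=float(w[0]), w_high=float(w[1]),
                        mu_low=float(mu[0]), mu_high=float(mu[1]),
                        sd_low=float(sd[0]), sd_high=float(sd[1]))


def _apply_transform(z: np.ndarray, resp_high: np.ndarray, spec: TransformSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Shift samples by delta and resample mode labels to hit w_high."""
    hard = resp_high >= 0.5
    hi_pool = z[hard]
    lo_pool = z[~hard]
    if hi_pool.size == 0 or lo_pool.size == 0:
        return z + spec.delta
    n = z.size
    take_hi = rng.random(n) < spec.w_high
    out = np.where(take_hi,
                   rng.choice(hi_pool, size=n, replace=True),
                   rng.choice(lo_pool, size=n, replace=True))
    return out + spec.delta


def impute_cross_density(high_samples: np.ndarray, target,
                         seed: int = 0) -> tuple[TransformSpec, np.ndarray]:
    """Impute a comparable-unit cross-density distribution.

    ``target`` is either an array of (non-comparable-unit) log samples of
    the other density condition, or a dict with keys ``mode_low``,
    ``mode_high``, ``w_high`` summarizing it.  The returned samples live in
    the units of ``high_samples``; the shift ``delta`` and reweighting
    ``w_high`` minimize the KS distance between the transformed source and
    the target *shape* (target recentred onto source units).
    """
    z = np.asarray(high_samples, dtype=float).ravel()
    src = fit_gmm2(z, seed=seed)
    resp = src.responsibility_high(z)
    rng = np.random.default_rng(seed)

    if isinstance(target, dict):
        spec = TransformSpec(delta=float(target["mode_high"]) - src.mu_high,
                             w_high=float(target["w_high"]))
        return spec, _apply_transform(z, resp, spec,
                                      np.random.default_rng(seed + 1))

    tgt = np.asarray(target, dtype=float).ravel()
    try:
        tfit = fit_gmm2(tgt, seed=seed)
        tgt_bimodal = not tfit.degenerate
    except ValueError:
        tfit, tgt_bimodal = None, False
    if tgt_bimodal:
        delta0 = tfit.mu_high - src.mu_high
        w_inits = {tfit.w_high, 0.25, 0.5, 0.75}
    else:
        warnings.warn("target distribution looks unimodal; imputing with the "
                      "high-mode weight pinned at its boundary", stacklevel=2)
        delta0 = float(np.median(tgt) - src.mu_high)
        w_inits = {0.0, 1.0}

    fixed_rng_seed = seed + 1

    def loss(x):
        d, w = x
        w = min(max(w, 0.0), 1.0)
        imp = _apply_transform(z, resp, TransformSpec(d, w),
                               np.random.default_rng(fixed_rng_seed))
        return ks_2samp(imp, tgt).statistic

    best = None
    for w_init in w_inits:
        res = minimize(loss, x0=[delta0, w_init], method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    spec = TransformSpec(delta=float(best.x[0]),
                         w_high=float(min(max(best.x[1], 0.0), 1.0)))
    imputed = _apply_transform(z, resp, spec,
                               np.random.default_rng(fixed_rng_seed))
    return spec, imputed


def sample_initials(mix, n: int, seed: int, correlated: bool = True,
                    norm: float | None = None,
                    factor_override: float | None = None) -> pd.DataFrame:
    """Draw per-cell latent log-fluorescence and map it to initial factors.

    Returns a table with ``latent`` and a multiplicative ``factor``
    (exp(latent) normalized to population mean 1) applied identically to
    the initial NF-kB:IkB complex, the basal Rela transcription rate, and
    the initial Rela mRNA - one extrinsic-noise axis per cell.  With
    ``correlated=False`` the three factors are drawn independently (a
    sensitivity-check mode).

    ``norm`` overrides the normalization constant (useful to put two
    distributions in a common anchor's units); ``factor_override`` pins all
    cells to one factor (the homogeneous mean-cell construction).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(mix, MixtureModel):
        draw = lambda: mix.sample(n, rng)
        default_norm = mix.mean_exp()
    else:
        pool = np.asarray(mix, dtype=float).ravel()
        draw = lambda: rng.choice(pool, size=n, replace=True)
        default_norm = float(np.mean(np.exp(pool)))
    norm = default_norm if norm is None else float(norm)
    z = draw()
    if factor_override is not None:
        f = float(factor_override)
        return pd.DataFrame({
            "cell_id": np.arange(n),
            "latent": np.full(n, math.log(f * norm)),
            "factor_complex": np.full(n, f),
            "factor_rela": np.full(n, f),
            "factor_mrna": np.full(n, f),
        })
    if correlated:
        f_complex = f_rela = f_mrna = np.exp(z) / norm
    else:
        f_complex = np.exp(z) / norm
        f_rela = np.exp(draw()) / norm
        f_mrna = np.exp(draw()) / norm
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "latent": z,
        "factor_complex": f_complex,
        "factor_rela": f_rela,
        "factor_mrna": f_mrna,
    })


def build_initial_ensemble(mix, n: int, params: ParameterSet, seed: int,
                           correlated: bool = True, norm: float | None = None,
                           factor_override: float | None = None):
    """Per-cell initial states plus per-cell basal Rela transcription rates.

    The mean cell's equilibrated basal state is the calibration anchor: the
    NF-kB-carrying pools (complex, free, nuclear, Rela mRNA) of each cell
    scale with its latent factor, so the population mean complex equals the
    anchor value.
    """
    table = sample_initials(mix, n, seed, correlated=correlated, norm=norm,
                            factor_override=factor_override)
    anchor = basal_state(params)
    base = anchor.to_array()
    from .model import SPECIES
    idx = {s: i for i, s in enumerate(SPECIES)}
    states = np.tile(base, (n, 1))
    for sp_name, col in [("nfkb_ikb_c", "factor_complex"),
                         ("nfkb_c", "factor_complex"),
                         ("nfkb_n", "factor_complex"),
                         ("rela_mrna", "factor_mrna")]:
        states[:, idx[sp_name]] = base[idx[sp_name]] * table[col].to_numpy()
    k_rela0 = params.k_rela0 * table["factor_rela"].to_numpy()
    initials = [CellState.from_array(row) for row in states]
    return initials, k_rela0, table


def save_mixture(path, mix: MixtureModel, transform: TransformSpec | None = None):
    payload = {"mixture": mix.to_dict()}
    if transform is not None:
        payload["transform"] = {"delta": transform.delta,
                                "w_high": transform.w_high}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_mixture(path) -> MixtureModel:
    with open(path) as fh:
        payload = json.load(fh)
    return MixtureModel.from_dict(payload["mixture"])
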