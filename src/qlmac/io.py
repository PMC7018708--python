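"""Table I/O and flow-cytometry display transforms.

Tables are tidy CSV (one row per cell per time, or per cell for
snapshots).  Display transforms implement the logicle scale (linear near
zero, log10 far from zero; Parks-Roeder-Moore biexponential) and the
simpler log10-with-shift approximation used for simulated histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = ["LogicleTransform", "transform_display", "read_cells_csv",
           "write_cells_csv"]


# ---------------------------------------------------------------------------
# Display transforms
# ---------------------------------------------------------------------------

class LogicleTransform:
    """Logicle (biexponential) display scale.

    Parameters follow the standard convention: ``T`` top of scale, ``W``
    linearization width in decades, ``M`` total display decades, ``A``
    additional negative decades.  ``transform`` maps data to display
    units in [0, 1]; ``inverse`` maps back.
    """

    def __init__(self, T: float = 262144.0, W: float = 0.5, M: float = 4.5,
                 A: float = 0.0):
        if T <= 0 or W < 0 or M <= 0 or A < 0:
            raise ValueError("require T > 0, W >= 0, M > 0, A >= 0")
        if W > M / 2:
            raise ValueError("linear width W too large for M (non-monotone "
                             "parameterization)")
        self.T, self.W, self.M, self.A = T, W, M, A
        b = (M + A) * math.log(10.0)
        w = W / (M + A)
        x2 = A / (M + A)
        x1 = x2 + w
        x0 = x2 + 2.0 * w
        if w > 0:
            d = brentq(lambda dd: 2.0 * (math.log(dd) - math.log(b))
                       + w * (b + dd), 1e-12, b - 1e-12)
        else:
            d = b
        c_a = math.exp(x0 * (b + d))
        mf_a = math.exp(b * x1) - c_a / math.exp(d * x1)
        self._a = T / ((math.exp(b) - mf_a) - c_a / math.exp(d))
        self._b, self._d = b, d
        self._c = c_a * self._a
        self._f = -mf_a * self._a
        self._x1 = x1

    def _biexp(self, y):
        """Display -> data (vectorized)."""
        y = np.asarray(y, dtype=float)
        pos = y >= self._x1
        yy = np.where(pos, y, 2.0 * self._x1 - y)
        s = (self._a * np.exp(self._b * yy) - self._c * np.exp(-self._d * yy)
             + self._f)
        return np.where(pos, s, -s)

    def inverse(self, y):
        return self._biexp(y)

    def transform(self, values):
        """Data -> display units in [0, 1], by monotone root finding."""
        v = np.atleast_1d(np.asarray(values, dtype=float))
        lo, hi = -0.5, 1.5
        ylo = np.full_like(v, lo)
        yhi = np.full_like(v, hi)
        # bisection: ~50 iterations gives ~1e-15 display resolution
        for _ in range(60):
            mid = 0.5 * (ylo + yhi)
            smaller = self._biexp(mid) < v
            ylo = np.where(smaller, mid, ylo)
            yhi = np.where(smaller, yhi, mid)
        out = 0.5 * (ylo + yhi)
        return out if np.ndim(values) else float(out[0])


def transform_display(values, mode: str = "log10_shift", **params):
    """Monotone display transform of fluorescence values.

    ``mode='log10_shift'`` computes log10(v + c) with shift ``c`` (> 0);
    ``mode='logicle'`` applies the logicle scale with parameters
    ``T, W, M, A``.
    """
    if mode == "log10_shift":
        c = params.get("c", 1.0)
        if c <= 0:
            raise ValueError("shift constant must be > 0")
        return np.log10(np.asarray(values, dtype=float) + c)
    if mode == "logicle":
        return LogicleTransform(**params).transform(values)
    raise ValueError(f"unknown display mode {mode!r}")


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_TRAJ_REQUIRED = ("cell_id", "time_h")
_SNAP_REQUIRED = ("cell_id",)


def read_cells_csv(path, snapshot: bool = False) -> pd.DataFrame:
    """Read a per-cell trajectory (or snapshot) table.

    Requires ``cell_id`` (and ``time_h`` for trajectories); all other
    columns must be numeric and are passed through untouched.  Raises
    a named error for missing columns and a row-indexed error for
    non-numeric cells.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"no rows in {path}")
    required = _SNAP_REQUIRED if snapshot else _TRAJ_REQUIRED
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r}, row(s) "
                f"{list(df.index[bad][:5])} of {path}")
        df[col] = coerced
    return df


def write_cells_csv(df: pd.DataFrame, path) -> None:
    """Write a table so a read round-trip is lossless (17 significant digits)."""
    df.to_csv(path, index=False, float_format="%.17g")
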