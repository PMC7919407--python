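"""CC1/2-versus-resolution sigmoid fitting and threshold inversion.

The achieved resolution of a merged data set is reported as the point where
a fitted sigmoid in s = 1/d² crosses a CC1/2 threshold (0.5 by default).
The model is the AIMLESS-style curve

    CC(s) = ½·(1 − tanh((s − d0)/r))·dcc − dcc + b

with plateau ``b`` at low resolution and ``b − dcc`` at high resolution.
Unlike the fixed-plateau variant, ``b`` is a free parameter: sparsely merged
serial data sets sit below CC1/2 = 1 even in low-resolution shells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class CCFitParams:
    """Sigmoid parameters (all abscissa quantities in s = 1/d², Å⁻²)."""

    d0: float  # midpoint
    r: float  # width
    dcc: float  # amplitude of the CC drop
    b: float  # low-resolution plateau
    residual_norm: float = float("nan")
    converged: bool = True


class ThresholdNotCrossed(ValueError):
    """The requested CC threshold lies outside the sigmoid's range."""


def cc_model(s: float | np.ndarray, p: CCFitParams) -> float | np.ndarray:
    """Evaluate the sigmoid; limits are b (s → −∞) and b − dcc (s → +∞)."""
    s_arr = np.asarray(s, dtype=float)
    out = 0.5 * (1.0 - np.tanh((s_arr - p.d0) / p.r)) * p.dcc - p.dcc + p.b
    return float(out) if np.isscalar(s) else out


def fit_cc_curve(
    s_mid: np.ndarray,
    cc_values: np.ndarray,
    weights: np.ndarray | None = None,
) -> CCFitParams:
    """Nonlinear least-squares fit of the CC1/2 sigmoid.

    ``s_mid`` are shell midpoints in s; optional ``weights`` (e.g. shell
    reflection counts) multiply the residuals.  Initialisation: b from the
    maximum CC, dcc from the CC range, d0 from the first crossing of the
    half-drop level, r from a tenth of the s range.  Degenerate input (flat
    CC, no drop) or optimiser failure is reported through ``converged`` on
    the result, never as an exception.
    """
    s_mid = np.asarray(s_mid, dtype=float)
    cc = np.asarray(cc_values, dtype=float)
    ok = np.isfinite(s_mid) & np.isfinite(cc)
    s_mid, cc = s_mid[ok], cc[ok]
    if weights is not None:
        weights = np.sqrt(np.asarray(weights, dtype=float)[ok])
    if len(s_mid) < 4:
        raise ValueError("need at least 4 shells to fit the sigmoid")

    b0 = float(cc.max())
    dcc0 = float(max(cc.max() - cc.min(), 1e-3))
    half_level = b0 - dcc0 / 2.0
    below = np.flatnonzero(cc < half_level)
    d0_0 = float(s_mid[below[0]]) if below.size else float(np.median(s_mid))
    r0 = float((s_mid.max() - s_mid.min()) / 10.0) or 1e-3

    def resid(theta):
        p = CCFitParams(*theta)
        res = cc_model(s_mid, p) - cc
        return res * weights if weights is not None else res

    lb = [-np.inf, 1e-9, 1e-9, -0.5]
    ub = [np.inf, np.inf, 1.5, 1.05]
    x0 = np.clip([d0_0, r0, dcc0, b0], lb, ub)
    try:
        sol = least_squares(resid, x0, bounds=(lb, ub))
        theta = sol.x
        residual = float(np.linalg.norm(sol.fun))
        ok_fit = bool(sol.success)
    except Exception:
        theta = x0
        residual = float(np.linalg.norm(resid(x0)))
        ok_fit = False
    # a vanishing amplitude means the data never drop: the fit is degenerate
    if theta[2] < 1e-3 * max(abs(theta[3]), 1.0):
        ok_fit = False
    return CCFitParams(
        d0=float(theta[0]),
        r=float(theta[1]),
        dcc=float(theta[2]),
        b=float(theta[3]),
        residual_norm=residual,
        converged=ok_fit,
    )


def resolution_at_threshold(p: CCFitParams, tau: float = 0.5) -> float:
    """Resolution d (Å) at which the fitted sigmoid crosses CC = tau.

    Closed form: s* = d0 + r·artanh(1 − 2·(tau + dcc − b)/dcc), valid when
    b − dcc < tau < b; the crossing must land at physical s* > 0.
    """
    if not p.b - p.dcc < tau < p.b:
        raise ThresholdNotCrossed(
            f"threshold {tau} not crossed: sigmoid spans ({p.b - p.dcc}, {p.b})"
        )
    arg = 1.0 - 2.0 * (tau + p.dcc - p.b) / p.dcc
    s_star = p.d0 + p.r * np.arctanh(arg)
    if s_star <= 0:
        raise ValueError("crossing outside physical range (s* <= 0)")
    return float(1.0 / np.sqrt(s_star))
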