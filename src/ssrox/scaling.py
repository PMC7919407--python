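"""The logarithmic photon-budget scaling law and its Wilson interpretation.

Across merged serial data sets, the achievable resolution follows

    1/d² = a · ln(b · N_photon)

where N_photon is the total photon count over the merged (indexed) images.
The law is an ordinary least-squares line in (ln N, 1/d²); ``a`` is the
slope and ``b`` follows from the intercept.  Its Wilson-plot reading: the
mean intensity decays as exp(−B·s/2) while the measurable floor I_min is
fixed, so the resolution where signal meets the floor grows with the log of
the photon budget.  With the mean squared atomic scattering factor
approximated by a single exponential 21.3·exp(−B_f·s/2) (B_f ≈ 10.16 Å²),
the analytic form is

    1/d² = [2/(B + B_f)] · ln( (21.3·n·c / I_min) · N_photon )

giving a = 2/(B + B_f) and b = 21.3·n·c/I_min, with n the number of atoms
in the unit cell and c the proportionality constant between photons and
recorded intensity.  The slope→B mapping is deliberately pluggable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

#: s = 0 value of the single-exponential fit to the mean squared atomic
#: scattering factor of protein matter (electrons², per atom).
F_SQ_ZERO = 21.3
#: decay constant of that fit, in the same s-convention as the Wilson B (Å²)
F_SQ_DECAY_B = 10.16


class BelowMeasurabilityThreshold(ValueError):
    """The photon budget is at or below the model's zero-crossing."""


@dataclass(frozen=True)
class LogScalingModel:
    """Fitted scaling law 1/d² = a_slope · ln(b_scale · N_photon)."""

    a_slope: float  # Å⁻²
    b_scale: float  # photons⁻¹
    r_squared: float = float("nan")
    residuals: tuple = ()

    def __post_init__(self) -> None:
        if self.a_slope <= 0 or self.b_scale <= 0:
            raise ValueError("a_slope and b_scale must be positive")


@dataclass(frozen=True)
class WilsonInterpretation:
    """Physical reading of a fitted scaling law."""

    n0: float  # zero-crossing photon count, 1/b
    k_composite: float  # 21.3·n·c/I_min, photons⁻¹ (equals b when consistent)
    b_from_slope: float  # Wilson B implied by the slope, Å² (NaN if no mapping)
    i_min: float | None
    n_atoms: float | None
    c_proportionality: float | None
    f_sq_zero: float = F_SQ_ZERO


def fit_log_model(points) -> LogScalingModel:
    """Least-squares fit of 1/d² against ln(N_photon).

    ``points`` is an iterable of (N_photon, 1/d²) pairs (≥ 2; all positive).
    Slope = a; intercept = a·ln b.  Closed-form and deterministic.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (N_photon, 1/d^2) points")
    n_photon, inv_d2 = pts[:, 0], pts[:, 1]
    if np.any(n_photon <= 0) or np.any(inv_d2 <= 0):
        raise ValueError("N_photon and 1/d^2 must be positive")
    x = np.log(n_photon)
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all N_photon equal")
    slope, intercept = np.polyfit(x, inv_d2, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((inv_d2 - fitted) ** 2))
    ss_tot = float(np.sum((inv_d2 - inv_d2.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LogScalingModel(
        a_slope=float(slope),
        b_scale=float(math.exp(intercept / slope)),
        r_squared=r2,
        residuals=tuple(inv_d2 - fitted),
    )


def predict_resolution(m: LogScalingModel, n_photon: float) -> float:
    """Resolution d = [a·ln(b·N)]^(−1/2) at a given photon budget."""
    if n_photon <= 1.0 / m.b_scale:
        raise BelowMeasurabilityThreshold(
            f"N_photon must exceed the zero-crossing 1/b = {1.0 / m.b_scale:.3e}"
        )
    inv_d2 = m.a_slope * math.log(m.b_scale * n_photon)
    return 1.0 / math.sqrt(inv_d2)


def zero_crossing(m: LogScalingModel) -> float:
    """Photon count N0 = 1/b below which no meaningful data are obtained."""
    return 1.0 / m.b_scale


def images_needed(
    m: LogScalingModel, d_target: float, photons_per_image: float
) -> int:
    """Merged images required to reach a target resolution.

    ceil( exp((1/d²)/a) / (b·photons_per_image) ).
    """
    if d_target <= 0 or photons_per_image <= 0:
        raise ValueError("d_target and photons_per_image must be positive")
    n_photon = math.exp((1.0 / d_target**2) / m.a_slope) / m.b_scale
    return math.ceil(n_photon / photons_per_image)


def wilson_b_from_log_slope(a_slope: float, f_sq_decay: float = F_SQ_DECAY_B) -> float:
    """Default slope→B mapping: B = 2/a − B_f.

    Follows from equating the Wilson-decayed signal n·c·N·21.3·
    exp(−(B+B_f)·s/2) with the floor I_min; the scattering-factor decay B_f
    uses the single-exponential approximation (less valid at high
    resolution).
    """
    if a_slope <= 0:
        raise ValueError("a_slope must be positive")
    return 2.0 / a_slope - f_sq_decay


def wilson_interpretation(
    m: LogScalingModel,
    n_atoms: float | None = None,
    c_proportionality: float | None = None,
    i_min: float | None = None,
    slope_to_b: Callable[[float], float] | None = wilson_b_from_log_slope,
) -> WilsonInterpretation:
    """Interpret a fitted law through the Wilson-plot equation.

    Reports the zero-crossing N0 = 1/b, the composite constant
    K = 21.3·n·c/I_min (for comparison with b, which it equals when the
    constants are self-consistent), and the Wilson B implied by the slope via
    the registered ``slope_to_b`` mapping (NaN when the mapping is None).
    Missing constants yield a partial report with K flagged as NaN.
    """
    for name, v in (("n_atoms", n_atoms), ("c_proportionality", c_proportionality), ("i_min", i_min)):
        if v is not None and v <= 0:
            raise ValueError(f"{name} must be positive")
    if None not in (n_atoms, c_proportionality, i_min):
        k = F_SQ_ZERO * n_atoms * c_proportionality / i_min
    else:
        k = float("nan")
    b_impl = slope_to_b(m.a_slope) if slope_to_b is not None else float("nan")
    return WilsonInterpretation(
        n0=1.0 / m.b_scale,
        k_composite=k,
        b_from_slope=b_impl,
        i_min=i_min,
        n_atoms=n_atoms,
        c_proportionality=c_proportionality,
    )
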