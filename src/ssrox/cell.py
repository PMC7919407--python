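"""Unit-cell parameters and reciprocal-space metric helpers.

The metric calculations are delegated to :mod:`gemmi`; this module only adds
validation, the tetragonal preset used throughout the simulator, and a
vectorised ``1/d**2`` evaluation for arrays of Miller indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell (lengths in Å, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0 < ang < 180:
                raise ValueError(f"cell angle {name} must be in (0, 180)")

    @classmethod
    def tetragonal(cls, a: float, c: float) -> "UnitCell":
        """Tetragonal preset: enforces a = b and all angles 90°."""
        return cls(a, a, c, 90.0, 90.0, 90.0)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G*, so that s = 1/d² = h·G*·h."""
        m = np.array(self.to_gemmi().frac.mat.tolist())
        return m @ m.T

    def s_of_hkl(self, hkl: np.ndarray) -> np.ndarray:
        """1/d² (Å⁻²) for an (n, 3) integer array of Miller indices."""
        hkl = np.asarray(hkl, dtype=float)
        gstar = self.reciprocal_metric()
        return np.einsum("ij,jk,ik->i", hkl, gstar, hkl)

    def d_of_hkl(self, hkl: np.ndarray) -> np.ndarray:
        """Bragg spacing d (Å) for an (n, 3) array of Miller indices."""
        return 1.0 / np.sqrt(self.s_of_hkl(hkl))

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
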