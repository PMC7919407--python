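"""Sequential-bin unit-cell drift statistics and dose-series damage metrics.

Non-isomorphism during a serial acquisition shows up as a slow trend of the
unit-cell parameters with acquisition order.  ``bin_cell_drift`` divides the
full image sequence (hits and non-hits alike) into sequential bins and
averages the cell of the *indexed* images in each bin, matching how such
drift plots are usually prepared.  Global radiation damage is tracked
through the Wilson B factor of merged intensities and reported as the ratio
B_ref/B_n along the dose series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .merge import MergedSet
from .simulate import ObservationStream

_CELL_PARAMS = ("a", "b", "c", "alpha", "beta", "gamma")


def bin_cell_drift(stream: ObservationStream, n_bins: int = 10) -> pd.DataFrame:
    """Per-bin mean and σ of each cell parameter over indexed images.

    All images (including non-hits) are divided into ``n_bins`` contiguous
    bins in acquisition order; statistics are computed from the indexed
    images only.  A bin with no indexed images keeps NaN statistics (flagged,
    not an error).  Columns: bin, i_low, i_high (half-open image-index
    range), n_indexed, then mean_<p> and std_<p> for each cell parameter.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = len(stream.images)
    if n == 0:
        raise ValueError("empty stream")
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    rows = []
    for j in range(n_bins):
        lo, hi = int(edges[j]), int(edges[j + 1])
        members = [im for im in stream.images[lo:hi] if im.indexed]
        row: dict = {
            "bin": j + 1,
            "i_low": lo,
            "i_high": hi,
            "n_indexed": len(members),
        }
        for p in _CELL_PARAMS:
            vals = np.array([getattr(im.cell, p) for im in members])
            row[f"mean_{p}"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"std_{p}"] = float(vals.std(ddof=0)) if len(vals) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def percent_change(start: float, end: float) -> float:
    """Relative change 100·(end − start)/start."""
    if start == 0:
        raise ValueError("start must be nonzero")
    return 100.0 * (end - start) / start


@dataclass(frozen=True)
class WilsonFit:
    """Wilson B estimate from the resolution decay of merged intensities."""

    b_wilson: float  # Å²
    intercept: float  # ln(scale)
    n_shells: int
    residual_norm: float


def wilson_b(
    merged: MergedSet,
    s_min: float = 0.1,
    s_max: float | None = None,
    n_shells: int = 20,
) -> WilsonFit:
    """Wilson B from regression of ln(shell mean I) on shell mean s.

    The default ``s_min`` of 0.1 Å⁻² (≈ 3.2 Å) excludes the low-resolution
    regime where solvent and structure dominate over Wilson decay.  Shells
    with non-positive mean intensity are excluded; at least 3 usable shells
    are required.  B = −2 × slope.
    """
    table = merged.table
    s = table["s"].to_numpy()
    sel = s >= s_min
    if s_max is not None:
        sel &= s <= s_max
    sub = table[sel]
    if len(sub) < n_shells:
        raise ValueError("too few reflections inside the fit range")
    edges = np.quantile(sub["s"].to_numpy(), np.linspace(0, 1, n_shells + 1))
    shell = np.clip(np.searchsorted(edges[1:-1], sub["s"].to_numpy(), "left"), 0, n_shells - 1)
    mean_i = pd.Series(sub["i_merged"].to_numpy()).groupby(shell).mean()
    mean_s = pd.Series(sub["s"].to_numpy()).groupby(shell).mean()
    usable = mean_i > 0
    if usable.sum() < 3:
        raise ValueError("fewer than 3 shells with positive mean intensity")
    x = mean_s[usable].to_numpy()
    y = np.log(mean_i[usable].to_numpy())
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.linalg.norm(y - (slope * x + intercept)))
    return WilsonFit(
        b_wilson=float(-2.0 * slope),
        intercept=float(intercept),
        n_shells=int(usable.sum()),
        residual_norm=resid,
    )


def b_ratio_series(b_ref: float, b_list) -> list[float]:
    """Damage ratios B_ref/B_n along a dose series.

    A ratio below 1 means the data set has a larger (more damaged) B than
    the reference.
    """
    if b_ref <= 0:
        raise ValueError("B values must be positive")
    out = []
    for b_n in b_list:
        if b_n <= 0:
            raise ValueError("B values must be positive")
        out.append(float(b_ref / b_n))
    return out
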