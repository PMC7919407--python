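"""Monte Carlo merging of observation streams.

Observations are Lorentz-corrected, divided by per-image linear scale
factors, mapped to the Laue-unique set and averaged.  Merged sigmas come
from the sample scatter of the contributing observations (not from the
per-observation counting sigmas, which are unreliable for strongly partial
data).  Half sets for CC1/2 and Rsplit are split by image-index parity.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .cell import UnitCell
from .simulate import LAUE_GROUPS, ObservationStream

#: bounds guarding degenerate per-image scale factors
SCALE_CLAMP = (0.01, 100.0)


def lorentz_factor(s: float | np.ndarray, wavelength: float) -> float | np.ndarray:
    """Rotation-geometry Lorentz factor L = 1/sin(2θ).

    ``s`` is 1/d² in Å⁻²; sinθ = wavelength·sqrt(s)/2 must lie in (0, 1).
    The correction divides an observed intensity by L (the simulator applies
    L multiplicatively, so correction round-trips to the true value).
    """
    s_arr = np.asarray(s, dtype=float)
    sin_theta = wavelength * np.sqrt(s_arr) / 2.0
    if np.any(sin_theta <= 0) or np.any(sin_theta >= 1):
        raise ValueError("reflection outside the sphere: need 0 < wavelength*sqrt(s)/2 < 1")
    two_theta = 2.0 * np.arcsin(sin_theta)
    out = 1.0 / np.sin(two_theta)
    return float(out) if np.isscalar(s) else out


def _to_asu(hkl: np.ndarray, laue: str) -> np.ndarray:
    """Map Miller indices to the reciprocal-space asymmetric unit."""
    sg = gemmi.SpaceGroup(LAUE_GROUPS[laue])
    asu = gemmi.ReciprocalAsu(sg)
    ops = sg.operations()
    uniq, inverse = np.unique(hkl, axis=0, return_inverse=True)
    mapped = np.array(
        [asu.to_asu([int(h), int(k), int(l)], ops)[0] for h, k, l in uniq],
        dtype=np.int32,
    )
    return mapped[inverse]


def stream_to_frame(stream: ObservationStream) -> pd.DataFrame:
    """Flatten a stream's indexed observations to one row per measurement."""
    parts = []
    for im in stream.images:
        if not im.indexed:
            continue
        n = len(im.observations)
        parts.append(
            pd.DataFrame(
                {
                    "image": np.full(n, im.index, dtype=np.int64),
                    "h": im.observations.hkl[:, 0],
                    "k": im.observations.hkl[:, 1],
                    "l": im.observations.hkl[:, 2],
                    "i_obs": im.observations.i_obs,
                    "sigma_obs": im.observations.sigma_obs,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["image", "h", "k", "l", "i_obs", "sigma_obs"]
        ).astype({"image": np.int64, "h": np.int32, "k": np.int32, "l": np.int32})
    return pd.concat(parts, ignore_index=True)


def _corrected_frame(stream: ObservationStream) -> pd.DataFrame:
    """Observation frame with ASU-mapped indices and Lorentz-corrected I."""
    df = stream_to_frame(stream)
    if df.empty:
        raise ValueError("stream has no indexed observations")
    hkl = _to_asu(df[["h", "k", "l"]].to_numpy(np.int32), stream.meta.laue)
    df[["h", "k", "l"]] = hkl
    cell = stream.meta.cell
    s = cell.s_of_hkl(hkl)
    lf = lorentz_factor(s, stream.meta.beam.wavelength)
    df["s"] = s
    df["i_corr"] = df["i_obs"] / lf
    df["sigma_corr"] = df["sigma_obs"] / lf
    return df


@dataclass
class ScaleResult:
    """Per-image linear scale factors with a degenerate-image flag count."""

    scales: pd.Series  # indexed by image index, geometric mean 1
    n_flagged: int


def estimate_image_scales(
    stream: ObservationStream, n_iterations: int = 3
) -> ScaleResult:
    """Iterative per-image linear scaling against a merged reference.

    Pass 0 merges the unscaled (Lorentz-corrected) observations into a
    reference R.  Each iteration fits, per image j, the least-squares factor
    g_j = Σ_h I_jh·R_h / Σ_h R_h² (the brightness of the image relative to
    the reference), clamps it to ``SCALE_CLAMP``, renormalises to geometric
    mean 1, and re-merges with I/g as the next reference.  Deterministic.
    Images with no usable overlap with the reference keep g = 1 and are
    counted in ``n_flagged``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    df = _corrected_frame(stream)
    key = df.groupby(["h", "k", "l"], sort=False).ngroup()
    img = df["image"].to_numpy()
    i_corr = df["i_corr"].to_numpy()
    images = np.unique(img)
    g = pd.Series(1.0, index=images)
    n_flagged = 0
    for _ in range(n_iterations):
        scaled = i_corr / g.loc[img].to_numpy()
        ref = pd.Series(scaled).groupby(key.to_numpy()).mean()
        r = ref.loc[key.to_numpy()].to_numpy()
        num = pd.Series(i_corr * r).groupby(img).sum()
        den = pd.Series(r * r).groupby(img).sum()
        usable = den > 0
        n_flagged = int((~usable).sum())
        new_g = pd.Series(1.0, index=images)
        new_g[usable[usable].index] = (num[usable] / den[usable]).clip(*SCALE_CLAMP)
        log_mean = np.log(new_g.to_numpy()).mean()
        g = new_g / np.exp(log_mean)
    return ScaleResult(scales=g, n_flagged=n_flagged)


@dataclass
class MergedSet:
    """Symmetry-unique merged reflections.

    ``table`` columns: h, k, l, d, s, i_merged, sigma (NaN when multiplicity
    < 2), m, i_even, i_odd (NaN when the half is empty), n_even, n_odd.
    """

    table: pd.DataFrame
    cell: UnitCell
    laue: str
    d_min: float
    wavelength: float

    def __len__(self) -> int:
        return len(self.table)


def monte_carlo_merge(
    stream: ObservationStream, scales: ScaleResult | pd.Series | None = None
) -> MergedSet:
    """Merge a stream by Monte Carlo averaging.

    Each observation is Lorentz-corrected and divided by its image's scale
    factor; corrected observations of the same Laue-unique reflection are
    averaged.  The merged sigma is the sample standard deviation over the
    multiplicity divided by sqrt(m) (NaN when m < 2).  Half-set means are
    assigned by image-index parity (even/odd acquisition index).
    """
    df = _corrected_frame(stream)
    if scales is None:
        g = pd.Series(1.0, index=np.unique(df["image"].to_numpy()))
    elif isinstance(scales, ScaleResult):
        g = scales.scales
    else:
        g = scales
    df["i_scaled"] = df["i_corr"].to_numpy() / g.loc[df["image"].to_numpy()].to_numpy()
    df["even"] = df["image"].to_numpy() % 2 == 0

    grp = df.groupby(["h", "k", "l"], sort=True)
    agg = grp["i_scaled"].agg(["mean", "std", "count"])
    agg.columns = ["i_merged", "_std", "m"]
    even = df[df["even"]].groupby(["h", "k", "l"], sort=True)["i_scaled"].agg(
        ["mean", "count"]
    )
    odd = df[~df["even"]].groupby(["h", "k", "l"], sort=True)["i_scaled"].agg(
        ["mean", "count"]
    )
    agg["i_even"] = even["mean"]
    agg["n_even"] = even["count"].reindex(agg.index).fillna(0).astype(int)
    agg["i_odd"] = odd["mean"]
    agg["n_odd"] = odd["count"].reindex(agg.index).fillna(0).astype(int)
    agg["sigma"] = agg["_std"] / np.sqrt(agg["m"])
    agg = agg.drop(columns="_std").reset_index()
    cell = stream.meta.cell
    hkl = agg[["h", "k", "l"]].to_numpy(np.int32)
    agg["s"] = cell.s_of_hkl(hkl)
    agg["d"] = 1.0 / np.sqrt(agg["s"])
    cols = [
        "h", "k", "l", "d", "s", "i_merged", "sigma", "m",
        "i_even", "i_odd", "n_even", "n_odd",
    ]
    return MergedSet(
        table=agg[cols].sort_values("s", ignore_index=True),
        cell=cell,
        laue=stream.meta.laue,
        d_min=stream.meta.d_min,
        wavelength=stream.meta.beam.wavelength,
    )


def _half_pairs(table: pd.DataFrame) -> pd.DataFrame:
    return table[(table["n_even"] > 0) & (table["n_odd"] > 0)]


def rsplit(merged: MergedSet | pd.DataFrame) -> float:
    """Half-set discrepancy Rsplit in percent.

    Rsplit = 100 · 2^{-1/2} · Σ|I_even − I_odd| / (½·Σ(I_even + I_odd)), over
    reflections measured in both halves.
    """
    table = merged.table if isinstance(merged, MergedSet) else merged
    pairs = _half_pairs(table)
    if pairs.empty:
        raise ValueError("no reflections with both half-set estimates")
    num = np.abs(pairs["i_even"] - pairs["i_odd"]).sum()
    den = 0.5 * (pairs["i_even"] + pairs["i_odd"]).sum()
    return float(100.0 / np.sqrt(2.0) * num / den)


def cc_half(merged: MergedSet | pd.DataFrame) -> float:
    """Half-set Pearson correlation CC1/2.

    NaN (flagged undefined, not an error) with fewer than 3 half-pairs or
    zero variance in either half.
    """
    table = merged.table if isinstance(merged, MergedSet) else merged
    pairs = _half_pairs(table)
    if len(pairs) < 3:
        return float("nan")
    x = pairs["i_even"].to_numpy()
    y = pairs["i_odd"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def shell_statistics(
    merged: MergedSet,
    possible_s: np.ndarray | pd.DataFrame,
    n_shells: int = 20,
) -> pd.DataFrame:
    """Per-resolution-shell quality statistics.

    Shells are equal-count partitions of the *possible* unique reflections
    (``possible_s``: their 1/d² values, e.g. the ``s`` column of
    :func:`ssrox.simulate.enumerate_unique_hkl`).  Returned columns: shell,
    s_low, s_high, s_mid, d_high, n_possible, n_unique, completeness,
    multiplicity, i_over_sigma, cc_half, rsplit.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    if isinstance(possible_s, pd.DataFrame):
        possible_s = possible_s["s"].to_numpy()
    possible_s = np.sort(np.asarray(possible_s, dtype=float))
    n_pos = len(possible_s)
    if n_pos == 0:
        raise ValueError("empty possible-reflection set")
    # internal edges at equal-count quantile positions of the possible set
    cuts = [possible_s[round(j * n_pos / n_shells) - 1] for j in range(1, n_shells)]
    edges = np.array([0.0] + cuts + [possible_s[-1]])
    table = merged.table
    shell_of = np.clip(np.searchsorted(edges[1:-1], table["s"].to_numpy(), "left"), 0, n_shells - 1)
    pos_shell = np.clip(np.searchsorted(edges[1:-1], possible_s, "left"), 0, n_shells - 1)
    rows = []
    for j in range(n_shells):
        sub = table[shell_of == j]
        n_possible = int((pos_shell == j).sum())
        n_unique = len(sub)
        with_sigma = sub[sub["sigma"].notna() & (sub["sigma"] > 0)]
        i_over_sig = (
            float((with_sigma["i_merged"] / with_sigma["sigma"]).mean())
            if len(with_sigma)
            else float("nan")
        )
        try:
            rs = rsplit(sub)
        except ValueError:
            rs = float("nan")
        rows.append(
            {
                "shell": j + 1,
                "s_low": edges[j],
                "s_high": edges[j + 1],
                "s_mid": 0.5 * (edges[j] + edges[j + 1]),
                "d_high": 1.0 / np.sqrt(edges[j + 1]),
                "n_possible": n_possible,
                "n_unique": n_unique,
                "completeness": 100.0 * n_unique / n_possible if n_possible else float("nan"),
                "multiplicity": float(sub["m"].mean()) if n_unique else float("nan"),
                "i_over_sigma": i_over_sig,
                "cc_half": cc_half(sub),
                "rsplit": rs,
            }
        )
    return pd.DataFrame(rows)
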