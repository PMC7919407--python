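"""Dose, photon and hit/index-rate accounting.

All quantities follow plain rate × time bookkeeping: each detector frame
exposes the crystal for ``1/frame_rate`` seconds, so

* photons per image = flux × transmission / frame_rate
* dose per image    = dose_rate / frame_rate

Doses are carried in MGy/s (rates) and reported per image in kGy, the unit in
which acquisition conditions are usually labelled.  A condition may also carry
a *nominal* dose label that differs from the computed product because of
rounding in the quoted dose rate; both are reported, never silently merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd


@dataclass(frozen=True)
class BeamCondition:
    """Beam and detector settings defining one acquisition condition.

    Parameters
    ----------
    flux : float
        Unattenuated photon flux in photons/s.
    transmission : float
        Filter transmission as a fraction in (0, 1].
    frame_rate : float
        Detector frame rate in Hz; exposure time per image is its inverse.
    dose_rate : float
        Absorbed dose rate in MGy/s at this transmission.
    nominal_dose_kgy : float
        The label under which the condition is known (kGy per image).
    wavelength : float
        X-ray wavelength in Å (used by the Lorentz factor).
    """

    flux: float
    transmission: float
    frame_rate: float
    dose_rate: float
    nominal_dose_kgy: float = 0.0
    wavelength: float = 1.0

    def __post_init__(self) -> None:
        if self.flux <= 0 or self.frame_rate <= 0:
            raise ValueError("flux and frame_rate must be positive")
        if not 0 < self.transmission <= 1:
            raise ValueError("transmission must be in (0, 1]")
        if self.dose_rate < 0:
            raise ValueError("dose_rate must be >= 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


@dataclass(frozen=True)
class DatasetCounts:
    """Image bookkeeping for one data set."""

    name: str
    n_images: int
    n_hits: int
    n_indexed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_indexed <= self.n_hits <= self.n_images:
            raise ValueError("counts must satisfy 0 <= indexed <= hits <= images")


def photons_per_image(beam: BeamCondition) -> float:
    """Photons delivered during one detector frame."""
    return beam.flux * beam.transmission / beam.frame_rate


def dose_per_image(beam: BeamCondition) -> float:
    """Absorbed dose per detector frame, in kGy."""
    return beam.dose_rate / beam.frame_rate * 1000.0


def total_photons(n_merged_images: int, photons_per_img: float) -> float:
    """Total photon budget of a merged data set."""
    if n_merged_images < 0:
        raise ValueError("image count must be >= 0")
    return n_merged_images * photons_per_img


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (as in printed percentage tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rate_summary(counts: list[DatasetCounts]) -> pd.DataFrame:
    """Per-set and overall hit and index rates.

    Returns a data frame with one row per data set plus an ``overall`` row
    computed from summed numerators and denominators.  Display columns
    (``hit_rate_pct``, ``index_rate_pct``) are rounded half-up to one decimal;
    full-precision values are kept in ``hit_rate`` / ``index_rate``.  The index
    rate is the fraction of *hit* images that indexed; it is NaN (flagged, not
    an error) when a set has no hits.
    """
    rows = []
    for c in counts:
        hit = 100.0 * c.n_hits / c.n_images if c.n_images else float("nan")
        idx = 100.0 * c.n_indexed / c.n_hits if c.n_hits else float("nan")
        rows.append((c.name, c.n_images, c.n_hits, c.n_indexed, hit, idx))
    n_img = sum(c.n_images for c in counts)
    n_hit = sum(c.n_hits for c in counts)
    n_idx = sum(c.n_indexed for c in counts)
    hit = 100.0 * n_hit / n_img if n_img else float("nan")
    idx = 100.0 * n_idx / n_hit if n_hit else float("nan")
    rows.append(("overall", n_img, n_hit, n_idx, hit, idx))
    df = pd.DataFrame(
        rows,
        columns=["dataset", "n_images", "n_hits", "n_indexed", "hit_rate", "index_rate"],
    )
    df["hit_rate_pct"] = [
        round_half_up(v) if pd.notna(v) else v for v in df["hit_rate"]
    ]
    df["index_rate_pct"] = [
        round_half_up(v) if pd.notna(v) else v for v in df["index_rate"]
    ]
    return df


def load_hit_index_table() -> pd.DataFrame:
    """Packaged acquisition table: 14 lysozyme SS-ROX data sets.

    Columns: dataset, dose_kgy, dose_rate_mgy_s, transmission_pct,
    frame_rate_hz, n_images, n_hits, n_indexed.
    """
    with resources.files("ssrox.data").joinpath("hit_index_counts.csv").open() as fh:
        return pd.read_csv(fh)


def counts_from_table(df: pd.DataFrame) -> list[DatasetCounts]:
    """Convert a counts table (as from :func:`load_hit_index_table`) to records."""
    return [
        DatasetCounts(str(r.dataset), int(r.n_images), int(r.n_hits), int(r.n_indexed))
        for r in df.itertuples()
    ]


#: Beam conditions of the seven dose points of the lysozyme study
#: (flux 4.8e12 ph/s without attenuation; dose adjusted via filter
#: transmission and detector frame rate).
DOSE_CONDITIONS: dict[float, BeamCondition] = {
    21.0: BeamCondition(4.8e12, 0.0949, 100.0, 2.1, 21.0),
    42.0: BeamCondition(4.8e12, 0.194, 100.0, 4.2, 42.0),
    83.0: BeamCondition(4.8e12, 0.401, 100.0, 8.3, 83.0),
    210.0: BeamCondition(4.8e12, 0.942, 100.0, 21.0, 210.0),
    420.0: BeamCondition(4.8e12, 1.0, 54.0, 23.0, 420.0),
    830.0: BeamCondition(4.8e12, 1.0, 27.0, 23.0, 830.0),
    1700.0: BeamCondition(4.8e12, 1.0, 13.0, 23.0, 1700.0),
}
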