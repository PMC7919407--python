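"""Text formats for streams, merged tables, shell tables and configs.

All formats are plain text with '.' decimals, tab separation inside stream
blocks, Å and degree units, and 0-based image indices.  Floats are written
with 17 significant digits so that read(write(x)) round-trips bit-exactly.

Stream file layout::

    # ssrox stream 1
    key = value            (header; unknown keys are preserved on rewrite)
    <blank line>
    index scan angle a b c alpha beta gamma n_lattices hit indexed   (tab-sep)
    h k l i_obs sigma_obs                                            (tab-sep)
    ...
    <blank line>           (terminates every image block, including the last)
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .cell import UnitCell
from .dose import BeamCondition
from .merge import MergedSet
from .simulate import (
    DamageModel,
    DriftModel,
    HitModel,
    ImageRecord,
    NoiseModel,
    Observations,
    ObservationStream,
    ParamDrift,
    ScanGeometry,
    SimulationConfig,
    StreamMeta,
)

MAGIC = "# ssrox stream 1"


class StreamParseError(ValueError):
    """Malformed stream file; the message names the offending line."""


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_stream(stream: ObservationStream, path: str | Path) -> None:
    """Serialise a stream (header + one block per image, in order)."""
    m = stream.meta
    lines = [MAGIC]
    lines.append(f"name = {m.name}")
    lines.append(f"laue = {m.laue}")
    lines.append(f"d_min = {_fmt(m.d_min)}")
    lines.append("cell = " + " ".join(_fmt(v) for v in m.cell.as_tuple()))
    g = m.geometry
    lines.append(
        "geometry = "
        + " ".join(
            [str(g.n_scans), str(g.images_per_scan)]
            + [_fmt(v) for v in (g.rotation_step, g.translation_step, g.scan_interval)]
        )
    )
    b = m.beam
    lines.append(
        "beam = "
        + " ".join(
            _fmt(v)
            for v in (
                b.flux,
                b.transmission,
                b.frame_rate,
                b.dose_rate,
                b.nominal_dose_kgy,
                b.wavelength,
            )
        )
    )
    lines.append(f"seed = {m.seed}")
    for key, value in m.extra:
        lines.append(f"{key} = {value}")
    lines.append("")
    for im in stream.images:
        c = im.cell
        lines.append(
            "\t".join(
                [str(im.index), str(im.scan), _fmt(im.angle)]
                + [_fmt(v) for v in c.as_tuple()]
                + [str(im.n_lattices), str(int(im.hit)), str(int(im.indexed))]
            )
        )
        for j in range(len(im.observations)):
            hkl = im.observations.hkl[j]
            lines.append(
                "\t".join(
                    [str(int(hkl[0])), str(int(hkl[1])), str(int(hkl[2]))]
                    + [
                        _fmt(im.observations.i_obs[j]),
                        _fmt(im.observations.sigma_obs[j]),
                    ]
                )
            )
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


_KNOWN_HEADER = {"name", "laue", "d_min", "cell", "geometry", "beam", "seed"}


def _parse_int(tok: str, lineno: int, what: str) -> int:
    try:
        return int(tok)
    except ValueError:
        raise StreamParseError(f"line {lineno}: non-integer {what}: {tok!r}") from None


def _parse_float(tok: str, lineno: int, what: str) -> float:
    try:
        return float(tok)
    except ValueError:
        raise StreamParseError(f"line {lineno}: bad {what}: {tok!r}") from None


def read_stream(path: str | Path) -> ObservationStream:
    """Parse a stream file back into records; inverse of write_stream."""
    text = Path(path).read_text()
    lines = text.split("\n")
    if not lines or lines[0].strip() != MAGIC:
        raise StreamParseError("line 1: missing stream magic line")
    header: dict[str, str] = {}
    extra: list[tuple[str, str]] = []
    i = 1
    while i < len(lines) and lines[i].strip() != "":
        line = lines[i]
        if "=" not in line:
            raise StreamParseError(f"line {i + 1}: malformed header line {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _KNOWN_HEADER:
            header[key] = value
        else:
            extra.append((key, value))
        i += 1
    try:
        cell_vals = [float(t) for t in header["cell"].split()]
        gtok = header["geometry"].split()
        btok = header["beam"].split()
        meta = StreamMeta(
            cell=UnitCell(*cell_vals),
            laue=header["laue"],
            d_min=float(header["d_min"]),
            geometry=ScanGeometry(
                int(gtok[0]), int(gtok[1]), float(gtok[2]), float(gtok[3]), float(gtok[4])
            ),
            beam=BeamCondition(*[float(t) for t in btok]),
            seed=int(header["seed"]),
            name=header.get("name", "stream"),
            extra=tuple(extra),
        )
    except (KeyError, IndexError, ValueError) as exc:
        raise StreamParseError(f"bad or incomplete stream header: {exc}") from None
    i += 1  # skip the blank line ending the header

    images: list[ImageRecord] = []
    while i < len(lines):
        if lines[i].strip() == "":
            i += 1
            continue
        lineno = i + 1
        tok = lines[i].split("\t")
        if len(tok) != 12:
            raise StreamParseError(
                f"line {lineno}: image line must have 12 fields, got {len(tok)}"
            )
        idx = _parse_int(tok[0], lineno, "image index")
        scan = _parse_int(tok[1], lineno, "scan index")
        angle = _parse_float(tok[2], lineno, "angle")
        cell = UnitCell(*[_parse_float(t, lineno, "cell parameter") for t in tok[3:9]])
        n_lat = _parse_int(tok[9], lineno, "lattice count")
        hit = bool(_parse_int(tok[10], lineno, "hit flag"))
        indexed = bool(_parse_int(tok[11], lineno, "indexed flag"))
        i += 1
        hkl, iobs, sobs = [], [], []
        terminated = False
        while i < len(lines):
            if lines[i].strip() == "":
                terminated = True
                i += 1
                break
            lineno = i + 1
            otok = lines[i].split("\t")
            if len(otok) == 12:
                break  # next image line: previous block missing terminator
            if len(otok) != 5:
                raise StreamParseError(
                    f"line {lineno}: observation line must have 5 fields, got {len(otok)}"
                )
            hkl.append(
                [_parse_int(otok[j], lineno, "Miller index") for j in range(3)]
            )
            iobs.append(_parse_float(otok[3], lineno, "intensity"))
            sobs.append(_parse_float(otok[4], lineno, "sigma"))
            i += 1
        if not terminated:
            raise StreamParseError(
                f"truncated stream: image block starting before line {lineno} "
                "has no blank-line terminator"
            )
        obs = (
            Observations(np.array(hkl, np.int32), iobs, sobs)
            if hkl
            else Observations.empty()
        )
        try:
            images.append(
                ImageRecord(idx, scan, angle, cell, n_lat, hit, indexed, obs)
            )
        except ValueError as exc:
            raise StreamParseError(f"image {idx}: {exc}") from None
    return ObservationStream(images, meta)


# ---------------------------------------------------------------------------
# merged reflection table (whitespace-separated, CrystFEL-hkl-like)

MERGED_COLUMNS = [
    "h", "k", "l", "i_merged", "sigma", "m", "i_even", "i_odd", "n_even", "n_odd",
]


def write_merged(merged: MergedSet, path: str | Path) -> None:
    """Whitespace table of merged reflections with a metadata header."""
    lines = [
        "# ssrox merged reflections",
        "# cell = " + " ".join(_fmt(v) for v in merged.cell.as_tuple()),
        f"# laue = {merged.laue}",
        f"# d_min = {_fmt(merged.d_min)}",
        f"# wavelength = {_fmt(merged.wavelength)}",
        "# " + " ".join(MERGED_COLUMNS),
    ]
    t = merged.table
    for row in t.itertuples(index=False):
        lines.append(
            " ".join(
                [
                    str(int(row.h)), str(int(row.k)), str(int(row.l)),
                    _fmt(row.i_merged),
                    _fmt(row.sigma) if pd.notna(row.sigma) else "nan",
                    str(int(row.m)),
                    _fmt(row.i_even) if pd.notna(row.i_even) else "nan",
                    _fmt(row.i_odd) if pd.notna(row.i_odd) else "nan",
                    str(int(row.n_even)), str(int(row.n_odd)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_merged(path: str | Path) -> MergedSet:
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                header[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    try:
        cell = UnitCell(*[float(t) for t in header["cell"].split()])
        laue = header["laue"]
        d_min = float(header["d_min"])
        wavelength = float(header["wavelength"])
    except (KeyError, ValueError) as exc:
        raise StreamParseError(f"bad merged-table header: {exc}") from None
    rows = [line.split() for line in lines[body_start:] if line.strip()]
    df = pd.DataFrame(rows, columns=MERGED_COLUMNS)
    for col in ("h", "k", "l", "m", "n_even", "n_odd"):
        df[col] = df[col].astype(int)
    for col in ("i_merged", "sigma", "i_even", "i_odd"):
        df[col] = df[col].astype(float)
    hkl = df[["h", "k", "l"]].to_numpy(np.int32)
    df["s"] = cell.s_of_hkl(hkl)
    df["d"] = 1.0 / np.sqrt(df["s"])
    cols = [
        "h", "k", "l", "d", "s", "i_merged", "sigma", "m",
        "i_even", "i_odd", "n_even", "n_odd",
    ]
    return MergedSet(df[cols], cell, laue, d_min, wavelength)


def write_shells(shells: pd.DataFrame, path: str | Path) -> None:
    shells.to_csv(path, index=False)


def read_shells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# flat key = value simulator configuration

def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as flat ``section.field = value`` lines."""
    lines = ["# ssrox simulation config"]
    c = config.cell
    for name in ("a", "b", "c", "alpha", "beta", "gamma"):
        lines.append(f"cell.{name} = {_fmt(getattr(c, name))}")
    for name in ("d_min", "b_true", "sigma0"):
        lines.append(f"{name} = {_fmt(getattr(config, name))}")
    lines.append(f"laue = {config.laue}")
    for obj, section in (
        (config.geometry, "geometry"),
        (config.beam, "beam"),
        (config.hits, "hits"),
        (config.damage, "damage"),
        (config.noise, "noise"),
    ):
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            lines.append(
                f"{section}.{f.name} = {_fmt(v) if isinstance(v, float) else v}"
            )
    for pname in ("a", "b", "c", "alpha", "beta", "gamma"):
        p: ParamDrift = getattr(config.drift, pname)
        for f in ("start", "end", "knot", "jitter"):
            lines.append(f"drift.{pname}.{f} = {_fmt(getattr(p, f))}")
    lines.append(f"drift.tetragonal = {int(config.drift.tetragonal)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> SimulationConfig:
    """Read a flat key = value config; missing keys keep their defaults."""
    kv: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise StreamParseError(f"line {lineno}: expected key = value, got {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()

    def grab(prefix: str, cls, cast=float):
        fields = {}
        for f in dataclasses.fields(cls):
            key = f"{prefix}.{f.name}"
            if key in kv:
                fields[f.name] = (
                    int(kv[key]) if f.type in ("int", int) else cast(kv[key])
                )
        return fields

    default = SimulationConfig()
    cell_kw = {
        name: float(kv[f"cell.{name}"])
        for name in ("a", "b", "c", "alpha", "beta", "gamma")
        if f"cell.{name}" in kv
    }
    cell = (
        dataclasses.replace(default.cell, **cell_kw) if cell_kw else default.cell
    )
    drifts = {}
    for pname in ("a", "b", "c", "alpha", "beta", "gamma"):
        base: ParamDrift = getattr(default.drift, pname)
        pf = {
            f: float(kv[f"drift.{pname}.{f}"])
            for f in ("start", "end", "knot", "jitter")
            if f"drift.{pname}.{f}" in kv
        }
        drifts[pname] = dataclasses.replace(base, **pf) if pf else base
    drift = DriftModel(
        **drifts,
        tetragonal=bool(int(kv.get("drift.tetragonal", int(default.drift.tetragonal)))),
    )
    return SimulationConfig(
        cell=cell,
        d_min=float(kv.get("d_min", default.d_min)),
        b_true=float(kv.get("b_true", default.b_true)),
        sigma0=float(kv.get("sigma0", default.sigma0)),
        laue=kv.get("laue", default.laue),
        geometry=dataclasses.replace(default.geometry, **grab("geometry", ScanGeometry)),
        beam=dataclasses.replace(default.beam, **grab("beam", BeamCondition)),
        hits=dataclasses.replace(default.hits, **grab("hits", HitModel)),
        drift=drift,
        damage=dataclasses.replace(default.damage, **grab("damage", DamageModel)),
        noise=dataclasses.replace(default.noise, **grab("noise", NoiseModel)),
    )
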