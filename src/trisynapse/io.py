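"""Localisation-table IO: the CSV dialect shared by every pipeline stage.

A localisation table holds one row per detected blink event with 3D
coordinates in nanometres, the channel (protein) label, the acquisition
frame, photon statistics and the estimated localisation precision.  The
on-disk form is a plain UTF-8 CSV with ``.`` decimal separator and the fixed
header::

    id,channel,frame,x_nm,y_nm,z_nm,photons,bg,sigma_xy_nm,sigma_z_nm[,cluster_id]

preceded by optional ``# key=<json>`` metadata lines.  nm-valued fields are
written with 6 decimal places and ``\\n`` line endings so that
``write_localizations(read_localizations(f))`` is byte-identical on
canonical files.  Unknown extra columns are carried through untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: cluster label for points DBSCAN classified as noise
NOISE = -1

MANDATORY_COLUMNS = [
    "id",
    "channel",
    "frame",
    "x_nm",
    "y_nm",
    "z_nm",
    "photons",
    "bg",
    "sigma_xy_nm",
    "sigma_z_nm",
]
#: optional trailing column; absent means cluster assignment is unset
OPTIONAL_COLUMNS = ["cluster_id"]

_FLOAT_COLUMNS = ["x_nm", "y_nm", "z_nm", "photons", "bg", "sigma_xy_nm", "sigma_z_nm"]
_INT_COLUMNS = ["id", "frame"]

ROLE_PRE = "presynaptic"
ROLE_POST = "postsynaptic"
ROLE_PERI = "perisynaptic"


class FormatError(ValueError):
    """The file does not conform to the localisation-table dialect."""


class ParseError(ValueError):
    """A value inside an otherwise well-formed table could not be parsed."""


@dataclass
class ChannelSet:
    """Ordered channel labels with synaptic roles.

    Exactly one channel must be presynaptic and one postsynaptic; any number
    (including zero) may be perisynaptic (e.g. the astrocytic GLT-1 channel).
    """

    names: list[str]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        for ch, role in self.roles.items():
            if ch not in self.names:
                raise ValueError(f"role assigned to unknown channel {ch!r}")
            if role not in (ROLE_PRE, ROLE_POST, ROLE_PERI):
                raise ValueError(f"unknown role {role!r} for channel {ch!r}")
        if len(self.by_role(ROLE_PRE)) != 1 or len(self.by_role(ROLE_POST)) != 1:
            raise ValueError(
                "a ChannelSet needs exactly one presynaptic and one postsynaptic channel"
            )

    def by_role(self, role: str) -> list[str]:
        return [ch for ch in self.names if self.roles.get(ch) == role]

    @property
    def presynaptic(self) -> str:
        return self.by_role(ROLE_PRE)[0]

    @property
    def postsynaptic(self) -> str:
        return self.by_role(ROLE_POST)[0]

    @property
    def perisynaptic(self) -> list[str]:
        return self.by_role(ROLE_PERI)


@dataclass
class LocalizationTable:
    """In-memory localisation table: a DataFrame plus acquisition metadata.

    ``df`` carries the dialect columns (see module docstring); ``meta`` holds
    at least ``channels`` (ordered labels) and optionally ``pixel_size_nm``,
    ``axial_range_nm`` and ``source``.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "channels" not in self.meta:
            seen = list(dict.fromkeys(self.df["channel"])) if len(self.df) else []
            self.meta["channels"] = seen

    def __len__(self) -> int:
        return len(self.df)

    @property
    def channels(self) -> list[str]:
        return list(self.meta["channels"])

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of x, y, z in nm."""
        return self.df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)

    def validate(self) -> None:
        ids = self.df["id"].to_numpy()
        if len(ids) and not np.array_equal(ids, np.arange(len(ids))):
            raise FormatError("ids must be dense 0..n-1 in row order")
        coords = self.coords
        if coords.size and not np.all(np.isfinite(coords)):
            raise FormatError("coordinates must be finite")
        unknown = set(self.df["channel"]) - set(self.meta["channels"])
        if unknown:
            raise FormatError(f"channel labels {sorted(unknown)} missing from meta.channels")

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.df.copy(), dict(self.meta))

    def with_cluster_labels(self, labels: Iterable[int]) -> "LocalizationTable":
        labels = np.asarray(list(labels), dtype=int)
        if len(labels) != len(self.df):
            raise ValueError("labels length must match table length")
        df = self.df.copy()
        df["cluster_id"] = labels
        return LocalizationTable(df, dict(self.meta))


def make_table(
    channel: np.ndarray,
    frame: np.ndarray,
    xyz: np.ndarray,
    photons: np.ndarray,
    bg: np.ndarray,
    sigma_xy: np.ndarray,
    sigma_z: np.ndarray,
    meta: Mapping | None = None,
    extra: Mapping[str, np.ndarray] | None = None,
) -> LocalizationTable:
    """Assemble a :class:`LocalizationTable` from aligned arrays (ids auto-assigned)."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    n = xyz.shape[0] if xyz.size else 0
    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "channel": np.asarray(channel, dtype=object) if n else np.array([], dtype=object),
            "frame": np.asarray(frame, dtype=int) if n else np.array([], dtype=int),
            "x_nm": xyz[:, 0] if n else np.array([], dtype=float),
            "y_nm": xyz[:, 1] if n else np.array([], dtype=float),
            "z_nm": xyz[:, 2] if n else np.array([], dtype=float),
            "photons": np.broadcast_to(np.asarray(photons, dtype=float), (n,)).copy(),
            "bg": np.broadcast_to(np.asarray(bg, dtype=float), (n,)).copy(),
            "sigma_xy_nm": np.broadcast_to(np.asarray(sigma_xy, dtype=float), (n,)).copy(),
            "sigma_z_nm": np.broadcast_to(np.asarray(sigma_z, dtype=float), (n,)).copy(),
        }
    )
    if extra:
        for k, v in extra.items():
            df[k] = v
    return LocalizationTable(df, dict(meta) if meta else {})


def _parse_meta_lines(lines: list[str]) -> dict:
    meta: dict = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            try:
                meta[key.strip()] = json.loads(val)
            except json.JSONDecodeError:
                meta[key.strip()] = val.strip()
    return meta


def read_localizations(path, meta_override: Mapping | None = None) -> LocalizationTable:
    """Read a localisation CSV in the package dialect.

    Leading ``#`` lines are parsed as metadata; ids are (re)assigned densely
    in file order; values stay in nm exactly as stored.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    lines = text.splitlines()
    meta_lines = []
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        meta_lines.append(lines[i])
        i += 1
    if i >= len(lines) or not lines[i].strip():
        raise FormatError(f"{path}: no header row found")
    header = [c.strip() for c in lines[i].split(",")]
    for col in MANDATORY_COLUMNS:
        if col not in header:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[i:])), dtype={"channel": str})
    for col in _FLOAT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}, data row {row}"
            )
        df[col] = coerced.astype(float)
    for col in _INT_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    df["id"] = np.arange(len(df), dtype=int)

    meta = _parse_meta_lines(meta_lines)
    if meta_override:
        meta.update(meta_override)
    table = LocalizationTable(df, meta)
    table.validate()
    return table


def write_localizations(table: LocalizationTable, path) -> None:
    """Write the canonical on-disk form (sorted meta lines, fixed column order,
    6-decimal nm fields, ``\\n`` newlines)."""
    table.validate()
    df = table.df
    cols = list(MANDATORY_COLUMNS)
    if "cluster_id" in df.columns:
        cols.append("cluster_id")
    cols += [c for c in df.columns if c not in cols]

    def fmt(col: str, v) -> str:
        if col in _FLOAT_COLUMNS:
            return f"{v:.6f}"
        if col in _INT_COLUMNS or col == "cluster_id":
            return str(int(v))
        if isinstance(v, float):
            return f"{v:.6f}"
        return str(v)

    out = []
    for key in sorted(table.meta):
        out.append(f"# {key}={json.dumps(table.meta[key])}")
    out.append(",".join(cols))
    for _, row in df.iterrows():
        out.append(",".join(fmt(c, row[c]) for c in cols))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(out) + "\n")


def filter_by_channel(table: LocalizationTable, channel: str) -> LocalizationTable:
    """Subset to one channel; original ids are kept in a ``source_id`` column."""
    if channel not in table.meta["channels"]:
        raise ValueError(
            f"unknown channel {channel!r}; valid channels: {list(table.meta['channels'])}"
        )
    sub = table.df[table.df["channel"] == channel].copy()
    sub["source_id"] = sub["id"].to_numpy()
    sub["id"] = np.arange(len(sub), dtype=int)
    sub.reset_index(drop=True, inplace=True)
    return LocalizationTable(sub, dict(table.meta))
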