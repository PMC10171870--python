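"""Readers and writers: event CSV, FCS 3.x, multi-page TIFF with sidecar.

CSV is the canonical event format (header mandatory, intensities written
with 6 significant digits).  FCS support is read-only list-mode (datatypes
F, D and I) for cytometry interchange; a minimal writer exists solely to
build test fixtures.  Images are multi-page TIFF, one page per channel,
with pixel size and channel names in a JSON sidecar next to the file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .simulate import ImageField
from .tables import RESERVED_COLUMNS, ordered_columns

__all__ = [
    "ChannelMap",
    "read_events",
    "write_events",
    "read_fcs",
    "write_fcs",
    "read_image",
    "write_image",
]

log = logging.getLogger("stochmix")

CHANNEL_ROLES = ("drug_tag", "auxiliary", "phenotype", "carrier_tag", "brightfield")


class ChannelMap:
    """Channel name -> role assignment.

    Roles: ``drug_tag`` (with a drug id), ``auxiliary`` (volume-proxy dye,
    at most one), ``phenotype``, ``carrier_tag`` (with a carrier id),
    ``brightfield``.
    """

    def __init__(self, roles: Mapping[str, str], drug_ids: Mapping[str, str] | None = None):
        self.roles = dict(roles)
        self.drug_ids = dict(drug_ids or {})
        for ch, role in self.roles.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown role {role!r} for channel {ch!r}")
        aux = [ch for ch, r in self.roles.items() if r == "auxiliary"]
        if len(aux) > 1:
            raise ValueError("at most one auxiliary channel is allowed")
        ids = [self.drug_ids[c] for c in self.drug_ids]
        if len(ids) != len(set(ids)):
            raise ValueError("drug ids must be unique")

    @property
    def auxiliary(self) -> str | None:
        for ch, r in self.roles.items():
            if r == "auxiliary":
                return ch
        return None

    def with_role(self, role: str) -> list[str]:
        return [ch for ch, r in self.roles.items() if r == role]

    def validate_against(self, columns: Sequence[str]) -> None:
        missing = [ch for ch in self.roles if ch not in columns]
        if missing:
            raise ValueError(f"mapped channels missing from data: {missing}")


# ---------------------------------------------------------------------------
# events


def write_events(cells: pd.DataFrame, path) -> None:
    """Event CSV: ``cell_id,x_um,y_um,<channels>...,sample,time_h,compartment``.

    Intensities and positions are written as decimals with 6 significant
    digits; the header row is mandatory.
    """
    cols = ordered_columns(cells)
    cells[cols].to_csv(path, index=False, float_format="%.6g")


def read_events(path, channel_map: ChannelMap | None = None) -> pd.DataFrame:
    """Read an event table from CSV (or FCS, by extension).

    Numeric columns are validated row by row; a malformed value raises with
    the offending line number.  With a channel map, mapped channels are
    checked for presence.
    """
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        return read_fcs(path, channel_map)
    df = pd.read_csv(path, header=0)
    if df.columns.str.contains("Unnamed").all():
        raise ValueError(f"{path}: header row missing or malformed")
    for col in df.columns:
        if col in ("sample", "compartment"):
            continue
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # header is line 1
                raise ValueError(
                    f"{path}: malformed numeric value in column {col!r} at line {line}"
                )
            df[col] = coerced
    if channel_map is not None:
        channel_map.validate_against(df.columns)
    log.info("read %d events from %s", len(df), path)
    return df


# ---------------------------------------------------------------------------
# FCS 3.x (minimal list-mode reader; writer exists for fixtures only)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        return {}
    delim = raw[0:1]
    parts = raw[1:].split(delim)
    kv = {}
    for i in range(0, len(parts) - 1, 2):
        key = parts[i].decode("utf-8", "replace").strip().upper()
        if key:
            kv[key] = parts[i + 1].decode("utf-8", "replace").strip()
    return kv


def read_fcs(path, channel_map: ChannelMap | None = None) -> pd.DataFrame:
    """Read a list-mode FCS 3.0/3.1 file into an event table.

    Supports datatypes F (float32), D (float64) and I (unsigned integer of
    8/16/32/64 bits), both byte orders.  Parameter short names ($PnN) become
    column names.
    """
    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    kv = _parse_text_segment(raw[text_start : text_end + 1])
    data_start = int(kv.get("$BEGINDATA") or raw[26:34])
    data_end = int(kv.get("$ENDDATA") or raw[34:42])
    n_par = int(kv["$PAR"])
    n_events = int(kv["$TOT"])
    dtype_code = kv["$DATATYPE"].upper()
    order = kv.get("$BYTEORD", "1,2,3,4")
    little = order.startswith("1")
    endian = "<" if little else ">"
    if kv.get("$MODE", "L").upper() != "L":
        raise ValueError("only list-mode FCS data are supported")
    names = [
        kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)
    ]
    bits = [int(kv.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)]
    payload = raw[data_start : data_end + 1]
    if dtype_code == "F":
        data = np.frombuffer(payload, dtype=f"{endian}f4", count=n_events * n_par)
    elif dtype_code == "D":
        data = np.frombuffer(payload, dtype=f"{endian}f8", count=n_events * n_par)
    elif dtype_code == "I":
        if len(set(bits)) != 1:
            raise ValueError("mixed $PnB integer widths are not supported")
        width = bits[0] // 8
        data = np.frombuffer(
            payload, dtype=f"{endian}u{width}", count=n_events * n_par
        )
    else:
        raise ValueError(f"unsupported $DATATYPE {dtype_code!r}")
    df = pd.DataFrame(
        data.reshape(n_events, n_par).astype(np.float64), columns=names
    )
    if channel_map is not None:
        channel_map.validate_against(df.columns)
    log.info("read %d FCS events (%d parameters) from %s", n_events, n_par, path)
    return df


def write_fcs(df: pd.DataFrame, path) -> None:
    """Write a minimal float32 list-mode FCS 3.1 file (fixture generation)."""
    cols = list(df.columns)
    data = df[cols].to_numpy(dtype="<f4")
    payload = data.tobytes()
    kv = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(len(cols)),
        "$TOT": str(len(df)),
        "$NEXTDATA": "0",
    }
    for i, c in enumerate(cols, start=1):
        kv[f"$P{i}N"] = c
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(data[:, i - 1], initial=1.0)))) + 1)
    # offsets depend on the TEXT length; iterate until self-consistent
    for _ in range(3):
        text = "/" + "/".join(f"{k}/{v}" for k, v in kv.items()) + "/"
        text_start = 58
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(payload) - 1
        kv["$BEGINDATA"] = str(data_start)
        kv["$ENDDATA"] = str(data_end)
    header = (
        f"FCS3.1    "
        f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}"
        f"{0:8d}{0:8d}"
    ).encode("ascii")
    assert len(header) == 58
    Path(path).write_bytes(header + text.encode("ascii") + payload)


# ---------------------------------------------------------------------------
# images


def write_image(field: ImageField, path) -> None:
    """Multi-page TIFF (one page per channel) + JSON sidecar with metadata."""
    path = Path(path)
    tifffile.imwrite(path, field.data, photometric="minisblack")
    sidecar = {
        "pixel_size_um": field.pixel_size,
        "channels": list(field.channels),
        "dtype": str(field.data.dtype),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_image(
    path,
    pixel_size: float | None = None,
    channels: Sequence[str] | None = None,
) -> ImageField:
    """Read a multi-page TIFF; pixel size / channel names come from the
    sidecar JSON unless given explicitly."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size = pixel_size or sidecar.get("pixel_size_um")
        channels = channels or sidecar.get("channels")
    if pixel_size is None:
        raise ValueError(f"{path}: pixel size not in sidecar and not provided")
    channels = list(channels) if channels else [f"ch{i}" for i in range(data.shape[0])]
    if len(channels) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} pages but {len(channels)} channel names"
        )
    return ImageField(data=data, pixel_size=float(pixel_size), channels=channels)
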