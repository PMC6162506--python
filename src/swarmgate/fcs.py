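"""Minimal FCS 3.0/3.1 list-mode reader.

Reads the event matrix of an FCS file: HEADER offsets, the delimited TEXT
segment, and a DATA segment of type F (float32), D (float64) or I
(integer, byte width from $PnB).  Channel names are taken from $PnS when
present, else $PnN.  Compensation/spillover keywords, analysis segments
and FCS 2.0 dialects are out of scope; writing is not supported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError

__all__ = ["read_fcs"]

_SUPPORTED_VERSIONS = ("FCS3.0", "FCS3.1")


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Return ``(values, channel_names)`` for an FCS 3.0/3.1 file."""
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = raw[0:6].decode("ascii", errors="replace")
    if version not in _SUPPORTED_VERSIONS:
        raise FormatError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed HEADER offsets") from exc
    if not (0 < text_start < text_end < len(raw)):
        raise FormatError(f"{path}: TEXT segment offsets out of range")

    keywords = _parse_text_segment(raw[text_start : text_end + 1], path)

    data_start, data_end = _data_offsets(raw, keywords, path)
    n_par = int(_require(keywords, "$PAR", path))
    n_events = int(_require(keywords, "$TOT", path))
    datatype = _require(keywords, "$DATATYPE", path).upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    mode = keywords.get("$MODE", "L").upper()
    if mode != "L":
        raise FormatError(f"{path}: only list mode ($MODE/L) is supported")
    endian = "<" if byteord.startswith("1") else ">"

    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        widths = {int(_require(keywords, f"$P{i}B", path)) for i in range(1, n_par + 1)}
        if len(widths) != 1 or widths.pop() not in (8, 16, 32):
            raise FormatError(f"{path}: unsupported integer bit widths")
        nbits = int(keywords[f"$P1B"])
        dtype = np.dtype(f"{endian}u{nbits // 8}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_values = n_events * n_par
    payload = raw[data_start : data_start + n_values * dtype.itemsize]
    if len(payload) < n_values * dtype.itemsize:
        raise FormatError(f"{path}: DATA segment truncated")
    values = np.frombuffer(payload, dtype=dtype).astype(float).reshape(n_events, n_par)

    names = []
    for i in range(1, n_par + 1):
        name = keywords.get(f"$P{i}S") or keywords.get(f"$P{i}N") or f"P{i}"
        names.append(name)
    return values, names


def _parse_text_segment(segment: bytes, path) -> dict[str, str]:
    if not segment:
        raise FormatError(f"{path}: empty TEXT segment")
    delim = segment[0:1]
    parts = segment[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FormatError(f"{path}: odd number of TEXT tokens")
    out: dict[str, str] = {}
    for key, val in zip(parts[::2], parts[1::2]):
        out[key.decode("utf-8", errors="replace").strip().upper()] = val.decode(
            "utf-8", errors="replace"
        ).strip()
    return out


def _data_offsets(raw: bytes, keywords: dict[str, str], path) -> tuple[int, int]:
    # HEADER offsets may be zero for large files; fall back to $BEGINDATA.
    try:
        start = int(raw[26:34])
        end = int(raw[34:42])
    except ValueError:
        start = end = 0
    if start == 0:
        start = int(_require(keywords, "$BEGINDATA", path))
        end = int(_require(keywords, "$ENDDATA", path))
    if not (0 < start <= end < len(raw) + 1):
        raise FormatError(f"{path}: DATA segment offsets out of range")
    return start, end


def _require(keywords: dict[str, str], key: str, path) -> str:
    if key not in keywords:
        raise FormatError(f"{path}: missing required keyword {key}")
    return keywords[key]
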