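"""Minimal FCS 3.1 list-mode reader and writer.

Flow-cytometry standard files store a HEADER with byte offsets, a
delimited TEXT segment of ``$KEYWORD`` pairs, and a binary DATA segment.
This module supports the subset the package needs: list mode (``$MODE L``),
single-precision float or integer data (``$DATATYPE F`` / ``I``), little-
or big-endian ``$BYTEORD``, one data segment.  Spillover/compensation
keywords are ignored — the two-channel panel this package targets is not
compensated.

Condition metadata (dose, time, replicate, line) is not part of the FCS
standard for this use; it travels in a JSON sidecar written next to the
file (``<name>.fcs.json``), one acquisition per condition.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np

from .exceptions import EmptyDataError, FormatError, SchemaError

__all__ = ["read_fcs", "write_fcs", "read_sidecar", "write_sidecar"]

_DELIM = "/"


def _pad_int(value: int, width: int = 8) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"offset {value} does not fit in {width} header bytes")
    return s.rjust(width).encode("ascii")


def write_fcs(path: str | os.PathLike, data: np.ndarray, channel_names: Sequence[str]) -> None:
    """Write a 2-D float array as an FCS 3.1 list-mode file.

    Parameters
    ----------
    data : (n_events, n_channels) array
        Event data; stored as little-endian float32.
    channel_names : sequence of str
        ``$PnN`` short names, one per column.
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise FormatError("data must be 2-D (events x channels)")
    n_events, n_par = data.shape
    if n_events == 0:
        raise EmptyDataError("refusing to write an FCS file with zero events")
    if len(channel_names) != n_par:
        raise SchemaError("one channel name required per data column")

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        # placeholders, fixed width so TEXT length is offset-independent
        ("$BEGINDATA", "%8d"),
        ("$ENDDATA", "%8d"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_events)),
    ]
    for j, name in enumerate(channel_names, start=1):
        if _DELIM in name:
            raise SchemaError(f"channel name {name!r} contains the TEXT delimiter")
        keywords += [
            (f"$P{j}B", "32"),
            (f"$P{j}E", "0,0"),
            (f"$P{j}N", name),
            (f"$P{j}R", str(int(max(1.0, float(np.nanmax(data[:, j - 1])) + 1)))),
        ]

    def render(begin_data: int, end_data: int) -> bytes:
        parts = [_DELIM]
        for key, val in keywords:
            if val == "%8d":
                val = str(begin_data if key == "$BEGINDATA" else end_data).rjust(8)
            parts.append(f"{key}{_DELIM}{val}{_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58  # "FCS3.1    " + 6 offset fields of 8 bytes
    text = render(0, 0)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1
    text = render(data_begin, data_end)

    header = b"FCS3.1    "
    header += _pad_int(text_begin) + _pad_int(text_end)
    header += _pad_int(data_begin) + _pad_int(data_end)
    header += _pad_int(0) + _pad_int(0)
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.astype("<f4").tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    # split on the delimiter; doubled delimiters (escapes) are not produced
    # by this writer and are vanishingly rare in 2-channel files
    tokens = body.split(delim)[1:]
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise FormatError("TEXT segment has an odd number of tokens")
    return {tokens[i].strip().upper(): tokens[i + 1] for i in range(0, len(tokens), 2)}


def read_fcs(path: str | os.PathLike) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS 3.0/3.1 list-mode file.

    Returns
    -------
    data : (n_events, n_channels) float64 array
    channel_names : list of ``$PnN`` values
    keywords : full TEXT-segment keyword dict
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58 or not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FormatError(f"{path}: not an FCS 3.0/3.1 file")
    try:
        offsets = [int(raw[10 + 8 * i : 18 + 8 * i]) for i in range(4)]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed header offsets") from exc
    text_begin, text_end, data_begin, data_end = offsets
    kw = _parse_text(raw[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    if kw.get("$MODE", "L").upper() != "L":
        raise FormatError("only list-mode ($MODE L) FCS data is supported")
    if datatype == "F":
        dtype = np.dtype(order + "f4")
    elif datatype == "D":
        dtype = np.dtype(order + "f8")
    elif datatype == "I":
        bits = {int(kw[f"$P{j}B"]) for j in range(1, n_par + 1)}
        if len(bits) != 1 or next(iter(bits)) not in (16, 32):
            raise FormatError("integer data requires uniform $PnB of 16 or 32")
        dtype = np.dtype(order + ("u2" if next(iter(bits)) == 16 else "u4"))
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * dtype.itemsize
    segment = raw[data_begin : data_begin + expected]
    if len(segment) != expected:
        raise FormatError(
            f"DATA segment truncated: expected {expected} bytes, got {len(segment)}"
        )
    data = np.frombuffer(segment, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)
    names = [kw.get(f"$P{j}N", f"P{j}") for j in range(1, n_par + 1)]
    return data, names, kw



def sidecar_path(path: str | os.PathLike) -> str:
    return str(path) + ".json"


def write_sidecar(path: str | os.PathLike, metadata: dict) -> None:
    """Write the per-acquisition condition metadata next to an FCS file."""
    with open(sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)


def read_sidecar(path: str | os.PathLike) -> dict:
    p = sidecar_path(path)
    if not os.path.exists(p):
        return {}
    with open(p, encoding="utf-8") as fh:
        return json.load(fh)
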