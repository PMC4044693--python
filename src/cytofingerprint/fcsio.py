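"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Covers exactly what cytometric fingerprinting needs: list-mode (``$MODE L``)
data segments with integer (``$DATATYPE I``), single- (``F``) or
double-precision (``D``) parameters, uniform ``$PnB`` bit widths, and either
byte order. Spillover matrices, analysis segments and the long tail of
optional keywords are ignored on read and never written.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["read_fcs", "write_fcs"]

_DTYPES = {"F": "f4", "D": "f8"}
_INT_WIDTHS = {8: "u1", 16: "u2", 32: "u4"}


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)
    # parts[0] is empty (segment starts with the delimiter)
    kv = parts[1:]
    out: dict[str, str] = {}
    for key, val in zip(kv[::2], kv[1::2]):
        out[key.strip().upper()] = val.strip()
    return out


def read_fcs(path) -> tuple[list[str], np.ndarray]:
    """Return (channel names, n_events x n_channels float array)."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 58:
        raise ValueError(f"{path}: truncated FCS header")
    version = buf[:6].decode("latin-1")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(buf[10:18])
        text_end = int(buf[18:26])
        data_start = int(buf[26:34])
        data_end = int(buf[34:42])
    except ValueError:
        raise ValueError(f"{path}: malformed FCS header offsets") from None
    text = _parse_text(buf[text_start : text_end + 1])
    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    mode = text.get("$MODE", "L")
    if mode != "L":
        raise ValueError(f"{path}: unsupported FCS mode {mode!r} (list mode only)")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    bits = {int(text.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise ValueError(f"{path}: mixed $PnB bit widths are not supported")
    nbits = bits.pop()
    if datatype in _DTYPES:
        dt = np.dtype(endian + _DTYPES[datatype])
    elif datatype == "I":
        if nbits not in _INT_WIDTHS:
            raise ValueError(f"{path}: unsupported integer width {nbits}")
        dt = np.dtype(endian + _INT_WIDTHS[nbits])
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {datatype!r}")
    names = [
        text.get(f"$P{i}N", text.get(f"$P{i}S", f"P{i}")) for i in range(1, n_par + 1)
    ]
    need = n_tot * n_par * dt.itemsize
    raw = buf[data_start : data_start + need]
    if len(raw) < need:
        raise ValueError(f"{path}: data segment shorter than $TOT*$PAR events")
    values = np.frombuffer(raw, dtype=dt).reshape(n_tot, n_par).astype(float)
    return names, values


def write_fcs(path, channels: list[str], values: np.ndarray) -> None:
    """Write a float32 little-endian FCS 3.0 list-mode file."""
    values = np.asarray(values, dtype="<f4")
    n_tot, n_par = values.shape
    if n_par != len(channels):
        raise ValueError("channel count does not match value columns")
    data = values.tobytes()
    kw: list[tuple[str, str]] = [
        ("$MODE", "L"),
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
    ]
    for i, name in enumerate(channels, start=1):
        kw += [(f"$P{i}N", name), (f"$P{i}B", "32"), (f"$P{i}E", "0,0"),
               (f"$P{i}R", "262144")]
    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw) + delim
    text_start = 58
    text_bytes = text.encode("latin-1")
    data_start = text_start + len(text_bytes)
    data_end = data_start + len(data) - 1
    header = b"FCS3.0    " + b"".join(
        str(v).rjust(8).encode() for v in
        (text_start, text_start + len(text_bytes) - 1, data_start, data_end, 0, 0)
    )
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(data)
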