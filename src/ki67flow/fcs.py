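"""Minimal FCS 3.1 list-mode reader/writer.

Supports what a cytometry pipeline needs for round-tripping event tables:
list mode (``$MODE L``), floating-point data (``$DATATYPE F`` or ``D``),
little- or big-endian ``$BYTEORD``, and ``$PnN`` short channel names.
Integer data, bit-packed parameters, multiple datasets (``$NEXTDATA``),
analysis segments and keyword editing are out of scope.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_fcs", "write_fcs"]

_DELIM = "/"


class FcsFormatError(ValueError):
    """Raised when a file is not an FCS file this reader supports."""


def _build_text(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        value = str(value)
        if _DELIM in value:
            raise FcsFormatError(f"keyword value for {key} contains the delimiter")
        parts.append(f"{key}{_DELIM}{value}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(df: pd.DataFrame, path) -> None:
    """Write an event table as FCS 3.1, float32 list mode, little endian.

    Column names become ``$PnN`` short names.  Values are cast to float32;
    callers needing exact round-trips should compare within float32
    precision (the CSV writer is the lossless path).
    """
    data = np.ascontiguousarray(df.to_numpy(dtype="<f4"))
    n_events, n_par = data.shape
    keywords = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for j, name in enumerate(df.columns, start=1):
        keywords[f"$P{j}N"] = str(name)
        keywords[f"$P{j}B"] = "32"
        keywords[f"$P{j}E"] = "0,0"
        ceiling = float(data[:, j - 1].max()) if n_events else 1.0
        keywords[f"$P{j}R"] = str(int(max(1.0, np.ceil(ceiling))))

    header_len = 58
    text_start = 256
    # Offsets appear inside TEXT, so iterate until the layout is stable.
    begin_data = end_data = 0
    for _ in range(8):
        keywords["$BEGINDATA"] = str(begin_data)
        keywords["$ENDDATA"] = str(end_data)
        text = _build_text(keywords)
        new_begin = text_start + len(text)
        new_end = new_begin + data.nbytes - 1 if data.nbytes else new_begin
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = _build_text(keywords)
    text_end = text_start + len(text) - 1

    def fld(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fld(text_start) + fld(text_end)
    header += fld(begin_data if end_data <= 99_999_999 else 0)
    header += fld(end_data if end_data <= 99_999_999 else 0)
    header += fld(0) + fld(0)
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_start - header_len))
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    text = raw.decode("ascii", errors="replace")
    delim = text[0]
    fields = text[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        raise FcsFormatError("TEXT segment has an odd number of fields")
    return {fields[i].strip(): fields[i + 1] for i in range(0, len(fields), 2)}


def read_fcs(path) -> pd.DataFrame:
    """Read a list-mode floating-point FCS 3.0/3.1 file into a DataFrame."""
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FcsFormatError(f"{path}: not an FCS 3.x file")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    keywords = _parse_text(raw[text_start:text_end + 1])

    if keywords.get("$MODE", "L") != "L":
        raise FcsFormatError("only list-mode ($MODE L) data is supported")
    datatype = keywords.get("$DATATYPE", "F")
    if datatype not in ("F", "D"):
        raise FcsFormatError(f"unsupported $DATATYPE {datatype!r}")
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if datatype == "F" else 8
    dtype = np.dtype(f"{endian}f{itemsize}")

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    begin_data = int(raw[26:34] or 0) or int(keywords["$BEGINDATA"])
    end_data = int(raw[34:42] or 0) or int(keywords["$ENDDATA"])

    expected = n_par * n_tot * itemsize
    buf = raw[begin_data:end_data + 1]
    if len(buf) < expected:
        raise FcsFormatError(
            f"data segment holds {len(buf)} bytes, expected {expected}"
        )
    values = np.frombuffer(buf[:expected], dtype=dtype).reshape(n_tot, n_par)
    names = [keywords.get(f"$P{j}N", f"P{j}") for j in range(1, n_par + 1)]
    return pd.DataFrame(values.astype(float), columns=names)
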