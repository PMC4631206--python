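"""Minimal FCS 3.0/3.1 reader and FCS 3.1 writer.

Covers the subset of the flow-cytometry standard this package produces and
consumes: list-mode data, single-precision float ($DATATYPE/F), little-endian
byte order, one TEXT segment, no ANALYSIS segment.  Enough to round-trip
simulated cohorts and to ingest instrument files written in the same common
profile.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

DELIM = "/"


def _escape(v: str) -> str:
    return v.replace(DELIM, DELIM + DELIM)


def write_fcs(path: str | Path, values: np.ndarray, names: list[str]) -> None:
    """Write an events x channels float matrix as FCS 3.1."""
    values = np.ascontiguousarray(values, dtype="<f4")
    n_events, n_par = values.shape
    if len(names) != n_par:
        raise ValueError("one name per channel required")

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_events),
    }
    rng_bits = 32
    for j, name in enumerate(names, start=1):
        kw[f"$P{j}B"] = str(rng_bits)
        kw[f"$P{j}E"] = "0,0"
        kw[f"$P{j}N"] = name
        kw[f"$P{j}R"] = str(int(max(1.0, float(np.max(values[:, j - 1], initial=0.0)) + 1)))

    data_bytes = values.tobytes()
    header_len = 58
    # iterate because BEGINDATA/ENDDATA values change the TEXT length
    begin_data = 0
    for _ in range(8):
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(begin_data + len(data_bytes) - 1 if data_bytes else 0)
        text = DELIM + DELIM.join(
            _escape(k) + DELIM + _escape(v) for k, v in kw.items()) + DELIM
        text_start = header_len
        text_end = text_start + len(text) - 1
        new_begin = text_end + 1
        if new_begin == begin_data:
            break
        begin_data = new_begin
    end_data = begin_data + len(data_bytes) - 1 if data_bytes else 0

    header = (b"FCS3.1    "
              + f"{text_start:>8d}".encode()
              + f"{text_end:>8d}".encode()
              + (f"{begin_data:>8d}".encode() if begin_data <= 99999999 else b"       0")
              + (f"{end_data:>8d}".encode() if end_data <= 99999999 else b"       0")
              + b"       0" + b"       0")
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("utf-8"))
        fh.write(data_bytes)


def _parse_text(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    delim = text[0]
    if text[-1] != delim:
        raise ValueError("malformed FCS TEXT segment: missing trailing delimiter")
    body = text[1:-1]
    # delimiters inside values are escaped by doubling
    parts = body.replace(delim + delim, "\x00").split(delim)
    parts = [p.replace("\x00", delim) for p in parts]
    if len(parts) % 2 != 0:
        raise ValueError("malformed FCS TEXT segment: odd keyword count")
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS 3.0/3.1 file; returns (values, channel names)."""
    raw = Path(path).read_bytes()
    magic = raw[:6].decode("ascii", errors="replace")
    if not magic.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version record {magic!r}")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as e:
        raise ValueError(f"{path}: malformed FCS header offsets") from e
    kw = _parse_text(raw[text_start:text_end + 1])

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    order = "<" if byteord.startswith("1") else ">"
    if dtype_code == "F":
        dt = np.dtype(order + "f4")
    elif dtype_code == "D":
        dt = np.dtype(order + "f8")
    elif dtype_code == "I":
        bits = {int(kw[f"$P{j}B"]) for j in range(1, n_par + 1)}
        if bits != {32} and bits != {16}:
            raise ValueError(f"{path}: unsupported mixed/odd integer widths {bits}")
        dt = np.dtype(f"{order}u{bits.pop() // 8}")
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code!r}")

    begin = int(kw.get("$BEGINDATA", "0") or 0)
    end = int(kw.get("$ENDDATA", "0") or 0)
    if begin == 0:
        begin = int(raw[26:34])
        end = int(raw[34:42])
    data = np.frombuffer(raw[begin:end + 1], dtype=dt, count=n_par * n_tot)
    values = data.reshape(n_tot, n_par).astype(float)

    names = []
    for j in range(1, n_par + 1):
        names.append(kw.get(f"$P{j}N", kw.get(f"$P{j}S", f"P{j}")))
    return values, names
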