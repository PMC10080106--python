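"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Flow cytometers export events as FCS files: a fixed ASCII header with segment
offsets, a delimited TEXT segment of $-keywords and a binary DATA segment.
This adapter covers the subset of the standard the pipeline needs — list-mode
($MODE L) files with float ($DATATYPE F/D) or unpadded integer ($DATATYPE I)
data in either byte order — and writes FCS 3.1 float32 files whose bytes are
deterministic for fixed content and metadata.

Channel naming convention on write: $PnN holds the short channel/detector id
and $PnS the marker (stain) name; on read $PnS is preferred and $PnN is the
fallback, mirroring how analysis software labels axes.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventMatrix

__all__ = ["read_fcs", "write_fcs", "FcsParseError"]

DELIM = "/"
HEADER_LEN = 58
TEXT_START = 256


class FcsParseError(ValueError):
    """Malformed FCS header, TEXT segment or DATA segment."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (file offset {offset})"
        super().__init__(message)


def _parse_text(raw: bytes, start: int) -> dict[str, str]:
    try:
        text = raw.decode("utf-8", errors="replace")
    except Exception as exc:  # pragma: no cover
        raise FcsParseError(f"undecodable TEXT segment: {exc}", start)
    if len(text) < 2:
        raise FcsParseError("TEXT segment too short", start)
    delim = text[0]
    if text[-1] != delim:
        raise FcsParseError("TEXT segment does not end with its delimiter", start)
    body = text[1:-1]
    # delimiter escaping per the standard: a doubled delimiter is literal
    parts = body.split(delim)
    fields: list[str] = []
    i = 0
    while i < len(parts):
        piece = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            piece += delim + parts[i + 2]
            i += 2
        fields.append(piece)
        i += 1
    if len(fields) % 2 != 0:
        raise FcsParseError("odd number of TEXT fields", start)
    return {
        fields[k].strip().upper(): fields[k + 1]
        for k in range(0, len(fields), 2)
    }


def read_fcs(path) -> EventMatrix:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventMatrix`.

    Channel names come from $PnS with $PnN as fallback; the event count must
    match $TOT and the DATA segment size, otherwise a parse error with the
    offending offset is raised.
    """
    raw = Path(path).read_bytes()
    if len(raw) < HEADER_LEN:
        raise FcsParseError("file shorter than an FCS header", 0)
    version = raw[0:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise FcsParseError(f"unsupported FCS version {version!r}", 0)

    def header_int(lo: int, hi: int, what: str) -> int:
        s = raw[lo:hi].decode("ascii", errors="replace").strip()
        if not s:
            return 0
        try:
            return int(s)
        except ValueError:
            raise FcsParseError(f"non-numeric {what} in header: {s!r}", lo)

    text_begin = header_int(10, 18, "TEXT begin")
    text_end = header_int(18, 26, "TEXT end")
    data_begin = header_int(26, 34, "DATA begin")
    data_end = header_int(34, 42, "DATA end")
    if text_end <= text_begin or text_end >= len(raw):
        raise FcsParseError("invalid TEXT segment offsets", 10)
    kw = _parse_text(raw[text_begin : text_end + 1], text_begin)

    if data_begin == 0:  # large files put offsets in TEXT only
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_end <= data_begin or data_end >= len(raw):
        raise FcsParseError("invalid DATA segment offsets", 26)

    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise FcsParseError(f"only list-mode files supported, got $MODE={mode}")
    datatype = kw.get("$DATATYPE", "").upper()
    n_par = int(kw.get("$PAR", "0"))
    n_tot = int(kw.get("$TOT", "0"))
    if n_par < 1 or n_tot < 0:
        raise FcsParseError("missing or invalid $PAR/$TOT")

    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"
    if datatype == "F":
        dtype = np.dtype(order + "f4")
    elif datatype == "D":
        dtype = np.dtype(order + "f8")
    elif datatype == "I":
        bits = {int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if len(bits) != 1 or next(iter(bits)) not in (16, 32):
            raise FcsParseError(
                "integer data requires uniform $PnB of 16 or 32"
            )
        dtype = np.dtype(order + ("u2" if next(iter(bits)) == 16 else "u4"))
    else:
        raise FcsParseError(f"unsupported $DATATYPE {datatype!r}")

    data = raw[data_begin : data_end + 1]
    expected = n_tot * n_par * dtype.itemsize
    if len(data) < expected:
        raise FcsParseError(
            f"DATA segment holds {len(data)} bytes, $TOT x $PAR needs "
            f"{expected}",
            data_begin,
        )
    values = np.frombuffer(data[:expected], dtype=dtype).reshape(n_tot, n_par)

    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}S", "").strip() or kw.get(f"$P{i}N", f"P{i}").strip()
        names.append(name)
    frame = pd.DataFrame(np.asarray(values, dtype=float), columns=names)
    meta = {
        "fcs_version": version.strip(),
        "keywords": {k: v for k, v in kw.items() if not k.startswith("$P")},
    }
    return EventMatrix(frame, metadata=meta)


def write_fcs(events: EventMatrix, path, extra_keywords: dict | None = None) -> None:
    """Write an :class:`EventMatrix` as FCS 3.1 (float32, little-endian).

    $PnN is a short channel id, $PnS the marker name.  Non-finite values are
    rejected.  Bytes are deterministic given fixed content and keywords.
    """
    values = events.data.to_numpy(dtype=np.float32)
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot write non-finite event values")
    n_tot, n_par = values.shape
    if n_par < 1:
        raise ValueError("cannot write a file with zero channels")
    payload = values.astype("<f4").tobytes()

    def esc(v: str) -> str:
        return str(v).replace(DELIM, DELIM + DELIM)

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$TOT", str(n_tot)),
        ("$PAR", str(n_par)),
    ]
    for i, col in enumerate(events.data.columns, start=1):
        rng = float(np.max(values[:, i - 1], initial=0.0))
        keywords += [
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}N", f"CH{i}"),
            (f"$P{i}S", str(col)),
            (f"$P{i}R", str(int(np.ceil(rng)) + 1)),
        ]
    for k, v in (extra_keywords or {}).items():
        keywords.append((str(k).upper(), str(v)))

    # two passes: data offsets depend on TEXT length, which contains them
    def render(data_begin: int, data_end: int) -> bytes:
        fields = keywords + [
            ("$BEGINDATA", str(data_begin)),
            ("$ENDDATA", str(data_end)),
        ]
        body = DELIM + DELIM.join(
            esc(k) + DELIM + esc(v) for k, v in fields
        ) + DELIM
        return body.encode("utf-8")

    guess = render(0, 0)
    text_begin = TEXT_START
    # data offsets grow the TEXT by a bounded number of digits; iterate
    data_begin = data_end = 0
    for _ in range(4):
        text = render(data_begin, data_end)
        new_begin = text_begin + len(text)
        new_end = new_begin + len(payload) - 1
        if (new_begin, new_end) == (data_begin, data_end):
            break
        data_begin, data_end = new_begin, new_end
    text = render(data_begin, data_end)
    text_end = text_begin + len(text) - 1

    header = (
        b"FCS3.1"
        + b" " * 4
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (
            f"{data_begin:>8d}".encode() + f"{data_end:>8d}".encode()
            if data_end <= 99_999_999
            else b"       0" * 2
        )
        + b"       0" * 2  # no ANALYSIS segment
    )
    assert len(header) == HEADER_LEN
    blob = header + b" " * (text_begin - len(header)) + text + payload
    Path(path).write_bytes(blob)
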