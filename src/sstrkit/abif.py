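"""Minimal ABIF (AB1) writer.

Produces files with the small subset of tags a basecalled-trace consumer
needs: called sequence (PBAS1/2), per-base qualities (PCON1/2), peak
locations (PLOC1/2), channel order (FWO_1) and the four analyzed channel
arrays (DATA9-12).  Each called base contributes one sharp peak per active
channel, placed at its PLOC index, so per-position peak heights survive a
write/read round trip exactly.
"""

from __future__ import annotations

import struct

import numpy as np

from .traceio import BASES, Trace

_DIRFMT = ">4sI2H4I"  # name, number, elemtype, elemsize, numelem, datasize, offset, handle
_HEADFMT = ">H4sI2H3I"  # version + a directory entry for the directory itself

# ABIF element type codes
_BYTE = 1
_CHAR = 2
_SHORT = 4
_PSTRING = 18

_PEAK_SPACING = 12


def _entry(name: bytes, number: int, elemtype: int, elemsize: int, data: bytes):
    return {
        "name": name,
        "number": number,
        "elemtype": elemtype,
        "elemsize": elemsize,
        "numelem": len(data) // elemsize,
        "data": data,
    }


def write_abif(trace: Trace, path) -> None:
    """Write a :class:`~sstrkit.traceio.Trace` as an ABIF/AB1 file."""
    n = len(trace)
    ploc = np.arange(n, dtype=np.int64) * _PEAK_SPACING + _PEAK_SPACING // 2
    raw_len = int(ploc[-1]) + _PEAK_SPACING if n else _PEAK_SPACING
    heights = np.rint(trace.peak_heights).astype(np.int64)
    if np.any(heights > np.iinfo(np.int16).max):
        raise ValueError("peak heights exceed the int16 range of ABIF DATA tags")

    order = "GATC"  # conventional dye order
    channels = {}
    for base in BASES:
        arr = np.zeros(raw_len, dtype=np.int16)
        arr[ploc] = heights[:, "ACGT".index(base)]
        channels[base] = arr

    phred = trace.phred
    if phred is None:
        phred = np.full(n, 40, dtype=int)
    pcon = bytes(int(min(q, 93)) for q in phred)
    seq = trace.called_sequence.encode()
    name = trace.name.encode()[:250]

    entries = []
    for i, base in enumerate(order):
        entries.append(
            _entry(
                b"DATA",
                9 + i,
                _SHORT,
                2,
                channels[base].astype(">i2").tobytes(),
            )
        )
    entries.append(_entry(b"FWO_", 1, _CHAR, 1, order.encode()))
    for number in (1, 2):
        entries.append(_entry(b"PBAS", number, _CHAR, 1, seq))
        entries.append(_entry(b"PCON", number, _CHAR, 1, pcon))
        entries.append(
            _entry(b"PLOC", number, _SHORT, 2, ploc.astype(">i2").tobytes())
        )
    entries.append(
        _entry(b"SMPL", 1, _PSTRING, 1, bytes([len(name)]) + name)
    )

    header_size = 128
    dir_entry_size = struct.calcsize(_DIRFMT)

    # Lay out data blocks after the header; directory goes last.
    blobs = []
    offset = header_size
    for e in entries:
        if len(e["data"]) > 4:
            e["offset"] = offset
            blobs.append(e["data"])
            offset += len(e["data"])
        else:
            e["offset"] = None  # stored inline in the directory entry
    dir_offset = offset

    with open(path, "wb") as fh:
        fh.write(b"ABIF")
        fh.write(
            struct.pack(
                _HEADFMT,
                101,
                b"tdir",
                1,
                1023,
                dir_entry_size,
                len(entries),
                dir_entry_size * len(entries),
                dir_offset,
            )
        )
        fh.write(b"\x00" * (header_size - fh.tell()))
        for blob in blobs:
            fh.write(blob)
        for e in entries:
            data = e["data"]
            if e["offset"] is None:
                inline = struct.unpack(">I", data.ljust(4, b"\x00"))[0]
                offset_field = inline
            else:
                offset_field = e["offset"]
            fh.write(
                struct.pack(
                    _DIRFMT,
                    e["name"],
                    e["number"],
                    e["elemtype"],
                    e["elemsize"],
                    e["numelem"],
                    len(data),
                    offset_field,
                    0,
                )
            )
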