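"""Sanger trace I/O and coordinate mapping.

A :class:`Trace` is a basecalled Sanger read carrying, for every called
position, the four channel peak heights (A, C, G, T) reported by the
basecaller.  Editing quantification works on these per-position heights, so
no raw electropherogram signal is kept.

Two on-disk dialects are supported: the binary ABIF/AB1 container produced
by capillary sequencers (read through Biopython) and a plain tab-separated
dialect with one row per called position — convenient for synthetic data and
for spreadsheet inspection.

Coordinates
-----------
Trace positions are 1-based over called bases.  Break-relative ("DSB
relative") coordinates are integers on the sense strand with 0 at the centre
of the staggered cut; negative positions lie toward the normalization anchor
(position -42, an 'A' in the default target).  :class:`TargetMap` converts
between the two systems once a target sequence has been located in a trace.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Default analysis window applied on load (positions over which the
#: background noise model is calibrated).
DEFAULT_WINDOW_START = 200
DEFAULT_WINDOW_END = 400

#: Default normalization anchor: break-relative position -42, an 'A'.
DEFAULT_ANCHOR = (-42, "A")


class TraceParseError(ValueError):
    """Raised when a trace file cannot be parsed."""


class TargetNotFoundError(ValueError):
    """Raised when the target sequence cannot be located in a trace."""


class AmbiguousTargetError(ValueError):
    """Raised when the target matches equally well at more than one placement."""


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


@dataclasses.dataclass
class Trace:
    """A called Sanger read with per-position 4-channel peak heights."""

    name: str
    called_sequence: str
    peak_heights: np.ndarray  # shape (n, 4), columns A, C, G, T
    phred: Optional[np.ndarray] = None
    source_format: str = "memory"

    def __post_init__(self) -> None:
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)
        if self.peak_heights.ndim != 2 or self.peak_heights.shape[1] != 4:
            raise ValueError("peak_heights must have shape (n, 4)")
        if self.peak_heights.shape[0] != len(self.called_sequence):
            raise ValueError("peak_heights length must equal called_sequence length")
        if np.any(self.peak_heights < 0):
            raise ValueError("peak heights must be nonnegative")
        if self.phred is not None:
            self.phred = np.asarray(self.phred, dtype=int)
            if self.phred.shape[0] != len(self.called_sequence):
                raise ValueError("phred length must equal called_sequence length")

    def __len__(self) -> int:
        return len(self.called_sequence)

    def height(self, position: int, base: str) -> float:
        """Peak height of ``base``'s channel at 1-based trace ``position``."""
        self._check_position(position)
        return float(self.peak_heights[position - 1, BASE_INDEX[base]])

    def called_base(self, position: int) -> str:
        self._check_position(position)
        return self.called_sequence[position - 1]

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside trace of length {len(self)}")


@dataclasses.dataclass(frozen=True)
class AnalysisWindow:
    """Trace-position window used for noise-model calibration."""

    start_5prime: int = DEFAULT_WINDOW_START
    end_3prime: int = DEFAULT_WINDOW_END
    region_of_interest: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.start_5prime >= self.end_3prime:
            raise ValueError("window start must precede end")
        roi = self.region_of_interest
        if roi is not None and not (
            self.start_5prime <= roi[0] <= roi[1] <= self.end_3prime
        ):
            raise ValueError("region of interest must lie within the window")

    def positions(self, trace: Trace) -> np.ndarray:
        """1-based positions of the window clipped to the trace."""
        lo = max(self.start_5prime, 1)
        hi = min(self.end_3prime, len(trace))
        return np.arange(lo, hi + 1)


DEFAULT_WINDOW = AnalysisWindow()


@dataclasses.dataclass(frozen=True)
class TargetMap:
    """Placement of a target sequence in a trace plus the DSB coordinate frame.

    ``rel_start`` is the break-relative coordinate of ``target_sequence[0]``
    (default -42, i.e. the target begins at the normalization anchor).
    """

    target_sequence: str
    trace_offset: int  # 1-based trace position of target start
    orientation: str  # "forward" | "reverse"
    rel_start: int = DEFAULT_ANCHOR[0]
    anchor: tuple[int, str] = DEFAULT_ANCHOR
    mismatches: int = 0

    def rel_to_trace(self, rel: int) -> int:
        idx = rel - self.rel_start
        if not 0 <= idx < len(self.target_sequence):
            raise ValueError(f"relative position {rel} outside the mapped target")
        if self.orientation == "forward":
            return self.trace_offset + idx
        return self.trace_offset + (len(self.target_sequence) - 1 - idx)

    def trace_to_rel(self, position: int) -> int:
        if self.orientation == "forward":
            idx = position - self.trace_offset
        else:
            idx = (len(self.target_sequence) - 1) - (position - self.trace_offset)
        if not 0 <= idx < len(self.target_sequence):
            raise ValueError(f"trace position {position} outside the mapped target")
        return self.rel_start + idx

    def base_on_trace(self, base: str) -> str:
        """Channel observed in the trace for a sense-strand ``base``."""
        return base if self.orientation == "forward" else complement(base)

    def anchor_position(self) -> int:
        return self.rel_to_trace(self.anchor[0])


# ---------------------------------------------------------------------------
# reading / writing


def read_trace(path, format: str = "tabular") -> Trace:
    """Read a trace file (``abif`` or ``tabular``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        return _read_tabular(path)
    if format == "abif":
        return _read_abif(path)
    raise ValueError(f"unknown trace format: {format!r}")


def _read_tabular(path: Path) -> Trace:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TraceParseError(f"{path}: {exc}") from exc
    required = ["position", "called_base", "A", "C", "G", "T"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing columns {missing}")
    df = df.sort_values("position")
    if not np.array_equal(df["position"].to_numpy(), np.arange(1, len(df) + 1)):
        raise TraceParseError(f"{path}: positions must be 1..n without gaps")
    heights = df[["A", "C", "G", "T"]].to_numpy(dtype=float)
    phred = df["phred"].to_numpy(dtype=int) if "phred" in df.columns else None
    return Trace(
        name=path.stem,
        called_sequence="".join(df["called_base"].astype(str)),
        peak_heights=heights,
        phred=phred,
        source_format="tabular",
    )


def write_trace_tabular(trace: Trace, path) -> None:
    n = len(trace)
    df = pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "called_base": list(trace.called_sequence),
            "A": trace.peak_heights[:, 0],
            "C": trace.peak_heights[:, 1],
            "G": trace.peak_heights[:, 2],
            "T": trace.peak_heights[:, 3],
        }
    )
    if trace.phred is not None:
        df["phred"] = trace.phred
    df.to_csv(path, sep="\t", index=False)


def _read_abif(path: Path) -> Trace:
    from Bio import SeqIO

    try:
        record = SeqIO.read(str(path), "abi")
    except ValueError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc
    raw = record.annotations["abif_raw"]
    seq = raw.get("PBAS2")
    ploc = raw.get("PLOC2")
    order = raw.get("FWO_1")
    if seq is None or ploc is None or order is None:
        raise TraceParseError(f"{path}: missing basecall tags (PBAS2/PLOC2/FWO_1)")
    seq = seq.decode() if isinstance(seq, bytes) else str(seq)
    order = order.decode() if isinstance(order, bytes) else str(order)
    channels = {}
    for i, base in enumerate(order):
        data = raw.get(f"DATA{9 + i}")
        if data is None:
            raise TraceParseError(f"{path}: missing channel DATA{9 + i}")
        channels[base] = np.asarray(data, dtype=float)
    missing = [b for b in BASES if b not in channels]
    if missing:
        raise TraceParseError(f"{path}: missing channels for {missing}")
    ploc = np.asarray(ploc, dtype=int)
    heights = np.column_stack([channels[b][ploc] for b in BASES])
    phred = None
    if record.letter_annotations.get("phred_quality"):
        phred = np.asarray(record.letter_annotations["phred_quality"], dtype=int)
    return Trace(
        name=path.stem,
        called_sequence=seq,
        peak_heights=heights,
        phred=phred,
        source_format="abif",
    )


# ---------------------------------------------------------------------------
# per-position signal and target location


def percent_signal(trace: Trace, position: int) -> np.ndarray:
    """Fractional signal of the four channels at a 1-based position.

    Returns an array (A, C, G, T) summing to 1, or all-NaN when the total
    height at that position is zero (reported as missing).
    """
    trace._check_position(position)
    heights = trace.peak_heights[position - 1]
    total = heights.sum()
    if total == 0:
        return np.full(4, np.nan)
    return heights / total


def locate_target(
    trace: Trace,
    target_sequence: str,
    *,
    max_mismatches: int = 2,
    rel_start: int = DEFAULT_ANCHOR[0],
    anchor: tuple[int, str] = DEFAULT_ANCHOR,
) -> TargetMap:
    """Locate ``target_sequence`` in a trace by ungapped scanning.

    Both orientations are scanned; the unique placement with the fewest
    mismatches (at most ``max_mismatches``) wins.  Ambiguity codes in the
    called sequence never match.
    """
    target = target_sequence.upper()
    if len(target) < 20:
        raise ValueError("target must be at least 20 nt")
    called = trace.called_sequence.upper()
    if len(target) > len(called):
        raise TargetNotFoundError("target longer than trace")

    hits: list[tuple[int, int, str]] = []  # (mismatches, offset0, orientation)
    for orientation, query in (
        ("forward", target),
        ("reverse", reverse_complement(target)),
    ):
        mm = _mismatch_profile(called, query)
        for off in np.flatnonzero(mm <= max_mismatches):
            hits.append((int(mm[off]), int(off), orientation))
    if not hits:
        raise TargetNotFoundError(
            f"target not found within {max_mismatches} mismatches"
        )
    hits.sort()
    best = hits[0]
    if len(hits) > 1 and hits[1][0] == best[0]:
        raise AmbiguousTargetError(
            f"target matches at {len([h for h in hits if h[0] == best[0]])} "
            "equally good placements"
        )
    tmap = TargetMap(
        target_sequence=target,
        trace_offset=best[1] + 1,
        orientation=best[2],
        rel_start=rel_start,
        anchor=anchor,
        mismatches=best[0],
    )
    return tmap


def _mismatch_profile(called: str, query: str) -> np.ndarray:
    """Mismatch count of ``query`` at every ungapped offset of ``called``."""
    n, m = len(called), len(query)
    arr = np.frombuffer(called.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    return (windows != q).sum(axis=1)
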