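"""Repair-outcome classification of colony amplicon reads.

Rapamycin-resistant colonies carry one of four outcomes at the targeted
locus, distinguished by comparing the colony PCR read to the wild-type
amplicon and to the expected-edit amplicon (the wild type with the
gRNA-targeted block replaced by the 24-nt non-homologous insert):

* ``SCARLESS_SSTR`` — perfect homology-directed replacement: the read
  matches the expected-edit amplicon exactly across the edited window.
* ``SCARRED_SSTR`` — at least part of the insert is present (a contiguous
  run of ``min_insert_match`` or more insert bases), but the edited window
  is not a perfect match: junction SNPs, indels or local duplications.
* ``INDEL`` — no insert bases, and an insertion/deletion overlapping the
  cut site relative to the wild type.
* ``WT`` — matches the wild type across the edited window.
* ``UNCALLED`` — unalignable or not fitting any category; excluded from
  tally denominators.

Classification aligns each read globally (affine gaps) against both
references, after orienting it to the better-matching strand, and
additionally scans for exact insert substrings (duplicated or rearranged
scars can hide insert bases from a single alignment path).

Population-level scarless SSTR is the product of the rapamycin-resistance
percentage (from the plate-count assay) and the scarless fraction among
sequenced colonies.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from Bio import Align

from .traceio import reverse_complement

CATEGORIES = ("SCARLESS_SSTR", "SCARRED_SSTR", "INDEL", "WT", "UNCALLED")


@dataclasses.dataclass(frozen=True)
class ClassifyParams:
    min_insert_match: int = 8  # contiguous insert bases counted as evidence
    identity_floor: float = 0.7  # below this vs both refs -> UNCALLED
    window_margin: int = 5  # flank added around the replaced block
    cut_site_margin: int = 5  # indel-to-cut-site proximity


@dataclasses.dataclass
class AmpliconRefs:
    """Wild-type and expected-edit references for one amplicon."""

    wt_amplicon: str
    insert_sequence: str
    replace_start: int  # wt coordinates (0-based, half-open) of replaced block
    replace_end: int
    cut_site: int

    def __post_init__(self) -> None:
        if not 0 <= self.replace_start < self.replace_end <= len(self.wt_amplicon):
            raise ValueError("replaced block outside the wt amplicon")
        if self.insert_sequence in self.wt_amplicon:
            raise ValueError("insert must not be a substring of the wt amplicon")

    @property
    def expected_edit_amplicon(self) -> str:
        wt = self.wt_amplicon
        return wt[: self.replace_start] + self.insert_sequence + wt[self.replace_end :]

    def window_wt(self, margin: int) -> tuple[int, int]:
        return (
            max(0, self.replace_start - margin),
            min(len(self.wt_amplicon), self.replace_end + margin),
        )

    def window_edited(self, margin: int) -> tuple[int, int]:
        start = max(0, self.replace_start - margin)
        end = min(
            len(self.expected_edit_amplicon),
            self.replace_start + len(self.insert_sequence) + margin,
        )
        return start, end


@dataclasses.dataclass
class OutcomeCall:
    read_id: str
    category: str
    identity_wt: float
    identity_edited: float
    insert_bases_matched: int
    strand: str = "+"
    reason: str = ""


@dataclasses.dataclass
class OutcomeTally:
    counts: dict[str, int]
    n: int  # called reads (UNCALLED excluded)
    n_uncalled: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.n == 0:
            return {c: float("nan") for c in self.counts}
        return {c: v / self.n for c, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": [fr[c] for c in self.counts],
            }
        )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _aligner()


def _best_alignment(ref: str, read: str):
    return _ALIGNER.align(ref, read)[0]


def _identity(alignment, ref: str, read: str) -> float:
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / aligned_cols if aligned_cols else 0.0


def _window_perfect(alignment, ref: str, read: str, window: tuple[int, int]) -> bool:
    """True iff the read matches ``ref`` exactly and gaplessly across
    ``window`` (ref coordinates, half-open)."""
    ws, we = window
    ref_blocks, read_blocks = alignment.aligned
    for (rs, re), (qs, qe) in zip(ref_blocks, read_blocks):
        if rs <= ws and we <= re:
            offset = qs + (ws - rs)
            return read[offset : offset + (we - ws)] == ref[ws:we]
    return False


def _indel_near_cut(alignment, refs: AmpliconRefs, margin: int) -> bool:
    """True iff the wt alignment has a gap overlapping the cut site."""
    ref_blocks, read_blocks = alignment.aligned
    lo, hi = refs.cut_site - margin, refs.cut_site + margin
    for k in range(len(ref_blocks) - 1):
        ref_gap = (ref_blocks[k][1], ref_blocks[k + 1][0])  # deletion span
        read_gap = read_blocks[k + 1][0] - read_blocks[k][1]  # insertion size
        if ref_gap[0] < ref_gap[1]:  # deletion in the read
            if ref_gap[0] <= hi and ref_gap[1] >= lo:
                return True
        if read_gap > 0 and lo <= ref_blocks[k][1] <= hi:  # insertion at this point
            return True
    return False


def _longest_insert_run(read: str, insert: str, minimum: int = 1) -> int:
    for k in range(len(insert), minimum - 1, -1):
        for i in range(len(insert) - k + 1):
            if insert[i : i + k] in read:
                return k
    return 0


def classify_read(
    read_id: str,
    read: str,
    refs: AmpliconRefs,
    params: ClassifyParams = ClassifyParams(),
) -> OutcomeCall:
    """Assign one repair-outcome category to a colony amplicon read."""
    read = read.upper()
    edited = refs.expected_edit_amplicon
    if len(read) < len(refs.wt_amplicon) // 2:
        return OutcomeCall(
            read_id, "UNCALLED", 0.0, 0.0, 0, reason="read shorter than half amplicon"
        )

    # orient by best strand against the edited reference
    fwd_score = _ALIGNER.score(edited, read)
    rev = reverse_complement(read)
    rev_score = _ALIGNER.score(edited, rev)
    if rev_score > fwd_score:
        read, strand = rev, "-"
    else:
        strand = "+"

    aln_wt = _best_alignment(refs.wt_amplicon, read)
    aln_ed = _best_alignment(edited, read)
    id_wt = _identity(aln_wt, refs.wt_amplicon, read)
    id_ed = _identity(aln_ed, edited, read)
    insert_run = _longest_insert_run(read, refs.insert_sequence)

    if max(id_wt, id_ed) < params.identity_floor:
        return OutcomeCall(
            read_id, "UNCALLED", id_wt, id_ed, insert_run, strand,
            reason="identity below floor vs both references",
        )

    if _window_perfect(aln_ed, edited, read, refs.window_edited(params.window_margin)):
        category, reason = "SCARLESS_SSTR", "perfect match across edited window"
    elif insert_run >= params.min_insert_match:
        category, reason = "SCARRED_SSTR", f"{insert_run} contiguous insert bases"
    elif _window_perfect(
        aln_wt, refs.wt_amplicon, read, refs.window_wt(params.window_margin)
    ):
        category, reason = "WT", "matches wt across edited window"
    elif _indel_near_cut(aln_wt, refs, params.cut_site_margin):
        category, reason = "INDEL", "indel overlapping cut site, no insert bases"
    else:
        category, reason = "UNCALLED", "no category fits"
    return OutcomeCall(read_id, category, id_wt, id_ed, insert_run, strand, reason)


def classify_reads(
    reads: list[tuple[str, str]],
    refs: AmpliconRefs,
    params: ClassifyParams = ClassifyParams(),
) -> list[OutcomeCall]:
    return [classify_read(rid, seq, refs, params) for rid, seq in reads]


def tally_outcomes(calls: list[OutcomeCall]) -> OutcomeTally:
    """Per-category counts and fractions; UNCALLED reads are excluded from
    the denominator (only clean colony PCRs are sequenced in practice)."""
    counts = {c: 0 for c in CATEGORIES if c != "UNCALLED"}
    n_uncalled = 0
    for call in calls:
        if call.category == "UNCALLED":
            n_uncalled += 1
        else:
            counts[call.category] += 1
    return OutcomeTally(counts=counts, n=sum(counts.values()), n_uncalled=n_uncalled)


def calls_to_frame(calls: list[OutcomeCall]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in calls])


@dataclasses.dataclass
class PopulationSSTR:
    """Population-level outcome rates: resistance x colony-PCR fractions."""

    scarless_pct: float
    scarred_pct: float
    indel_pct: float
    resistance_pct: float
    n_colonies: int


def population_sstr(
    rapamycin_resistance_pct: float, tally: OutcomeTally
) -> PopulationSSTR:
    """Population-level scarless SSTR percentage (and the scarred/indel
    analogues): resistance % times the per-category colony fraction."""
    if not 0.0 <= rapamycin_resistance_pct <= 100.0:
        raise ValueError("resistance percentage must lie in [0, 100]")
    if tally.n < 1:
        raise ValueError("tally must contain at least one called read")
    fr = tally.fractions
    return PopulationSSTR(
        scarless_pct=rapamycin_resistance_pct * fr["SCARLESS_SSTR"],
        scarred_pct=rapamycin_resistance_pct * fr["SCARRED_SSTR"],
        indel_pct=rapamycin_resistance_pct * fr["INDEL"],
        resistance_pct=rapamycin_resistance_pct,
        n_colonies=tally.n,
    )
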