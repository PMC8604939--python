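"""Editing symmetry up- and downstream of the DNA break.

The discriminator between the two forms of single-strand templated repair:
synthesis-dependent strand annealing (SDSA) predicts that edits encoded on
the 3' homology arm of the ssODN are lost (new DNA synthesis is
unidirectional), while direct single-strand DNA incorporation (ssDI)
predicts symmetric editing on both arms.  Two readouts are analysed:

* SNP panels — per-position editing fractions across biological replicates,
  tested with a one-way ANOVA across positions (post-hoc Tukey HSD attached
  when the ANOVA is significant) and summarized by the 3'/5' arm mean ratio.
* Restriction-digest readouts — site-wise digestion efficiencies from gel
  band intensities, with the 3'-site efficiency normalized to the 5' site
  and a one-sided one-sample t test of the replicate normalized values
  against 1.

Arm identity is orientation-dependent: for a sense-strand ssODN, negative
break-relative positions lie on the 5' homology arm; for an antisense
ssODN, the arms swap.  The position-0 SNP sits on neither arm: it is
excluded from arm means but included in the ANOVA.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclasses.dataclass
class SNPPanelResult:
    """One-way ANOVA over SNP positions plus the arm-asymmetry summary."""

    F: float
    df1: int
    df2: int
    p: float
    position_means: pd.Series
    arm_means: dict[str, float]
    asymmetry_ratio: float
    tukey: Optional[pd.DataFrame] = None
    excluded_positions: tuple[int, ...] = ()


@dataclasses.dataclass
class DigestLane:
    """Band intensities for one restriction digest lane."""

    enzyme: str
    bands: list[tuple[float, float]]  # (fragment length bp, intensity)
    site_rel_position: int  # e.g. -26 or +26
    arm: str  # "5prime" | "3prime"

    def __post_init__(self) -> None:
        if any(i < 0 for _, i in self.bands):
            raise ValueError("band intensities must be nonnegative")
        lengths = [l for l, _ in self.bands]
        if len(lengths) < 2:
            raise ValueError("a digest lane needs at least cut and uncut bands")
        if lengths.count(max(lengths)) != 1:
            raise ValueError("exactly one uncut (full-length) band expected")

    @property
    def uncut_length(self) -> float:
        return max(l for l, _ in self.bands)


@dataclasses.dataclass
class DigestResult:
    """Site-wise digestion efficiencies and the 3'/5' normalized value."""

    efficiency_5prime: float
    efficiency_3prime: float
    normalized_value: float
    t: Optional[float] = None
    df: Optional[int] = None
    p: Optional[float] = None
    alternative: str = "less"


def _arm_of(position: int, orientation: str) -> Optional[str]:
    if position == 0:
        return None
    if orientation == "sense":
        return "5prime" if position < 0 else "3prime"
    if orientation == "antisense":
        return "5prime" if position > 0 else "3prime"
    raise ValueError(f"orientation must be sense/antisense, got {orientation!r}")


def _grouped(estimates: pd.DataFrame) -> dict[int, np.ndarray]:
    required = {"position", "editing"}
    if missing := required - set(estimates.columns):
        raise ValueError(f"estimates table missing columns {sorted(missing)}")
    return {
        int(pos): grp["editing"].to_numpy(dtype=float)
        for pos, grp in estimates.groupby("position")
    }


def asymmetry_ratio(estimates: pd.DataFrame, orientation: str = "sense") -> float:
    """Mean 3'-arm editing divided by mean 5'-arm editing.

    Position 0 belongs to neither arm and is excluded.  Returns NaN when the
    5'-arm mean is zero (undefined, reported as missing).
    """
    groups = _grouped(estimates)
    arms: dict[str, list[float]] = {"5prime": [], "3prime": []}
    for pos, values in groups.items():
        arm = _arm_of(pos, orientation)
        if arm is not None:
            arms[arm].extend(values)
    for arm, vals in arms.items():
        if not vals:
            raise ValueError(f"no positions on the {arm} arm")
    mean5 = float(np.mean(arms["5prime"]))
    mean3 = float(np.mean(arms["3prime"]))
    if mean5 == 0:
        return float("nan")
    return mean3 / mean5


def symmetry_anova(
    estimates: pd.DataFrame,
    orientation: str = "sense",
    alpha: float = DEFAULT_ALPHA,
) -> SNPPanelResult:
    """One-way ANOVA of editing across SNP positions.

    ``estimates`` is a long table with columns ``position``, ``editing``
    (and optionally ``replicate``).  Positions with fewer than two
    replicates are excluded with a warning.  A Tukey HSD pairwise table is
    attached only when the ANOVA is significant at ``alpha``.
    """
    groups = _grouped(estimates)
    excluded = tuple(p for p, v in groups.items() if len(v) < 2)
    if excluded:
        warnings.warn(
            f"positions {excluded} have fewer than 2 replicates and are excluded"
        )
        groups = {p: v for p, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least two positions with >=2 replicates")

    positions = sorted(groups)
    samples = [groups[p] for p in positions]
    F, p = stats.f_oneway(*samples)
    k = len(samples)
    N = sum(len(s) for s in samples)
    if not np.isfinite(F) or not np.isfinite(p):
        # identical groups: zero between- and within-group variance
        F, p = 0.0, 1.0
    elif F < 0:  # numerical round-off on a zero between-group sum of squares
        F = 0.0

    tukey = None
    if p < alpha:
        res = stats.tukey_hsd(*samples)
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "position_a": positions[i],
                        "position_b": positions[j],
                        "mean_diff": float(
                            np.mean(samples[i]) - np.mean(samples[j])
                        ),
                        "p_adj": float(res.pvalue[i, j]),
                    }
                )
        tukey = pd.DataFrame(rows)

    position_means = pd.Series(
        {p: float(np.mean(groups[p])) for p in positions}, name="editing"
    )
    arm_values: dict[str, list[float]] = {"5prime": [], "3prime": []}
    for pos in positions:
        arm = _arm_of(pos, orientation)
        if arm is not None:
            arm_values[arm].extend(groups[pos])
    arm_means = {
        arm: float(np.mean(v)) if v else float("nan")
        for arm, v in arm_values.items()
    }
    ratio = (
        arm_means["3prime"] / arm_means["5prime"]
        if arm_means.get("5prime") not in (0.0, float("nan"))
        and arm_values["5prime"]
        and arm_values["3prime"]
        else float("nan")
    )
    return SNPPanelResult(
        F=float(F),
        df1=k - 1,
        df2=N - k,
        p=float(p),
        position_means=position_means,
        arm_means=arm_means,
        asymmetry_ratio=ratio,
        tukey=tukey,
        excluded_positions=excluded,
    )


# ---------------------------------------------------------------------------
# restriction digests


def digestion_efficiency(lane: DigestLane, mass_correction: str = "length") -> float:
    """Fraction of template cut, from band intensities.

    With ``mass_correction="length"`` each band intensity is divided by its
    fragment length before summing (intercalating-stain intensity is mass-
    proportional, so molar comparison needs length normalization); the cut
    molar amount is the mean over cut fragments.  ``"none"`` uses raw
    intensities.
    """
    uncut_len = lane.uncut_length
    cut_bands = [(l, i) for l, i in lane.bands if l != uncut_len]
    uncut_intensity = sum(i for l, i in lane.bands if l == uncut_len)
    total_intensity = sum(i for _, i in lane.bands)
    if total_intensity == 0:
        raise ValueError(f"lane {lane.enzyme}: total intensity is zero")
    if mass_correction == "length":
        cut_molar = float(np.mean([i / l for l, i in cut_bands]))
        uncut_molar = uncut_intensity / uncut_len
    elif mass_correction == "none":
        cut_molar = sum(i for _, i in cut_bands)
        uncut_molar = uncut_intensity
    else:
        raise ValueError(f"mass_correction must be 'length' or 'none'")
    return cut_molar / (cut_molar + uncut_molar)


def digest_normalized(
    lane5: DigestLane, lane3: DigestLane, mass_correction: str = "length"
) -> DigestResult:
    """3'-site efficiency normalized to the 5' site for one replicate."""
    e5 = digestion_efficiency(lane5, mass_correction)
    e3 = digestion_efficiency(lane3, mass_correction)
    if e5 == 0:
        raise ValueError("5' site efficiency is zero; normalized value undefined")
    return DigestResult(e5, e3, e3 / e5)


def digest_normalized_replicates(
    pairs: list[tuple[DigestLane, DigestLane]],
    mass_correction: str = "length",
    alternative: str = "less",
) -> tuple[pd.DataFrame, DigestResult]:
    """Normalized 3'/5' values across replicates plus a one-sided one-sample
    t test against 1 (H0: the 3' site is digested as efficiently as the 5')."""
    results = [digest_normalized(l5, l3, mass_correction) for l5, l3 in pairs]
    values = np.array([r.normalized_value for r in results])
    table = pd.DataFrame(
        {
            "replicate": np.arange(1, len(results) + 1),
            "efficiency_5prime": [r.efficiency_5prime for r in results],
            "efficiency_3prime": [r.efficiency_3prime for r in results],
            "normalized_value": values,
        }
    )
    summary = DigestResult(
        efficiency_5prime=float(np.mean(table["efficiency_5prime"])),
        efficiency_3prime=float(np.mean(table["efficiency_3prime"])),
        normalized_value=float(np.mean(values)),
    )
    if len(values) >= 2 and np.std(values, ddof=1) > 0:
        t, p = stats.ttest_1samp(values, 1.0, alternative=alternative)
        summary.t = float(t)
        summary.df = len(values) - 1
        summary.p = float(p)
        summary.alternative = alternative
    return table, summary


def lanes_from_table(df: pd.DataFrame) -> list[tuple[DigestLane, DigestLane]]:
    """Build (5' lane, 3' lane) replicate pairs from a long band table with
    columns replicate, site, enzyme, fragment_length, intensity."""
    pairs = []
    for rep, grp in df.groupby("replicate"):
        lanes = {}
        for site, sgrp in grp.groupby("site"):
            rel = -26 if site == "5prime" else 26
            lanes[site] = DigestLane(
                enzyme=str(sgrp["enzyme"].iloc[0]),
                bands=list(
                    zip(
                        sgrp["fragment_length"].astype(float),
                        sgrp["intensity"].astype(float),
                    )
                ),
                site_rel_position=rel,
                arm=str(site),
            )
        pairs.append((lanes["5prime"], lanes["3prime"]))
    return pairs
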