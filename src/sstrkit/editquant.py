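"""Control-normalized SNP editing quantification from Sanger traces.

The measurement problem: after delivering a nuclease plus an ssODN repair
template carrying single-nucleotide changes, the fraction of edited alleles
in a cell population shows up as a secondary peak in the Sanger chromatogram
of the bulk PCR product.  The naive peak-height ratio

    H(snp) / (H(snp) + H(wt))

is biased, because Sanger peak heights depend on local sequence context.
The dual-control normalization implemented here cancels that bias using two
matched control chromatograms sequenced over the same target: a negative
control (pure wild-type sequence) and, for each SNP, a positive control
(pure SNP sequence).  Per chromatogram, every peak height is first divided
by the height of the anchor base (an 'A' at break-relative position -42)
within the same chromatogram, converting absolute heights to relative ones.
The sample's relative wt peak is then divided by the negative control's
relative wt peak at the same position; the sample's relative SNP peak by the
positive control's relative SNP peak.  The editing fraction is

    editing = norm_snp / (norm_snp + norm_wt).

Detection of a SNP above background is a separate question answered by a
per-base null model of background percent signal: a zero-adjusted gamma (or
lognormal) fitted to the non-consensus channel signals inside the analysis
window, with the tail probability of the observed SNP percent signal as the
detection p-value (alpha = 0.05 by convention).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import stats

from .traceio import (
    BASES,
    DEFAULT_WINDOW,
    AnalysisWindow,
    TargetMap,
    Trace,
    percent_signal,
)

DEFAULT_ALPHA = 0.05


class AnchorError(ValueError):
    """Anchor base missing, wrong, or with zero peak height."""


class ControlError(ValueError):
    """A control chromatogram is uninformative for the requested SNP."""


@dataclasses.dataclass(frozen=True)
class SNPSpec:
    """A single nucleotide change at a break-relative position."""

    rel_position: int
    wt_base: str
    snp_base: str

    def __post_init__(self) -> None:
        for b in (self.wt_base, self.snp_base):
            if b not in BASES:
                raise ValueError(f"invalid base {b!r}")
        if self.wt_base == self.snp_base:
            raise ValueError("SNP base must differ from wt base")


@dataclasses.dataclass(frozen=True)
class BaseNull:
    """Fitted null distribution of background percent signal for one base."""

    base: str
    zero_prob: float
    shape: float
    scale: float
    model_mu: float
    filliben: float
    n: int
    family: str = "gamma"
    degenerate: bool = False

    def continuous(self):
        if self.family == "gamma":
            return stats.gamma(self.shape, scale=self.scale)
        if self.family == "lognormal":
            return stats.lognorm(self.shape, scale=self.scale)
        raise ValueError(f"unknown family {self.family!r}")

    def sf(self, x: float) -> float:
        """P(background percent signal >= x)."""
        if x <= 0:
            return 1.0
        if self.degenerate:
            return 0.0
        return float((1.0 - self.zero_prob) * self.continuous().sf(x))


@dataclasses.dataclass
class NoiseModel:
    """Per-base background null models fitted over an analysis window."""

    per_base: dict[str, BaseNull]
    fit_window: AnalysisWindow
    family: str = "gamma"

    @property
    def model_mu(self) -> dict[str, float]:
        return {b: m.model_mu for b, m in self.per_base.items()}

    @property
    def filliben(self) -> dict[str, float]:
        return {b: m.filliben for b, m in self.per_base.items()}


@dataclasses.dataclass
class ControlSet:
    """Negative (wt) and per-SNP positive control chromatograms."""

    negative: Trace
    positives: dict[SNPSpec, Trace]


@dataclasses.dataclass
class EditingEstimate:
    """Normalized editing fraction for one SNP with all intermediates."""

    snp: SNPSpec
    editing_fraction: float
    detection_p: float
    r_sample_wt: float
    r_sample_snp: float
    r_neg_wt: float
    r_pos_snp: float
    norm_wt: float
    norm_snp: float
    naive_fraction: float  # un-normalized peak ratio

    def to_row(self) -> dict:
        """One output row, mirroring the spreadsheet column names."""
        return {
            "position": self.snp.rel_position,
            "WT_base": self.snp.wt_base,
            "SNP_base": self.snp.snp_base,
            "WT base (norm_neg)": self.norm_wt,
            "SNP base (norm_pos)": self.norm_snp,
            "Editing (norm)": self.editing_fraction,
            "Editing (EditR)": self.naive_fraction,
            "detection_p": self.detection_p,
        }


@dataclasses.dataclass
class QualityMetrics:
    """average percent signal, model mu, Filliben's correlation."""

    average_percent_signal: float
    model_mu: dict[str, float]
    filliben: dict[str, float]


# ---------------------------------------------------------------------------
# noise model


def _background_values(trace: Trace, window: AnalysisWindow, base: str) -> np.ndarray:
    positions = window.positions(trace)
    vals = []
    for pos in positions:
        if trace.called_base(pos) == base:
            continue
        frac = percent_signal(trace, pos)
        v = frac[BASES.index(base)]
        if not np.isnan(v):
            vals.append(v)
    return np.asarray(vals, dtype=float)


def filliben_correlation(values: np.ndarray, dist) -> float:
    """Probability-plot correlation coefficient (order-statistic medians).

    Ties at zero are excluded upstream; returns NaN for fewer than 3 points.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n < 3:
        return float("nan")
    m = np.empty(n)
    m[0] = 1.0 - 0.5 ** (1.0 / n)
    m[-1] = 0.5 ** (1.0 / n)
    i = np.arange(2, n)
    m[1:-1] = (i - 0.3175) / (n + 0.365)
    theor = dist.ppf(m)
    if np.std(theor) == 0 or np.std(values) == 0:
        return float("nan")
    return float(np.corrcoef(theor, values)[0, 1])


def fit_noise_model(
    trace: Trace,
    window: AnalysisWindow = DEFAULT_WINDOW,
    family: str = "gamma",
) -> NoiseModel:
    """Fit per-base null distributions to background percent signals.

    The zero mass is the empirical fraction of exact zeros; the continuous
    part is fitted by maximum likelihood to the nonzero values (gamma by
    default, lognormal as fallback/alternative).  A base whose background is
    identically zero yields a degenerate point-mass model.
    """
    if len(window.positions(trace)) < 50:
        raise ValueError("analysis window must contain at least 50 positions")
    per_base = {}
    for base in BASES:
        values = _background_values(trace, window, base)
        n = len(values)
        nonzero = values[values > 0]
        zero_prob = 1.0 - len(nonzero) / n if n else 1.0
        if len(nonzero) < 3:
            per_base[base] = BaseNull(
                base, 1.0, float("nan"), float("nan"), 0.0, float("nan"), n,
                family, degenerate=True,
            )
            continue
        if np.ptp(nonzero) == 0:
            # constant background: point mass at that value
            c = float(nonzero[0])
            per_base[base] = BaseNull(
                base, zero_prob, float("nan"), c,
                (1.0 - zero_prob) * c, float("nan"), n, family, degenerate=True,
            )
            continue
        shape, scale, dist = _fit_continuous(nonzero, family)
        mu = (1.0 - zero_prob) * float(dist.mean())
        fill = filliben_correlation(nonzero, dist)
        per_base[base] = BaseNull(base, zero_prob, shape, scale, mu, fill, n, family)
    return NoiseModel(per_base=per_base, fit_window=window, family=family)


def _fit_continuous(values: np.ndarray, family: str):
    if family == "gamma":
        try:
            shape, _, scale = stats.gamma.fit(values, floc=0)
            if np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0:
                return float(shape), float(scale), stats.gamma(shape, scale=scale)
        except Exception:
            pass
        family = "lognormal"  # fallback when the gamma fit fails
    if family == "lognormal":
        s, _, scale = stats.lognorm.fit(values, floc=0)
        return float(s), float(scale), stats.lognorm(s, scale=scale)
    raise ValueError(f"unknown noise family {family!r}")


def snp_detection_p(
    model: NoiseModel, trace: Trace, position: int, base: str
) -> float:
    """Tail probability of the observed percent signal under the null.

    ``position`` is a 1-based trace position.  Raises if ``base`` is the
    called consensus there (the null describes background channels only).
    """
    if trace.called_base(position) == base:
        raise ValueError(
            f"base {base} is the called consensus at position {position}; "
            "detection p is undefined for the consensus channel"
        )
    obs = percent_signal(trace, position)[BASES.index(base)]
    if np.isnan(obs):
        return float("nan")
    return model.per_base[base].sf(float(obs))


def quality_metrics(
    trace: Trace, model: NoiseModel, window: AnalysisWindow = DEFAULT_WINDOW
) -> QualityMetrics:
    """Average background percent signal plus the fitted model summaries."""
    noise_vals = []
    for pos in window.positions(trace):
        frac = percent_signal(trace, pos)
        if np.any(np.isnan(frac)):
            continue
        called = trace.called_base(pos)
        for b in BASES:
            if b != called:
                noise_vals.append(frac[BASES.index(b)])
    avg = float(np.mean(noise_vals)) if noise_vals else float("nan")
    return QualityMetrics(
        average_percent_signal=avg,
        model_mu=model.model_mu,
        filliben=model.filliben,
    )


# ---------------------------------------------------------------------------
# editing fraction


def _relative_peak(trace: Trace, tmap: TargetMap, rel_pos: int, base: str) -> float:
    """Peak height at a break-relative position, divided by the anchor peak
    within the same chromatogram."""
    anchor_rel, anchor_base = tmap.anchor
    anchor_pos = tmap.rel_to_trace(anchor_rel)
    expected = tmap.base_on_trace(anchor_base)
    if trace.called_base(anchor_pos) != expected:
        raise AnchorError(
            f"trace {trace.name!r}: anchor base at relative position "
            f"{anchor_rel} is {trace.called_base(anchor_pos)!r}, "
            f"expected {expected!r}"
        )
    anchor_h = trace.height(anchor_pos, expected)
    if anchor_h <= 0:
        raise AnchorError(f"trace {trace.name!r}: anchor peak height is zero")
    pos = tmap.rel_to_trace(rel_pos)
    return trace.height(pos, tmap.base_on_trace(base)) / anchor_h


def editing_fraction(
    sample: Trace,
    controls: ControlSet,
    snp: SNPSpec,
    tmap: TargetMap,
    *,
    window: AnalysisWindow = DEFAULT_WINDOW,
    model: Optional[NoiseModel] = None,
) -> EditingEstimate:
    """Dual-control normalized editing fraction for one SNP.

    ``tmap`` must map the shared target in all three chromatograms (the
    sample and both controls are sequenced over the same locus with the same
    primer, so one placement serves all, as long as each trace is laid out
    identically; for independently laid-out traces, locate the target per
    trace and use :func:`editing_fraction_mapped`).
    """
    return editing_fraction_mapped(
        sample, tmap, controls.negative, tmap,
        controls.positives[snp], tmap, snp, window=window, model=model,
    )


def editing_fraction_mapped(
    sample: Trace,
    sample_map: TargetMap,
    negative: Trace,
    negative_map: TargetMap,
    positive: Trace,
    positive_map: TargetMap,
    snp: SNPSpec,
    *,
    window: AnalysisWindow = DEFAULT_WINDOW,
    model: Optional[NoiseModel] = None,
) -> EditingEstimate:
    """As :func:`editing_fraction` with per-trace target placements."""
    r_sample_wt = _relative_peak(sample, sample_map, snp.rel_position, snp.wt_base)
    r_sample_snp = _relative_peak(sample, sample_map, snp.rel_position, snp.snp_base)
    r_neg_wt = _relative_peak(negative, negative_map, snp.rel_position, snp.wt_base)
    r_pos_snp = _relative_peak(positive, positive_map, snp.rel_position, snp.snp_base)
    if r_neg_wt <= 0:
        raise ControlError(
            f"negative control uninformative: wt relative peak is 0 at "
            f"position {snp.rel_position}"
        )
    if r_pos_snp <= 0:
        raise ControlError(
            f"positive control uninformative: SNP relative peak is 0 at "
            f"position {snp.rel_position}"
        )
    norm_wt = r_sample_wt / r_neg_wt
    norm_snp = r_sample_snp / r_pos_snp
    editing = norm_snp / (norm_snp + norm_wt)

    pos = sample_map.rel_to_trace(snp.rel_position)
    snp_channel = sample_map.base_on_trace(snp.snp_base)
    wt_channel = sample_map.base_on_trace(snp.wt_base)
    h_snp = sample.height(pos, snp_channel)
    h_wt = sample.height(pos, wt_channel)
    naive = h_snp / (h_snp + h_wt) if (h_snp + h_wt) > 0 else float("nan")

    if sample.called_base(pos) == snp_channel:
        detection_p = float("nan")  # SNP channel is the consensus here
    else:
        if model is None:
            model = fit_noise_model(sample, window)
        detection_p = snp_detection_p(model, sample, pos, snp_channel)

    return EditingEstimate(
        snp=snp,
        editing_fraction=editing,
        detection_p=detection_p,
        r_sample_wt=r_sample_wt,
        r_sample_snp=r_sample_snp,
        r_neg_wt=r_neg_wt,
        r_pos_snp=r_pos_snp,
        norm_wt=norm_wt,
        norm_snp=norm_snp,
        naive_fraction=naive,
    )
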