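"""Editing-efficiency statistics for the plate-count (rapamycin) assay.

Efficiency of one biological replicate is the volume-normalized ratio of
resistant to total colony-forming units:

    efficiency % = 100 * (c_sel / v_sel) / (c_ns / v_ns)

with c = colony counts and v = plated volumes of the selective and
non-selective plates.  Noisy counts can push efficiencies above 100%; they
are never clipped in statistics.

The statistical protocol around the efficiencies:

* Tukey's fences outlier flagging with spreadsheet-style inclusive
  (linearly interpolated) quartiles, applied only to experiments with at
  least ``min_n`` (default 5) replicates; flagged values are retained in
  all downstream analyses.
* Dunnett's many-to-one comparison of each treatment against a control,
  with the adjusted p computed from the equicorrelated multivariate-t
  distribution implied by the group sizes.
* Games-Howell pairwise comparisons (Welch standard errors and degrees of
  freedom, studentized-range "Tukey corrected" p values) for families with
  strongly unequal variances.
* Classical one-way ANOVA, Levene (mean-centred by default), Shapiro-Wilk
  and one/two-sample t tests.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GroupDict = dict[str, np.ndarray]


@dataclasses.dataclass(frozen=True)
class PlateCountRecord:
    """Paired selective/non-selective colony counts for one replicate."""

    replicate: str
    genotype: str
    colonies_nonselective: int
    volume_nonselective: float
    colonies_selective: int
    volume_selective: float

    def __post_init__(self) -> None:
        if self.colonies_nonselective < 0 or self.colonies_selective < 0:
            raise ValueError("colony counts must be nonnegative")
        if self.volume_nonselective <= 0 or self.volume_selective <= 0:
            raise ValueError("plated volumes must be positive")


@dataclasses.dataclass(frozen=True)
class OutlierRule:
    """Tukey's fences with inclusive (linear-interpolation) quartiles."""

    k: float = 1.5
    quartile_method: str = "inclusive"
    min_n: int = 5


@dataclasses.dataclass
class TestResult:
    statistic: float
    df: float | tuple
    p: float
    alternative: str = "two-sided"
    method: str = ""


def editing_efficiency(
    record: PlateCountRecord | pd.DataFrame,
) -> float | pd.Series:
    """Editing efficiency in percent; NaN where the non-selective count is 0.

    Accepts a single :class:`PlateCountRecord` or a DataFrame with its
    column layout (vectorized).
    """
    if isinstance(record, pd.DataFrame):
        sel_rate = record["colonies_selective"] / record["volume_selective"]
        ns_rate = record["colonies_nonselective"] / record["volume_nonselective"]
        out = 100.0 * sel_rate / ns_rate
        out[record["colonies_nonselective"] == 0] = np.nan
        return out
    if record.colonies_nonselective == 0:
        return float("nan")
    sel_rate = record.colonies_selective / record.volume_selective
    ns_rate = record.colonies_nonselective / record.volume_nonselective
    return 100.0 * sel_rate / ns_rate


def flag_outliers(
    values: Sequence[float], rule: OutlierRule = OutlierRule()
) -> np.ndarray:
    """Boolean flags per value; no flags when fewer than ``min_n`` values.

    Fences are [Q1 - k*IQR, Q3 + k*IQR] with quartiles from linear
    interpolation at p = (i-1)/(n-1) (the spreadsheet "inclusive" method).
    Flagged values are informational only: callers retain them.
    """
    values = np.asarray(values, dtype=float)
    if rule.quartile_method != "inclusive":
        raise ValueError("only the inclusive quartile method is supported")
    flags = np.zeros(len(values), dtype=bool)
    finite = np.isfinite(values)
    if finite.sum() < rule.min_n:
        return flags
    q1, q3 = np.quantile(values[finite], [0.25, 0.75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - rule.k * iqr, q3 + rule.k * iqr
    flags[finite] = (values[finite] < lo) | (values[finite] > hi)
    return flags


def summarize_groups(df: pd.DataFrame, value: str = "efficiency_pct",
                     group: str = "genotype",
                     rule: OutlierRule = OutlierRule()) -> pd.DataFrame:
    """Per-group mean, SD, n and outlier count (outliers retained)."""
    rows = []
    for g, grp in df.groupby(group, sort=False):
        vals = grp[value].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        flags = flag_outliers(vals, rule)
        rows.append(
            {
                group: g,
                "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                "n": len(vals),
                "n_outliers": int(flags.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dunnett many-to-one


def _as_groups(groups: GroupDict) -> GroupDict:
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def _dunnett_corr(n0: int, ns: np.ndarray) -> np.ndarray:
    lam = np.sqrt(ns / (ns + n0))
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return corr


def _mvt_rectangle(t: float, corr: np.ndarray, df: int) -> float:
    """P(|T_j| <= t for all j) for a central multivariate t."""
    k = corr.shape[0]
    mvt = stats.multivariate_t(loc=np.zeros(k), shape=corr, df=df)
    return float(
        mvt.cdf(
            np.full(k, t),
            lower_limit=np.full(k, -t),
            random_state=np.random.default_rng(0),
        )
    )


def compare_to_control(
    groups: GroupDict, control_label: str
) -> pd.DataFrame:
    """Dunnett's test of every treatment group against the control.

    Pooled variance across all groups; two-sided adjusted p from the
    multivariate-t distribution with the equicorrelation structure implied
    by the group sizes.  With a single treatment this reduces exactly to
    the pooled two-sample t test.
    """
    groups = _as_groups(groups)
    if control_label not in groups:
        raise ValueError(f"control label {control_label!r} absent from groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs at least 2 observations")
    control = groups[control_label]
    treatments = {g: v for g, v in groups.items() if g != control_label}
    if not treatments:
        raise ValueError("need at least one treatment group")

    all_vals = list(groups.values())
    n_groups = len(all_vals)
    N = sum(len(v) for v in all_vals)
    df = N - n_groups
    s2 = sum((len(v) - 1) * np.var(v, ddof=1) for v in all_vals) / df
    n0 = len(control)
    labels = list(treatments)
    ns = np.array([len(treatments[g]) for g in labels])
    t_stats = np.array(
        [
            (np.mean(treatments[g]) - np.mean(control))
            / np.sqrt(s2 * (1 / len(treatments[g]) + 1 / n0))
            for g in labels
        ]
    )
    if len(labels) == 1:
        p_adj = [2 * stats.t.sf(abs(t_stats[0]), df)]
    else:
        corr = _dunnett_corr(n0, ns)
        p_adj = [1.0 - _mvt_rectangle(abs(t), corr, df) for t in t_stats]
    return pd.DataFrame(
        {
            "comparison": [f"{g} - {control_label}" for g in labels],
            "group": labels,
            "estimate": [
                float(np.mean(treatments[g]) - np.mean(control)) for g in labels
            ],
            "statistic": t_stats,
            "df": df,
            "p_adj": np.clip(p_adj, 0.0, 1.0),
            "method": "dunnett",
        }
    )


def dunnett_critical_value(
    n_control: int, n_treatments: Sequence[int], alpha: float = 0.05
) -> float:
    """Two-sided critical value c with P(max_j |T_j| > c) = alpha under the
    global null, for the group sizes given (useful for error-rate
    simulations: reject iff max |t| exceeds c)."""
    ns = np.asarray(list(n_treatments))
    df = int(n_control + ns.sum() - (len(ns) + 1))
    corr = _dunnett_corr(n_control, ns)
    from scipy.optimize import brentq

    return float(
        brentq(lambda c: _mvt_rectangle(c, corr, df) - (1 - alpha), 1.0, 12.0,
               xtol=1e-5)
    )


# ---------------------------------------------------------------------------
# Games-Howell


def pairwise_unequal_var(
    groups: GroupDict, control_label: Optional[str] = None
) -> pd.DataFrame:
    """Games-Howell pairwise comparisons.

    Welch-type standard errors and Welch-Satterthwaite degrees of freedom
    per pair; the adjusted p uses the studentized-range distribution with
    the total number of groups ("Tukey corrected").  When ``control_label``
    is given only control-vs-other pairs are reported (the family size, and
    hence the correction, still counts every group).  Groups with fewer
    than 2 observations are excluded with a warning.
    """
    import warnings

    groups = _as_groups(groups)
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        warnings.warn(f"excluding groups with <2 observations: {small}")
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least two groups with >=2 observations")
    if control_label is not None and control_label not in groups:
        raise ValueError(f"control label {control_label!r} absent from groups")

    labels = list(groups)
    k = len(labels)
    stats_by_group = {
        g: (np.mean(v), np.var(v, ddof=1), len(v)) for g, v in groups.items()
    }
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            if control_label is not None and control_label not in (a, b):
                continue
            ma, va, na = stats_by_group[a]
            mb, vb, nb = stats_by_group[b]
            se2 = va / na + vb / nb
            if se2 == 0:
                t, df, p = 0.0, float(na + nb - 2), 1.0
            else:
                t = (ma - mb) / np.sqrt(se2)
                df = se2**2 / (
                    (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
                )
                q = abs(t) * np.sqrt(2.0)
                p = float(stats.studentized_range.sf(q, k, df))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "estimate": float(ma - mb),
                    "se": float(np.sqrt(se2 / 2)),
                    "statistic": float(t),
                    "df": float(df),
                    "p_adj": min(max(p, 0.0), 1.0),
                    "method": "games-howell",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classical tests


def basic_tests(data, test: str, **kwargs) -> TestResult:
    """Dispatch to the classical tests used around the assay.

    ``test`` is one of ``anova`` (data: sequence of group arrays),
    ``levene`` (idem; ``center="mean"`` by default), ``shapiro`` (one
    array), ``t_one_sample`` (one array; ``popmean``, ``alternative``),
    ``t_two_sample`` (pair of arrays; ``equal_var=True``,
    ``alternative``).
    """
    if test == "anova":
        samples = [np.asarray(g, dtype=float) for g in data]
        F, p = stats.f_oneway(*samples)
        k, N = len(samples), sum(len(s) for s in samples)
        if not np.isfinite(F) or not np.isfinite(p):
            F, p = 0.0, 1.0
        elif F < 0:  # round-off on a zero between-group sum of squares
            F = 0.0
        return TestResult(float(F), (k - 1, N - k), float(p), method="anova")
    if test == "levene":
        samples = [np.asarray(g, dtype=float) for g in data]
        center = kwargs.get("center", "mean")
        W, p = stats.levene(*samples, center=center)
        k, N = len(samples), sum(len(s) for s in samples)
        return TestResult(
            float(W), (k - 1, N - k), float(p), method=f"levene[{center}]"
        )
    if test == "shapiro":
        values = np.asarray(data, dtype=float)
        if np.ptp(values) == 0:
            raise ValueError("Shapiro-Wilk is undefined for constant data")
        W, p = stats.shapiro(values)
        return TestResult(float(W), len(values), float(p), method="shapiro")
    if test == "t_one_sample":
        values = np.asarray(data, dtype=float)
        alternative = kwargs.get("alternative", "two-sided")
        t, p = stats.ttest_1samp(values, kwargs["popmean"], alternative=alternative)
        return TestResult(
            float(t), len(values) - 1, float(p), alternative, "t_one_sample"
        )
    if test == "t_two_sample":
        a, b = (np.asarray(g, dtype=float) for g in data)
        alternative = kwargs.get("alternative", "two-sided")
        equal_var = kwargs.get("equal_var", True)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
        df = len(a) + len(b) - 2 if equal_var else None
        if df is None:
            va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
            se2 = va / len(a) + vb / len(b)
            df = se2**2 / (
                (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
            )
        return TestResult(float(t), float(df), float(p), alternative, "t_two_sample")
    raise ValueError(f"unknown test {test!r}")


def groups_from_frame(
    df: pd.DataFrame, value: str = "efficiency_pct", group: str = "genotype"
) -> GroupDict:
    """Group label -> value array, dropping non-finite values (e.g. missing
    selective plates)."""
    out = {}
    for g, grp in df.groupby(group, sort=False):
        vals = grp[value].to_numpy(dtype=float)
        out[str(g)] = vals[np.isfinite(vals)]
    return out
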