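"""Normality-gated statistical testing and fold-change normalization.

Group comparisons are routed through a Shapiro–Wilk gate at
``NORMALITY_ALPHA`` (0.01): if every group is consistent with normality
the parametric branch is used
(two-tailed unpaired t-test for two groups, one-way ANOVA for three or
more), otherwise the rank-based branch (two-sided Mann–Whitney U,
Kruskal–Wallis). Significance stars follow the usual convention
(* p <= 0.05, ** p <= 0.01, *** p <= 0.001, **** p <= 0.0001, else ns).

Also here: box-and-whisker summaries (median, quartile box, 5th/95th
percentile whiskers), densitometry fold-change normalization against a
loading control, and qPCR relative quantification by 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestResult",
    "p_to_stars",
    "route_two_group_test",
    "route_multi_group_test",
    "box_whisker_summary",
    "normalize_fold_change",
    "qpcr_relative_quantification",
]

# Gate level for the Shapiro–Wilk normality screen. Every group must pass
# for the parametric branch. 0.01 keeps the probability of spuriously
# demoting genuinely Gaussian group pairs to the rank branch below ~2%
# (at 0.05 it would be ~10%, since each group is screened separately),
# while heavy-tailed or skewed samples of realistic size still fail the
# screen essentially always.
NORMALITY_ALPHA = 0.01
STAR_BREAKPOINTS = (0.0001, 0.001, 0.01, 0.05)


@dataclass
class GroupSample:
    """A labelled sample of per-cell (or per-replicate) measurements."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 3:
            raise ValueError(f"group {self.label!r} needs >= 3 one-dimensional values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    stars: str
    gate_decision: str  # "normal" | "non-normal"
    shapiro_p: tuple[float, ...] = ()


def p_to_stars(p: float) -> str:
    """Monotone step function of p with breakpoints at 0.05/0.01/0.001/0.0001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _gate(groups: list[GroupSample]) -> tuple[str, tuple[float, ...]]:
    """Shapiro–Wilk on every group; parametric only if all pass at alpha."""
    ps = tuple(float(sps.shapiro(g.values).pvalue) for g in groups)
    decision = "normal" if all(p > NORMALITY_ALPHA for p in ps) else "non-normal"
    return decision, ps


def route_two_group_test(
    a: GroupSample, b: GroupSample, *, equal_var: bool = False
) -> TestResult:
    """Shapiro–Wilk-gated two-group comparison.

    Normal/normal routes to the two-tailed unpaired t-test (Welch by
    default); anything else routes to the two-sided Mann–Whitney U, whose
    implementation handles ties via the normal approximation with tie
    correction. Identical constant samples are a degenerate no-signal case
    and return p = 1.
    """
    gate, shapiro_ps = _gate_or_degenerate([a, b])
    if gate == "degenerate":
        return TestResult("degenerate", 0.0, 1.0, "ns", "non-normal", shapiro_ps)
    if gate == "normal":
        res = sps.ttest_ind(a.values, b.values, equal_var=equal_var)
        name = "t-test" if equal_var else "welch-t-test"
    else:
        res = sps.mannwhitneyu(a.values, b.values, alternative="two-sided")
        name = "mann-whitney-u"
    p = float(res.pvalue)
    return TestResult(name, float(res.statistic), p, p_to_stars(p), gate, shapiro_ps)


def _gate_or_degenerate(groups: list[GroupSample]) -> tuple[str, tuple[float, ...]]:
    # Shapiro-Wilk is undefined on constant data; constant groups force the
    # rank branch, and all-identical data short-circuits to p = 1.
    if all(np.ptp(g.values) == 0 for g in groups):
        vals = [g.values[0] for g in groups]
        if len(set(vals)) == 1:
            return "degenerate", ()
    if any(np.ptp(g.values) == 0 for g in groups):
        return "non-normal", ()
    return _gate(groups)


def route_multi_group_test(groups: list[GroupSample]) -> TestResult:
    """Gated omnibus test across >= 3 groups: one-way ANOVA or Kruskal–Wallis."""
    if len(groups) < 3:
        raise ValueError("multi-group routing requires at least 3 groups")
    gate, shapiro_ps = _gate_or_degenerate(groups)
    if gate == "degenerate":
        return TestResult("degenerate", 0.0, 1.0, "ns", "non-normal", shapiro_ps)
    arrays = [g.values for g in groups]
    if gate == "normal":
        res = sps.f_oneway(*arrays)
        name = "one-way-anova"
    else:
        res = sps.kruskal(*arrays)
        name = "kruskal-wallis"
    p = float(res.pvalue)
    return TestResult(name, float(res.statistic), p, p_to_stars(p), gate, shapiro_ps)


def box_whisker_summary(groups: list[GroupSample]) -> pd.DataFrame:
    """Median, quartile box bounds and 5th/95th-percentile whiskers per group."""
    rows = []
    for g in groups:
        q = np.percentile(g.values, [5, 25, 50, 75, 95])
        rows.append(
            {
                "group": g.label,
                "n": g.n,
                "whisker_lo_p5": q[0],
                "box_lo_p25": q[1],
                "median": q[2],
                "box_hi_p75": q[3],
                "whisker_hi_p95": q[4],
            }
        )
    return pd.DataFrame(rows)


def normalize_fold_change(
    table: pd.DataFrame,
    *,
    value_col: str = "value",
    reference_col: str = "reference",
    condition_col: str = "condition",
    control_condition: str,
) -> pd.DataFrame:
    """Densitometry-style fold change against a loading control.

    Each row's ``value`` is divided by its ``reference`` (loading-control)
    signal, then by the control condition's normalized value, so the
    control condition maps to exactly 1. Row order is irrelevant.
    """
    for col in (value_col, reference_col, condition_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if (table[reference_col] <= 0).any():
        raise ValueError("reference (loading control) values must be positive")
    out = table.copy()
    norm = out[value_col] / out[reference_col]
    ctrl = norm[out[condition_col] == control_condition]
    if ctrl.empty:
        raise ValueError(f"control condition {control_condition!r} not present")
    out["fold_change"] = norm / ctrl.mean()
    return out


def qpcr_relative_quantification(
    ct: pd.DataFrame,
    *,
    target_col: str = "ct_target",
    reference_col: str = "ct_reference",
    condition_col: str = "condition",
    control_condition: str,
) -> pd.DataFrame:
    """Relative quantification by the 2^(-ddCt) method.

    ``dCt = Ct_target - Ct_reference`` per replicate; ``ddCt`` is taken
    relative to the control condition's mean dCt; fold change is
    ``2 ** (-ddCt)``, so the control condition averages to fold 1 on the
    dCt scale.
    """
    for col in (target_col, reference_col, condition_col):
        if col not in ct.columns:
            raise ValueError(f"missing column {col!r}")
    if not np.all(np.isfinite(ct[[target_col, reference_col]].to_numpy())):
        raise ValueError("Ct values must be finite")
    out = ct.copy()
    out["d_ct"] = out[target_col] - out[reference_col]
    ctrl = out.loc[out[condition_col] == control_condition, "d_ct"]
    if ctrl.empty:
        raise ValueError(f"control condition {control_condition!r} not present")
    out["dd_ct"] = out["d_ct"] - ctrl.mean()
    out["fold_change"] = 2.0 ** (-out["dd_ct"])
    return out
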