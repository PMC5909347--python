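"""Normality-gated two-group statistics and correlation analyses.

The cohort workflow compares co-transplanted against non-co-transplanted
tumours, separately per cell line and with both lines merged: each
sample first passes a Kolmogorov-Smirnov normality gate (Lilliefors
corrected, since the normal's moments are estimated from the sample);
if both groups look normal a two-sample t test fires, otherwise the
Mann-Whitney U test.  Spearman rank correlations relate imaging readouts
to the histological reference, with an explicit exclusion mechanism for
the flagged 100%-necrosis outlier.  Ordinal time-of-flight vessel scores
(0/1/2) are compared with a Pearson chi-square on the group x score
contingency table.  Significance is declared at p < 0.050.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

ALPHA_DEFAULT = 0.050


@dataclass
class GroupSample:
    """One variable's values for one stratum of the cohort."""

    values: np.ndarray
    group: str = ""                 # co | non-co
    cell_line: str = ""             # H1299 | A549 | merged
    variable: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("values must be non-empty")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing/non-finite entries must be handled upstream")


@dataclass(frozen=True)
class TestResult:
    test_name: Literal["ks", "mann-whitney-u", "t", "chi-square"]
    statistic: float
    p_value: float
    significant: bool
    alpha: float = ALPHA_DEFAULT
    gate: tuple[str, str] | None = None   # normality decision per group


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    excluded_ids: tuple = ()


@dataclass(frozen=True)
class SummaryRow:
    mode: Literal["median-iqr", "mean-sd"]
    location: float
    spread: float

    def __str__(self) -> str:
        if self.mode == "median-iqr":
            return f"{self.location:g} ({self.spread:g})"
        return f"{self.location:g} ± {self.spread:g}"


def normality_gate(sample: GroupSample, alpha: float = ALPHA_DEFAULT,
                   method: Literal["lilliefors", "ks"] = "lilliefors"
                   ) -> tuple[str, float]:
    """Normal / non-normal decision for one sample.

    One-sample KS against a normal with mean/SD estimated from the data;
    the Lilliefors correction accounts for that estimation (the plain KS
    p-value is anti-conservative and kept only for comparison).  Constant
    samples are degenerate and declared non-normal outright.  Returns
    ``(decision, p)`` with decision 'normal' iff p >= alpha.
    """
    x = sample.values
    if x.size < 4:
        raise ValueError("normality gate needs n >= 4")
    if np.ptp(x) == 0:
        return "non-normal", 0.0
    if method == "lilliefors":
        _, p = lilliefors(x, dist="norm")
    else:
        _, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return ("normal" if p >= alpha else "non-normal"), float(p)


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with mid-rank tie handling.

    Exact null distribution when both groups have n <= 20 and the data
    are tie-free; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(a: GroupSample, b: GroupSample,
                       alpha: float = ALPHA_DEFAULT,
                       force: Literal[None, "always-t", "always-u"] = None,
                       equal_var: bool = True) -> TestResult:
    """Normality-gated two-group comparison.

    Both samples pass the gate; only if both are declared normal does the
    two-sample t test fire, otherwise the Mann-Whitney U test.  ``force``
    overrides the gate (recorded in the result) so gate flakiness can
    never silently change a published table.  Samples too small for the
    gate (n < 4) route to the nonparametric branch, recorded as
    'too-small'.
    """
    if min(a.values.size, b.values.size) < 4 and force is None:
        gate_a = gate_b = "too-small"
    else:
        gate_a, _ = normality_gate(a, alpha) if force is None else ("forced", 0)
        gate_b, _ = normality_gate(b, alpha) if force is None else ("forced", 0)
    use_t = gate_a == gate_b == "normal"
    if force == "always-t":
        use_t, gate_a, gate_b = True, "forced", "forced"
    elif force == "always-u":
        use_t, gate_a, gate_b = False, "forced", "forced"
    if use_t:
        stat, p = sps.ttest_ind(a.values, b.values, equal_var=equal_var)
        name = "t"
    else:
        stat, p = mann_whitney_u(a.values, b.values)
        name = "mann-whitney-u"
    p = float(np.clip(p, 0.0, 1.0))
    return TestResult(test_name=name, statistic=float(stat), p_value=p,
                      significant=p < alpha, alpha=alpha,
                      gate=(gate_a, gate_b))


def spearman(x: Sequence[float], y: Sequence[float],
             ids: Sequence | None = None,
             excluded_ids: Sequence = ()) -> CorrelationResult:
    """Spearman rank correlation with recorded case exclusions.

    rho is the Pearson correlation of mid-ranks (average ranks on ties);
    ``excluded_ids`` are removed from the paired data before ranking and
    echoed in the result so the exclusion rerun is auditable.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    keep = np.ones(x.size, dtype=bool)
    if excluded_ids:
        if ids is None:
            raise ValueError("excluded_ids given but no ids")
        keep = ~np.isin(np.asarray(ids), np.asarray(list(excluded_ids)))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("Spearman needs n >= 3 after exclusions")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(r=float(rho), p_value=float(p), n=int(x.size),
                             excluded_ids=tuple(excluded_ids))


def chi_square_ordinal(a: Sequence[int], b: Sequence[int],
                       levels: Sequence[int] = (0, 1, 2),
                       alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Pearson chi-square on the 2 x k group-by-score contingency table.

    Score levels absent from both groups are dropped with the degrees of
    freedom adjusted; identical distributions give statistic 0 (p = 1).
    """
    a = np.asarray(a, int)
    b = np.asarray(b, int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    observed = set(a.tolist()) | set(b.tolist())
    if not observed <= set(levels):
        raise ValueError(
            f"scores outside levels {tuple(levels)}: {sorted(observed - set(levels))}")
    table = np.array([[int(np.sum(a == s)) for s in levels],
                      [int(np.sum(b == s)) for s in levels]])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return TestResult("chi-square", 0.0, 1.0, False, alpha)
    res = sps.chi2_contingency(table, correction=False)
    p = float(res.pvalue)
    return TestResult("chi-square", float(res.statistic), p, p < alpha, alpha)


def summarize(values: Sequence[float],
              mode: Literal["median-iqr", "mean-sd"] = "median-iqr") -> SummaryRow:
    """Median (IQR, linear-interpolation quartiles) or mean +/- SD (n-1)."""
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("empty sample")
    if mode == "median-iqr":
        q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
        return SummaryRow("median-iqr", float(np.median(x)), float(q3 - q1))
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return SummaryRow("mean-sd", float(x.mean()), sd)


def build_comparison_table(data: pd.DataFrame,
                           variables: Sequence[str] | None = None,
                           alpha: float = ALPHA_DEFAULT,
                           modes: dict[str, str] | None = None,
                           force: Literal[None, "always-t", "always-u"] = None
                           ) -> pd.DataFrame:
    """Cohort comparison table: per-cell-line and merged columns per variable.

    ``data`` is tidy with columns ``animal_id, cell_line, group, variable,
    value``.  For each variable and each stratum (every cell line plus the
    pooled 'merged' column) the two transplantation groups are summarised
    and compared with the gated test; the chosen test is recorded in a
    machine-readable provenance column.
    """
    required = {"animal_id", "cell_line", "group", "variable", "value"}
    if not required <= set(data.columns):
        raise ValueError(f"data must carry columns {sorted(required)}")
    if variables is None:
        variables = list(data["variable"].unique())
    modes = modes or {}
    cell_lines = list(data["cell_line"].unique())
    strata = cell_lines + ["merged"]
    rows = []
    for var in variables:
        dv = data[data["variable"] == var]
        mode = modes.get(var, "median-iqr")
        for stratum in strata:
            ds = dv if stratum == "merged" else dv[dv["cell_line"] == stratum]
            groups = sorted(ds["group"].unique())
            if len(groups) != 2:
                raise ValueError(
                    f"variable {var!r}, stratum {stratum!r}: need exactly two groups")
            g_co = ds[ds["group"] == groups[0]]["value"].to_numpy()
            g_non = ds[ds["group"] == groups[1]]["value"].to_numpy()
            sa = GroupSample(g_co, groups[0], stratum, var)
            sb = GroupSample(g_non, groups[1], stratum, var)
            res = compare_two_groups(sa, sb, alpha=alpha, force=force)
            rows.append({
                "variable": var, "cell_line": stratum,
                f"summary_{groups[0]}": str(summarize(g_co, mode)),
                f"summary_{groups[1]}": str(summarize(g_non, mode)),
                "summary_mode": mode,
                "test": res.test_name, "statistic": res.statistic,
                "p_value": res.p_value, "significant": res.significant,
                "gate": "/".join(res.gate) if res.gate else "",
                "n_" + groups[0]: g_co.size, "n_" + groups[1]: g_non.size,
            })
    return pd.DataFrame(rows)
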