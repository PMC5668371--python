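"""Group-level statistics: layers, binned distributions, tests, summaries.

Implements the population comparisons used to contrast young-adult and
senescent groups: cortical-layer assignment from recording depth, the
fixed response-metric bins, Pearson chi-square on binned distributions,
one-/two-tailed two-sample t-tests, fixed-effects two-way ANOVA (age x
layer) on balanced designs, percent-change summaries, and mean +/- SD
group summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: Cortical layer boundaries (micrometres from the pial surface), half-open
#: [lo, hi) except the deepest layer, which includes its upper bound.
DEFAULT_LAYER_BOUNDARIES = {
    "I": (0.0, 100.0),
    "II-III": (100.0, 500.0),
    "IV": (500.0, 700.0),
    "V": (700.0, 1100.0),
    "VI": (1100.0, 1500.0),
}


@dataclass(frozen=True)
class Bin:
    """One bin of a distribution: label plus an interval with inclusivity."""

    label: str
    lo: float
    hi: float
    lo_closed: bool
    hi_closed: bool

    def contains(self, x: float) -> bool:
        above = x > self.lo or (self.lo_closed and x == self.lo)
        below = x < self.hi or (self.hi_closed and x == self.hi)
        return above and below


@dataclass(frozen=True)
class BinSpec:
    """A named, non-overlapping partition of a metric's value range."""

    name: str
    bins: tuple[Bin, ...]

    def index_of(self, x: float) -> int:
        hits = [i for i, b in enumerate(self.bins) if b.contains(x)]
        if len(hits) != 1:
            raise ValueError(
                f"value {x!r} falls in {len(hits)} bins of spec {self.name!r}"
            )
        return hits[0]


_INF = float("inf")

#: The response-metric bins used in the group distribution comparisons.
#: Inclusivity follows the printed bin definitions exactly; where a boundary
#: value is left unassigned by the text (AR exactly 30, SNR exactly 10) it
#: goes to the upper bin.
DEFAULT_BIN_SPECS: dict[str, BinSpec] = {
    "osi": BinSpec(
        "osi",
        (
            Bin("<=0.4", -_INF, 0.4, False, True),
            Bin("0.4-0.65", 0.4, 0.65, False, False),
            Bin(">=0.65", 0.65, _INF, True, False),
        ),
    ),
    "dsi": BinSpec(
        "dsi",
        (
            Bin("<=0.4", -_INF, 0.4, False, True),
            Bin("0.4-0.6", 0.4, 0.6, False, False),
            Bin(">=0.6", 0.6, _INF, True, False),
        ),
    ),
    "or": BinSpec(
        "or",
        (
            Bin("<=60", -_INF, 60.0, False, True),
            Bin(">60", 60.0, _INF, False, False),
        ),
    ),
    "ar": BinSpec(
        "ar",
        (
            Bin("<30", -_INF, 30.0, False, False),
            Bin(">=30", 30.0, _INF, True, False),
        ),
    ),
    "sa": BinSpec(
        "sa",
        (
            Bin("<5", -_INF, 5.0, False, False),
            Bin("5-10", 5.0, 10.0, True, True),
            Bin(">10", 10.0, _INF, False, False),
        ),
    ),
    "snr": BinSpec(
        "snr",
        (
            Bin("<10", -_INF, 10.0, False, False),
            Bin(">=10", 10.0, _INF, True, False),
        ),
    ),
}


@dataclass
class GroupSummary:
    group: str
    metric: str
    mean: float
    sd: float
    n: int


def assign_layer(
    depth_um: float,
    boundaries: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Map a recording depth (um from the pia) to a cortical layer label.

    Intervals are half-open [lo, hi); the deepest layer's upper bound is
    included so the full 0-1500 um range is covered.
    """
    if boundaries is None:
        boundaries = DEFAULT_LAYER_BOUNDARIES
    labels = list(boundaries)
    top = max(hi for _, hi in boundaries.values())
    for label in labels:
        lo, hi = boundaries[label]
        if lo <= depth_um < hi:
            return label
        if hi == top and depth_um == hi:
            return label
    raise ValueError(f"depth {depth_um} um outside the layered range [0, {top}]")


def bin_distribution(
    values: Sequence[float], spec: BinSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Count values per bin and return (counts, percentages).

    Percentages are 100*count/n rounded to 1 decimal, matching how the
    group distributions are reported.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bin an empty sample")
    counts = np.zeros(len(spec.bins), dtype=int)
    for x in values:
        counts[spec.index_of(float(x))] += 1
    pct = np.round(100.0 * counts / values.size, 1)
    return counts, pct


def chi_square_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns (statistic, degrees of freedom, p).  Expected counts are the
    usual product-of-margins estimates; a zero row or column margin is an
    error rather than a silent drop.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(table < 0):
        raise ValueError("contingency table counts must be nonnegative")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("contingency table has a zero marginal")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    tails: int = 2,
    variant: str = "welch",
) -> tuple[float, float, float]:
    """Two-sample t-test (Welch by default), one- or two-tailed.

    The one-tailed p is half the two-tailed p when the observed effect lies
    in the hypothesized direction (mean(b) != mean(a) as observed), i.e. it
    tests the direction the data point to.  Returns (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        df = float(a.size + b.size - 2)
        return 0.0, df, 1.0
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if tails == 1:
        p = p / 2.0
    return t, df, p


def two_way_anova(
    values: Sequence[float],
    factor_age: Sequence[str],
    factor_layer: Sequence[str],
) -> dict[str, tuple[float, int, int, float]]:
    """Fixed-effects two-way ANOVA with interaction on a balanced design.

    Returns {"age": (F, df1, df2, p), "layer": ..., "age:layer": ...}.
    The design must be balanced (equal cell counts); unbalanced input is
    rejected rather than silently re-weighted.  A single-level second
    factor degenerates to one-way ANOVA on age (only "age" is returned).
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "age": list(factor_age),
            "layer": list(factor_layer),
        }
    )
    if df["age"].nunique() < 2:
        raise ValueError("the age factor needs at least two levels")
    if df["layer"].nunique() == 1:
        groups = [g["value"].to_numpy() for _, g in df.groupby("age", sort=True)]
        if len({len(g) for g in groups}) != 1:
            raise ValueError("unbalanced design: equal cell counts required")
        F, p = sps.f_oneway(*groups)
        df1 = len(groups) - 1
        df2 = len(df) - len(groups)
        if not np.isfinite(F):
            F, p = 0.0, 1.0
        return {"age": (float(F), df1, df2, float(p))}
    cell_counts = df.groupby(["age", "layer"], sort=True).size()
    n_cells = df["age"].nunique() * df["layer"].nunique()
    if len(cell_counts) != n_cells:
        raise ValueError("empty design cell: balanced design required")
    if cell_counts.nunique() != 1:
        raise ValueError("unbalanced design: equal cell counts required")
    na, nl = df["age"].nunique(), df["layer"].nunique()
    if np.ptp(df["value"].to_numpy()) == 0:  # constant response: all F = 0
        df2 = len(df) - na * nl
        return {
            "age": (0.0, na - 1, df2, 1.0),
            "layer": (0.0, nl - 1, df2, 1.0),
            "age:layer": (0.0, (na - 1) * (nl - 1), df2, 1.0),
        }
    model = smf.ols("value ~ C(age) * C(layer)", data=df).fit()
    with warnings.catch_warnings():
        # an all-equal response yields 0/0 F ratios; report them as 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = sm.stats.anova_lm(model, typ=2)
    df2 = int(tab.loc["Residual", "df"])
    out: dict[str, tuple[float, int, int, float]] = {}
    for row, key in (
        ("C(age)", "age"),
        ("C(layer)", "layer"),
        ("C(age):C(layer)", "age:layer"),
    ):
        F = float(tab.loc[row, "F"])
        p = float(tab.loc[row, "PR(>F)"])
        if not np.isfinite(F):  # zero residual variance, zero effect SS
            F, p = 0.0, 1.0
        out[key] = (F, int(tab.loc[row, "df"]), df2, p)
    return out


def percent_change(
    reference_mean: float, comparison_mean: float, decimals: int = 1
) -> float:
    """Signed percent change of ``comparison`` relative to ``reference``."""
    if reference_mean == 0:
        raise ValueError("reference mean must be nonzero")
    change = 100.0 * (comparison_mean - reference_mean) / reference_mean
    return float(np.round(change, decimals))


def summarize_group(
    values: Sequence[float], group: str = "", metric: str = ""
) -> GroupSummary:
    """Mean, sample SD (n-1 denominator) and n, skipping NaN entries."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no defined values to summarize")
    if values.size == 1:
        warnings.warn("single observation: SD reported as 0", stacklevel=2)
        return GroupSummary(group, metric, float(values[0]), 0.0, 1)
    return GroupSummary(
        group,
        metric,
        float(np.mean(values)),
        float(np.std(values, ddof=1)),
        int(values.size),
    )
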