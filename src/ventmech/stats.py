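"""Linkage statistics between ventilation heterogeneity, lung mechanics
and airway hyperresponsiveness.

The study table holds one row per subject per condition (PreMch baseline,
PostMch after a methacholine challenge, PostDI after five deep
inspirations) with the image CV, the four mechanics features, PC20 and
FEV1 %predicted.  The analysis mirrors a classical small-cohort design:

* per-group condition summaries with paired t-tests across conditions,
  unpaired t-tests between groups, and post-hoc power for each contrast
  (noncentral-t at the observed standardized effect, alpha = 0.05);
* pooled and per-group Pearson correlations of CV against R_low, R_high,
  R_het and E_low, all subject-condition rows entering as points;
* asthmatic-only correlation of each baseline (PreMch) variable against
  PC20, excluding subjects whose PC20 exceeded the 25 mg/mL maximum dose.

No multiple-testing correction is applied; significance is a single-test
p < 0.05 together with power >= 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateTestError,
    InsufficientDataError,
    UndefinedCorrelationError,
)

__all__ = [
    "CorrelationResult",
    "ComparisonResult",
    "FEATURES",
    "CONDITIONS",
    "validate_study_table",
    "pearson",
    "paired_t",
    "unpaired_t",
    "posthoc_power",
    "condition_summary",
    "linkage_analysis",
    "ahr_analysis",
]

FEATURES = ["cv", "r_low", "r_high", "r_het", "e_low"]
CONDITIONS = ["PreMch", "PostMch", "PostDI"]
PC20_MAX_DOSE = 25.0  # mg/mL: maximum administered methacholine dose

REQUIRED_COLUMNS = [
    "subject_id", "group", "condition", "cv", "r_low", "r_high", "r_het",
    "e_low", "pc20_mg_ml", "fev1_pct_pred",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    subset: str = "pooled"
    pair: tuple[str, str] = ("x", "y")


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    contrast: str
    test: str  # "paired_t" | "unpaired_t"
    t: float
    p: float
    power: float
    n: int


def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema and uniqueness checks; returns the table unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table missing columns: {missing}")
    if table.duplicated(["subject_id", "condition"]).any():
        raise ValueError("duplicate (subject_id, condition) rows")
    groups = table.groupby("subject_id")["group"].nunique()
    if (groups > 1).any():
        raise ValueError("group must be constant within subject")
    bad = set(table["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {bad}")
    return table


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    subset: str = "pooled",
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Product-moment correlation with the two-tailed p-value from the
    t transform ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero variance in input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r, p, n, subset, pair)


def paired_t(a: Sequence[float], b: Sequence[float], variable: str = "",
             contrast: str = "", alpha: float = 0.05,
             with_power: bool = True) -> ComparisonResult:
    """Two-tailed paired Student's t-test with post-hoc power
    (``with_power=False`` skips the power computation, leaving NaN)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("all pairwise differences are identical")
    t, p = sps.ttest_rel(a, b)
    if with_power:
        power = posthoc_power("paired", float(d.mean() / sd), a.size, alpha)
    else:
        power = float("nan")
    return ComparisonResult(variable, contrast, "paired_t", float(t), float(p),
                            power, int(a.size))


def unpaired_t(a: Sequence[float], b: Sequence[float], variable: str = "",
               contrast: str = "", alpha: float = 0.05,
               with_power: bool = True) -> ComparisonResult:
    """Two-tailed unpaired (equal-variance) Student's t-test with power."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    sp = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if sp == 0:
        raise DegenerateTestError("zero pooled variance")
    t, p = sps.ttest_ind(a, b)
    if with_power:
        effect = float((a.mean() - b.mean()) / sp)
        power = posthoc_power("unpaired", effect, a.size, alpha, n2=b.size)
    else:
        power = float("nan")
    return ComparisonResult(variable, contrast, "unpaired_t", float(t), float(p),
                            power, int(a.size + b.size))


def posthoc_power(
    test: str, effect: float, n: int, alpha: float = 0.05, n2: int | None = None
) -> float:
    """Two-sided power of a t-test at the observed standardized effect.

    Noncentral-t computation via statsmodels: ``paired`` treats the
    differences as a one-sample test of size ``n``; ``unpaired`` uses
    group sizes ``n`` and ``n2`` (default ``n``).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    from statsmodels.stats.power import TTestIndPower, TTestPower

    effect = abs(float(effect))
    if test == "paired":
        return float(TTestPower().power(effect, n, alpha, alternative="two-sided"))
    if test == "unpaired":
        n2 = n if n2 is None else n2
        return float(
            TTestIndPower().power(effect, n, alpha, ratio=n2 / n,
                                  alternative="two-sided")
        )
    raise ValueError(f"unknown test {test!r}")


def condition_summary(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per group x condition mean +- SD, plus the pairwise contrast grid.

    Paired t-tests compare conditions within each group (subjects missing
    a condition are dropped from that contrast); unpaired t-tests compare
    the groups within each condition.  Each contrast carries its post-hoc
    power; degenerate contrasts (zero-variance differences) surface as a
    note instead of aborting the summary.
    """
    validate_study_table(table)
    rows = []
    for (group, cond), sub in table.groupby(["group", "condition"], sort=False):
        for var in FEATURES:
            vals = sub[var].to_numpy(dtype=float)
            rows.append({
                "group": group, "condition": cond, "variable": var,
                "mean": vals.mean(), "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                "n": vals.size,
            })
    summary = pd.DataFrame(rows)

    comparisons = []
    wide = table.set_index(["subject_id", "condition"])
    for group, sub in table.groupby("group", sort=False):
        subjects = sub["subject_id"].unique()
        for c1, c2 in combinations([c for c in CONDITIONS
                                    if c in set(sub["condition"])], 2):
            have = [s for s in subjects
                    if (s, c1) in wide.index and (s, c2) in wide.index]
            if len(have) < len(subjects):
                import logging
                logging.getLogger(__name__).warning(
                    "%s: %d subject(s) missing %s/%s dropped from paired contrast",
                    group, len(subjects) - len(have), c1, c2)
            if len(have) < 2:
                continue
            for var in FEATURES:
                a = wide.loc[[(s, c1) for s in have], var].to_numpy(dtype=float)
                b = wide.loc[[(s, c2) for s in have], var].to_numpy(dtype=float)
                comparisons.append(
                    _contrast_row(a, b, "paired", var, f"{group}: {c1} vs {c2}", alpha)
                )
    groups = list(dict.fromkeys(table["group"]))
    if len(groups) == 2:
        g1, g2 = groups
        for cond in CONDITIONS:
            t1 = table[(table["group"] == g1) & (table["condition"] == cond)]
            t2 = table[(table["group"] == g2) & (table["condition"] == cond)]
            if len(t1) < 2 or len(t2) < 2:
                continue
            for var in FEATURES:
                comparisons.append(
                    _contrast_row(t1[var].to_numpy(float), t2[var].to_numpy(float),
                                  "unpaired", var, f"{cond}: {g1} vs {g2}", alpha)
                )
    return summary, pd.DataFrame(comparisons)


def _contrast_row(a, b, kind, var, contrast, alpha):
    fn = paired_t if kind == "paired" else unpaired_t
    try:
        res = fn(a, b, variable=var, contrast=contrast, alpha=alpha)
        return {"variable": var, "contrast": contrast, "test": res.test,
                "t": res.t, "p": res.p, "power": res.power, "n": res.n,
                "note": ""}
    except DegenerateTestError as exc:
        return {"variable": var, "contrast": contrast, "test": f"{kind}_t",
                "t": np.nan, "p": np.nan, "power": np.nan,
                "n": len(a) if kind == "paired" else len(a) + len(b),
                "note": f"degenerate: {exc}"}


def linkage_analysis(table: pd.DataFrame) -> list[CorrelationResult]:
    """CV against each mechanics feature: pooled over every
    subject-condition row, then healthy-only, then asthmatic-only."""
    validate_study_table(table)
    out = []
    subsets = [("pooled", table),
               ("healthy", table[table["group"] == "healthy"]),
               ("asthmatic", table[table["group"] == "asthmatic"])]
    for name, sub in subsets:
        if len(sub) < 3:
            continue
        for var in ["r_low", "r_high", "r_het", "e_low"]:
            out.append(pearson(sub["cv"], sub[var], subset=name, pair=("cv", var)))
    return out


def ahr_analysis(
    table: pd.DataFrame, log_pc20: bool = False
) -> list[CorrelationResult]:
    """Baseline predictors of airway hyperresponsiveness.

    Asthmatic subjects only; rows censored at the maximum dose
    (PC20 > 25 mg/mL, flagged via ``pc20_censored`` when present) are
    excluded, and each PreMch variable is correlated against PC20 on the
    linear scale (``log_pc20`` switches to log10)."""
    validate_study_table(table)
    sub = table[(table["group"] == "asthmatic") & (table["condition"] == "PreMch")]
    if "pc20_censored" in sub.columns:
        sub = sub[~sub["pc20_censored"].astype(bool)]
    sub = sub[sub["pc20_mg_ml"] <= PC20_MAX_DOSE]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"only {len(sub)} asthmatic subjects with quantified PC20"
        )
    pc20 = sub["pc20_mg_ml"].to_numpy(dtype=float)
    if np.any(pc20 <= 0):
        raise ValueError("PC20 must be positive")
    yname = "pc20_mg_ml"
    if log_pc20:
        pc20 = np.log10(pc20)
        yname = "log10_pc20"
    return [pearson(sub[var], pc20, subset="asthmatic_premch", pair=(var, yname))
            for var in FEATURES]
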