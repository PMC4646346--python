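"""Correlation, t-tests, post-hoc power and the cohort-level analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ventmech.errors import (
    DegenerateTestError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from ventmech.stats import (
    ahr_analysis,
    condition_summary,
    linkage_analysis,
    paired_t,
    pearson,
    posthoc_power,
    unpaired_t,
    validate_study_table,
)


def pearson_oracle(x, y):
    """Direct product-moment formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestPearson:
    def test_perfect_positive(self):
        assert pearson([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson([1, 2, 3], [-1, -2, -3]).r == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            res = pearson(x, y)
            assert res.r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
            # p from the t transform
            t = res.r * np.sqrt(8 / (1 - res.r**2))
            assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 8), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


class TestTTests:
    def test_identical_paired_samples_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_degenerate(self):
        # differences {-1,-1,-1} have zero SD
        with pytest.raises(DegenerateTestError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_unpaired_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = unpaired_t(a, b)
        t, p = sps.ttest_ind(a, b)
        assert res.t == pytest.approx(float(t)) and res.p == pytest.approx(float(p))

    @pytest.mark.parametrize("kind", ["paired", "unpaired"])
    def test_type_i_error_calibrated(self, kind, rng):
        # rejection rate under the null stays at alpha (0.05 +- 0.01)
        reps, n, rejections = 10_000, 10, 0
        for _ in range(reps):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            fn = paired_t if kind == "paired" else unpaired_t
            res = fn(a, b, with_power=False)
            rejections += res.p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.01)


class TestPower:
    def test_null_effect_power_is_alpha(self):
        assert posthoc_power("paired", 0.0, 12, 0.05) == pytest.approx(0.05,
                                                                       abs=1e-6)

    def test_huge_effect_power_is_one(self):
        assert posthoc_power("paired", 50.0, 12, 0.05) == pytest.approx(1.0,
                                                                        abs=1e-9)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            posthoc_power("paired", 1.0, 10, 1.5)

    def test_paired_power_matches_monte_carlo(self, rng):
        # d = 1.0, n = 9: simulate the paired test at 1e5 reps
        d, n, reps = 1.0, 9, 100_000
        x = rng.normal(d, 1.0, size=(reps, n))
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        p = 2 * sps.t.sf(np.abs(t), n - 1)
        mc = np.mean(p < 0.05)
        assert posthoc_power("paired", d, n, 0.05) == pytest.approx(mc, abs=0.02)

    def test_unpaired_power_matches_monte_carlo(self, rng):
        d, n, reps = 0.8, 12, 100_000
        a = rng.normal(d, 1.0, size=(reps, n))
        b = rng.normal(0.0, 1.0, size=(reps, n))
        sp = np.sqrt((a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2)
        t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(2 / n))
        p = 2 * sps.t.sf(np.abs(t), 2 * n - 2)
        mc = np.mean(p < 0.05)
        assert posthoc_power("unpaired", d, n, 0.05) == pytest.approx(mc, abs=0.02)


def make_table(n_healthy=4, n_asthmatic=9, postmch_cv_shift=0.1, seed=0,
               censor_one=True):
    """Small deterministic study table with a built-in PostMch CV shift in
    the asthmatic group."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("healthy", n_healthy), ("asthmatic", n_asthmatic)):
        for i in range(n):
            sid = f"{group[0].upper()}{i + 1}"
            base_cv = rng.normal(0.40 if group == "asthmatic" else 0.38, 0.02)
            pc20 = 25.0 if group == "healthy" else float(
                np.clip(10 ** rng.normal(0.5, 0.4), 0.1, 30.0))
            censored = group == "healthy" or pc20 > 25.0
            if censor_one and group == "asthmatic" and i == 0:
                pc20, censored = 25.0, True
            for cond in ("PreMch", "PostMch", "PostDI"):
                shift = postmch_cv_shift if (
                    cond == "PostMch" and group == "asthmatic") else 0.0
                cv = base_cv + shift + rng.normal(0, 0.005)
                rows.append({
                    "subject_id": sid, "group": group, "condition": cond,
                    "cv": cv,
                    "r_low": 4 + 20 * cv + rng.normal(0, 0.5),
                    "r_high": 3 + 2 * cv + rng.normal(0, 0.3),
                    "r_het": 1 + 18 * cv + rng.normal(0, 0.4),
                    "e_low": 6 + 10 * cv + rng.normal(0, 0.5),
                    "pc20_mg_ml": min(pc20, 25.0),
                    "pc20_censored": censored,
                    "fev1_pct_pred": 100.0,
                })
    return pd.DataFrame(rows)


class TestConditionSummary:
    def test_builtin_shift_detected(self):
        table = make_table(postmch_cv_shift=0.1)
        summary, comparisons = condition_summary(table)
        row = comparisons[
            (comparisons.variable == "cv")
            & (comparisons.contrast == "asthmatic: PreMch vs PostMch")
        ].iloc[0]
        assert row.p < 0.05
        assert row.test == "paired_t"

    def test_summary_cells_complete(self):
        summary, _ = condition_summary(make_table())
        assert len(summary) == 2 * 3 * 5  # groups x conditions x variables
        assert (summary.n > 0).all()

    def test_degenerate_contrast_surfaced_per_variable(self):
        table = make_table()
        # make PostMch identical to PreMch for every subject
        wide = table.set_index(["subject_id", "condition"])
        for sid in table.subject_id.unique():
            for var in ("cv", "r_low", "r_high", "r_het", "e_low"):
                wide.loc[(sid, "PostMch"), var] = wide.loc[(sid, "PreMch"), var]
        _, comparisons = condition_summary(wide.reset_index())
        degen = comparisons[
            comparisons.contrast.str.contains("PreMch vs PostMch")]
        assert (degen.note.str.startswith("degenerate")).all()
        assert degen.p.isna().all()

    def test_missing_condition_dropped_from_paired(self, caplog):
        table = make_table()
        table = table[~((table.subject_id == "A1")
                        & (table.condition == "PostMch"))]
        with caplog.at_level("WARNING"):
            _, comparisons = condition_summary(table)
        row = comparisons[
            (comparisons.variable == "cv")
            & (comparisons.contrast == "asthmatic: PreMch vs PostMch")
        ].iloc[0]
        assert row.n == 8  # 9 asthmatics minus the dropped one

    def test_duplicate_rows_rejected(self):
        table = make_table()
        with pytest.raises(ValueError):
            validate_study_table(pd.concat([table, table.iloc[[0]]]))


class TestLinkage:
    def test_subsets_and_pairs_enumerated(self):
        res = linkage_analysis(make_table())
        subsets = {c.subset for c in res}
        assert subsets == {"pooled", "healthy", "asthmatic"}
        assert len(res) == 3 * 4

    def test_builtin_coupling_detected(self):
        res = linkage_analysis(make_table())
        pooled = {c.pair[1]: c for c in res if c.subset == "pooled"}
        assert pooled["r_het"].r > 0.5
        assert pooled["r_low"].r > 0.5


class TestAhr:
    def test_exclusion_arithmetic(self):
        # 9 asthmatics, one censored at the maximum dose -> n = 8
        res = ahr_analysis(make_table(censor_one=True))
        assert all(c.n == 8 for c in res)

    def test_healthy_rows_never_enter(self):
        res = ahr_analysis(make_table())
        assert all(c.subset == "asthmatic_premch" for c in res)

    def test_all_censored_insufficient(self):
        table = make_table()
        table.loc[table.group == "asthmatic", "pc20_censored"] = True
        with pytest.raises(InsufficientDataError):
            ahr_analysis(table)

    def test_log_scale_option(self):
        res = ahr_analysis(make_table(), log_pc20=True)
        assert all(c.pair[1] == "log10_pc20" for c in res)
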