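"""Friedman / Wilcoxon machinery and the model-comparison report.

Small-sample p-values are validated against full permutation enumerations
built independently with itertools; the chi-square path is cross-checked
against scipy's friedmanchisquare.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from audiomaze.comparison import (
    MODEL_PAIRS,
    compare_models,
    comparison_records,
    friedman_test,
    subgroup_analysis,
    wilcoxon_posthoc,
)


def _fits_frame(rng, n_participants=8, effect=None, trials=(1, 2, 3)):
    """Long fits table with iid scores, optionally shifted per model."""
    effect = effect or {}
    rows = []
    for p in range(n_participants):
        style = "allocentric" if p < n_participants // 2 else "egocentric"
        for trial in trials:
            base = rng.normal(2.0, 0.05)
            for kind in ("FB", "MBr", "MBu"):
                rows.append(
                    {
                        "participant_id": f"P{p:02d}",
                        "navigator_style": style,
                        "trial_index": trial,
                        "model_kind": kind,
                        "L_step_norm": base + effect.get(kind, 0.0) + rng.normal(0, 0.01),
                        "L_turn_norm": base + rng.normal(0, 0.01),
                    }
                )
    return pd.DataFrame(rows)


class TestFriedman:
    def test_perfect_ordering_closed_form(self):
        """Ten units ranking C > B > A identically: statistic 12n/(k(k+1)) *
        sum (Rbar - 2)^2 = 20 for n=10, k=3."""
        x = np.tile([1.0, 2.0, 3.0], (10, 1))
        stat, p = friedman_test(x, method="chi2")
        assert stat == pytest.approx(20.0, abs=1e-12)
        assert p < 1e-4

    def test_identical_columns_null(self):
        x = np.tile([[5.0, 5.0, 5.0]], (6, 1))
        stat, p = friedman_test(x, method="chi2")
        assert stat == 0.0 and p == 1.0

    def test_exact_matches_brute_force_enumeration(self):
        """Exact p equals the full 6^n within-row permutation null."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 3))
        stat, p = friedman_test(x, method="exact")

        ranks = np.vstack([stats.rankdata(row) for row in x])
        a1 = (ranks**2).sum()
        c1 = 6 * 3 * 16 / 4.0
        perms = list(itertools.permutations(range(3)))
        count = 0
        total = 0
        for combo in itertools.product(perms, repeat=6):
            cols = np.zeros(3)
            for i, perm in enumerate(combo):
                cols += ranks[i, list(perm)]
            s = 2 * ((cols - 6 * 2.0) ** 2).sum() / (a1 - c1)
            count += s >= stat - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_exact_with_ties_matches_enumeration(self):
        x = np.array(
            [[1.0, 1.0, 2.0], [3.0, 1.0, 1.0], [2.0, 2.0, 2.0], [0.0, 1.0, 2.0]]
        )
        stat, p = friedman_test(x, method="exact")
        ranks = np.vstack([stats.rankdata(row) for row in x])
        a1 = (ranks**2).sum()
        c1 = 4 * 3 * 16 / 4.0
        perms = list(itertools.permutations(range(3)))
        hits = total = 0
        for combo in itertools.product(perms, repeat=4):
            cols = np.zeros(3)
            for i, perm in enumerate(combo):
                cols += ranks[i, list(perm)]
            if a1 - c1 <= 0:
                s = 0.0
            else:
                s = 2 * ((cols - 4 * 2.0) ** 2).sum() / (a1 - c1)
            hits += s >= stat - 1e-12
            total += 1
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_chi2_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 3))
        stat, p = friedman_test(x, method="chi2")
        sp = stats.friedmanchisquare(*x.T)
        assert stat == pytest.approx(sp.statistic, rel=1e-12)
        assert p == pytest.approx(sp.pvalue, rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(9, 3))
        stat, _ = friedman_test(x, method="chi2")
        stat2, _ = friedman_test(np.exp(3 * x), method="chi2")
        assert stat2 == pytest.approx(stat, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="3 complete units"):
            friedman_test(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="missing"):
            friedman_test(np.array([[1.0, np.nan, 2.0]] * 4))


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        a = np.arange(1.0, 9.0)
        b = a - np.linspace(0.1, 0.8, 8)
        stat, raw, corr, flag = wilcoxon_posthoc(a, b)
        assert stat == 0.0
        assert raw == pytest.approx(2 / 256, abs=1e-12)
        assert corr == pytest.approx(6 / 256, abs=1e-12)
        assert flag is None

    def test_identical_samples_flagged(self):
        a = np.ones(6)
        stat, raw, corr, flag = wilcoxon_posthoc(a, a)
        assert raw == 1.0 and corr == 1.0 and flag is not None

    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.3, 1.0, 12)
        b = rng.normal(0.0, 1.0, 12)
        _, raw, corr, _ = wilcoxon_posthoc(a, b, n_comparisons=3)
        assert corr == pytest.approx(min(1.0, raw * 3), abs=1e-15)
        assert corr >= raw

    def test_exact_p_matches_sign_enumeration(self):
        """Two-sided exact p equals enumeration over all 2^n sign flips."""
        rng = np.random.default_rng(4)
        for trial in range(5):
            diff = rng.normal(0.2, 1.0, 8)
            while len(np.unique(np.abs(diff))) < len(diff) or (diff == 0).any():
                diff = rng.normal(0.2, 1.0, 8)
            stat, raw, _, _ = wilcoxon_posthoc(diff, np.zeros_like(diff))
            ranks = stats.rankdata(np.abs(diff))
            n = len(diff)
            t_obs = min(ranks[diff > 0].sum(), ranks[diff < 0].sum())
            null = []
            for signs in itertools.product([0, 1], repeat=n):
                tplus = sum(r for r, s in zip(ranks, signs) if s)
                null.append(min(tplus, n * (n + 1) / 2 - tplus))
            p_enum = np.mean([t <= t_obs for t in null])
            assert raw == pytest.approx(p_enum, abs=1e-12)


class TestCompareModels:
    def test_trial_one_skips_map_pair(self):
        rng = np.random.default_rng(5)
        fits = _fits_frame(rng, effect={"MBu": 0.1, "MBr": 0.05})
        results = compare_models(fits, metric="step")
        by_trial = {r.trial_index: r for r in results}
        skipped = [pw for pw in by_trial[1].pairwise if pw.skipped]
        assert len(skipped) == 1 and skipped[0].pair == ("MBr", "MBu")
        assert all(pw.skipped is None for pw in by_trial[2].pairwise)
        assert [pw.pair for pw in by_trial[2].pairwise] == list(MODEL_PAIRS)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(6)
        fits = _fits_frame(rng, n_participants=12, effect={"MBr": 0.2, "MBu": 0.4})
        res = compare_models(fits, metric="step")
        for block in res:
            assert block.friedman_p < 1e-3
            fb_mbu = [pw for pw in block.pairwise if pw.pair == ("FB", "MBu")][0]
            assert fb_mbu.significant

    def test_unknown_metric_rejected(self):
        fits = _fits_frame(np.random.default_rng(7))
        with pytest.raises(ValueError, match="metric"):
            compare_models(fits, metric="speed")

    def test_report_table_shape(self):
        rng = np.random.default_rng(8)
        fits = _fits_frame(rng)
        table = comparison_records(compare_models(fits, metric="step"))
        # per trial: one friedman row + three pairwise rows
        assert len(table) == 3 * 4
        assert set(table["test"]) == {"friedman", "wilcoxon"}


class TestSubgroups:
    def test_one_style_only_skips_other(self):
        rng = np.random.default_rng(9)
        fits = _fits_frame(rng)
        styles = fits[["participant_id"]].drop_duplicates()
        styles["navigator_style"] = "allocentric"
        with pytest.warns(UserWarning, match="egocentric"):
            out = subgroup_analysis(
                fits.assign(navigator_style="allocentric"),
                pd.concat(
                    [
                        styles,
                        pd.DataFrame(
                            {"participant_id": ["P98", "P99"],
                             "navigator_style": ["egocentric", "egocentric"]}
                        ),
                    ]
                ),
            )
        assert "allocentric" in out and "egocentric" not in out

    def test_unlabelled_participant_rejected(self):
        rng = np.random.default_rng(10)
        fits = _fits_frame(rng)
        styles = fits[["participant_id", "navigator_style"]].drop_duplicates().iloc[:-1]
        with pytest.raises(ValueError, match="without style"):
            subgroup_analysis(fits, styles)

    def test_both_groups_reported(self):
        rng = np.random.default_rng(11)
        fits = _fits_frame(rng, n_participants=12)
        styles = fits[["participant_id", "navigator_style"]].drop_duplicates()
        out = subgroup_analysis(fits, styles)
        assert set(out) == {"allocentric", "egocentric"}


def test_pipeline_type_one_error_on_null():
    """Friedman gate + Bonferroni post-hocs on null cohorts rejects at
    most ~alpha of the time."""
    rng = np.random.default_rng(12)
    n_rep = 400
    false_hits = 0
    for _ in range(n_rep):
        fits = _fits_frame(rng, n_participants=8, trials=(2,))
        block = compare_models(fits, metric="step")[0]
        if block.friedman_p < 0.05 and any(
            pw.significant for pw in block.pairwise if not pw.skipped
        ):
            false_hits += 1
    rate = false_hits / n_rep
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
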