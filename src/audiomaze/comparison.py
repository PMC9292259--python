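"""Nonparametric comparison of the three models' normalized log-likelihoods.

Within each trial, participants provide paired scores for FB, MBr and MBu.
A Friedman test (within-participant ranks, tie-corrected chi-square with
k - 1 = 2 degrees of freedom, or an exact rank-permutation null for small
cohorts) gates post-hoc two-sided Wilcoxon signed-rank tests on the three
model pairs, Bonferroni-corrected.  The MBr-MBu contrast is skipped in
trial 1, where the two models coincide by construction.  The
egocentric/allocentric subgroup contrast repeats the whole comparison
within each navigator-style group.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MODEL_ORDER = ("FB", "MBr", "MBu")
MODEL_PAIRS = (("FB", "MBr"), ("FB", "MBu"), ("MBr", "MBu"))

_METRIC_COLUMNS = {"step": "L_step_norm", "turn": "L_turn_norm"}


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float = np.nan
    raw_p: float = np.nan
    corrected_p: float = np.nan
    significant: bool = False
    skipped: str | None = None  # reason, when the contrast was not run
    flag: str | None = None


@dataclass
class ComparisonResult:
    trial_index: int
    metric: str
    friedman_stat: float
    friedman_p: float
    pairwise: list[PairwiseResult]
    n_units: int


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from an (n, k) mid-rank matrix."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    if a1 - c1 <= 0:  # every row completely tied
        return 0.0
    num = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    return num / (a1 - c1)


def _friedman_exact_p(ranks: np.ndarray, observed: float) -> float:
    """Exact permutation p: all k!^n within-row orderings, by convolution.

    The tie-corrected statistic depends on the ranks only through the
    column sums (the sum of squared ranks is permutation-invariant), so the
    null distribution is built by convolving per-row column-sum
    contributions.  Mid-ranks are doubled to keep the state integral.
    """
    n, k = ranks.shape
    doubled = np.rint(ranks * 2).astype(int)
    states: dict[tuple[int, ...], float] = {tuple([0] * (k - 1)): 1.0}
    perms = list(itertools.permutations(range(k)))
    for i in range(n):
        row = doubled[i]
        new: dict[tuple[int, ...], float] = {}
        for state, prob in states.items():
            for perm in perms:
                key = tuple(state[j] + row[perm[j]] for j in range(k - 1))
                new[key] = new.get(key, 0.0) + prob / len(perms)
        states = new
    total = int(doubled.sum())  # row sums are permutation-invariant
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    p = 0.0
    for state, prob in states.items():
        col2 = np.array(list(state) + [total - sum(state)]) / 2.0
        if a1 - c1 <= 0:
            stat = 0.0
        else:
            stat = (k - 1) * float(((col2 - n * (k + 1) / 2.0) ** 2).sum()) / (a1 - c1)
        if stat >= observed - 1e-12:
            p += prob
    return min(1.0, p)


def friedman_test(matrix, method: str = "auto") -> tuple[float, float]:
    """Friedman test over an (n units, k treatments) matrix of paired values.

    method 'chi2' uses the tie-corrected chi-square approximation with
    k - 1 degrees of freedom; 'exact' enumerates the within-unit rank
    permutation null; 'auto' picks exact for n <= 8.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("matrix must be (n units, k >= 2 treatments)")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing cells; drop incomplete units first")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 complete units")
    ranks = np.vstack([stats.rankdata(row) for row in x])
    stat = _friedman_statistic(ranks)
    if method == "auto":
        method = "exact" if n <= 8 else "chi2"
    if method == "exact":
        return stat, _friedman_exact_p(ranks, stat)
    if method != "chi2":
        raise ValueError("method must be 'auto', 'chi2' or 'exact'")
    if stat == 0.0:
        return 0.0, 1.0
    return stat, float(stats.chi2.sf(stat, k - 1))


def wilcoxon_posthoc(
    a, b, n_comparisons: int = 3
) -> tuple[float, float, float, str | None]:
    """Two-sided Wilcoxon signed-rank test with Bonferroni correction.

    Zero differences are dropped before ranking; the statistic is the
    smaller signed-rank sum.  The null is exact for n <= 25 without ties,
    otherwise the normal approximation with tie and continuity correction.
    Returns (statistic, raw_p, corrected_p, flag).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    diff = diff[diff != 0.0]
    if len(diff) == 0:
        return 0.0, 1.0, 1.0, "all differences zero"
    no_ties = len(np.unique(np.abs(diff))) == len(diff)
    method = "exact" if (len(diff) <= 25 and no_ties) else "approx"
    res = stats.wilcoxon(
        diff,
        zero_method="wilcox",
        alternative="two-sided",
        correction=(method == "approx"),
        method=method,
    )
    raw_p = float(res.pvalue)
    return float(res.statistic), raw_p, min(1.0, raw_p * n_comparisons), None


def _pivot_trial(fits: pd.DataFrame, trial: int, value_col: str) -> pd.DataFrame:
    sub = fits[fits["trial_index"] == trial]
    wide = sub.pivot_table(
        index="participant_id", columns="model_kind", values=value_col, aggfunc="mean"
    )
    missing = [m for m in MODEL_ORDER if m not in wide.columns]
    if missing:
        raise ValueError(f"trial {trial}: no fits for model(s) {missing}")
    return wide[list(MODEL_ORDER)].dropna()


def compare_models(
    fits: pd.DataFrame,
    metric: str = "step",
    alpha: float = 0.05,
    friedman_method: str = "chi2",
    n_comparisons: int = 3,
) -> list[ComparisonResult]:
    """One Friedman + post-hoc Wilcoxon block per trial for one metric.

    ``fits`` is the long fits table (columns participant_id, trial_index,
    model_kind, L_step_norm, L_turn_norm); units are participants, and a
    unit missing any model in a trial is dropped from that trial's block.
    """
    if metric not in _METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COLUMNS)}")
    col = _METRIC_COLUMNS[metric]
    out: list[ComparisonResult] = []
    for trial in sorted(fits["trial_index"].unique()):
        wide = _pivot_trial(fits, trial, col)
        stat, p = friedman_test(wide.to_numpy(), method=friedman_method)
        pairwise: list[PairwiseResult] = []
        for pair in MODEL_PAIRS:
            if trial == 1 and pair == ("MBr", "MBu"):
                pairwise.append(
                    PairwiseResult(pair=pair, skipped="identical by definition")
                )
                continue
            w, raw, corr, flag = wilcoxon_posthoc(
                wide[pair[0]].to_numpy(),
                wide[pair[1]].to_numpy(),
                n_comparisons=n_comparisons,
            )
            pairwise.append(
                PairwiseResult(
                    pair=pair,
                    statistic=w,
                    raw_p=raw,
                    corrected_p=corr,
                    significant=bool(corr < alpha),
                    flag=flag,
                )
            )
        out.append(
            ComparisonResult(
                trial_index=int(trial),
                metric=metric,
                friedman_stat=stat,
                friedman_p=p,
                pairwise=pairwise,
                n_units=len(wide),
            )
        )
    return out


def subgroup_analysis(
    fits: pd.DataFrame,
    styles: pd.DataFrame,
    metric: str = "step",
    alpha: float = 0.05,
    friedman_method: str = "chi2",
) -> dict[str, list[ComparisonResult]]:
    """Repeat the model comparison within each navigator-style subgroup.

    ``styles`` maps participant_id -> navigator_style (egocentric /
    allocentric).  A group with fewer than 3 participants is skipped with a
    warning.
    """
    style_map = dict(zip(styles["participant_id"], styles["navigator_style"]))
    unlabelled = set(fits["participant_id"]) - set(style_map)
    if unlabelled:
        raise ValueError(f"participants without style labels: {sorted(unlabelled)}")
    out: dict[str, list[ComparisonResult]] = {}
    for style in sorted(set(style_map.values())):
        members = {p for p, s in style_map.items() if s == style}
        sub = fits[fits["participant_id"].isin(members)]
        if sub["participant_id"].nunique() < 3:
            warnings.warn(f"subgroup {style!r} has < 3 participants; skipped")
            continue
        out[style] = compare_models(
            sub, metric=metric, alpha=alpha, friedman_method=friedman_method
        )
    return out


def comparison_records(results) -> pd.DataFrame:
    """Flatten ComparisonResults into a tidy report table."""
    rows = []
    items = results.items() if isinstance(results, dict) else [(None, results)]
    for group, blocks in items:
        for block in blocks:
            rows.append(
                {
                    "group": group,
                    "trial_index": block.trial_index,
                    "metric": block.metric,
                    "test": "friedman",
                    "pair": "",
                    "statistic": block.friedman_stat,
                    "raw_p": block.friedman_p,
                    "corrected_p": np.nan,
                    "significant": block.friedman_p < 0.05,
                    "note": f"n={block.n_units}",
                }
            )
            for pw in block.pairwise:
                rows.append(
                    {
                        "group": group,
                        "trial_index": block.trial_index,
                        "metric": block.metric,
                        "test": "wilcoxon",
                        "pair": f"{pw.pair[0]}-{pw.pair[1]}",
                        "statistic": pw.statistic,
                        "raw_p": pw.raw_p,
                        "corrected_p": pw.corrected_p,
                        "significant": pw.significant,
                        "note": pw.skipped or pw.flag or "",
                    }
                )
    return pd.DataFrame(rows)
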