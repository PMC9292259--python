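"""Study-level evaluation: replicate cohorts and their directional summaries.

Drives the full pipeline (simulate -> three models -> fits -> paired
tests) over replicate synthetic cohorts and reduces each replicate to the
qualitative quantities the models are meant to reproduce: wall-label
fractions per model, the fitted wall vs no-wall step-size contrast, the
normalized log-likelihood ordering on repeated trials, and the
navigator-style interaction in the MBr-MBu contrast.
"""

from __future__ import annotations

import pandas as pd

from .comparison import subgroup_analysis
from .maze import build_maze
from .pipeline import fit_trial_models
from .simulate import simulate_cohort
from .util import child_seed


def _mbr_mbu_significant(blocks) -> bool:
    """Any post-trial-1 MBr-MBu contrast significant after Bonferroni."""
    for block in blocks:
        if block.trial_index == 1:
            continue
        for pw in block.pairwise:
            if pw.pair == ("MBr", "MBu") and not pw.skipped and pw.significant:
                return True
    return False


def run_replicate_battery(
    seed: int,
    n_replicates: int = 50,
    n_participants: int = 16,
    shape: str = "Z",
    trials_per_maze: int = 3,
    step_cap: int = 400,
) -> pd.DataFrame:
    """One row of directional outcomes per replicate cohort.

    Columns: per-model pooled wall-label fractions and mean normalized
    step log-likelihoods on trials 2-3, the fitted class step means, and
    boolean outcomes — ``wall_frac_ordered`` (FB < both map models),
    ``step_means_ordered`` (no-wall mean > wall mean), ``loglik_ordered``
    (MBu >= MBr >= FB on trials 2-3), ``allo_sig`` / ``ego_sig`` (MBr-MBu
    Wilcoxon significant within the style subgroup).
    """
    maze = build_maze(shape)
    rows = []
    for rep in range(n_replicates):
        records, manifest = simulate_cohort(
            n_participants,
            [maze],
            trials_per_maze=trials_per_maze,
            style_split=0.5,
            seed=child_seed(seed, 1, rep),
            step_cap=step_cap,
        )
        fits = fit_trial_models(records, seed=child_seed(seed, 2, rep))
        wf = fits.groupby("model_kind")["wall_fraction"].mean()
        mean_nowall = float((fits["alpha_nowall"] * fits["beta_nowall"]).mean())
        mean_wall = float((fits["alpha_wall"] * fits["beta_wall"]).mean())
        late = fits[fits["trial_index"] >= 2]
        ll = late.groupby("model_kind")["L_step_norm"].mean()
        styles = manifest[["participant_id", "navigator_style"]].drop_duplicates()
        groups = subgroup_analysis(fits, styles, metric="step")
        rows.append(
            {
                "replicate": rep,
                "wall_frac_FB": float(wf["FB"]),
                "wall_frac_MBr": float(wf["MBr"]),
                "wall_frac_MBu": float(wf["MBu"]),
                "step_mean_nowall": mean_nowall,
                "step_mean_wall": mean_wall,
                "loglik_FB": float(ll["FB"]),
                "loglik_MBr": float(ll["MBr"]),
                "loglik_MBu": float(ll["MBu"]),
                "wall_frac_ordered": bool(
                    wf["MBr"] > wf["FB"] and wf["MBu"] > wf["FB"]
                ),
                "step_means_ordered": bool(mean_nowall > mean_wall),
                "loglik_ordered": bool(
                    ll["MBu"] >= ll["MBr"] and ll["MBr"] >= ll["FB"]
                ),
                "allo_sig": _mbr_mbu_significant(groups.get("allocentric", [])),
                "ego_sig": _mbr_mbu_significant(groups.get("egocentric", [])),
            }
        )
    return pd.DataFrame(rows)


def battery_summary(battery: pd.DataFrame) -> dict[str, float]:
    """Replicate-level rates and pooled magnitudes, percentages in 0-100."""
    n = len(battery)
    return {
        "wall_frac_direction_rate_pct": 100.0 * battery["wall_frac_ordered"].mean(),
        "step_mean_direction_rate_pct": 100.0 * battery["step_means_ordered"].mean(),
        "loglik_ordering_rate_pct": 100.0 * battery["loglik_ordered"].mean(),
        "allo_mbr_mbu_sig_rate_pct": 100.0 * battery["allo_sig"].mean(),
        "ego_mbr_mbu_sig_rate_pct": 100.0 * battery["ego_sig"].mean(),
        "wall_label_fraction_fb_pct": 100.0 * battery["wall_frac_FB"].mean(),
        "wall_label_fraction_mbr_pct": 100.0 * battery["wall_frac_MBr"].mean(),
        "wall_label_fraction_mbu_pct": 100.0 * battery["wall_frac_MBu"].mean(),
        "step_mean_nowall_cm": 100.0 * battery["step_mean_nowall"].mean(),
        "step_mean_wall_cm": 100.0 * battery["step_mean_wall"].mean(),
        "norm_loglik_step_fb": battery["loglik_FB"].mean(),
        "norm_loglik_step_mbr": battery["loglik_MBr"].mean(),
        "norm_loglik_step_mbu": battery["loglik_MBu"].mean(),
        "n_replicates": float(n),
    }
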