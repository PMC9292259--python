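"""End-to-end orchestration: trial records -> model runs -> fits table.

For every trial, each of the three models labels the steps, the eight
movement parameters are fit per label class, and the trial's normalized
log-likelihoods are scored.  The map-updating model carries its final map
across the trials of a maze (in trial order); the other two never do.
Noise RNG streams are derived from one master seed and the (participant,
maze, trial) index — shared across models so that MBr and MBu see the same
noise and coincide exactly on trial 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import fit_model_params, log_likelihood
from .models import MODEL_KINDS, NoiseSpec, WallCriterionConfig, run_model
from .simulate import TrialRecord
from .util import child_seed

FIT_COLUMNS = [
    "participant_id",
    "navigator_style",
    "maze_id",
    "trial_index",
    "model_kind",
    "alpha_nowall",
    "beta_nowall",
    "alpha_wall",
    "beta_wall",
    "mu_nowall",
    "sigma_nowall",
    "mu_wall",
    "sigma_wall",
    "n_wall",
    "n_nowall",
    "wall_fraction",
    "L_step",
    "L_turn",
    "L_step_norm",
    "L_turn_norm",
]


def _param_row(params) -> dict:
    def g(p, attr):
        return np.nan if p is None else getattr(p, attr)

    return {
        "alpha_nowall": g(params.gamma_nowall, "shape"),
        "beta_nowall": g(params.gamma_nowall, "scale"),
        "alpha_wall": g(params.gamma_wall, "shape"),
        "beta_wall": g(params.gamma_wall, "scale"),
        "mu_nowall": g(params.vm_nowall, "location"),
        "sigma_nowall": g(params.vm_nowall, "dispersion"),
        "mu_wall": g(params.vm_wall, "location"),
        "sigma_wall": g(params.vm_wall, "dispersion"),
        "n_wall": params.n_wall,
        "n_nowall": params.n_nowall,
    }


def fit_trial_models(
    records: list[TrialRecord],
    seed: int = 0,
    noise_cov: np.ndarray | None = None,
    config: WallCriterionConfig | None = None,
    abs_turn: bool = False,
    room: tuple[float, float] = (8.0, 9.0),
) -> pd.DataFrame:
    """Run FB/MBr/MBu over a cohort of trial records and fit each run.

    Returns the long fits table (one row per trial x model).  Trials whose
    label classes are too small to fit keep their parameter columns but
    get NaN likelihoods; downstream comparisons drop such units.
    """
    participants = sorted({r.participant_id for r in records})
    mazes = sorted({r.maze_id for r in records})
    p_idx = {p: i for i, p in enumerate(participants)}
    m_idx = {m: i for i, m in enumerate(mazes)}

    rows = []
    for pid in participants:
        for maze_id in mazes:
            trials = sorted(
                (r for r in records if r.participant_id == pid and r.maze_id == maze_id),
                key=lambda r: r.trial_index,
            )
            carry = None
            for rec in trials:
                series = rec.to_motion_series()
                noise_seed = child_seed(seed, p_idx[pid], m_idx[maze_id], rec.trial_index)
                for kind in MODEL_KINDS:
                    noise = NoiseSpec(
                        covariance=(
                            noise_cov if noise_cov is not None else NoiseSpec().covariance
                        ),
                        seed=noise_seed,
                    )
                    run = run_model(
                        series,
                        kind,
                        carry_map=(carry if kind == "MBu" else None),
                        noise=noise,
                        config=config,
                        room=room,
                    )
                    if kind == "MBu":
                        carry = run.final_map
                    params = fit_model_params(run.motions, run.labels, abs_turn=abs_turn)
                    row = {
                        "participant_id": pid,
                        "navigator_style": rec.navigator_style,
                        "maze_id": maze_id,
                        "trial_index": rec.trial_index,
                        "model_kind": kind,
                        "wall_fraction": run.labels.wall_fraction,
                        **_param_row(params),
                    }
                    try:
                        fr = log_likelihood(params, run.motions, run.labels, abs_turn=abs_turn)
                        row.update(
                            L_step=fr.loglik_step,
                            L_turn=fr.loglik_turn,
                            L_step_norm=fr.normalized_step,
                            L_turn_norm=fr.normalized_turn,
                        )
                    except ValueError:
                        row.update(
                            L_step=np.nan, L_turn=np.nan,
                            L_step_norm=np.nan, L_turn_norm=np.nan,
                        )
                    rows.append(row)
    return pd.DataFrame(rows, columns=FIT_COLUMNS)
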