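"""The three navigation models: feedback-only (FB), map-resetting (MBr),
and map-updating (MBu).

All three share the same state machinery.  The navigator cannot see, so the
model replaces each measured motion vector V* with a noisy estimate
V = V* + |V*| eps, eps ~ N(0, Sigma), and dead-reckons position by summing
the estimates from the measured start — a planar random walk whose drift
variance grows linearly with step count.  The estimated hand position is
the estimated body position plus the measured hand-body offset.

The models differ only in how they predict, before each step, whether a
wall lies immediately ahead:

* FB  — a hand beep received on the previous step while reaching within
  +/-45 degrees of the previous heading, or a head beep;
* MBr / MBu — a learned Gaussian-mixture mental map queried 5-20 cm ahead
  and 5-30 cm to the sides (wall evidence must rise ahead and open-space
  evidence must rise laterally, both relative to the current position);
  MBr starts each trial with a fresh map, MBu inherits the map from
  earlier trials of the same maze.  On the first trial the two are
  identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mental_map import MentalMap, update_map
from .preprocess import MotionSeries, MotionVectors, motion_vectors
from .util import wrap_angle

MODEL_KINDS = ("FB", "MBr", "MBu")

#: Printed displacement-noise covariance (m^2 per unit step length).
DEFAULT_NOISE_COV = np.array([[0.002, 0.0005], [0.0005, 0.002]])


@dataclass
class NoiseSpec:
    """Gaussian motion-estimate noise: V = V* + |V*| eps, eps ~ N(0, cov)."""

    covariance: np.ndarray = field(default_factory=lambda: DEFAULT_NOISE_COV.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("noise covariance must be a symmetric 2x2 matrix")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-12:
            raise ValueError("noise covariance must be positive semi-definite")
        self.covariance = cov
        # PSD square root via eigendecomposition (cholesky fails at rank deficiency)
        w, q = np.linalg.eigh(cov)
        self._sqrt = q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


@dataclass
class DeadReckonState:
    """Estimated pose after step ``step_index``."""

    step_index: int
    body_est: np.ndarray
    body_measured_start: np.ndarray
    hand_offset: np.ndarray

    @property
    def hand_est(self) -> np.ndarray:
        return self.body_est + self.hand_offset


@dataclass
class WallCriterionConfig:
    """Geometry of the wall-ahead criteria.

    feedback_halfwidth: angular gate (rad) around the previous heading for
    hand-beep evidence; ahead_range / lateral_range: probe intervals (m)
    along the heading and at +/-90 degrees; probe_spacing: probe step (m);
    lateral_rule: whether the lateral open-space condition must hold on
    either one side or on both.
    """

    feedback_halfwidth: float = np.pi / 4
    ahead_range: tuple[float, float] = (0.05, 0.20)
    lateral_range: tuple[float, float] = (0.05, 0.30)
    probe_spacing: float = 0.025
    lateral_rule: str = "either_side"

    def __post_init__(self) -> None:
        for lo, hi in (self.ahead_range, self.lateral_range):
            if not (0 < lo < hi):
                raise ValueError("probe ranges must be positive and ordered")
        if self.lateral_rule not in ("either_side", "both_sides"):
            raise ValueError("lateral_rule must be 'either_side' or 'both_sides'")


@dataclass
class StepLabelSeq:
    """Per-step wall/no-wall labels produced by one model on one trial."""

    labels: np.ndarray  # bool, True = wall predicted ahead
    model_kind: str

    @property
    def wall_fraction(self) -> float:
        return float(np.mean(self.labels)) if len(self.labels) else 0.0


def add_motion_noise(v_measured, noise: NoiseSpec, rng: np.random.Generator):
    """One noisy motion estimate: v + ||v|| * eps with eps ~ N(0, cov).

    A zero measured displacement is returned unchanged (the noise scales
    with step length).  Draws exactly one 2-vector from ``rng``.
    """
    v = np.asarray(v_measured, dtype=float)
    eps = noise._sqrt @ rng.standard_normal(2)
    return v + np.hypot(v[0], v[1]) * eps


def dead_reckon(
    v_estimated: np.ndarray, start, hand_offsets: np.ndarray
) -> list[DeadReckonState]:
    """Cumulative-sum position estimates from the measured start.

    v_estimated: (T, 2) noisy step estimates; hand_offsets: (T, 2) measured
    hand-body offsets U*_t.  Returns one state per step.
    """
    v_estimated = np.asarray(v_estimated, dtype=float)
    if v_estimated.ndim != 2 or len(v_estimated) == 0:
        raise ValueError("need a non-empty (T, 2) motion sequence")
    hand_offsets = np.asarray(hand_offsets, dtype=float)
    if hand_offsets.shape != v_estimated.shape:
        raise ValueError("motions and hand_offsets must have equal length")
    start = np.asarray(start, dtype=float)
    body = start + np.cumsum(v_estimated, axis=0)
    return [
        DeadReckonState(
            step_index=t + 1,
            body_est=body[t],
            body_measured_start=start,
            hand_offset=hand_offsets[t],
        )
        for t in range(len(body))
    ]


def fb_wall_ahead(
    hand_beep: bool,
    beep_bearing: float,
    head_beep: bool,
    config: WallCriterionConfig,
) -> bool:
    """Feedback-only criterion: hand beep within the angular gate, or head beep."""
    if head_beep:
        return True
    return bool(hand_beep) and abs(beep_bearing) <= config.feedback_halfwidth


def _probe_offsets(rng: tuple[float, float], spacing: float) -> np.ndarray:
    lo, hi = rng
    n = int(np.floor((hi - lo) / spacing + 1e-9)) + 1
    return lo + spacing * np.arange(n)


def mb_wall_ahead(
    mmap: MentalMap,
    body_est,
    heading: float,
    config: WallCriterionConfig,
) -> bool:
    """Map-based criterion: wall evidence ahead, open-space evidence beside.

    (a) max wall density over probes 5-20 cm along the heading exceeds the
    wall density at the current estimated position AND max no-wall density
    over those probes is below the no-wall density here; (b) on a
    qualifying side (per lateral_rule), max no-wall density over probes
    5-30 cm at +/-90 degrees exceeds the no-wall density here AND max wall
    density there is below the wall density here.  All inequalities strict,
    so a never-updated (uniform) map yields False.
    """
    p = np.asarray(body_est, dtype=float)
    u = np.array([np.cos(heading), np.sin(heading)])
    left = np.array([-u[1], u[0]])

    w, h = mmap.room
    if not (0 <= p[0] <= w and 0 <= p[1] <= h):
        # the dead-reckoned estimate has drifted out of the room: no
        # in-room evidence can be compared, so no wall is predicted
        return False

    def clip_room(pts: np.ndarray) -> np.ndarray:
        # probes that fall outside the room carry no evidence either way
        ok = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
        return pts[ok]

    here_wall = mmap.density(p, "wall")
    here_nowall = mmap.density(p, "nowall")

    ahead = clip_room(p + np.outer(_probe_offsets(config.ahead_range, config.probe_spacing), u))
    if len(ahead) == 0:
        return False
    cond_a = (
        mmap.density(ahead, "wall").max() > here_wall
        and mmap.density(ahead, "nowall").max() < here_nowall
    )
    if not cond_a:
        return False

    lat_off = _probe_offsets(config.lateral_range, config.probe_spacing)
    side_ok = []
    for sgn in (+1.0, -1.0):
        pts = clip_room(p + np.outer(lat_off, sgn * left))
        if len(pts) == 0:
            side_ok.append(False)
            continue
        side_ok.append(
            mmap.density(pts, "nowall").max() > here_nowall
            and mmap.density(pts, "wall").max() < here_wall
        )
    if config.lateral_rule == "either_side":
        return any(side_ok)
    return all(side_ok)


@dataclass
class ModelRun:
    """Everything one model produced on one trial."""

    labels: StepLabelSeq
    final_map: MentalMap | None
    states: list[DeadReckonState] | None
    motions: MotionVectors


def run_model(
    series: MotionSeries,
    model_kind: str,
    carry_map: MentalMap | None = None,
    noise: NoiseSpec | None = None,
    config: WallCriterionConfig | None = None,
    seed: int | None = None,
    room: tuple[float, float] = (8.0, 9.0),
) -> ModelRun:
    """Label every motion step of a trial as wall/no-wall under one model.

    Labels are predictive: the label of step t uses only information
    available before the step (feedback up to sample t-1 for FB; the map
    and dead-reckoned pose after step t-1 for MBr/MBu).  Map models then
    apply the motion-noise/dead-reckoning update and absorb step t's
    feedback into the map.  The first step, which has no previous heading,
    is labelled no-wall.

    carry_map is only legal for MBu; passing None there (trial 1) makes
    MBu bit-identical to MBr.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    if carry_map is not None and model_kind != "MBu":
        raise ValueError("carry_map is only permitted for the map-updating model")
    noise = noise if noise is not None else NoiseSpec()
    config = config if config is not None else WallCriterionConfig()
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    mv = motion_vectors(series)
    T = mv.n_steps
    labels = np.zeros(T, dtype=bool)

    if model_kind == "FB":
        # bearing of the reaching arm at sample t-1, against heading theta_{t-1}
        arm = series.hand - series.torso_com
        arm_angle = np.arctan2(arm[:, 1], arm[:, 0])
        for t in range(1, T):
            bearing = wrap_angle(arm_angle[t] - mv.heading[t - 1])
            labels[t] = fb_wall_ahead(
                bool(series.hand_beep[t]),
                float(bearing),
                bool(series.head_beep[t]),
                config,
            )
        return ModelRun(
            labels=StepLabelSeq(labels=labels, model_kind="FB"),
            final_map=None,
            states=None,
            motions=mv,
        )

    mmap = carry_map.copy() if carry_map is not None else MentalMap(room=room)
    start = series.torso_com[0]
    body_est = start.copy()
    states: list[DeadReckonState] = []
    for t in range(1, T + 1):  # motion step t covers samples t-1 -> t
        if t >= 2:
            labels[t - 1] = mb_wall_ahead(mmap, body_est, mv.heading[t - 2], config)
        v_est = add_motion_noise(mv.v_measured[t - 1], noise, rng)
        body_est = body_est + v_est
        hand_offset = series.hand[t] - series.torso_com[t]
        state = DeadReckonState(
            step_index=t,
            body_est=body_est.copy(),
            body_measured_start=start,
            hand_offset=hand_offset,
        )
        states.append(state)
        update_map(
            mmap,
            state.hand_est,
            state.body_est,
            bool(series.hand_beep[t]),
            bool(series.head_beep[t]),
        )
    return ModelRun(
        labels=StepLabelSeq(labels=labels, model_kind=model_kind),
        final_map=mmap,
        states=states,
        motions=mv,
    )
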