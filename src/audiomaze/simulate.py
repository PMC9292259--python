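"""Synthetic maze-walker: the generative twin of the navigation models.

Simulates a blindfolded agent exploring an invisible corridor maze at 2 Hz
(one decision per 500 ms).  Exploration alternates between two regimes
that mirror the wall/no-wall split of the analysis models:

* **walking** — ballistic bouts along a held course (vestibular course
  stabilization), with occasional exploratory arm reaches; step lengths
  follow the no-wall Gamma, turns the no-wall von Mises around the course
  correction;
* **wall examination (dwell)** — after noticing a wall (an auditory touch
  it reacts to, or its mental map predicting a wall ahead) the agent walks
  up to the wall and stands at it for a geometrically distributed number
  of steps, wobbling in place (wall-regime Gamma/von Mises draws) while
  patting the surface in reach-withdraw cycles, then departs on a course
  chosen from its map.

The agent cannot see: it dead-reckons its position with the same
noise-corrupted motion estimate the analysis models assume, and its mental
map lives entirely in those estimated coordinates.  Body steps are clipped
1 cm before wall contact; the reaching hand stops at the first wall within
arm's reach and the "hand beep" sounds when it ends up within the touch
threshold ("head beep": the torso itself within threshold).

Policies mirror the analysis models: ``feedback_reactive`` agents notice
walls through beeps only; ``map_reset`` agents build a fresh mental map
every trial; ``map_update`` agents inherit the map across the three trials
of a maze.  Map carrying pays off through informed departure courses and
map-predicted caution at walls the agent has not yet touched this trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .maze import MazeSpec, wall_touch_query
from .mental_map import MentalMap, update_map
from .models import NoiseSpec, WallCriterionConfig, add_motion_noise, mb_wall_ahead
from .preprocess import MotionSeries, RawMocapTrack
from .util import child_seed, wrap_angle

POLICIES = ("feedback_reactive", "map_reset", "map_update")

#: angular spread (rad) of wall-patting reaches around the wallward direction
PAT_JITTER = 0.6

TRIAL_CSV_COLUMNS = [
    "time_s",
    "torso_x",
    "torso_y",
    "hand_x",
    "hand_y",
    "head_x",
    "head_y",
    "hand_beep",
    "head_beep",
]


@dataclass
class AgentParams:
    """Ground-truth movement parameters of one synthetic walker.

    Step sizes (m) are Gamma(shape, scale); turning angles (rad) are
    von Mises(location, concentration), one pair of generators per
    wall/no-wall regime.  Defaults give mean steps of 6.6 cm walking and
    2.25 cm at walls (a slow, careful blindfolded pace).

    Behavioural parameters: ``reach_prob`` — chance per walking step of a
    full-arm exploratory reach; ``react_prob`` — chance a beep is acted on
    (subjects miss or ignore some feedback); ``dwell_mean`` — mean length
    (steps) of a wall examination; ``pat_prob`` — chance per dwell step
    that the hand pats the wall rather than riding withdrawn;
    ``refractory`` — walking steps after a dwell before re-engaging;
    ``arm_sweep_sd`` — angular spread (rad) of exploratory reaches around
    the walking direction.  ``informed_turns`` enables map-informed
    departure courses and corridor steering; ``course_stabilize`` the
    ballistic walking bouts.  Both are on for the study conditions; switch
    them off for pure regime-switched kinematics.
    """

    gamma_wall: tuple[float, float] = (1.5, 0.015)
    gamma_nowall: tuple[float, float] = (2.0, 0.033)
    vm_wall: tuple[float, float] = (0.4, 1.5)
    vm_nowall: tuple[float, float] = (0.0, 4.0)
    hand_reach: float = 0.6
    touch_threshold: float = 0.05
    arm_sweep_sd: float = 1.2
    reach_prob: float = 0.35
    react_prob: float = 0.7
    dwell_mean: float = 8.0
    pat_prob: float = 0.3
    refractory: int = 10
    policy: str = "map_update"
    informed_turns: bool = True
    course_stabilize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gamma_wall", "gamma_nowall"):
            shape, scale = getattr(self, name)
            if shape <= 0 or scale <= 0:
                raise ValueError(f"{name} shape/scale must be strictly positive")
        for name in ("vm_wall", "vm_nowall"):
            _, kappa = getattr(self, name)
            if kappa <= 0:
                raise ValueError(f"{name} concentration must be strictly positive")
        if self.policy not in POLICIES:
            raise ValueError(f"policy must be one of {POLICIES}")

    def param_dict(self) -> dict[str, float]:
        return {
            "true_alpha_wall": self.gamma_wall[0],
            "true_beta_wall": self.gamma_wall[1],
            "true_alpha_nowall": self.gamma_nowall[0],
            "true_beta_nowall": self.gamma_nowall[1],
            "true_mu_wall": self.vm_wall[0],
            "true_kappa_wall": self.vm_wall[1],
            "true_mu_nowall": self.vm_nowall[0],
            "true_kappa_nowall": self.vm_nowall[1],
        }


@dataclass
class TrialRecord:
    """One simulated (or loaded) maze exploration at 2 Hz."""

    participant_id: str
    navigator_style: str
    maze_id: str
    trial_index: int
    samples: pd.DataFrame
    sample_rate: float = 2.0

    def __post_init__(self) -> None:
        missing = set(TRIAL_CSV_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"trial samples missing columns {sorted(missing)}")
        dt = np.diff(self.samples["time_s"].to_numpy())
        if len(dt) and (dt <= 0).any():
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_motion_series(self) -> MotionSeries:
        s = self.samples
        return MotionSeries(
            times=s["time_s"].to_numpy(dtype=float),
            torso_com=s[["torso_x", "torso_y"]].to_numpy(dtype=float),
            hand=s[["hand_x", "hand_y"]].to_numpy(dtype=float),
            head=s[["head_x", "head_y"]].to_numpy(dtype=float),
            hand_beep=s["hand_beep"].to_numpy(dtype=bool),
            head_beep=s["head_beep"].to_numpy(dtype=bool),
            sample_rate=self.sample_rate,
        )

    def to_csv(self, path_or_buf=None):
        out = self.samples.copy()
        out["hand_beep"] = out["hand_beep"].astype(int)
        out["head_beep"] = out["head_beep"].astype(int)
        return out.to_csv(path_or_buf, index=False, columns=TRIAL_CSV_COLUMNS)

    @classmethod
    def from_csv(
        cls,
        path_or_buf,
        participant_id: str = "?",
        navigator_style: str = "?",
        maze_id: str = "?",
        trial_index: int = 1,
    ) -> "TrialRecord":
        df = pd.read_csv(path_or_buf)
        df["hand_beep"] = df["hand_beep"].astype(bool)
        df["head_beep"] = df["head_beep"].astype(bool)
        return cls(participant_id, navigator_style, maze_id, trial_index, df)


def _unit(angle: float) -> np.ndarray:
    return np.array([np.cos(angle), np.sin(angle)])


def _escape_course(
    mmap: MentalMap | None,
    pos: np.ndarray,
    heading: float,
    rng: np.random.Generator,
) -> float:
    """Choose a departure course after examining a wall.

    Candidate courses fan out around the current heading; each is scored by
    the map's open-space evidence minus wall evidence over probes 0.3-0.9 m
    out.  Without a map, or when nothing distinguishes the candidates, a
    random candidate is taken — this is exactly where a carried map pays
    off: at a bend or dead end it points the agent down the corridor
    instead of back the way it came.
    """
    candidates = heading + np.array([0.0, 0.6, -0.6, 1.2, -1.2, 1.8, -1.8])
    if mmap is None:
        return wrap_angle(float(rng.choice(candidates)))
    w, h = mmap.room
    dists = np.arange(0.3, 0.95, 0.2)
    scores = np.full(len(candidates), -np.inf)
    for i, cand in enumerate(candidates):
        pts = pos + np.outer(dists, _unit(cand))
        ok = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
        if not ok.any():
            continue
        scores[i] = float(
            mmap.density(pts[ok], "nowall").max() - mmap.density(pts[ok], "wall").max()
        )
    best = scores.max()
    if not np.isfinite(best):
        return wrap_angle(float(rng.choice(candidates)))
    # random tie-break among near-best candidates (fresh maps score flat)
    near = np.flatnonzero(scores >= best - 1e-9)
    return wrap_angle(float(candidates[rng.choice(near)]))


def _steer_course(
    mmap: MentalMap | None,
    pos: np.ndarray,
    course: float,
    rng: np.random.Generator,
) -> float:
    """Re-aim the held course along mapped open space.

    Scores candidate courses (course and +/-0.4 rad) by the mapped no-wall
    evidence minus wall evidence over probes 0.3-0.9 m ahead and keeps the
    best; with no map (or no evidence) the course is unchanged.  This is
    how a carried map pays off in open corridor: the agent cruises along
    known open space instead of zigzagging into walls.
    """
    if mmap is None:
        return course
    w, h = mmap.room
    dists = np.arange(0.3, 0.95, 0.2)
    best, best_score = course, -np.inf
    for delta in (0.0, 0.25, -0.25):
        cand = course + delta
        pts = pos + np.outer(dists, _unit(cand))
        ok = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
        if not ok.any():
            continue
        score = float(
            mmap.density(pts[ok], "nowall").max() - mmap.density(pts[ok], "wall").max()
        )
        if score > best_score + 1e-12:
            best, best_score = cand, score
    return wrap_angle(best)


def simulate_trial(
    maze: MazeSpec,
    agent: AgentParams,
    carry_map: MentalMap | None = None,
    seed: int | None = None,
    step_cap: int = 600,
    participant_id: str = "sim",
    navigator_style: str = "allocentric",
    trial_index: int = 1,
) -> tuple[TrialRecord, MentalMap | None]:
    """Walk one agent through one maze; returns the record and, for
    map-using policies, the final internal map.

    Per 500 ms step the agent (i) predicts wall/no-wall via its policy,
    (ii) draws a turn and a step from that regime's generators, (iii) is
    clipped 1 cm before any wall contact, and (iv) emits feedback from the
    resulting hand/torso positions.  The trial ends on crossing the exit
    segment or at ``step_cap`` steps.
    """
    if step_cap <= 0:
        raise ValueError("step_cap must be positive")
    if carry_map is not None and agent.policy != "map_update":
        raise ValueError("carry_map is only permitted for the map_update policy")
    touching, dist = wall_touch_query(maze.start_position, maze, agent.touch_threshold)
    if touching:
        raise ValueError(
            f"agent start {maze.start_position} is inside/on a wall (distance {dist:.3f} m)"
        )

    rng = np.random.default_rng(agent.seed if seed is None else seed)
    config = WallCriterionConfig(ahead_range=(0.05, 0.20), lateral_range=(0.05, 0.30))
    uses_map = agent.policy in ("map_reset", "map_update")
    mmap = carry_map.copy() if carry_map is not None else (
        MentalMap(room=(maze.room_width, maze.room_height)) if uses_map else None
    )

    pos = np.asarray(maze.start_position, dtype=float)
    heading = float(maze.start_heading)
    course = heading
    # the agent cannot see: it only knows a dead-reckoned position estimate,
    # which is also where its mental map is built (the map and the map
    # criterion live entirely in estimated coordinates)
    noise = NoiseSpec()
    est_pos = pos.copy()
    # navigation state machine: cruise (walking), approach (walking toward a
    # noticed wall), dwell (standing at the wall, examining it)
    state = "cruise"
    dwell_left = 0
    approach_left = 0
    refractory_left = 0  # after a dwell, walk away before re-engaging

    def sense(position: np.ndarray, hd: float, probing: bool) -> tuple[np.ndarray, float, bool, bool]:
        # while examining a wall the hand pats the touched surface in
        # reach-withdraw cycles; while walking the arm sweeps around the
        # walking direction and reaches out only now and then
        if probing:
            _, toward = maze.nearest_wall(position)
            aim = float(np.arctan2(toward[1], toward[0])) + rng.normal(0.0, PAT_JITTER)
            bearing = wrap_angle(aim - hd)
            extent = agent.hand_reach if rng.random() < agent.pat_prob else 0.05
        else:
            bearing = rng.normal(0.0, agent.arm_sweep_sd)
            aim = hd + bearing
            extent = agent.hand_reach if rng.random() < agent.reach_prob else 0.15
        u = _unit(aim)
        reach = maze.first_wall_hit(position, u, extent)
        hand = position + reach * u + rng.normal(0.0, 0.02, size=2)
        dists = maze.wall_distances(np.vstack([hand, position]))
        hand_beep = bool(dists[0] <= agent.touch_threshold)
        head_beep = bool(dists[1] <= agent.touch_threshold)
        return hand, bearing, hand_beep, head_beep

    rows = []
    true_regimes = []  # ground-truth wall/no-wall regime per motion step
    hand, arm_bearing, hand_beep, head_beep = sense(pos, heading, probing=False)
    head = pos + rng.normal(0.0, 0.01, size=2)
    rows.append((0.0, *pos, *hand, *head, hand_beep, head_beep))
    prev_heading = heading

    for t in range(1, step_cap + 1):
        # (i) update the navigation state.  A touch (reacted to with some
        # probability — subjects miss or ignore some feedback) or, for map
        # agents, the map's wall-ahead prediction makes the agent walk up
        # to the wall; once there it dwells, examining the wall with small
        # wobbly steps and hand pats, then departs on a course chosen from
        # its map (or at random).
        true_dist, toward = maze.nearest_wall(pos)

        def dwell_length() -> int:
            return 1 + int(rng.geometric(1.0 / agent.dwell_mean))

        if state == "cruise":
            refractory_left -= 1
            noticed = refractory_left <= 0 and (
                ((hand_beep or head_beep) and rng.random() < agent.react_prob)
                or (uses_map and mb_wall_ahead(mmap, est_pos, prev_heading, config))
            )
            if noticed:
                if true_dist <= 0.25:
                    state = "dwell"
                    dwell_left = dwell_length()
                else:
                    state = "approach"
                    approach_left = 15
                    course = float(np.arctan2(toward[1], toward[0]))
        elif state == "approach":
            approach_left -= 1
            course = float(np.arctan2(toward[1], toward[0]))
            if true_dist <= 0.25:
                state = "dwell"
                dwell_left = dwell_length()
            elif approach_left <= 0:
                state = "cruise"

        wall_regime = state == "dwell"
        true_regimes.append(wall_regime)

        # (ii) draw turn and step from the regime's generators
        if wall_regime:
            dwell_left -= 1
            mu, kappa = agent.vm_wall
            shape, scale = agent.gamma_wall
            if true_dist < 0.12:
                # keep the head clear of the wall while examining it
                away = float(np.arctan2(-toward[1], -toward[0]))
                theta = rng.vonmises(wrap_angle(away - heading), kappa)
            else:
                theta = rng.vonmises(abs(mu), kappa)
                if rng.random() < 0.5:
                    theta = -theta  # probing wobble has no preferred side
            if dwell_left <= 0:
                # dwell over: depart along mapped open space (or at random),
                # and do not immediately re-examine the same wall
                state = "cruise"
                refractory_left = agent.refractory
                course = (
                    _escape_course(mmap, est_pos, heading, rng)
                    if agent.informed_turns
                    else wrap_angle(heading + float(rng.uniform(-np.pi, np.pi)))
                )
        else:
            mu, kappa = agent.vm_nowall
            shape, scale = agent.gamma_nowall
            if agent.course_stabilize:
                # steer back toward the held course (vestibular sense keeps
                # blindfolded walking roughly ballistic between wall contacts);
                # map agents in open space also re-aim along mapped corridors
                if agent.informed_turns and state == "cruise":
                    course = _steer_course(mmap, est_pos, course, rng)
                mu = wrap_angle(course - heading)
            theta = rng.vonmises(mu, kappa)
        d = rng.gamma(shape, scale)
        prev_heading = heading
        heading = wrap_angle(heading + theta)
        u = _unit(heading)

        # (iii) clip the step 1 cm before wall contact; a blocked walking
        # step makes the agent turn away rather than push into the wall
        hit = maze.first_wall_hit(pos, u, d)
        step_len = d if hit >= d else max(hit - 0.01, 0.0)
        new_pos = pos + step_len * u
        if not wall_regime and d > 0 and step_len < 0.005:
            course = (
                _escape_course(mmap, est_pos, heading, rng)
                if agent.informed_turns
                else wrap_angle(heading + float(rng.uniform(-np.pi, np.pi)))
            )

        # (iv) sense, dead-reckon, and record
        hand, arm_bearing, hand_beep, head_beep = sense(new_pos, heading, probing=wall_regime)
        head = new_pos + rng.normal(0.0, 0.01, size=2)
        rows.append((0.5 * t, *new_pos, *hand, *head, hand_beep, head_beep))

        v_true = new_pos - pos
        est_pos = est_pos + add_motion_noise(v_true, noise, rng)
        if uses_map:
            update_map(mmap, est_pos + (hand - new_pos), est_pos, hand_beep, head_beep)

        exited = step_len > 0 and maze.crossed_exit(pos, new_pos)
        pos = new_pos
        if exited:
            break

    df = pd.DataFrame(rows, columns=TRIAL_CSV_COLUMNS)
    df["hand_beep"] = df["hand_beep"].astype(bool)
    df["head_beep"] = df["head_beep"].astype(bool)
    record = TrialRecord(
        participant_id=participant_id,
        navigator_style=navigator_style,
        maze_id=maze.shape_id,
        trial_index=trial_index,
        samples=df,
    )
    # ground-truth regime labels (one per motion step), kept in memory for
    # parameter-recovery oracles; not part of the on-disk trial format
    record.true_wall_regime = np.asarray(true_regimes, dtype=bool)
    return record, (mmap if uses_map else None)


def simulate_cohort(
    n_participants: int,
    mazes: list[MazeSpec],
    trials_per_maze: int = 3,
    style_split: float = 0.5,
    seed: int = 0,
    agent_params: AgentParams | None = None,
    step_cap: int = 600,
    drop_rate: float = 0.0,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Simulate a full cohort; returns trial records and a ground-truth manifest.

    The first round(style_split * n) participants are allocentric and walk
    with the map-carrying ``map_update`` policy; the rest are egocentric
    and reset their map every trial (``map_reset``).  Per-trial RNG streams
    are derived from ``seed`` and the (participant, maze, trial) index, so
    identical calls are bit-identical.  ``drop_rate`` optionally discards
    trials at random, mimicking unusable recordings.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if trials_per_maze < 1:
        raise ValueError("need at least 1 trial per maze")
    if not (0.0 <= style_split <= 1.0):
        raise ValueError("style_split must lie in [0, 1]")
    base = agent_params if agent_params is not None else AgentParams()
    n_allo = int(round(style_split * n_participants))

    drop_rng = np.random.default_rng(child_seed(seed, 999_983))
    records: list[TrialRecord] = []
    manifest_rows = []
    for p in range(n_participants):
        style = "allocentric" if p < n_allo else "egocentric"
        policy = "map_update" if style == "allocentric" else "map_reset"
        # navigator style shapes strategy: allocentric walkers lean on their
        # (carried) world-centred map and often let momentary feedback pass,
        # egocentric walkers react to nearly every touch
        react = 0.45 if style == "allocentric" else 0.85
        agent = replace(base, policy=policy, react_prob=react)
        pid = f"P{p + 1:02d}"
        for m, maze in enumerate(mazes):
            carry: MentalMap | None = None
            for trial in range(1, trials_per_maze + 1):
                trial_seed = child_seed(seed, p, m, trial)
                record, final_map = simulate_trial(
                    maze,
                    agent,
                    carry_map=carry if policy == "map_update" else None,
                    seed=trial_seed,
                    step_cap=step_cap,
                    participant_id=pid,
                    navigator_style=style,
                    trial_index=trial,
                )
                if policy == "map_update":
                    carry = final_map
                if drop_rate > 0 and drop_rng.random() < drop_rate:
                    continue
                records.append(record)
                manifest_rows.append(
                    {
                        "participant_id": pid,
                        "navigator_style": style,
                        "maze_id": maze.shape_id,
                        "trial_index": trial,
                        "policy": policy,
                        "n_samples": record.n_samples,
                        "seed": trial_seed,
                        **agent.param_dict(),
                    }
                )
    return records, pd.DataFrame(manifest_rows)


def to_raw_track(
    record: TrialRecord,
    source_rate: float = 480.0,
    jitter_sd: float = 0.002,
    seed: int = 0,
    n_torso_markers: int = 3,
) -> RawMocapTrack:
    """Re-expand a 2 Hz record into jittered high-rate marker frames.

    Exists to exercise the preprocessing chain: linear interpolation
    between the 2 Hz samples, white positional jitter per frame, several
    torso markers at fixed zero-sum offsets around the centre of mass, and
    each beep placed at the first frame of its 500 ms bin so OR-reduction
    recovers the original flags.
    """
    ratio = source_rate / record.sample_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("source_rate must be an integer multiple of the record rate")
    r = int(round(ratio))
    rng = np.random.default_rng(seed)
    s = record.samples
    n2 = len(s)
    n_frames = (n2 - 1) * r + 1
    t2 = s["time_s"].to_numpy(dtype=float)
    times = np.linspace(t2[0], t2[-1], n_frames)

    def interp(cols: list[str]) -> np.ndarray:
        pts = s[cols].to_numpy(dtype=float)
        out = np.empty((n_frames, 2))
        for k in range(2):
            out[:, k] = np.interp(times, t2, pts[:, k])
        return out

    com = interp(["torso_x", "torso_y"])
    angles = 2 * np.pi * np.arange(n_torso_markers) / n_torso_markers
    offsets = 0.08 * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    offsets -= offsets.mean(axis=0)  # zero-sum: marker mean recovers the com
    markers = {
        f"torso_{i}": com + offsets[i] + rng.normal(0.0, jitter_sd, size=(n_frames, 2))
        for i in range(n_torso_markers)
    }
    markers["hand"] = interp(["hand_x", "hand_y"]) + rng.normal(0.0, jitter_sd, size=(n_frames, 2))
    markers["head"] = interp(["head_x", "head_y"]) + rng.normal(0.0, jitter_sd, size=(n_frames, 2))

    hand_beep = np.zeros(n_frames, dtype=bool)
    head_beep = np.zeros(n_frames, dtype=bool)
    hand_beep[::r] = s["hand_beep"].to_numpy(dtype=bool)
    head_beep[::r] = s["head_beep"].to_numpy(dtype=bool)
    return RawMocapTrack(
        sample_rate=source_rate,
        times=times,
        markers=markers,
        hand_beep=hand_beep,
        head_beep=head_beep,
    )
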