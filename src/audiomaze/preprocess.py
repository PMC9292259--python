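"""Raw motion-capture frames -> 2 Hz torso-centre series -> motion vectors.

The modelling stages consume one motion vector per 500 ms: the displacement
of the torso centre of mass between consecutive 2 Hz samples, expressed as
a step size d (m) and a turning angle theta (rad, the wrapped change of
heading).  Raw marker frames (nominally 480 Hz) are first smoothed with a
centred five-point moving average, then decimated; feedback flags are
OR-reduced into each 500 ms bin so no touch event is lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .util import wrap_angle

#: Steps shorter than this (m) inherit the previous heading: the direction
#: of a sub-millimetre displacement is measurement noise.
MIN_HEADING_STEP = 1e-3


@dataclass
class RawMocapTrack:
    """Per-frame marker positions with role labels.

    markers maps a role label (``torso_0``, ``torso_1``, ..., ``hand``,
    ``head``) to an (n, 2) position array; z coordinates, if recorded,
    are dropped upstream — all modelling is planar.
    """

    sample_rate: float
    times: np.ndarray
    markers: dict[str, np.ndarray]
    hand_beep: np.ndarray
    head_beep: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not any(k.startswith("torso") for k in self.markers):
            raise ValueError("at least one torso-role marker is required")
        for k, v in self.markers.items():
            if v.shape != (n, 2):
                raise ValueError(f"marker {k!r} shape {v.shape} != ({n}, 2)")

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class MotionSeries:
    """2 Hz torso-centre-of-mass series with per-bin feedback flags."""

    times: np.ndarray
    torso_com: np.ndarray
    hand: np.ndarray
    head: np.ndarray
    hand_beep: np.ndarray
    head_beep: np.ndarray
    sample_rate: float = 2.0

    def __post_init__(self) -> None:
        dt = np.diff(self.times)
        expected = 1.0 / self.sample_rate
        if len(dt) and not np.allclose(dt, expected, atol=1e-9):
            raise ValueError(f"samples not uniform at {self.sample_rate} Hz")

    @property
    def n_samples(self) -> int:
        return len(self.times)


@dataclass
class MotionVectors:
    """Per-step kinematics derived from a MotionSeries.

    Step t (1-based over samples) covers samples t-1 -> t.  headings are
    absolute directions of each step; theta[0] is 0 by convention (no
    previous heading exists at the first step).
    """

    v_measured: np.ndarray  # (T, 2) displacements
    d: np.ndarray  # (T,) step sizes, m
    heading: np.ndarray  # (T,) absolute step directions, rad
    theta: np.ndarray  # (T,) wrapped heading changes, rad

    @property
    def n_steps(self) -> int:
        return len(self.d)


def moving_average(track: RawMocapTrack, window: int = 5) -> RawMocapTrack:
    """Centred moving average over ``window`` frames, per marker coordinate.

    Edges use shrinking (truncated) windows so the series length is
    preserved.  window must be odd; a window of 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > track.n_frames:
        raise ValueError(
            f"window {window} exceeds series length {track.n_frames}"
        )
    half = window // 2
    n = track.n_frames
    if window == 1:  # exact identity, no cumsum round-off
        return RawMocapTrack(
            sample_rate=track.sample_rate,
            times=track.times.copy(),
            markers={k: v.copy() for k, v in track.markers.items()},
            hand_beep=track.hand_beep.copy(),
            head_beep=track.head_beep.copy(),
        )

    def smooth(arr: np.ndarray) -> np.ndarray:
        # cumulative-sum trick with clipped window edges
        cs = np.vstack([np.zeros((1, arr.shape[1])), np.cumsum(arr, axis=0)])
        lo = np.clip(np.arange(n) - half, 0, n)
        hi = np.clip(np.arange(n) + half + 1, 0, n)
        return (cs[hi] - cs[lo]) / (hi - lo)[:, None]

    return RawMocapTrack(
        sample_rate=track.sample_rate,
        times=track.times.copy(),
        markers={k: smooth(v) for k, v in track.markers.items()},
        hand_beep=track.hand_beep.copy(),
        head_beep=track.head_beep.copy(),
    )


def downsample(track: RawMocapTrack, target_rate: float = 2.0) -> MotionSeries:
    """Decimate to ``target_rate`` keeping every (source/target)-th frame.

    The torso centre of mass is the arithmetic mean of all torso-role
    markers at each kept frame.  Feedback flags are OR-reduced over each
    output bin (frames [i*r, (i+1)*r)): a single touch anywhere in a bin
    marks the bin.
    """
    ratio = track.sample_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"source rate {track.sample_rate} not an integer multiple of {target_rate}"
        )
    r = int(round(ratio))
    keep = np.arange(0, track.n_frames, r)
    torso_keys = sorted(k for k in track.markers if k.startswith("torso"))
    torso = np.mean([track.markers[k][keep] for k in torso_keys], axis=0)

    def or_reduce(flags: np.ndarray) -> np.ndarray:
        out = np.zeros(len(keep), dtype=bool)
        for i, s in enumerate(keep):
            out[i] = flags[s : s + r].any()
        return out

    return MotionSeries(
        times=track.times[keep],
        torso_com=torso,
        hand=track.markers["hand"][keep],
        head=track.markers["head"][keep],
        hand_beep=or_reduce(np.asarray(track.hand_beep, dtype=bool)),
        head_beep=or_reduce(np.asarray(track.head_beep, dtype=bool)),
        sample_rate=target_rate,
    )


def motion_vectors(series: MotionSeries) -> MotionVectors:
    """Finite-difference kinematics of the 2 Hz torso-centre track.

    d is the Euclidean step length; heading is atan2 of the displacement,
    with sub-millimetre steps inheriting the previous heading; theta is the
    heading change wrapped to (-pi, pi].
    """
    if series.n_samples < 3:
        raise ValueError("need at least 3 samples to compute a turning angle")
    v = np.diff(series.torso_com, axis=0)
    d = np.hypot(v[:, 0], v[:, 1])
    heading = np.arctan2(v[:, 1], v[:, 0])
    for t in range(1, len(d)):
        if d[t] < MIN_HEADING_STEP:
            heading[t] = heading[t - 1]
    theta = np.zeros_like(d)
    theta[1:] = wrap_angle(np.diff(heading))
    return MotionVectors(v_measured=v, d=d, heading=heading, theta=theta)
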