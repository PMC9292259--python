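"""Gaussian-mixture mental maps of wall and no-wall evidence.

The map-based navigation models carry two spatial probability fields over
the room: one accumulating "wall here" evidence and one accumulating "open
space here" evidence.  Both start uniform; each movement step appends one
isotropic Gaussian component — at the estimated hand position when the hand
feedback sounded (wall field), at the estimated body position when no
feedback sounded (no-wall field).  Steps where only the head contacted a
wall leave both fields untouched.  Fields are unnormalized accumulations:
every criterion that consumes them compares densities of the same field at
different locations, so normalization would cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    @njit(cache=True)
    def _mix_sum(pts, mu, p00, p01, p11):
        out = np.zeros(pts.shape[0])
        for i in range(pts.shape[0]):
            acc = 0.0
            for j in range(mu.shape[0]):
                dx = pts[i, 0] - mu[j, 0]
                dy = pts[i, 1] - mu[j, 1]
                acc += np.exp(-0.5 * (p00 * dx * dx + 2.0 * p01 * dx * dy + p11 * dy * dy))
            out[i] = acc
        return out

    _mix_sum(np.zeros((1, 2)), np.zeros((1, 2)), 1.0, 0.0, 1.0)  # warm the JIT
except Exception:  # pragma: no cover

    def _mix_sum(pts, mu, p00, p01, p11):
        diff = pts[:, None, :] - mu[None, :, :]
        q = (
            p00 * diff[..., 0] ** 2
            + 2.0 * p01 * diff[..., 0] * diff[..., 1]
            + p11 * diff[..., 1] ** 2
        )
        return np.exp(-0.5 * q).sum(axis=1)

#: Per-touch kernel covariance (m^2).  The implied 1-D marginal has a
#: full-width at half-maximum of 2*sqrt(2 ln2 * 0.002) ~ 0.105 m.
DEFAULT_KERNEL_VARIANCE = 0.002


def kernel_fwhm(variance: float = DEFAULT_KERNEL_VARIANCE) -> float:
    """Full-width at half-maximum (m) of the 1-D marginal of the map kernel."""
    return 2.0 * np.sqrt(2.0 * np.log(2.0) * variance)


@dataclass
class MentalMap:
    """Paired wall / no-wall Gaussian-mixture evidence fields.

    Parameters
    ----------
    room : (width, height) in metres; fixes the uniform base 1/area and the
        validity region for density queries.
    kernel_covariance : 2x2 covariance of every mixture component.
    """

    room: tuple[float, float] = (8.0, 9.0)
    kernel_covariance: np.ndarray = field(
        default_factory=lambda: np.eye(2) * DEFAULT_KERNEL_VARIANCE
    )
    wall_components: list[tuple[float, float]] = field(default_factory=list)
    nowall_components: list[tuple[float, float]] = field(default_factory=list)
    n_head_only: int = 0  # head-beep-only steps: seen but never mapped

    def __post_init__(self) -> None:
        cov = np.asarray(self.kernel_covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("kernel covariance must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("kernel covariance must be positive definite")
        self.kernel_covariance = cov
        self._prec = np.linalg.inv(cov)
        self._norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(cov)))
        # cached component arrays, rebuilt lazily when components were added
        self._cache: dict[str, np.ndarray] = {}

    @property
    def uniform_base(self) -> float:
        return 1.0 / (self.room[0] * self.room[1])

    def copy(self) -> "MentalMap":
        return MentalMap(
            room=self.room,
            kernel_covariance=self.kernel_covariance.copy(),
            wall_components=list(self.wall_components),
            nowall_components=list(self.nowall_components),
            n_head_only=self.n_head_only,
        )

    @property
    def n_steps_processed(self) -> int:
        return len(self.wall_components) + len(self.nowall_components) + self.n_head_only

    # -- density ----------------------------------------------------------

    def density(self, points, which: str) -> np.ndarray | float:
        """Evidence density of one field at one point or an (n, 2) array.

        uniform_base + sum over the field's components of the kernel Gaussian
        centred at each component.  Raises for points outside the room.
        """
        if which == "wall":
            comps = self.wall_components
        elif which == "nowall":
            comps = self.nowall_components
        else:
            raise ValueError(f"field must be 'wall' or 'nowall', got {which!r}")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        w, h = self.room
        if ((pts[:, 0] < 0) | (pts[:, 0] > w) | (pts[:, 1] < 0) | (pts[:, 1] > h)).any():
            raise ValueError("density query outside the room")
        out = np.full(len(pts), self.uniform_base)
        if comps:
            mu = self._component_array(which, comps)  # (m, 2)
            p = self._prec
            out = out + self._norm * _mix_sum(
                np.ascontiguousarray(pts), mu, p[0, 0], p[0, 1], p[1, 1]
            )
        return out if np.asarray(points).ndim == 2 else float(out[0])

    def _component_array(self, which: str, comps: list) -> np.ndarray:
        """Component means as an array, kept in an amortized growing buffer."""
        buf, count = self._cache.get(which, (np.empty((16, 2)), 0))
        n = len(comps)
        if n < count:  # components were replaced wholesale; rebuild
            buf, count = np.empty((max(16, n), 2)), 0
        if n > count:
            if n > len(buf):
                grown = np.empty((max(2 * len(buf), n), 2))
                grown[:count] = buf[:count]
                buf = grown
            buf[count:n] = comps[count:n]
            self._cache[which] = (buf, n)
        return buf[:n]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "room": list(self.room),
            "kernel_covariance": self.kernel_covariance.tolist(),
            "wall_components": [list(c) for c in self.wall_components],
            "nowall_components": [list(c) for c in self.nowall_components],
            "n_head_only": self.n_head_only,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "MentalMap":
        return cls(
            room=tuple(obj["room"]),
            kernel_covariance=np.asarray(obj["kernel_covariance"]),
            wall_components=[tuple(c) for c in obj["wall_components"]],
            nowall_components=[tuple(c) for c in obj["nowall_components"]],
            n_head_only=obj.get("n_head_only", 0),
        )


def update_map(
    mmap: MentalMap,
    hand_position,
    body_position,
    hand_beep: bool,
    head_beep: bool,
) -> MentalMap:
    """Apply one step's feedback to the map (in place; the map is returned).

    hand beep -> wall component at the (estimated) hand position;
    no beep at all -> no-wall component at the (estimated) body position;
    head beep without hand beep -> no update (counted for bookkeeping).
    """
    if hand_beep:
        x, y = np.asarray(hand_position, dtype=float)
        mmap.wall_components.append((float(x), float(y)))
    elif head_beep:
        mmap.n_head_only += 1
    else:
        x, y = np.asarray(body_position, dtype=float)
        mmap.nowall_components.append((float(x), float(y)))
    return mmap


def map_density(mmap: MentalMap, point, field: str):
    """Functional alias for :meth:`MentalMap.density`."""
    return mmap.density(point, field)
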