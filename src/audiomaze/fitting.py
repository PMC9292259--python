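"""Maximum-likelihood estimation of the eight movement parameters and
log-likelihood model scoring.

Each model splits a trial's motion steps into wall and no-wall classes;
step sizes d within a class are fit by a Gamma(alpha, beta) MLE (Newton on
the profile score, Minka initialization) and turning angles theta by a von
Mises MLE (circular mean + Bessel-ratio inversion).  Following the
convention that sigma is variance-like, the von Mises spread is reported as
a dispersion sigma = 1/kappa.  Model fit is the summed log-density of the
observed (d, theta) under the fitted class parameters, normalized by the
number of steps so trials of different lengths are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .models import StepLabelSeq
from .preprocess import MotionVectors
from .util import wrap_angle

#: Steps shorter than this (m) are excluded from step-size fits and
#: likelihoods: a blocked agent can be exactly stationary, and the Gamma
#: support is d > 0.
MIN_FIT_STEP = 1e-4


class DegenerateDataError(ValueError):
    """The MLE does not exist for this sample (e.g. all values identical)."""


@dataclass
class GammaParams:
    """Gamma step-size parameters: shape alpha, scale beta (m)."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass
class VonMisesParams:
    """von Mises turning-angle parameters.

    location is the circular mean mu (rad, wrapped to (-pi, pi]);
    dispersion is sigma = 1/kappa, so small sigma means concentrated turns.
    flag marks degenerate fits: 'uniform' (no resultant; dispersion inf)
    and 'concentrated' (all angles identical; dispersion 0).
    """

    location: float
    dispersion: float
    flag: str | None = None

    @property
    def kappa(self) -> float:
        return np.inf if self.dispersion == 0 else 1.0 / self.dispersion


@dataclass
class ModelParamSet:
    """The eight free parameters of one model on one trial."""

    gamma_nowall: GammaParams | None
    gamma_wall: GammaParams | None
    vm_nowall: VonMisesParams | None
    vm_wall: VonMisesParams | None
    model_kind: str = "?"
    participant_id: str = "?"
    trial_index: int = 0
    n_wall: int = 0
    n_nowall: int = 0

    @property
    def missing_classes(self) -> list[str]:
        out = []
        if self.gamma_wall is None or self.vm_wall is None:
            out.append("wall")
        if self.gamma_nowall is None or self.vm_nowall is None:
            out.append("nowall")
        return out


@dataclass
class FitResult:
    """Total and per-step log-likelihoods of one model on one trial."""

    loglik_step: float
    loglik_turn: float
    n_steps: int

    @property
    def normalized_step(self) -> float:
        return self.loglik_step / self.n_steps

    @property
    def normalized_turn(self) -> float:
        return self.loglik_turn / self.n_steps


def fit_gamma(samples, max_iter: int = 100, tol: float = 1e-10) -> GammaParams:
    """Gamma MLE via Newton iterations on the profile score.

    The profile score in the shape is log(alpha) - digamma(alpha) = s with
    s = log(mean) - mean(log); the scale MLE is mean/shape.  Initialized
    with Minka's closed-form approximation.  Requires >= 3 strictly
    positive samples; identical samples (s = 0) have no finite MLE.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if (x <= 0).any():
        raise ValueError("Gamma samples must be strictly positive")
    s = np.log(x.mean()) - np.log(x).mean()
    if s < 1e-12:
        raise DegenerateDataError("all samples (near-)identical: Gamma MLE diverges")
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        f = np.log(a) - special.digamma(a) - s
        fprime = 1.0 / a - special.polygamma(1, a)
        step = f / fprime
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < tol * a:
            a = a_new
            break
        a = a_new
    return GammaParams(shape=float(a), scale=float(x.mean() / a))


def _bessel_ratio(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa), computed with scaled Bessels."""
    return special.i1e(kappa) / special.i0e(kappa)


def fit_vonmises(angles, tol: float = 1e-10) -> VonMisesParams:
    """von Mises MLE: circular-mean location, kappa from A(kappa) = Rbar.

    The concentration is recovered by bisecting the monotone Bessel ratio
    on [1e-8, 1e8].  A vanishing mean resultant (uniform sample) and a
    unit resultant (identical angles) are flagged, with dispersion
    reported as inf and 0 respectively.
    """
    th = np.asarray(angles, dtype=float)
    if len(th) < 3:
        raise ValueError("need at least 3 angles")
    C, S = np.cos(th).mean(), np.sin(th).mean()
    rbar = float(np.hypot(C, S))
    loc = float(wrap_angle(np.arctan2(S, C)))
    if rbar < 1e-12:
        return VonMisesParams(location=loc, dispersion=np.inf, flag="uniform")
    lo, hi = 1e-8, 1e8
    if rbar >= _bessel_ratio(hi):
        return VonMisesParams(location=loc, dispersion=0.0, flag="concentrated")
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if _bessel_ratio(mid) < rbar:
            lo = mid
        else:
            hi = mid
    kappa = 0.5 * (lo + hi)
    return VonMisesParams(location=loc, dispersion=float(1.0 / kappa))


def _partition(motions: MotionVectors, labels: StepLabelSeq, abs_turn: bool):
    lab = np.asarray(labels.labels, dtype=bool)
    if len(lab) != motions.n_steps:
        raise ValueError("labels and motions length mismatch")
    theta = np.abs(motions.theta) if abs_turn else motions.theta
    keep = motions.d >= MIN_FIT_STEP
    return {
        "wall": (motions.d[keep & lab], theta[keep & lab]),
        "nowall": (motions.d[keep & ~lab], theta[keep & ~lab]),
    }


def fit_model_params(
    motions: MotionVectors,
    labels: StepLabelSeq,
    min_class_size: int = 3,
    abs_turn: bool = False,
) -> ModelParamSet:
    """Fit the eight parameters from label-partitioned steps.

    A class with fewer than ``min_class_size`` usable steps gets its
    parameters flagged missing (None) rather than raising; callers exclude
    such trials from comparisons that need the class.
    """
    parts = _partition(motions, labels, abs_turn)
    fitted: dict[str, tuple] = {}
    for cls, (d, th) in parts.items():
        if len(d) < min_class_size:
            fitted[cls] = (None, None)
            continue
        try:
            g = fit_gamma(d)
            v = fit_vonmises(th)
        except DegenerateDataError:
            fitted[cls] = (None, None)
            continue
        fitted[cls] = (g, v)
    return ModelParamSet(
        gamma_nowall=fitted["nowall"][0],
        gamma_wall=fitted["wall"][0],
        vm_nowall=fitted["nowall"][1],
        vm_wall=fitted["wall"][1],
        model_kind=labels.model_kind,
        n_wall=len(parts["wall"][0]),
        n_nowall=len(parts["nowall"][0]),
    )


def log_likelihood(
    params: ModelParamSet,
    motions: MotionVectors,
    labels: StepLabelSeq,
    abs_turn: bool = False,
) -> FitResult:
    """Summed log-density of the steps under the fitted class parameters.

    Gamma log-density of d plus von Mises log-density of theta, each under
    the step's label; totals are also reported per step (normalized), which
    corrects for trial-length imbalance.  Raises if a label class present
    in the data has missing parameters.
    """
    parts = _partition(motions, labels, abs_turn)
    ll_step = 0.0
    ll_turn = 0.0
    n = 0
    for cls, (d, th) in parts.items():
        if len(d) == 0:
            continue
        g = params.gamma_wall if cls == "wall" else params.gamma_nowall
        v = params.vm_wall if cls == "wall" else params.vm_nowall
        if g is None or v is None:
            raise ValueError(f"parameters for present class {cls!r} are missing")
        if (d <= 0).any():
            raise ValueError("step sizes must be strictly positive")
        ll_step += float(stats.gamma.logpdf(d, g.shape, scale=g.scale).sum())
        ll_turn += float(stats.vonmises.logpdf(th, v.kappa, loc=v.location).sum())
        n += len(d)
    if n == 0:
        raise ValueError("no usable steps")
    return FitResult(loglik_step=ll_step, loglik_turn=ll_turn, n_steps=n)
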