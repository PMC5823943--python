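"""Waiting-time distributions for coarse-grained kinetic transitions.

A single enzyme moving between coarse-grained states (free enzyme E,
enzyme--substrate complex ES, inhibitor-bound complexes EI/ESI) dwells in
each state for a random waiting time.  Collapsing many microscopic
intermediates into one coarse state makes these dwell times generally
non-exponential, so the theory is parameterized by full waiting-time
distributions rather than rates.  This module provides the distribution
abstraction used everywhere else: density, survival function, Laplace
transform, moments and reproducible sampling.

Concrete families
-----------------
``exponential``
    The Markovian (memoryless) baseline, one rate in ms^-1.
``hyperexponential2``
    Mixture of two exponentials, ``p k1 e^{-k1 t} + (1-p) k2 e^{-k2 t}``.
    Arises from a two-conformation enzyme where substrate binding commits
    the complex to a fast or slow catalytic pathway; its coefficient of
    variation is always >= 1.
``gamma`` / ``weibull`` / ``lognormal``
    Generic unimodal families covering CV below and above 1, constructed
    either from native parameters or moment-matched to a target
    (mean, CV) pair.

Units: times in milliseconds, rates in ms^-1 throughout.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gamma as gamma_fn

from .errors import InvalidParameterError, NumericalFailureError
from .quadrature import TAIL_SURVIVAL, integrate_tail

__all__ = [
    "WaitingTimeDistribution",
    "make_exponential",
    "make_hyperexponential2",
    "make_gamma",
    "make_weibull",
    "make_lognormal",
    "make_moment_matched",
    "from_spec",
]

_FAMILIES = ("exponential", "hyperexponential2", "gamma", "weibull", "lognormal")


class WaitingTimeDistribution:
    """A positive random waiting time with analytic and numeric accessors.

    Instances are immutable; build them through the ``make_*`` factories or
    :func:`from_spec`.
    """

    def __init__(self, family: str, params: Mapping[str, float]):
        if family not in _FAMILIES:
            raise InvalidParameterError(f"unknown family {family!r}")
        self.family = family
        self.params = dict(params)
        self._frozen = self._freeze()

    # -- construction ---------------------------------------------------

    def _freeze(self):
        p = self.params
        if self.family == "exponential":
            rate = p["rate"]
            if not rate > 0:
                raise InvalidParameterError(f"rate must be > 0, got {rate}")
            return stats.expon(scale=1.0 / rate)
        if self.family == "hyperexponential2":
            prob, k1, k2 = p["p"], p["k1"], p["k2"]
            if not (0.0 <= prob <= 1.0):
                raise InvalidParameterError(f"mixture weight p={prob} outside [0, 1]")
            if not (k1 > 0 and k2 > 0):
                raise InvalidParameterError("hyperexponential rates must be > 0")
            return None  # handled directly; scipy has no hyperexponential
        if self.family == "gamma":
            shape, scale = p["shape"], p["scale"]
            if not (shape > 0 and scale > 0):
                raise InvalidParameterError("gamma shape and scale must be > 0")
            return stats.gamma(shape, scale=scale)
        if self.family == "weibull":
            shape, scale = p["shape"], p["scale"]
            if not (shape > 0 and scale > 0):
                raise InvalidParameterError("weibull shape and scale must be > 0")
            return stats.weibull_min(shape, scale=scale)
        if self.family == "lognormal":
            sigma, scale = p["sigma"], p["scale"]
            if not (sigma > 0 and scale > 0):
                raise InvalidParameterError("lognormal sigma and scale must be > 0")
            return stats.lognorm(sigma, scale=scale)
        raise AssertionError(self.family)

    # -- density / survival ---------------------------------------------

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "hyperexponential2":
            p, k1, k2 = self.params["p"], self.params["k1"], self.params["k2"]
            out = p * k1 * np.exp(-k1 * t) + (1.0 - p) * k2 * np.exp(-k2 * t)
            return np.where(t < 0, 0.0, out)
        return self._frozen.pdf(t)

    def sf(self, t):
        """Survival function  F̄(t) = Pr(T > t)."""
        t = np.asarray(t, dtype=float)
        if self.family == "hyperexponential2":
            p, k1, k2 = self.params["p"], self.params["k1"], self.params["k2"]
            out = p * np.exp(-k1 * t) + (1.0 - p) * np.exp(-k2 * t)
            return np.where(t < 0, 1.0, out)
        return self._frozen.sf(t)

    def isf(self, q: float) -> float:
        """Inverse survival function (far-tail quantiles for quadrature cutoffs)."""
        if self.family == "hyperexponential2":
            p, k1, k2 = self.params["p"], self.params["k1"], self.params["k2"]
            # bracket by the slower branch, then bisect
            hi = -math.log(max(q, 1e-300)) / min(k1, k2) + 1.0
            return brentq(lambda t: self.sf(t) - q, 0.0, hi, xtol=1e-14, rtol=1e-12)
        return float(self._frozen.isf(q))

    @property
    def tail_cutoff(self) -> float:
        """Truncation point T* (the 1 - 1e-12 quantile) for quadrature."""
        return self.isf(TAIL_SURVIVAL)

    # -- moments ---------------------------------------------------------

    @property
    def mean(self) -> float:
        p = self.params
        if self.family == "exponential":
            return 1.0 / p["rate"]
        if self.family == "hyperexponential2":
            return p["p"] / p["k1"] + (1.0 - p["p"]) / p["k2"]
        return float(self._frozen.mean())

    @property
    def var(self) -> float:
        p = self.params
        if self.family == "hyperexponential2":
            m2 = 2.0 * (p["p"] / p["k1"] ** 2 + (1.0 - p["p"]) / p["k2"] ** 2)
            return m2 - self.mean**2
        return float(self._frozen.var())

    @property
    def std(self) -> float:
        return math.sqrt(self.var)

    @property
    def cv(self) -> float:
        """Coefficient of variation, std/mean."""
        return self.std / self.mean

    # -- Laplace transform ----------------------------------------------

    def laplace(self, s: float) -> float:
        """E[exp(-s T)]; closed form where available, quadrature otherwise.

        The transform is the workhorse of the renewal-theory rate formulas:
        the modulation factors of uncompetitive inhibition are ratios of
        such transforms evaluated at s = k_on^ESI [I].
        """
        if s < 0:
            raise InvalidParameterError(f"Laplace argument s={s} must be >= 0")
        if s == 0:
            return 1.0
        p = self.params
        if self.family == "exponential":
            k = p["rate"]
            return k / (k + s)
        if self.family == "hyperexponential2":
            w, k1, k2 = p["p"], p["k1"], p["k2"]
            return w * k1 / (k1 + s) + (1.0 - w) * k2 / (k2 + s)
        if self.family == "gamma":
            return (1.0 + p["scale"] * s) ** (-p["shape"])
        # weibull / lognormal: no closed form.  Integrate by parts,
        # f̃(s) = 1 - s ∫ e^{-st} F̄(t) dt, which avoids evaluating the pdf
        # (singular at 0 for shape < 1).  For s <= 1/mean the integrand lives
        # on the distribution's own time scale; for larger s substitute
        # x = s t so the mass sits at x ~ 1 regardless of how stiff s is.
        sf = self._frozen.sf
        if s * self.mean <= 1.0:
            surv = s * integrate_tail(lambda t: math.exp(-s * t) * float(sf(t)), self.tail_cutoff)
        else:
            surv = integrate_tail(lambda x: math.exp(-x) * float(sf(x / s)), 1.0)
        return 1.0 - surv

    # -- sampling ---------------------------------------------------------

    def sample(self, n: int, seed) -> np.ndarray:
        """Draw ``n`` waiting times; ``seed`` is an int or a numpy Generator."""
        if n < 1:
            raise InvalidParameterError(f"sample size must be >= 1, got {n}")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        p = self.params
        if self.family == "exponential":
            return rng.exponential(1.0 / p["rate"], size=n)
        if self.family == "hyperexponential2":
            fast = rng.random(n) < p["p"]
            scale = np.where(fast, 1.0 / p["k1"], 1.0 / p["k2"])
            return rng.exponential(scale)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size=n)
        if self.family == "weibull":
            return p["scale"] * rng.weibull(p["shape"], size=n)
        if self.family == "lognormal":
            return rng.lognormal(math.log(p["scale"]), p["sigma"], size=n)
        raise AssertionError(self.family)

    def make_sampler(self, rng: np.random.Generator) -> Callable[[], float]:
        """Return a zero-argument scalar sampler bound to ``rng``.

        Used by the event-driven simulator, where waiting times are drawn
        one at a time inside the state-machine loop.
        """
        p = self.params
        if self.family == "exponential":
            scale = 1.0 / p["rate"]
            exp = rng.exponential
            return lambda: exp(scale)
        if self.family == "hyperexponential2":
            w, s1, s2 = p["p"], 1.0 / p["k1"], 1.0 / p["k2"]
            exp, unif = rng.exponential, rng.random
            return lambda: exp(s1 if unif() < w else s2)
        if self.family == "gamma":
            shape, scale = p["shape"], p["scale"]
            gam = rng.gamma
            return lambda: gam(shape, scale)
        if self.family == "weibull":
            shape, scale = p["shape"], p["scale"]
            wei = rng.weibull
            return lambda: scale * wei(shape)
        if self.family == "lognormal":
            mu, sigma = math.log(p["scale"]), p["sigma"]
            logn = rng.lognormal
            return lambda: logn(mu, sigma)
        raise AssertionError(self.family)

    # -- serialization ----------------------------------------------------

    def to_spec(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"WaitingTimeDistribution({self.family}, {inner})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WaitingTimeDistribution)
            and self.family == other.family
            and self.params == other.params
        )

    def __hash__(self):
        return hash((self.family, tuple(sorted(self.params.items()))))


# -- factories -------------------------------------------------------------


def make_exponential(rate: float) -> WaitingTimeDistribution:
    """Exponential waiting time with the given rate (ms^-1)."""
    return WaitingTimeDistribution("exponential", {"rate": float(rate)})


def make_hyperexponential2(p: float, k1: float, k2: float) -> WaitingTimeDistribution:
    """Two-branch exponential mixture (the two-conformation catalysis model).

    With probability ``p`` the time is exponential at rate ``k1``, otherwise
    at rate ``k2``.  CV >= 1 always, with equality iff the mixture is
    degenerate (k1 == k2 or p in {0, 1}).
    """
    return WaitingTimeDistribution(
        "hyperexponential2", {"p": float(p), "k1": float(k1), "k2": float(k2)}
    )


def make_gamma(shape: float, scale: float) -> WaitingTimeDistribution:
    return WaitingTimeDistribution("gamma", {"shape": float(shape), "scale": float(scale)})


def make_weibull(shape: float, scale: float) -> WaitingTimeDistribution:
    return WaitingTimeDistribution("weibull", {"shape": float(shape), "scale": float(scale)})


def make_lognormal(sigma: float, scale: float) -> WaitingTimeDistribution:
    """Lognormal with log-space sd ``sigma`` and median ``scale`` (ms)."""
    return WaitingTimeDistribution("lognormal", {"sigma": float(sigma), "scale": float(scale)})


def _weibull_shape_from_cv(cv: float) -> float:
    """Invert CV(k) = sqrt(G(1+2/k)/G(1+1/k)^2 - 1); monotone decreasing in k."""

    def cv2(k: float) -> float:
        g1 = gamma_fn(1.0 + 1.0 / k)
        g2 = gamma_fn(1.0 + 2.0 / k)
        return g2 / g1**2 - 1.0

    target = cv * cv
    lo, hi = 0.05, 50.0
    # widen the bracket if needed (extreme CVs)
    while cv2(lo) < target:
        lo *= 0.5
        if lo < 1e-4:
            raise NumericalFailureError(f"weibull shape solve failed for cv={cv}")
    while cv2(hi) > target:
        hi *= 2.0
        if hi > 1e6:
            raise NumericalFailureError(f"weibull shape solve failed for cv={cv}")
    return brentq(lambda k: cv2(k) - target, lo, hi, xtol=1e-14, rtol=1e-14)


def make_moment_matched(family: str, mean: float, cv: float) -> WaitingTimeDistribution:
    """Build a gamma/weibull/lognormal with prescribed mean (ms) and CV.

    Matching two moments pins down both parameters of each family; the
    three families then differ only in higher-order shape, which is exactly
    the lever the non-Markovian rate theory is sensitive to.
    """
    if mean <= 0 or cv <= 0:
        raise InvalidParameterError(f"mean and cv must be > 0, got mean={mean}, cv={cv}")
    if family == "gamma":
        shape = 1.0 / cv**2
        return make_gamma(shape, mean / shape)
    if family == "weibull":
        shape = _weibull_shape_from_cv(cv)
        return make_weibull(shape, mean / gamma_fn(1.0 + 1.0 / shape))
    if family == "lognormal":
        sigma2 = math.log1p(cv**2)
        return make_lognormal(math.sqrt(sigma2), mean * math.exp(-0.5 * sigma2))
    raise InvalidParameterError(
        f"moment matching supports gamma/weibull/lognormal, got {family!r}"
    )


def from_spec(spec: Mapping) -> WaitingTimeDistribution:
    """Build a distribution from a serialized spec.

    Accepts ``{"family": ..., "params": {...}}`` or the moment-matched form
    ``{"family": ..., "mean": ..., "cv": ...}``.
    """
    if "family" not in spec:
        raise InvalidParameterError("distribution spec missing 'family'")
    family = spec["family"]
    if "params" in spec:
        return WaitingTimeDistribution(family, spec["params"])
    if "mean" in spec and "cv" in spec:
        if family == "exponential":
            if abs(spec["cv"] - 1.0) > 1e-12:
                raise InvalidParameterError("exponential requires cv == 1")
            return make_exponential(1.0 / spec["mean"])
        return make_moment_matched(family, spec["mean"], spec["cv"])
    raise InvalidParameterError(
        "distribution spec needs either 'params' or both 'mean' and 'cv'"
    )
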