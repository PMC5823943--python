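"""Inhibitor-activator duality criteria and {[I], 1/[S]} phase diagrams.

An uncompetitive "inhibitor" binds the ES complex and shuts catalysis down
completely while bound — yet it can *increase* the mean turnover rate.  The
mechanism is renewal-theoretic: the inhibitor interrupts the ES state at a
random inspection epoch, and when the ES lifetime is over-dispersed
(CV > 1) the interrupted visit is disproportionately likely to be a long,
unproductive one.  Unbinding then resets the ES clock, which on average
helps.  This module evaluates the resulting activation criteria:

* the general criterion — the ratio ``<T_off_ESI>/<W_ES^0>`` must fall
  below a fluctuation term ``(CV^2 - 1)/2`` plus a breakdown-bias term
  involving the ES lifetime conditioned on product formation;
* the simplified form for exponential substrate unbinding —
  ``<T_off_ESI> < (CV^2 - 1)/2 * (1/v_max) * (1 + k_off/(k_on [S]))``;

and classifies the {[I], 1/[S]} plane into activation / transition /
inhibition phases by the sign of dk_turn/d[I] and the comparison of
k_turn with its uninhibited value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .distributions import WaitingTimeDistribution
from .errors import (
    InvalidParameterError,
    UnsupportedInputError,
    UnsupportedModeError,
)
from .kinetics import (
    InhibitionScheme,
    _AB,
    _base_constants,
    effective_constants,
    turnover,
)
from .quadrature import integrate_tail

__all__ = [
    "DualityReport",
    "PhaseDiagram",
    "ESLifetimeFunctionals",
    "residual_lifetime_mean",
    "es_lifetime_functionals",
    "duality_criterion_general",
    "duality_criterion_markovian_binding",
    "turnover_derivative_at_zero",
    "phase_at",
    "phase_diagram",
]

logger = logging.getLogger(__name__)

#: relative band within which a point is treated as sitting on a phase boundary
BOUNDARY_TOL = 1e-9


def residual_lifetime_mean(W: WaitingTimeDistribution) -> float:
    """Mean residual lifetime of ``W`` observed at a random inspection epoch.

    Renewal theory gives  <W>/2 + sigma^2(W)/(2 <W>): inspection is
    length-biased, so broad lifetimes (CV > 1) leave *more* than the plain
    mean remaining, the inspection paradox at the heart of the duality
    phenomenon.  Equals the mean exactly iff sigma^2 = <W>^2 (exponential).
    """
    m, v = W.mean, W.var
    if not (math.isfinite(m) and math.isfinite(v)):
        raise UnsupportedInputError("residual lifetime needs finite mean and variance")
    return 0.5 * m + 0.5 * v / m


@dataclass(frozen=True)
class ESLifetimeFunctionals:
    """Moments of W_ES^0 = min(T_cat, T_off) and the product-conditioned mean."""

    mean: float  # ms
    variance: float  # ms^2
    cv: float
    cond_mean_given_product: float  # <W_ES^0 | ES -> E+P>, ms
    p_cat: float  # Pr(T_cat < T_off)


def es_lifetime_functionals(T_cat: WaitingTimeDistribution,
                            T_off: WaitingTimeDistribution) -> ESLifetimeFunctionals:
    """Quadrature functionals of the uninhibited ES lifetime.

    mean = ∫ F̄_cat F̄_off dt;  second moment = 2 ∫ t F̄_cat F̄_off dt;
    conditional mean given catalysis = ∫ t f_cat F̄_off dt / Pr(T_cat<T_off).

    With exponential unbinding the zeroth-order integrals collapse onto the
    catalysis-time Laplace transform (avoiding any pdf evaluation, which can
    be singular at 0 for shape < 1 families); the remaining integrands carry
    a factor of t and are bounded.
    """
    cutoff = min(T_cat.tail_cutoff, T_off.tail_cutoff)
    sf_c, sf_o, pdf_c = T_cat.sf, T_off.sf, T_cat.pdf
    if T_off.family == "exponential":
        k = T_off.params["rate"]
        p_cat = T_cat.laplace(k)
        mean = (1.0 - p_cat) / k
    else:
        mean = integrate_tail(lambda t: float(sf_c(t)) * float(sf_o(t)), cutoff)
        p_cat = integrate_tail(lambda t: float(pdf_c(t)) * float(sf_o(t)), cutoff)
    m2 = 2.0 * integrate_tail(lambda t: t * float(sf_c(t)) * float(sf_o(t)), cutoff)
    t_prod = integrate_tail(lambda t: t * float(pdf_c(t)) * float(sf_o(t)), cutoff)
    var = max(m2 - mean * mean, 0.0)
    return ESLifetimeFunctionals(
        mean=mean,
        variance=var,
        cv=math.sqrt(var) / mean,
        cond_mean_given_product=t_prod / p_cat,
        p_cat=p_cat,
    )


@dataclass(frozen=True)
class DualityReport:
    """Both sides of an activation criterion and the verdict.

    ``holds`` is True when the criterion predicts dk_turn/d[I] > 0 at
    [I] = 0, i.e. the "inhibitor" initially activates.
    """

    criterion: str  # "general" or "markovian_binding"
    lhs: float
    rhs: float
    holds: bool
    cv_WES0: float
    cond_mean_WES0_given_product: float  # ms
    residual_mean_WES0: float  # ms
    S: float  # μM


def _require_uncompetitive_with_ESI(scheme: InhibitionScheme) -> None:
    if scheme.mode != "uncompetitive":
        raise UnsupportedModeError(
            f"duality criterion requires uncompetitive mode, got {scheme.mode!r}"
        )
    if not scheme.has_ESI:
        raise InvalidParameterError("duality criterion needs an ESI binding channel")


def _residual_mean_from(fn: ESLifetimeFunctionals) -> float:
    return 0.5 * fn.mean + 0.5 * fn.variance / fn.mean


def duality_criterion_general(scheme: InhibitionScheme, S: float) -> DualityReport:
    """General activation criterion for arbitrary T_cat and T_off.

    lhs = <T_off_ESI>/<W_ES^0>;
    rhs = (CV^2 - 1)/2 + [1 - <W_ES^0|ES->E+P>/<W_ES^0>] / ([S]/(K_m+[S])).
    Activation at [I] -> 0+ iff lhs < rhs.
    """
    _require_uncompetitive_with_ESI(scheme)
    if S <= 0:
        raise InvalidParameterError(f"substrate concentration must be > 0, got {S}")
    fn = es_lifetime_functionals(scheme.T_cat, scheme.T_off)
    ec = effective_constants(scheme)
    lhs = scheme.T_off_ESI.mean / fn.mean
    occupancy = S / (ec.K_m + S)
    rhs = 0.5 * (fn.cv**2 - 1.0) + (1.0 - fn.cond_mean_given_product / fn.mean) / occupancy
    return DualityReport(
        criterion="general",
        lhs=lhs,
        rhs=rhs,
        holds=lhs < rhs,
        cv_WES0=fn.cv,
        cond_mean_WES0_given_product=fn.cond_mean_given_product,
        residual_mean_WES0=_residual_mean_from(fn),
        S=S,
    )


def duality_criterion_markovian_binding(scheme: InhibitionScheme, S: float) -> DualityReport:
    """Simplified criterion assuming exponential substrate unbinding.

    lhs = <T_off_ESI>  (ms);
    rhs = (CV^2 - 1)/2 * (1/v_max) * (1 + k_off/(k_on [S]))  (ms).
    Requires exponential T_off; other unbinding laws must use the general
    criterion.
    """
    _require_uncompetitive_with_ESI(scheme)
    if scheme.T_off.family != "exponential":
        raise UnsupportedInputError(
            "simplified criterion assumes exponential substrate unbinding; "
            "use duality_criterion_general for other T_off laws"
        )
    if S <= 0:
        raise InvalidParameterError(f"substrate concentration must be > 0, got {S}")
    fn = es_lifetime_functionals(scheme.T_cat, scheme.T_off)
    ec = effective_constants(scheme)
    k_off = scheme.T_off.params["rate"]
    lhs = scheme.T_off_ESI.mean
    rhs = 0.5 * (fn.cv**2 - 1.0) / ec.v_max * (1.0 + k_off / (scheme.k_on * S))
    return DualityReport(
        criterion="markovian_binding",
        lhs=lhs,
        rhs=rhs,
        holds=lhs < rhs,
        cv_WES0=fn.cv,
        cond_mean_WES0_given_product=fn.cond_mean_given_product,
        residual_mean_WES0=_residual_mean_from(fn),
        S=S,
    )


# -- numerical dose-response derivative ------------------------------------


def _turnover_smooth(scheme: InhibitionScheme, S: float, I: float) -> float:
    """Turnover as an analytic function of I, valid for slightly negative I.

    The modulation factors extend analytically to small negative transform
    arguments, which lets the derivative at [I] = 0 use a symmetric stencil.
    """
    ec = effective_constants(scheme)
    s = (scheme.k_on_ESI or 0.0) * I
    if scheme.has_ESI and s != 0.0:
        A, B, _, _ = _AB(scheme, s)
        esi = I / ec.K_ESI
    else:
        A = B = 1.0
        esi = 0.0
    ei = I / ec.K_EI if (scheme.mode == "mixed" and scheme.has_EI) else 0.0
    inv = ec.K_m * (1.0 + ei) * A / (ec.v_max * S) + (1.0 + esi) * B / ec.v_max
    return 1.0 / inv


def turnover_derivative_at_zero(scheme: InhibitionScheme, S: float) -> float:
    """dk_turn/d[I] at [I] = 0, central difference with one Richardson step.

    The step is chosen so that the transform argument moves by ~1e-4 of the
    characteristic ES decay rate 1/<W_ES^0>.
    """
    if scheme.mode not in ("uncompetitive", "mixed"):
        raise UnsupportedModeError(
            f"dose-response derivative needs uncompetitive/mixed mode, got {scheme.mode!r}"
        )
    mean_w0, _ = _base_constants(scheme)
    k_esi = scheme.k_on_ESI or 0.0
    if k_esi <= 0:
        # no ESI channel: only competitive-type terms, derivative from K_EI alone
        h = 1e-4 / (scheme.k_on * mean_w0)
    else:
        h = 1e-4 / (k_esi * mean_w0)

    def central(hh: float) -> float:
        return (_turnover_smooth(scheme, S, hh) - _turnover_smooth(scheme, S, -hh)) / (2 * hh)

    d1, d2 = central(h), central(h / 2.0)
    return (4.0 * d2 - d1) / 3.0


def _turnover_derivative_at(scheme: InhibitionScheme, S: float, I: float) -> float:
    """dk_turn/d[I] at I > 0 (central difference)."""
    if I == 0.0:
        return turnover_derivative_at_zero(scheme, S)
    h = 1e-5 * max(I, 1e-12)
    return (turnover(scheme, S, I + h) - turnover(scheme, S, I - h)) / (2 * h)


# -- phase classification ---------------------------------------------------


@dataclass
class PhaseDiagram:
    """Phase labels over an (S, I) grid plus bisection-refined boundaries.

    ``boundary_peak`` collects (S, I) points where dk_turn/d[I] = 0 (the
    activation/transition border, where turnover attains its maximum);
    ``boundary_crossing`` collects (S, I) where k_turn re-attains its
    uninhibited value (the transition/inhibition border).
    """

    S_grid: np.ndarray
    I_grid: np.ndarray
    phase: np.ndarray  # shape (len(S_grid), len(I_grid)), dtype=object labels
    boundary_peak: list = field(default_factory=list)
    boundary_crossing: list = field(default_factory=list)


def phase_at(scheme: InhibitionScheme, S: float, I: float) -> str:
    """Classify one (S, I) point as activation / transition / inhibition."""
    if scheme.mode not in ("uncompetitive", "mixed"):
        raise UnsupportedModeError(
            f"phase classification needs uncompetitive/mixed mode, got {scheme.mode!r}"
        )
    if I < 0:
        raise InvalidParameterError(f"inhibitor concentration must be >= 0, got {I}")
    k0 = turnover(scheme, S, 0.0)
    if I == 0.0:
        deriv = turnover_derivative_at_zero(scheme, S)
        return "activation" if deriv > 0 else "inhibition"
    k = turnover(scheme, S, I)
    deriv = _turnover_derivative_at(scheme, S, I)
    rel = (k - k0) / k0
    if abs(rel) < BOUNDARY_TOL:
        logger.info("phase boundary band at S=%g, I=%g; assigning 'inhibition'", S, I)
        return "inhibition"
    if rel > 0:
        return "activation" if deriv > 0 else "transition"
    if deriv > 0:
        logger.info(
            "k_turn below baseline but rising at S=%g, I=%g; assigning 'inhibition'", S, I
        )
    return "inhibition"


def phase_diagram(scheme: InhibitionScheme, S_grid, I_grid,
                  refine_boundaries: bool = True) -> PhaseDiagram:
    """Classify a full (S, I) grid and locate the two phase borders.

    Boundaries are refined per substrate level by bisection to 1e-6
    relative in I, between grid points where the relevant sign changes.
    """
    S_grid = np.asarray(S_grid, dtype=float)
    I_grid = np.asarray(I_grid, dtype=float)
    labels = np.empty((S_grid.size, I_grid.size), dtype=object)
    peak_pts: list = []
    cross_pts: list = []
    for i, S in enumerate(S_grid):
        for j, I in enumerate(I_grid):
            labels[i, j] = phase_at(scheme, S, float(I))
        if not refine_boundaries:
            continue
        k0 = turnover(scheme, S, 0.0)
        if turnover_derivative_at_zero(scheme, S) <= 0:
            continue  # no activation phase at this S
        Imax = float(I_grid.max())
        # peak: dk/dI = 0
        d_hi = _turnover_derivative_at(scheme, S, Imax)
        if d_hi < 0:
            I_peak = brentq(
                lambda x: _turnover_derivative_at(scheme, S, x),
                I_grid[I_grid > 0].min() * 1e-3, Imax, rtol=1e-6,
            )
            peak_pts.append((float(S), float(I_peak)))
            # crossing: k(I) = k0 for I beyond the peak
            if turnover(scheme, S, Imax) < k0:
                I_cross = brentq(
                    lambda x: turnover(scheme, S, x) - k0,
                    I_peak, Imax, rtol=1e-6,
                )
                cross_pts.append((float(S), float(I_cross)))
    return PhaseDiagram(
        S_grid=S_grid, I_grid=I_grid, phase=labels,
        boundary_peak=peak_pts, boundary_crossing=cross_pts,
    )
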