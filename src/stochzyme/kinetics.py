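"""Analytic turnover rates for inhibited single-enzyme reactions.

The enzyme is modelled as a semi-Markov process on the coarse states
{E, ES, EI, ESI, E+P}: dwell times in each state come from arbitrary
distributions (clocks reset on every state entry), while substrate and
inhibitor binding are exponential with pseudo-first-order rates
``k_on [S]``, ``k_on_EI [I]`` and ``k_on_ESI [I]`` because the single enzyme
sits in a sea of substrate/inhibitor molecules.

Renewal analysis of this process yields closed-form mean turnover rates:

* competitive inhibition keeps the classical hyperbolic form, with
  generalized constants ``v_max = Pr(T_cat < T_off)/<W_ES^0>``,
  ``K_m = (k_on <W_ES^0>)^-1`` and ``K_EI = (<T_off_EI> k_on_EI)^-1``,
  where ``W_ES^0 = min(T_cat, T_off)`` is the uninhibited ES lifetime;
* uncompetitive and mixed inhibition acquire two inhibitor-dependent
  modulation factors A([I]) and B([I]) — ratios of Laplace-transform
  functionals of the catalysis and unbinding times, equal to 1 for all [I]
  only in the fully Markovian (exponential-catalysis) case.

All rates are per ms, concentrations in μM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from .distributions import WaitingTimeDistribution
from .errors import InvalidParameterError, UnsupportedModeError
from .quadrature import integrate_tail

__all__ = [
    "InhibitionScheme",
    "EffectiveConstants",
    "ModulationFactors",
    "effective_constants",
    "f_tilde_M",
    "f_tilde_P",
    "modulation_factors",
    "turnover_classical",
    "turnover_competitive",
    "turnover_uncompetitive",
    "turnover_mixed",
    "turnover",
]

MODES = ("none", "competitive", "uncompetitive", "mixed")


@dataclass(frozen=True)
class InhibitionScheme:
    """Full parameterization of one inhibition scenario.

    Absent binding channels are encoded by ``None`` (or rate 0), meaning the
    corresponding equilibrium constant is +inf — the exact algebraic limit,
    not a large-number surrogate.
    """

    mode: str
    k_on: float  # substrate binding, (μM ms)^-1
    T_cat: WaitingTimeDistribution
    T_off: WaitingTimeDistribution
    k_on_EI: Optional[float] = None  # inhibitor -> free enzyme (competitive/mixed)
    T_off_EI: Optional[WaitingTimeDistribution] = None
    k_on_ESI: Optional[float] = None  # inhibitor -> ES complex (uncompetitive/mixed)
    T_off_ESI: Optional[WaitingTimeDistribution] = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if not self.k_on > 0:
            raise InvalidParameterError(f"k_on must be > 0, got {self.k_on}")
        for name in ("k_on_EI", "k_on_ESI"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        if self.mode in ("competitive", "mixed") and self.has_EI and self.T_off_EI is None:
            raise InvalidParameterError(f"{self.mode} scheme with k_on_EI needs T_off_EI")
        if self.mode in ("uncompetitive", "mixed") and self.has_ESI and self.T_off_ESI is None:
            raise InvalidParameterError(f"{self.mode} scheme with k_on_ESI needs T_off_ESI")
        if self.mode == "competitive" and self.has_ESI:
            raise InvalidParameterError("competitive mode cannot carry an ESI channel")
        if self.mode == "uncompetitive" and self.has_EI:
            raise InvalidParameterError("uncompetitive mode cannot carry an EI channel")

    @property
    def has_EI(self) -> bool:
        return self.k_on_EI is not None and self.k_on_EI > 0

    @property
    def has_ESI(self) -> bool:
        return self.k_on_ESI is not None and self.k_on_ESI > 0


@dataclass(frozen=True)
class EffectiveConstants:
    """Generalized Michaelis-Menten constants of a scheme.

    ``K_EI``/``K_ESI`` are +inf when the corresponding channel is absent.
    """

    K_m: float  # μM
    v_max: float  # ms^-1
    K_EI: float  # μM
    K_ESI: float  # μM
    mean_W_ES0: float  # ms, <min(T_cat, T_off)>
    p_cat: float  # Pr(T_cat < T_off)


@dataclass(frozen=True)
class ModulationFactors:
    """A([I]), B([I]) and the probabilistic quantities behind them."""

    A: float
    B: float
    s: float  # k_on_ESI [I], ms^-1
    mean_W_ES: float  # <min(T_cat, T_off, T_on_ESI)>, ms
    p_cat_inhibited: float  # Pr(T_cat < T_off, T_on_ESI)


# -- core renewal integrals -------------------------------------------------


def _es_integrals(T_cat: WaitingTimeDistribution, T_off: WaitingTimeDistribution,
                  s: float) -> tuple[float, float]:
    """Return (∫ e^{-st} F̄_cat F̄_off dt,  ∫ e^{-st} f_cat F̄_off dt).

    At s = 0 these are the mean ES lifetime <W_ES^0> and the catalysis
    probability Pr(T_cat < T_off); at s = k_on_ESI [I] they give the
    inhibited-lifetime analogues (an exponential inhibitor-arrival clock at
    rate s is just an extra e^{-st} survival factor).

    When substrate unbinding is exponential both integrals collapse onto the
    catalysis-time Laplace transform, which is closed-form for the
    exponential / two-state / gamma families.
    """
    if T_off.family == "exponential":
        u = s + T_off.params["rate"]
        p = T_cat.laplace(u)
        return (1.0 - p) / u, p
    cutoff = min(T_cat.tail_cutoff, T_off.tail_cutoff)
    sf_c, sf_o, pdf_c = T_cat.sf, T_off.sf, T_cat.pdf
    w = integrate_tail(lambda t: math.exp(-s * t) * float(sf_c(t)) * float(sf_o(t)), cutoff)
    p = integrate_tail(lambda t: math.exp(-s * t) * float(pdf_c(t)) * float(sf_o(t)), cutoff)
    return w, p


def _es_integrals_quadrature(T_cat, T_off, s: float) -> tuple[float, float]:
    """Same integrals as :func:`_es_integrals`, forced through quadrature.

    Kept as an independent route so the Laplace-form and probabilistic-form
    representations of A and B can be cross-checked against each other.
    """
    cutoff = min(T_cat.tail_cutoff, T_off.tail_cutoff)
    sf_c, sf_o, pdf_c = T_cat.sf, T_off.sf, T_cat.pdf
    w = integrate_tail(lambda t: math.exp(-s * t) * float(sf_c(t)) * float(sf_o(t)), cutoff)
    p = integrate_tail(lambda t: math.exp(-s * t) * float(pdf_c(t)) * float(sf_o(t)), cutoff)
    return w, p


@lru_cache(maxsize=512)
def _base_constants(scheme: InhibitionScheme) -> tuple[float, float]:
    """(mean_W_ES0, p_cat) for the uninhibited ES state, cached per scheme."""
    return _es_integrals(scheme.T_cat, scheme.T_off, 0.0)


def effective_constants(scheme: InhibitionScheme) -> EffectiveConstants:
    """Compute K_m, v_max and the inhibitor equilibrium constants."""
    mean_w0, p_cat = _base_constants(scheme)
    K_m = 1.0 / (scheme.k_on * mean_w0)
    v_max = p_cat / mean_w0
    K_EI = (
        1.0 / (scheme.T_off_EI.mean * scheme.k_on_EI) if scheme.has_EI else math.inf
    )
    K_ESI = (
        1.0 / (scheme.T_off_ESI.mean * scheme.k_on_ESI) if scheme.has_ESI else math.inf
    )
    return EffectiveConstants(
        K_m=K_m, v_max=v_max, K_EI=K_EI, K_ESI=K_ESI,
        mean_W_ES0=mean_w0, p_cat=p_cat,
    )


def f_tilde_M(scheme: InhibitionScheme, s: float) -> float:
    """Normalized transform of the ES survival product:  <W_ES>(s)/<W_ES^0>."""
    if s < 0:
        raise InvalidParameterError(f"s must be >= 0, got {s}")
    mean_w0, _ = _base_constants(scheme)
    w, _ = _es_integrals(scheme.T_cat, scheme.T_off, s)
    return w / mean_w0


def f_tilde_P(scheme: InhibitionScheme, s: float) -> float:
    """Normalized transform of the catalysis flux:  Pr_s(cat first)/Pr(T_cat<T_off)."""
    if s < 0:
        raise InvalidParameterError(f"s must be >= 0, got {s}")
    _, p0 = _base_constants(scheme)
    _, p = _es_integrals(scheme.T_cat, scheme.T_off, s)
    return p / p0


def _AB(scheme: InhibitionScheme, s: float) -> tuple[float, float, float, float]:
    """(A, B, mean_W_ES, p_cat_inhibited) at transform argument s (fast path)."""
    mean_w0, p0 = _base_constants(scheme)
    w, p = _es_integrals(scheme.T_cat, scheme.T_off, s)
    ftM = w / mean_w0
    ftP = p / p0
    A = (1.0 - s * mean_w0 * ftM) / ftP
    B = ftM / ftP
    return A, B, w, p


def modulation_factors(scheme: InhibitionScheme, I: float, check: bool = True,
                       check_tol: float = 1e-8) -> ModulationFactors:
    """Evaluate A([I]) and B([I]) for an uncompetitive or mixed scheme.

    The Laplace-transform representation is primary.  With ``check=True``
    the probabilistic representation — built from the inhibited ES lifetime
    ``<W_ES> = <min(T_cat, T_off, T_on_ESI)>`` and the three-way catalysis
    probability, both recomputed by direct quadrature — is evaluated
    independently and must agree within ``check_tol``.
    """
    if I < 0:
        raise InvalidParameterError(f"inhibitor concentration must be >= 0, got {I}")
    if scheme.mode not in ("uncompetitive", "mixed"):
        raise UnsupportedModeError(
            f"modulation factors require uncompetitive/mixed mode, got {scheme.mode!r}"
        )
    s = (scheme.k_on_ESI or 0.0) * I
    A, B, w, p = _AB(scheme, s)
    if check and s > 0:
        mean_w0, p0 = _base_constants(scheme)
        wq, pq = _es_integrals_quadrature(scheme.T_cat, scheme.T_off, s)
        # probabilistic forms: A = (1 - <W_ES>/<T_on_ESI>) / (Pr_3/Pr_2),
        # B = <W_ES> Pr_2 / (<W_ES^0> Pr_3)
        A_prob = (1.0 - s * wq) / (pq / p0)
        B_prob = wq * p0 / (mean_w0 * pq)
        if abs(A_prob - A) > check_tol * max(1.0, abs(A)) or (
            abs(B_prob - B) > check_tol * max(1.0, abs(B))
        ):
            raise InvalidParameterError(
                "Laplace and probabilistic forms of A/B disagree: "
                f"A {A:.12g} vs {A_prob:.12g}, B {B:.12g} vs {B_prob:.12g}"
            )
    return ModulationFactors(A=A, B=B, s=s, mean_W_ES=w, p_cat_inhibited=p)


# -- turnover laws ----------------------------------------------------------


def turnover_classical(K_m: float, v_max: float, K_EI: float, K_ESI: float,
                       S: float, I: float) -> float:
    """Classical bulk rate law; K_EI/K_ESI may be +inf (limit cases)."""
    if S <= 0:
        raise InvalidParameterError(f"substrate concentration must be > 0, got {S}")
    if I < 0:
        raise InvalidParameterError(f"inhibitor concentration must be >= 0, got {I}")
    ei = 0.0 if math.isinf(K_EI) else I / K_EI
    esi = 0.0 if math.isinf(K_ESI) else I / K_ESI
    inv = K_m * (1.0 + ei) / (v_max * S) + (1.0 + esi) / v_max
    return 1.0 / inv


def turnover_competitive(scheme: InhibitionScheme, S: float, I: float) -> float:
    """Single-enzyme competitive rate: classical form with generalized constants.

    Depends on the EI dwell-time distribution only through its mean (via
    K_EI), and on catalysis/unbinding only through K_m and v_max.
    """
    if scheme.mode != "competitive":
        raise UnsupportedModeError(f"expected competitive mode, got {scheme.mode!r}")
    ec = effective_constants(scheme)
    return turnover_classical(ec.K_m, ec.v_max, ec.K_EI, math.inf, S, I)


def turnover_uncompetitive(scheme: InhibitionScheme, S: float, I: float) -> float:
    """Single-enzyme uncompetitive rate with modulation factors A, B."""
    if scheme.mode != "uncompetitive":
        raise UnsupportedModeError(f"expected uncompetitive mode, got {scheme.mode!r}")
    return _turnover_modulated(scheme, S, I, with_EI=False)


def turnover_mixed(scheme: InhibitionScheme, S: float, I: float) -> float:
    """Single-enzyme mixed-inhibition rate (both EI and ESI channels)."""
    if scheme.mode != "mixed":
        raise UnsupportedModeError(f"expected mixed mode, got {scheme.mode!r}")
    return _turnover_modulated(scheme, S, I, with_EI=True)


def _turnover_modulated(scheme: InhibitionScheme, S: float, I: float,
                        with_EI: bool) -> float:
    if S <= 0:
        raise InvalidParameterError(f"substrate concentration must be > 0, got {S}")
    if I < 0:
        raise InvalidParameterError(f"inhibitor concentration must be >= 0, got {I}")
    ec = effective_constants(scheme)
    if scheme.has_ESI and I > 0:
        A, B, _, _ = _AB(scheme, scheme.k_on_ESI * I)
        esi = I / ec.K_ESI
    else:
        A = B = 1.0
        esi = 0.0
    ei = I / ec.K_EI if (with_EI and scheme.has_EI) else 0.0
    inv = ec.K_m * (1.0 + ei) * A / (ec.v_max * S) + (1.0 + esi) * B / ec.v_max
    return 1.0 / inv


def turnover(scheme: InhibitionScheme, S: float, I: float) -> float:
    """Dispatch on the scheme's mode; 'none' gives the uninhibited MM rate."""
    if scheme.mode == "none":
        ec = effective_constants(scheme)
        return turnover_classical(ec.K_m, ec.v_max, math.inf, math.inf, S, 0.0)
    if scheme.mode == "competitive":
        return turnover_competitive(scheme, S, I)
    if scheme.mode == "uncompetitive":
        return turnover_uncompetitive(scheme, S, I)
    return turnover_mixed(scheme, S, I)
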