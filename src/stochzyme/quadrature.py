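"""Shared adaptive-quadrature policy for waiting-time integrals.

All semi-infinite integrals in the package go through :func:`integrate_tail`,
so there is a single numerical-accuracy knob.  Integrands are smooth products
of densities/survival functions and an ``exp(-s t)`` kernel; we split the
domain at a characteristic cutoff (a far quantile of the underlying waiting
time) so the adaptive rule resolves mass concentrated at short times before
handling the tail.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from scipy.integrate import IntegrationWarning, quad

from .errors import NumericalFailureError

#: survival level defining the truncation cutoff T* (1 - 1e-12 quantile)
TAIL_SURVIVAL = 1e-12
#: relative tolerance for all adaptive quadrature
REL_TOL = 1e-11
#: absolute tolerance floor
ABS_TOL = 1e-13


def integrate_tail(f: Callable[[float], float], cutoff: float) -> float:
    """Integrate ``f`` over [0, inf), splitting at ``cutoff``.

    ``cutoff`` should be a far quantile of the integrand's natural time
    scale (e.g. the 1-1e-12 quantile of a waiting time).  Raises
    :class:`NumericalFailureError` if scipy reports a failure.
    """
    if not np.isfinite(cutoff) or cutoff <= 0:
        raise NumericalFailureError(f"invalid quadrature cutoff {cutoff!r}")
    with warnings.catch_warnings():
        # roundoff warnings are re-judged below against our own error bound
        warnings.simplefilter("ignore", IntegrationWarning)
        head, head_err = quad(f, 0.0, cutoff, epsabs=ABS_TOL, epsrel=REL_TOL, limit=400)
        tail, tail_err = quad(f, cutoff, np.inf, epsabs=ABS_TOL, epsrel=REL_TOL, limit=400)
    total = head + tail
    err = head_err + tail_err
    if not np.isfinite(total):
        raise NumericalFailureError("quadrature returned a non-finite value")
    if err > max(ABS_TOL * 10, 1e-7 * max(abs(total), 1.0)):
        raise NumericalFailureError(
            f"quadrature error estimate {err:.3g} too large for value {total:.6g}"
        )
    return total
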