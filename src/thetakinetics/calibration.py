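"""Mixing-time calibration from an internal-standard binding timer.

A nanobody-epitope pair with independently known rate constants is
co-electrosprayed with the analyte from the two channels of a theta
emitter. Because the timer's occupancy evolves on a known schedule after
the channels mix, the observed timer bound fraction of each spectrum can
be inverted through the theoretical binding curve into that spectrum's
mixing time ("droplet lifetime").

The mixing factor alpha (fraction of the mixed droplet contributed by
the protein channel) sets the post-mixing initial concentrations

    P0 = alpha * epitope_total,    L0 = (1 - alpha) * nb_total,

so the calibration curve — and hence every assigned time — depends on
alpha. alpha = 0.5 is ideal 1:1 mixing (a 2-fold dilution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kinetics import (
    BindingSystem,
    RateConstants,
    closed_form_complex,
    equilibrium_bound,
    time_to_complex,
)

__all__ = [
    "TimerSystem",
    "CalibrationCurve",
    "EquilibratedSpectrumError",
    "build_curve",
    "invert_time",
    "sensitivity_window",
]

logger = logging.getLogger(__name__)

#: default tolerance: observed fractions within (1 - eps) of the plateau
#: are treated as equilibrated and carry no time information
DEFAULT_EQUILIBRATED_EPS = 0.01


class EquilibratedSpectrumError(ValueError):
    """The observed timer fraction is at the curve plateau.

    Such a spectrum's mixing time is unresolvable (any sufficiently long
    time is consistent with the observation) and it must be excluded
    from kinetic fitting rather than assigned a capped time.
    """


@dataclass(frozen=True)
class TimerSystem:
    """The internal-standard timer pair with its channel totals.

    ``epitope_total`` is the concentration of the epitope-bearing protein
    in the protein channel; ``nb_total`` the nanobody concentration in the
    ligand channel (both pre-mixing). ``rates`` are externally determined
    (e.g. by biolayer interferometry); koff = 0 is permitted for timers
    such as the ALFA pair whose dissociation is unmeasurably slow.
    """

    epitope_total: float
    nb_total: float
    rates: RateConstants

    def __post_init__(self) -> None:
        if self.epitope_total <= 0 or self.nb_total <= 0:
            raise ValueError("timer channel concentrations must be > 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map from mixing time to timer bound fraction at fixed alpha."""

    alpha: float
    system: BindingSystem  # post-mixing concentrations, timer rates
    plateau_fraction: float

    def __call__(self, t):
        """Timer bound fraction at time ``t`` (vectorized)."""
        return closed_form_complex(self.system, t) / self.system.p_total

    def invert(self, f_obs: float, eps: float = DEFAULT_EQUILIBRATED_EPS) -> float:
        """Mixing time at which the bound fraction equals ``f_obs``.

        Exact analytic inversion of the closed-form curve. Raises
        :class:`EquilibratedSpectrumError` for fractions within ``eps``
        (relative) of the plateau.
        """
        if f_obs < 0:
            raise ValueError(f"observed fraction must be >= 0, got {f_obs!r}")
        if f_obs >= self.plateau_fraction * (1.0 - eps):
            raise EquilibratedSpectrumError(
                f"timer fraction {f_obs:.4g} is within {eps:.0%} of the plateau "
                f"{self.plateau_fraction:.4g}: mixing time unresolvable"
            )
        return time_to_complex(self.system, f_obs * self.system.p_total)

    def invert_many(self, f_obs, eps: float = DEFAULT_EQUILIBRATED_EPS):
        """Vectorized inversion returning ``(times, usable_mask)``.

        Equilibrated entries get ``usable=False`` and ``time=inf``;
        negative fractions raise.
        """
        f = np.asarray(f_obs, dtype=float)
        if np.any(f < 0):
            raise ValueError("observed fractions must be >= 0")
        usable = f < self.plateau_fraction * (1.0 - eps)
        c = np.where(usable, f, 0.0) * self.system.p_total
        t = time_to_complex(self.system, c)
        t = np.where(usable, t, np.inf)
        return t, usable

    def invert_bracketed(self, f_obs: float, eps: float = DEFAULT_EQUILIBRATED_EPS) -> float:
        """Bracketed (Brent) inversion; slower cross-check of :meth:`invert`.

        Expands the bracket geometrically until the curve exceeds
        ``f_obs``, then solves to 1e-8 relative accuracy.
        """
        if f_obs < 0:
            raise ValueError(f"observed fraction must be >= 0, got {f_obs!r}")
        if f_obs == 0:
            return 0.0
        if f_obs >= self.plateau_fraction * (1.0 - eps):
            raise EquilibratedSpectrumError(
                f"timer fraction {f_obs:.4g} at plateau: mixing time unresolvable"
            )
        hi = 1.0
        while self(hi) < f_obs:
            hi *= 2.0
        return brentq(lambda t: self(t) - f_obs, 0.0, hi, rtol=1e-12, xtol=1e-300)


def build_curve(timer: TimerSystem, alpha: float) -> CalibrationCurve:
    """Theoretical timer binding curve under mixing factor ``alpha``.

    Post-mixing initial concentrations are P0 = alpha * epitope_total and
    L0 = (1 - alpha) * nb_total. The plateau is the equilibrium bound
    fraction (or the limiting-reagent fraction min(P0, L0)/P0 for an
    irreversible timer).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    p0 = alpha * timer.epitope_total
    l0 = (1.0 - alpha) * timer.nb_total
    system = BindingSystem(p_total=p0, l_total=l0, rates=timer.rates)
    if timer.rates.irreversible:
        plateau = min(p0, l0) / p0
    else:
        plateau = equilibrium_bound(p0, l0, timer.rates.kd) / p0
    return CalibrationCurve(alpha=alpha, system=system, plateau_fraction=plateau)


def invert_time(
    curve: CalibrationCurve, f_obs: float, eps: float = DEFAULT_EQUILIBRATED_EPS
) -> float:
    """Functional alias for :meth:`CalibrationCurve.invert`."""
    return curve.invert(f_obs, eps=eps)


def sensitivity_window(
    curve: CalibrationCurve, lo: float = 0.05, hi: float = 0.95
) -> tuple[float, float]:
    """Times at which the curve reaches ``lo`` and ``hi`` of its plateau.

    Between these bounds the curve is steep enough to resolve mixing
    times; outside it, small fraction errors translate into large time
    errors. Defaults bracket 5-95% of the plateau.
    """
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("require 0 < lo < hi < 1")
    t_lo = curve.invert(lo * curve.plateau_fraction, eps=0.0)
    t_hi = curve.invert(hi * curve.plateau_fraction, eps=0.0)
    return t_lo, t_hi
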