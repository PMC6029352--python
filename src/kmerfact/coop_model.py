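"""Equilibrium occupancy of a TF binding site with and without cooperativity.

A TF x occupies a single site as a simple binding isotherm,

    O_x = 1 - 1 / (1 + [x] / Kd_x),

i.e. one minus the probability the site is unbound.  If x can also bind as
an xy heterodimer with a partner y (with [xy] = Ka_xy [x][y] at equilibrium,
and f = Ka_xy [y] the fraction of x in xy form), monomer (concentration
[x](1-f)) and dimer ([x]f) compete for the same single site.  The exact
single-site partition function gives

    O_x_coop = 1 - 1 / (1 + [x](1-f)/Kd_x + [x] f / Kd_xy),

which collapses to the plain isotherm exactly when f = 0 or Kd_xy = Kd_x.
A widely used independent-species approximation instead multiplies the two
unbound probabilities,

    O_x_indep = 1 - [1 / (1 + [x](1-f)/Kd_x)] * [1 / (1 + [x] f / Kd_xy)],

which differs by a cross term ([x]^2 f(1-f) / (Kd_x Kd_xy)) that counts
monomer and dimer bound to the one site simultaneously; it is provided for
comparison as :func:`coop_occupancy_independent`.

When the dimer binds more tightly (Kd_xy < Kd_x) the cooperative curve is
steeper than the monomer curve around half occupancy, so small changes in
[x] near the critical concentration produce larger changes in occupancy —
cooperative binding is intrinsically the more variable regime.  The module
also aligns the two curves at 50% occupancy for side-by-side plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CooperativityParams",
    "occupancy",
    "coop_occupancy",
    "coop_occupancy_independent",
    "half_occupancy_concentration",
    "steepness_compare",
]


@dataclass(frozen=True)
class CooperativityParams:
    """Parameters of the cooperative-binding occupancy model.

    ``x_conc``: TF concentration [x] (arbitrary concentration units).
    ``kd_x``: dissociation constant of x alone, same units.
    ``kd_xy``: dissociation constant of the xy heterodimer.
    ``f_xy``: dimensionless fraction of x bound up in xy form (Ka_xy [y]).
    """

    x_conc: float
    kd_x: float
    kd_xy: float
    f_xy: float

    def __post_init__(self) -> None:
        if self.x_conc < 0 or self.kd_x <= 0 or self.kd_xy <= 0:
            raise ValueError("concentrations and Kd values must be positive")
        if not 0.0 <= self.f_xy < 1.0:
            raise ValueError("f_xy must be in [0, 1)")
        if self.kd_xy > self.kd_x:
            warnings.warn(
                "kd_xy > kd_x: the heterodimer binds more weakly than the "
                "monomer, which is not the expected regime", stacklevel=2
            )


def occupancy(x_conc, kd_x: float):
    """Fractional occupancy of a single site by TF x alone."""
    if kd_x <= 0:
        raise ValueError("Kd must be positive")
    x = np.asarray(x_conc, dtype=float)
    if (x < 0).any():
        raise ValueError("concentration must be non-negative")
    out = 1.0 - 1.0 / (1.0 + x / kd_x)
    return float(out) if np.isscalar(x_conc) else out


def coop_occupancy(params: CooperativityParams, x_conc=None):
    """Fractional occupancy with cooperative partner binding (competitive).

    Monomer and heterodimer compete for the single site; with ``f_xy = 0``
    or ``kd_xy = kd_x`` this collapses exactly to the non-cooperative
    isotherm.
    """
    x = np.asarray(params.x_conc if x_conc is None else x_conc, dtype=float)
    f = params.f_xy
    unbound = 1.0 / (1.0 + x * (1.0 - f) / params.kd_x + x * f / params.kd_xy)
    out = 1.0 - unbound
    return float(out) if out.ndim == 0 else out


def coop_occupancy_independent(params: CooperativityParams, x_conc=None):
    """Independent-species approximation: product of unbound probabilities.

    Over-counts simultaneous monomer+dimer binding of the one site, so it
    exceeds :func:`coop_occupancy` slightly and collapses to the plain
    isotherm only at ``f_xy = 0``.
    """
    x = np.asarray(params.x_conc if x_conc is None else x_conc, dtype=float)
    f = params.f_xy
    unbound = (1.0 / (1.0 + x * (1.0 - f) / params.kd_x)) * \
              (1.0 / (1.0 + x * f / params.kd_xy))
    out = 1.0 - unbound
    return float(out) if out.ndim == 0 else out


def half_occupancy_concentration(
    curve, x_lo: float, x_hi: float, tol: float = 1e-10
) -> float:
    """Concentration where an occupancy curve crosses 0.5 (bisection).

    ``curve`` maps concentration -> occupancy and must bracket 0.5 on
    ``[x_lo, x_hi]``; otherwise a ValueError is raised.
    """
    f_lo, f_hi = curve(x_lo) - 0.5, curve(x_hi) - 0.5
    if f_lo * f_hi > 0:
        raise ValueError("half-occupancy not bracketed by the concentration grid")
    return float(brentq(lambda x: curve(x) - 0.5, x_lo, x_hi, xtol=tol))


def _slope(curve, x: float, rel_step: float = 1e-6) -> float:
    h = x * rel_step
    return (curve(x + h) - curve(x - h)) / (2 * h)


def steepness_compare(
    params: CooperativityParams,
    x_grid: np.ndarray,
) -> dict:
    """Compare cooperative vs plain binding-curve steepness at half occupancy.

    Each curve's half-occupancy concentration is found numerically on the
    grid's range and the local slope dO/d[x] measured by central difference.
    Curves are also re-expressed on concentration axes shifted so both cross
    50% at the same point ("aligned"), for plotting.  The grid must bracket
    half occupancy for both curves.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.size < 2 or (np.diff(x_grid) <= 0).any():
        raise ValueError("x_grid must be increasing with >= 2 points")
    plain = lambda x: occupancy(x, params.kd_x)
    coop = lambda x: coop_occupancy(params, x)
    x_lo, x_hi = float(x_grid[0]), float(x_grid[-1])
    x_half_plain = half_occupancy_concentration(plain, x_lo, x_hi)
    x_half_coop = half_occupancy_concentration(coop, x_lo, x_hi)
    slope_plain = _slope(plain, x_half_plain)
    slope_coop = _slope(coop, x_half_coop)
    return {
        "x_half_plain": x_half_plain,
        "x_half_coop": x_half_coop,
        "slope_plain": slope_plain,
        "slope_coop": slope_coop,
        "grid": x_grid,
        "occupancy_plain": plain(x_grid),
        "occupancy_coop": coop(x_grid),
        # aligned curves: concentration axes shifted so both cross 0.5 together
        "aligned_grid_plain": x_grid - x_half_plain,
        "aligned_grid_coop": x_grid - x_half_coop,
    }
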