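"""Optical-reach estimation: how much tissue, how many opsin-positive cells
and how many endogenous spikes an optogenetic manipulation touches.

Light exits the fiber in a cone of half-angle arcsin(NA); down to the
maximal depth at which the transmitted power still exceeds the minimal
effective power, the illuminated volume is a truncated cone (frustum). Cell
counts follow the planar-density stereology formula T = N * V / t, scaled by
the double-labelled (opsin-expressing) fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "FiberSpec",
    "DecayModel",
    "DensityEstimate",
    "fit_transmission",
    "max_depth",
    "frustum_volume",
    "cells_in_volume",
    "expected_interfered_spikes",
]


@dataclass
class FiberSpec:
    diameter: float = 0.2  # mm
    na: float = 0.22

    def __post_init__(self):
        if not (0 < self.na < 1):
            raise ValueError("NA must be in (0, 1)")
        if not self.diameter > 0:
            raise ValueError("diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class DecayModel:
    """Tissue transmission fraction vs depth; transmission(0) = 1."""

    form: str                # "exp" or "geom_exp"
    params: tuple            # exp: (length_constant,); geom_exp: (lc, z_spread)
    residual_norm: float = 0.0

    def transmission(self, z_mm):
        z = np.asarray(z_mm, dtype=float)
        if self.form == "exp":
            (lc,) = self.params
            out = np.exp(-z / lc)
        elif self.form == "geom_exp":
            lc, zs = self.params
            out = np.exp(-z / lc) / (1.0 + z / zs) ** 2
        else:
            raise ValueError(f"unknown decay model {self.form!r}")
        return out if out.shape else float(out)


_FORMS = {
    "exp": (lambda z, lc: np.exp(-z / lc), (0.2,)),
    "geom_exp": (lambda z, lc, zs: np.exp(-z / lc) / (1.0 + z / zs) ** 2, (0.2, 0.2)),
}


def fit_transmission(thickness_mm, fraction, form: str = "exp") -> DecayModel:
    """Least-squares fit of the transmission-vs-thickness curve.

    Transmission at zero thickness is fixed at 1 by the model form. A grossly
    non-monotone dataset is fitted anyway with a warning.
    """
    z = np.asarray(thickness_mm, float)
    y = np.asarray(fraction, float)
    if z.size < 4:
        raise ValueError("need >= 4 measurement points")
    if np.any((y <= 0) | (y > 1)):
        raise ValueError("fractions must lie in (0, 1]")
    if np.any(np.diff(y[np.argsort(z)]) > 0.1):
        import logging

        logging.getLogger(__name__).warning("transmission data grossly non-monotone")
    fun, p0 = _FORMS[form]
    popt, _ = optimize.curve_fit(fun, z, y, p0=p0, maxfev=10000)
    resid = float(np.linalg.norm(y - fun(z, *popt)))
    return DecayModel(form, tuple(popt), resid)


def max_depth(decay: DecayModel, surface_power_mW: float, min_power_mW: float,
              z_max: float = 20.0, tol: float = 1e-4) -> float:
    """Depth at which transmission falls to min_power/surface_power (mm).

    Solved by bisection to ``tol`` (1e-4 mm = 0.1 um); a ratio >= 1 means the
    surface power is already insufficient and the depth is 0.
    """
    if not min_power_mW < surface_power_mW:
        return 0.0
    ratio = min_power_mW / surface_power_mW
    f = lambda z: decay.transmission(z) - ratio
    if f(z_max) > 0:
        raise ValueError(f"transmission does not fall to {ratio:.3g} within {z_max} mm")
    return float(optimize.brentq(f, 0.0, z_max, xtol=tol))


def frustum_volume(fiber: FiberSpec, depth_mm: float) -> float:
    """Illuminated truncated-cone volume, mm^3.

    Base radius = fiber radius, half-angle arcsin(NA), height = depth:
    V = pi*h/3 * (r0^2 + r0*r1 + r1^2) with r1 = r0 + h*tan(arcsin(NA)).
    """
    if depth_mm < 0:
        raise ValueError("depth must be >= 0")
    r0 = fiber.radius
    r1 = r0 + depth_mm * np.tan(np.arcsin(fiber.na))
    return float(np.pi * depth_mm / 3.0 * (r0**2 + r0 * r1 + r1**2))


@dataclass
class DensityEstimate:
    N_per_mm2: float            # labelled cells per mm^2 (planar density)
    section_thickness_mm: float = 0.04
    double_label_fraction: float = 1.0

    def __post_init__(self):
        if self.N_per_mm2 < 0 or not self.section_thickness_mm > 0:
            raise ValueError("invalid density estimate")
        if not 0 <= self.double_label_fraction <= 1:
            raise ValueError("double_label_fraction must be in [0, 1]")


def cells_in_volume(density: DensityEstimate, volume_mm3: float) -> float:
    """Opsin-positive cells in the volume: T = N*V/t times the double-labelled
    fraction (exact value; round for reporting)."""
    return density.N_per_mm2 * volume_mm3 / density.section_thickness_mm \
        * density.double_label_fraction


def expected_interfered_spikes(n_cells: float, p_active_state: float,
                               spikes_per_active_state: float) -> float:
    """Endogenous spikes per state the manipulation interferes with."""
    if min(n_cells, p_active_state, spikes_per_active_state) < 0:
        raise ValueError("inputs must be >= 0")
    return n_cells * p_active_state * spikes_per_active_state
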