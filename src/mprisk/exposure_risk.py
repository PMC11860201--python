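"""Deterministic core of the risk model: leach fraction, exposure
concentration, average daily dose, hazard quotient, excess cancer risk.

A particle load of C_mp particles per litre of groundwater, each of volume
V (μm³) and density ρ (g/cm³), carries a plasticizer mass fraction R
(w/w).  Two leaching pathways release that burden to the ingested water:
a fraction L1 leaches into the groundwater itself before ingestion, and a
fraction L2 leaches from ingested particles into digestive fluids.  The
two terms are independent, so the total dissolved exposure concentration
is

    C_w = C_w1 + C_w2,   C_wi = C_mp · (ρ·V) · R · Li     [mg/L]

with the particle mass ρ·V converted from (g/cm³ · μm³) to mg exactly
once here (1 μm³ = 1e-12 cm³, 1 g = 1e3 mg).  Intake then follows the
standard drinking-water dose equation

    ADD = C_w · CR_w · EF · ED / (BW · AT)     [mg/kg-day]

and risk characterization uses the chemical's oral toxicity values:
HQ = ADD / RfD0 (non-carcinogenic) and ECR = SF0 · ADD (carcinogenic),
so ECR = SF0 · RfD0 · HQ identically.

All functions are vectorized: fields may be scalars or equal-length
NumPy arrays (one entry per Monte Carlo iteration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "ExposureParams",
    "ReceptorParams",
    "ToxicityValues",
    "leach_fraction",
    "exposure_concentration",
    "average_daily_dose",
    "hazard_quotient",
    "excess_cancer_risk",
    "UM3_TO_CM3",
    "MG_PER_G",
]

ArrayLike = Union[float, np.ndarray]

#: cm³ per μm³ — the single volume unit conversion point of the package.
UM3_TO_CM3 = 1e-12
MG_PER_G = 1e3


def _nonneg(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValidationError(f"{name} must be >= 0")


def _fraction(name: str, value) -> None:
    _nonneg(name, value)
    if np.any(np.asarray(value) > 1):
        raise ValidationError(f"{name} must be <= 1")


@dataclass
class ExposureParams:
    """Inputs of the exposure-concentration equation (scalars or arrays).

    c_mp : particles per litre of groundwater.
    rho : particle density, g/cm³.
    volume_um3 : particle volume, μm³.
    content : plasticizer mass fraction R, w/w in [0, 1].
    l1, l2 : leached fractions (groundwater / in-body) in [0, 1].
    """

    c_mp: ArrayLike
    rho: ArrayLike
    volume_um3: ArrayLike
    content: ArrayLike
    l1: ArrayLike
    l2: ArrayLike

    def __post_init__(self):
        _nonneg("c_mp", self.c_mp)
        _nonneg("rho", self.rho)
        _nonneg("volume_um3", self.volume_um3)
        _fraction("content", self.content)
        _fraction("l1", self.l1)
        _fraction("l2", self.l2)


@dataclass
class ReceptorParams:
    """Intake parameters for one receptor population.

    cr_w : groundwater intake, L/day.
    ef : exposure frequency, days/year (<= 365).
    ed : exposure duration, years.
    bw : body weight, kg.
    at : averaging time, days.
    """

    label: str
    cr_w: ArrayLike
    ef: ArrayLike
    ed: ArrayLike
    bw: ArrayLike
    at: ArrayLike

    def __post_init__(self):
        for name in ("cr_w", "ef", "ed", "bw", "at"):
            v = np.asarray(getattr(self, name))
            if np.any(v <= 0):
                raise ValidationError(f"receptor {self.label!r}: {name} must be > 0")
        if np.any(np.asarray(self.ef) > 365):
            raise ValidationError(f"receptor {self.label!r}: ef must be <= 365")


@dataclass(frozen=True)
class ToxicityValues:
    """Oral reference dose (mg/kg-day) and oral slope factor ((mg/kg-day)⁻¹)."""

    rfd0: float
    sf0: float

    def __post_init__(self):
        if self.rfd0 <= 0:
            raise ValidationError("rfd0 must be > 0")
        if self.sf0 <= 0:
            raise ValidationError("sf0 must be > 0")


def leach_fraction(leached_mass_ug_per_g: ArrayLike, content: ArrayLike):
    """Fraction of a particle's plasticizer burden released.

    ``leached_mass_ug_per_g`` is the measured release in μg of additive per
    gram of particle; ``content`` the additive mass fraction (w/w, in
    (0, 1]).  A gram of particle holds ``content * 1e6`` μg of additive, so
    the released fraction is ``leached / (content * 1e6)``.

    >>> round(leach_fraction(4.37, 0.341) * 100, 4)   # as a percentage
    0.0013
    """
    _nonneg("leached_mass_ug_per_g", leached_mass_ug_per_g)
    c = np.asarray(content, dtype=float)
    if np.any(c <= 0) or np.any(c > 1):
        raise ValidationError("content must lie in (0, 1]")
    out = np.asarray(leached_mass_ug_per_g, dtype=float) / (c * 1e6)
    return out if out.ndim else float(out)


def exposure_concentration(p: ExposureParams):
    """Total and per-pathway dissolved exposure concentrations, mg/L.

    Returns ``(C_w, C_w1, C_w2)`` with ``C_w = C_w1 + C_w2``.  Particle
    mass in mg is ``rho [g/cm³] · volume [μm³] · 1e-12 [cm³/μm³] · 1e3
    [mg/g]``; this is the only place the package converts volume units.
    """
    mass_mg = (
        np.asarray(p.rho, dtype=float)
        * np.asarray(p.volume_um3, dtype=float)
        * UM3_TO_CM3
        * MG_PER_G
    )
    base = np.asarray(p.c_mp, dtype=float) * mass_mg * np.asarray(p.content, dtype=float)
    c_w1 = base * np.asarray(p.l1, dtype=float)
    c_w2 = base * np.asarray(p.l2, dtype=float)
    c_w = c_w1 + c_w2
    if c_w1.ndim:
        return c_w, c_w1, c_w2
    return float(c_w), float(c_w1), float(c_w2)


def average_daily_dose(c_w: ArrayLike, r: ReceptorParams):
    """Average daily dose, mg/kg-day: ``C_w·CR_w·EF·ED / (BW·AT)``."""
    _nonneg("c_w", c_w)
    out = (
        np.asarray(c_w, dtype=float)
        * np.asarray(r.cr_w, dtype=float)
        * np.asarray(r.ef, dtype=float)
        * np.asarray(r.ed, dtype=float)
        / (np.asarray(r.bw, dtype=float) * np.asarray(r.at, dtype=float))
    )
    return out if out.ndim else float(out)


def hazard_quotient(add: ArrayLike, tox: ToxicityValues):
    """HQ = ADD / RfD0; HQ < 1 means no expected non-carcinogenic effect."""
    _nonneg("add", add)
    out = np.asarray(add, dtype=float) / tox.rfd0
    return out if out.ndim else float(out)


def excess_cancer_risk(add: ArrayLike, tox: ToxicityValues):
    """ECR = SF0 · ADD; the identity ECR = SF0·RfD0·HQ holds for any ADD."""
    _nonneg("add", add)
    out = tox.sf0 * np.asarray(add, dtype=float)
    return out if out.ndim else float(out)
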