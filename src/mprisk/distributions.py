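"""Seeded sampling and analytic CDF/quantile primitives.

Every stochastic input of the risk model is described by a
:class:`DistributionSpec` naming one of six families:

``point``
    A degenerate distribution at a single value.
``uniform``
    Continuous uniform on ``[low, high]``.
``triangular``
    Triangular with ``min <= mode <= max``; a fully degenerate support
    (``min == max``) is allowed and returns the point value.
``truncated_normal``
    Normal(``mean``, ``sd``) restricted to ``[lower_bound, upper_bound]``
    by resampling (rejection); bounds are optional.
``minimum_extreme``
    The Gumbel distribution for minima (left-skewed), parameterized by its
    ``mode`` (location) and ``scale``, with pdf
    ``(1/b) * exp((x-m)/b) * exp(-exp((x-m)/b))``.  Optional truncation
    bounds are enforced by resampling.  This is the parameterization used
    by spreadsheet Monte Carlo tools for "minimum extreme" inputs.
``power_law``
    Truncated Pareto-type size spectrum with density proportional to
    ``x**-alpha`` on ``[x_min, x_max]`` (``alpha != 1``), sampled by
    analytic inversion of the CDF

    ``F(x) = (x_min**(1-a) - x**(1-a)) / (x_min**(1-a) - x_max**(1-a))``.

All sampling goes through :func:`numpy.random.default_rng`; passing the
same seed twice yields identical draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "DistributionSpec",
    "sample",
    "cdf",
    "power_law_quantile",
    "power_law_cdf",
    "power_law_normalizer",
    "EULER_GAMMA",
]

#: Euler-Mascheroni constant; the mean of a Gumbel-minimum variate is
#: ``mode - EULER_GAMMA * scale``.
EULER_GAMMA = float(np.euler_gamma)

_FAMILY_PARAMS = {
    "point": {"value"},
    "uniform": {"low", "high"},
    "triangular": {"min", "mode", "max"},
    "truncated_normal": {"mean", "sd", "lower_bound", "upper_bound"},
    "minimum_extreme": {"mode", "scale", "lower_bound", "upper_bound"},
    "power_law": {"alpha", "x_min", "x_max"},
}

_REQUIRED_PARAMS = {
    "point": {"value"},
    "uniform": {"low", "high"},
    "triangular": {"min", "mode", "max"},
    "truncated_normal": {"mean", "sd"},
    "minimum_extreme": {"mode", "scale"},
    "power_law": {"alpha", "x_min", "x_max"},
}

# Cap on resampling rounds for truncated families; hitting it means the
# acceptance region has negligible mass under the parent distribution.
_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class DistributionSpec:
    """A named probability distribution for one model symbol.

    Parameters
    ----------
    family : str
        One of ``point``, ``uniform``, ``triangular``, ``truncated_normal``,
        ``minimum_extreme``, ``power_law``.
    parameters : mapping of str to float
        Family-specific named parameters (see module docstring).
    label : str
        The model symbol this spec instantiates (e.g. ``"C_mp"``, ``"R"``).
    """

    family: str
    parameters: Mapping[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        if self.family not in _FAMILY_PARAMS:
            raise ConfigurationError(
                f"unknown distribution family {self.family!r}; expected one of "
                f"{sorted(_FAMILY_PARAMS)}"
            )
        object.__setattr__(self, "parameters", dict(self.parameters))
        given = set(self.parameters)
        missing = _REQUIRED_PARAMS[self.family] - given
        if missing:
            raise ValidationError(
                f"{self.family} ({self.label or 'unlabelled'}): missing "
                f"parameter(s) {sorted(missing)}"
            )
        unknown = given - _FAMILY_PARAMS[self.family]
        if unknown:
            raise ValidationError(
                f"{self.family} ({self.label or 'unlabelled'}): unknown "
                f"parameter(s) {sorted(unknown)}"
            )
        self._validate()

    # -- invariants ---------------------------------------------------------
    def _validate(self) -> None:
        p = self.parameters
        fam = self.family
        if fam == "uniform":
            if not p["low"] < p["high"]:
                raise ValidationError("uniform: 'low' must be < 'high'")
        elif fam == "triangular":
            if not (p["min"] <= p["mode"] <= p["max"]):
                raise ValidationError(
                    "triangular: require 'min' <= 'mode' <= 'max'"
                )
        elif fam == "truncated_normal":
            if p["sd"] < 0:
                raise ValidationError("truncated_normal: 'sd' must be >= 0")
            lo = p.get("lower_bound", -math.inf)
            hi = p.get("upper_bound", math.inf)
            if lo >= hi:
                raise ValidationError(
                    "truncated_normal: 'lower_bound' must be < 'upper_bound'"
                )
        elif fam == "minimum_extreme":
            if p["scale"] <= 0:
                raise ValidationError("minimum_extreme: 'scale' must be > 0")
            lo = p.get("lower_bound", -math.inf)
            hi = p.get("upper_bound", math.inf)
            if lo >= hi:
                raise ValidationError(
                    "minimum_extreme: 'lower_bound' must be < 'upper_bound'"
                )
        elif fam == "power_law":
            if not 0 < p["x_min"] < p["x_max"]:
                raise ValidationError("power_law: require 0 < 'x_min' < 'x_max'")
            if p["alpha"] <= 0:
                raise ValidationError("power_law: 'alpha' must be > 0")
            if p["alpha"] == 1:
                raise ValidationError(
                    "power_law: 'alpha' = 1 is singular for this CDF form"
                )

    def to_dict(self) -> dict:
        d = {"family": self.family}
        d.update(self.parameters)
        return d

    @classmethod
    def from_dict(cls, d: Mapping, label: str = "") -> "DistributionSpec":
        d = dict(d)
        try:
            fam = d.pop("family")
        except KeyError:
            raise ConfigurationError(
                f"distribution for {label or 'unlabelled symbol'}: "
                "missing 'family' key"
            ) from None
        return cls(fam, d, label=label)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _resolve_rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _rejection(draw, accept, n: int, what: str) -> np.ndarray:
    """Fill ``n`` accepted draws by repeated resampling."""
    out = np.empty(n)
    filled = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        x = draw(n - filled)
        x = x[accept(x)]
        out[filled : filled + x.size] = x
        filled += x.size
        if filled == n:
            return out
    raise ValidationError(
        f"{what}: truncation bounds exclude essentially all probability mass"
    )


def sample(spec: DistributionSpec, n: int, seed=None, rng=None) -> np.ndarray:
    """Draw ``n`` values from ``spec``, reproducibly under a fixed seed.

    Parameters
    ----------
    spec : DistributionSpec
    n : int
        Number of draws, ``>= 1``.
    seed : int, optional
        Seed for a fresh :func:`numpy.random.default_rng`.
    rng : numpy.random.Generator, optional
        Existing generator; takes precedence over ``seed``.
    """
    if n < 1:
        raise ValidationError("sample: 'n' must be >= 1")
    g = _resolve_rng(seed, rng)
    p = spec.parameters
    fam = spec.family

    if fam == "point":
        return np.full(n, float(p["value"]))
    if fam == "uniform":
        return g.uniform(p["low"], p["high"], n)
    if fam == "triangular":
        if p["min"] == p["max"]:  # degenerate support
            return np.full(n, float(p["min"]))
        return g.triangular(p["min"], p["mode"], p["max"], n)
    if fam == "truncated_normal":
        lo = p.get("lower_bound", -math.inf)
        hi = p.get("upper_bound", math.inf)
        if p["sd"] == 0:
            x = float(p["mean"])
            if not lo <= x <= hi:
                raise ValidationError(
                    "truncated_normal: zero-sd mean outside truncation bounds"
                )
            return np.full(n, x)
        return _rejection(
            lambda m: g.normal(p["mean"], p["sd"], m),
            lambda x: (x >= lo) & (x <= hi),
            n,
            "truncated_normal",
        )
    if fam == "minimum_extreme":
        lo = p.get("lower_bound", -math.inf)
        hi = p.get("upper_bound", math.inf)

        def draw(m):
            u = g.uniform(size=m)
            # inverse CDF of the Gumbel-minimum: F(x) = 1 - exp(-exp((x-m)/b))
            return p["mode"] + p["scale"] * np.log(-np.log1p(-u))

        if math.isinf(lo) and math.isinf(hi):
            return draw(n)
        return _rejection(draw, lambda x: (x >= lo) & (x <= hi), n, "minimum_extreme")
    if fam == "power_law":
        u = g.uniform(size=n)
        return power_law_quantile(u, p["alpha"], p["x_min"], p["x_max"])
    raise ConfigurationError(f"unknown distribution family {fam!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# analytic CDFs (used by goodness-of-fit tests and the quantile identity)
# ---------------------------------------------------------------------------

def cdf(spec: DistributionSpec, x) -> np.ndarray:
    """Analytic CDF of ``spec`` evaluated at ``x``."""
    x = np.asarray(x, dtype=float)
    p = spec.parameters
    fam = spec.family
    if fam == "point":
        return (x >= p["value"]).astype(float)
    if fam == "uniform":
        return stats.uniform(loc=p["low"], scale=p["high"] - p["low"]).cdf(x)
    if fam == "triangular":
        if p["min"] == p["max"]:
            return (x >= p["min"]).astype(float)
        c = (p["mode"] - p["min"]) / (p["max"] - p["min"])
        return stats.triang(c, loc=p["min"], scale=p["max"] - p["min"]).cdf(x)
    if fam == "truncated_normal":
        lo = p.get("lower_bound", -math.inf)
        hi = p.get("upper_bound", math.inf)
        a = (lo - p["mean"]) / p["sd"]
        b = (hi - p["mean"]) / p["sd"]
        return stats.truncnorm(a, b, loc=p["mean"], scale=p["sd"]).cdf(x)
    if fam == "minimum_extreme":
        parent = stats.gumbel_l(loc=p["mode"], scale=p["scale"])
        lo = p.get("lower_bound", -math.inf)
        hi = p.get("upper_bound", math.inf)
        flo, fhi = parent.cdf(lo), parent.cdf(hi)
        out = (parent.cdf(np.clip(x, lo, hi)) - flo) / (fhi - flo)
        return np.clip(out, 0.0, 1.0)
    if fam == "power_law":
        return power_law_cdf(x, p["alpha"], p["x_min"], p["x_max"])
    raise ConfigurationError(f"unknown distribution family {fam!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# truncated power law primitives
# ---------------------------------------------------------------------------

def power_law_cdf(x, alpha: float, x_min: float, x_max: float):
    """CDF of the size spectrum ``pdf(x) ∝ x**-alpha`` on ``[x_min, x_max]``."""
    if alpha == 1:
        raise ValidationError("power_law_cdf: 'alpha' = 1 is singular")
    x = np.clip(np.asarray(x, dtype=float), x_min, x_max)
    a1 = 1.0 - alpha
    return (x_min**a1 - x**a1) / (x_min**a1 - x_max**a1)


def power_law_quantile(u, alpha: float, x_min: float, x_max: float):
    """Inverse of :func:`power_law_cdf`; strictly increasing on ``[0, 1]``.

    ``u = 0`` maps to ``x_min`` and ``u = 1`` to ``x_max``.
    """
    if alpha == 1:
        raise ValidationError("power_law_quantile: 'alpha' = 1 is singular")
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr > 1)):
        raise ValidationError("power_law_quantile: 'u' must lie in [0, 1]")
    a1 = 1.0 - alpha
    x = (x_min**a1 - u_arr * (x_min**a1 - x_max**a1)) ** (1.0 / a1)
    # the power round trip can land a few ulp outside the support
    x = np.clip(x, x_min, x_max)
    return x if isinstance(u, np.ndarray) else float(x)


def power_law_normalizer(alpha: float, x_min: float) -> float:
    """Prefactor ``b = (alpha - 1) * x_min**(alpha - 1)``.

    With this ``b``, ``b * x**-alpha`` integrates to one on
    ``[x_min, infinity)``; it requires ``alpha > 1`` (for ``alpha <= 1``
    the unbounded-support integral diverges).
    """
    if x_min <= 0:
        raise ValidationError("power_law_normalizer: 'x_min' must be > 0")
    if alpha <= 1:
        raise ValidationError(
            "power_law_normalizer: 'alpha' must be > 1 "
            "(normalizer undefined on unbounded support)"
        )
    return (alpha - 1.0) * x_min ** (alpha - 1.0)
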