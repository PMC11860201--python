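"""Power-law particle-size spectra fitted from site abundance tables.

Groundwater microplastic surveys report, per sampling site, the relative
abundance (% of particles) in a handful of size classes, each class
identified by the particle size of its largest member (μm).  Fragmentation
makes small particles dominate, and the abundance-vs-size relation is well
described by a power law ``y = b * x**-alpha``.  This module fits that
relation per site by ordinary least squares in log-log space (the standard
"power trendline"), aggregates the exponent across sites, and turns the
aggregate exponent into a continuous, sampleable size distribution on a
bounded range (20-5000 μm by default elsewhere in the package).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .distributions import power_law_cdf, power_law_normalizer, power_law_quantile
from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "SiteAbundanceTable",
    "PowerLawFit",
    "PowerLawSizeDistribution",
    "fit_power_law",
    "aggregate_alpha",
    "build_size_distribution",
    "read_abundance_csv",
    "write_abundance_csv",
    "write_fits_csv",
]

#: Tolerance on the total abundance of a site table (rounding of printed %).
TOTAL_ABUNDANCE_TOL = 1.0


@dataclass
class SiteAbundanceTable:
    """Relative abundance (%) of particles per size class at one site.

    ``sizes`` holds each class's largest particle size in μm, strictly
    increasing; ``abundances`` the matching percentages, summing to
    100 within :data:`TOTAL_ABUNDANCE_TOL`.
    """

    site_label: str
    sizes: np.ndarray
    abundances: np.ndarray

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.sizes.ndim != 1 or self.sizes.shape != self.abundances.shape:
            raise ValidationError(
                f"site {self.site_label!r}: 'sizes' and 'abundances' must be "
                "1-D and equally long"
            )
        if np.any(self.sizes <= 0):
            raise ValidationError(f"site {self.site_label!r}: 'sizes' must be > 0")
        if np.any(np.diff(self.sizes) <= 0):
            raise ValidationError(
                f"site {self.site_label!r}: 'sizes' must be strictly increasing"
            )
        if np.any(self.abundances < 0):
            raise ValidationError(
                f"site {self.site_label!r}: 'abundances' must be >= 0"
            )
        total = float(self.abundances.sum())
        if abs(total - 100.0) > TOTAL_ABUNDANCE_TOL:
            raise ValidationError(
                f"site {self.site_label!r}: abundances sum to {total:.4f}, "
                f"expected 100 +/- {TOTAL_ABUNDANCE_TOL}"
            )
        if int((self.abundances > 0).sum()) < 3:
            raise ValidationError(
                f"site {self.site_label!r}: need at least 3 size classes with "
                "positive abundance"
            )

    def positive_rows(self) -> tuple[np.ndarray, np.ndarray]:
        """Size/abundance pairs with abundance > 0 (log fit excludes zeros)."""
        m = self.abundances > 0
        return self.sizes[m], self.abundances[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_label,
                "size_um": self.sizes,
                "abundance_pct": self.abundances,
            }
        )


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting ``y = b * x**-alpha`` to one site table."""

    alpha: float
    b: float
    r_squared: float
    site_label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError(
                f"fit {self.site_label!r}: r_squared={self.r_squared} not in [0, 1]"
            )


@dataclass(frozen=True)
class PowerLawSizeDistribution:
    """Continuous particle-size spectrum ``pdf(x) ∝ x**-alpha`` on
    ``[x_min, x_max]`` μm.

    ``b`` is the unbounded-support prefactor ``(alpha-1) * x_min**(alpha-1)``
    where it exists (``alpha > 1``); for ``alpha <= 1`` it is NaN and only
    the bounded-support CDF/quantile (always well defined for
    ``alpha != 1``) are used.
    """

    alpha: float
    x_min: float
    x_max: float
    b: float = field(default=math.nan)

    def __post_init__(self):
        if not 0 < self.x_min < self.x_max:
            raise ValidationError(
                "PowerLawSizeDistribution: require 0 < x_min < x_max"
            )
        if self.alpha <= 0:
            raise ValidationError("PowerLawSizeDistribution: alpha must be > 0")
        if self.alpha == 1:
            raise ValidationError("PowerLawSizeDistribution: alpha = 1 is singular")
        if math.isnan(self.b):
            b = (
                power_law_normalizer(self.alpha, self.x_min)
                if self.alpha > 1
                else math.nan
            )
            object.__setattr__(self, "b", b)

    def cdf(self, x):
        return power_law_cdf(x, self.alpha, self.x_min, self.x_max)

    def quantile(self, u):
        return power_law_quantile(u, self.alpha, self.x_min, self.x_max)

    def pdf(self, x):
        """Bounded-support density; strictly decreasing in x for alpha > 0."""
        x = np.asarray(x, dtype=float)
        a1 = 1.0 - self.alpha
        norm = (self.x_max**a1 - self.x_min**a1) / a1
        out = np.where(
            (x >= self.x_min) & (x <= self.x_max), x**-self.alpha / norm, 0.0
        )
        return out

    def sample(self, n: int, seed=None, rng=None) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(seed)
        return self.quantile(rng.uniform(size=n))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_power_law(table: SiteAbundanceTable, method: str = "loglog") -> PowerLawFit:
    """Fit ``y = b * x**-alpha`` to one site's abundance table.

    Parameters
    ----------
    table : SiteAbundanceTable
        Zero-abundance classes are excluded before fitting.
    method : {"loglog", "nls"}
        ``"loglog"`` (default) is ordinary least squares on
        ``(ln x, ln y)``; ``alpha`` is the negated slope and ``r_squared``
        the coefficient of determination of that regression.  ``"nls"``
        is nonlinear least squares in linear space (offered for
        comparison; its ``r_squared`` is computed on the linear residuals).
    """
    x, y = table.positive_rows()
    if x.size < 3:
        raise InsufficientDataError(
            f"site {table.site_label!r}: need >= 3 positive-abundance rows, "
            f"got {x.size}"
        )
    if method == "loglog":
        lx, ly = np.log(x), np.log(y)
        if np.ptp(ly) == 0.0:  # constant abundances: zero slope by convention
            return PowerLawFit(
                alpha=0.0,
                b=float(np.exp(ly[0])),
                r_squared=0.0,
                site_label=table.site_label,
            )
        res = stats.linregress(lx, ly)
        return PowerLawFit(
            alpha=float(-res.slope),
            b=float(np.exp(res.intercept)),
            r_squared=float(res.rvalue**2),
            site_label=table.site_label,
        )
    if method == "nls":
        p0 = (float(y[0] * x[0]), 1.5)
        popt, _ = optimize.curve_fit(
            lambda xx, b, a: b * xx**-a, x, y, p0=p0, maxfev=20000
        )
        resid = y - popt[0] * x ** -popt[1]
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        return PowerLawFit(
            alpha=float(popt[1]),
            b=float(popt[0]),
            r_squared=min(max(r2, 0.0), 1.0),
            site_label=table.site_label,
        )
    raise ValidationError(f"fit_power_law: unknown method {method!r}")


def aggregate_alpha(fits: Sequence) -> tuple[float, float]:
    """Unweighted mean and sample standard deviation (n-1) of site exponents.

    ``fits`` may hold :class:`PowerLawFit` objects or bare floats.  A single
    fit returns sd 0 with a warning.
    """
    alphas = np.array(
        [f.alpha if isinstance(f, PowerLawFit) else float(f) for f in fits],
        dtype=float,
    )
    if alphas.size == 0:
        raise ValidationError("aggregate_alpha: need at least one fit")
    if alphas.size == 1:
        warnings.warn(
            "aggregate_alpha: single fit, standard deviation undefined; "
            "reporting 0",
            stacklevel=2,
        )
        return float(alphas[0]), 0.0
    return float(alphas.mean()), float(alphas.std(ddof=1))


def build_size_distribution(
    alpha: float, x_min: float, x_max: float
) -> PowerLawSizeDistribution:
    """Continuous size spectrum from an aggregate exponent and size bounds."""
    return PowerLawSizeDistribution(alpha=alpha, x_min=x_min, x_max=x_max)


# ---------------------------------------------------------------------------
# CSV dialect: site, size_um, abundance_pct
# ---------------------------------------------------------------------------

def read_abundance_csv(path) -> list[SiteAbundanceTable]:
    """Read site abundance tables from CSV (columns: site, size_um,
    abundance_pct), one table per distinct site, in order of appearance."""
    df = pd.read_csv(path, comment="#")
    required = {"site", "size_um", "abundance_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: abundance CSV missing column(s) {sorted(missing)}"
        )
    tables = []
    for site in df["site"].drop_duplicates():
        sub = df[df["site"] == site].sort_values("size_um")
        tables.append(
            SiteAbundanceTable(
                site_label=str(site),
                sizes=sub["size_um"].to_numpy(),
                abundances=sub["abundance_pct"].to_numpy(),
            )
        )
    return tables


def write_abundance_csv(tables: Iterable[SiteAbundanceTable], path) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
        path, index=False
    )


def write_fits_csv(fits: Iterable[PowerLawFit], path) -> None:
    """Write fit results as CSV with columns site, alpha, b, r_squared."""
    pd.DataFrame(
        [
            {
                "site": f.site_label,
                "alpha": f.alpha,
                "b": f.b,
                "r_squared": f.r_squared,
            }
            for f in fits
        ]
    ).to_csv(path, index=False)
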