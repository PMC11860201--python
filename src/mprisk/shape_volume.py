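"""Shape-resolved particle volumes from sizes and aspect-ratio bounds.

Environmental microplastics are conventionally classed as fragments,
fibers, films, and spheres.  Given a particle's length L (its longest
dimension, the "size"), its width W and height H follow from
dimensionless aspect ratios W/L and H/L, and its volume from an idealized
solid per class:

========  =================  ==============================
kind      solid              volume
========  =================  ==============================
fragment  ellipsoid          (4π/3)·(L/2)·(W/2)·(H/2)
fiber     cylinder           π·(W/2)²·L   (radius W/2, length L)
film      hexahedron (box)   L·W·H
sphere    sphere             (4π/3)·(L/2)³
========  =================  ==============================

A :class:`VolumeDistribution` composes a power-law size spectrum with a
shape model ("per_shape" mode), spans a global uniform envelope between
the smallest fiber and the largest fragment volume ("uniform_envelope"
mode), conditions the uniform envelope on the sampled size
("size_conditional_envelope"), or degenerates to a point ("fixed").

The packaged ratio table (``data/default_shape_ratios.csv``) holds the
default W/L and H/L bounds per shape; it is a package-constructed default
(see methods note), replaceable by any CSV with the same columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .size_distribution import PowerLawSizeDistribution

__all__ = [
    "SHAPE_KINDS",
    "ShapeModel",
    "VolumeDistribution",
    "particle_volume",
    "sample_volumes",
    "envelope_bounds",
    "load_ratio_table",
    "default_ratio_table",
]

SHAPE_KINDS = ("fragment", "fiber", "film", "sphere")


@dataclass(frozen=True)
class ShapeModel:
    """One shape class plus its W/L and H/L aspect-ratio bounds.

    Length is the longest dimension, so each ratio pair satisfies
    ``0 < low <= high <= 1``; a sphere has both pairs pinned at (1, 1).
    """

    kind: str
    width_ratio_bounds: tuple[float, float]
    height_ratio_bounds: tuple[float, float]

    def __post_init__(self):
        if self.kind not in SHAPE_KINDS:
            raise ConfigurationError(
                f"unknown shape kind {self.kind!r}; expected one of {SHAPE_KINDS}"
            )
        for name, (lo, hi) in (
            ("width_ratio_bounds", self.width_ratio_bounds),
            ("height_ratio_bounds", self.height_ratio_bounds),
        ):
            if not 0 < lo <= hi <= 1:
                raise ValidationError(
                    f"{self.kind}: {name}={lo, hi} must satisfy 0 < low <= high <= 1"
                )
        if self.kind == "sphere" and (
            self.width_ratio_bounds != (1.0, 1.0)
            or self.height_ratio_bounds != (1.0, 1.0)
        ):
            raise ValidationError("sphere: both ratio pairs must be (1, 1)")

    def max_ratios(self) -> tuple[float, float]:
        return self.width_ratio_bounds[1], self.height_ratio_bounds[1]

    def min_ratios(self) -> tuple[float, float]:
        return self.width_ratio_bounds[0], self.height_ratio_bounds[0]

    def volume_coefficient(self, which: str = "max") -> float:
        """c such that volume = c * L**3 at this model's min or max ratios."""
        wl, hl = self.max_ratios() if which == "max" else self.min_ratios()
        return float(particle_volume(self.kind, 1.0, wl, hl))


def particle_volume(kind: str, size, width_ratio, height_ratio):
    """Volume (μm³) of a particle of longest dimension ``size`` (μm).

    Scales as ``size**3`` with ratios held fixed.  ``height_ratio`` is
    ignored for fibers (circular section of diameter W) and spheres.
    """
    if kind not in SHAPE_KINDS:
        raise ConfigurationError(
            f"unknown shape kind {kind!r}; expected one of {SHAPE_KINDS}"
        )
    size = np.asarray(size, dtype=float)
    if np.any(size <= 0):
        raise ValidationError("particle_volume: 'size' must be > 0")
    wr = np.asarray(width_ratio, dtype=float)
    hr = np.asarray(height_ratio, dtype=float)
    if np.any((wr <= 0) | (wr > 1)) or np.any((hr <= 0) | (hr > 1)):
        raise ValidationError("particle_volume: ratios must lie in (0, 1]")
    L = size
    W = wr * L
    H = hr * L
    if kind == "fragment":
        out = (4.0 * math.pi / 3.0) * (L / 2) * (W / 2) * (H / 2)
    elif kind == "fiber":
        out = math.pi * (W / 2) ** 2 * L
    elif kind == "film":
        out = L * W * H
    else:  # sphere
        out = (4.0 * math.pi / 3.0) * (L / 2) ** 3
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# ratio table
# ---------------------------------------------------------------------------

def load_ratio_table(path=None) -> dict[str, ShapeModel]:
    """Load W/L, H/L bounds per shape from CSV (columns shape, wl_low,
    wl_high, hl_low, hl_high).

    With no ``path`` the packaged default table is used; its values are a
    package-constructed default (the original survey-derived table is not
    redistributable), chosen so that fragments at maximum ratios coincide
    with spheres, fibers are slender cylinders, and films are thin sheets.
    """
    if path is None:
        src = resources.files("mprisk.data") / "default_shape_ratios.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    required = {"shape", "wl_low", "wl_high", "hl_low", "hl_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ratio table missing column(s) {sorted(missing)}")
    return {
        row["shape"]: ShapeModel(
            kind=row["shape"],
            width_ratio_bounds=(float(row["wl_low"]), float(row["wl_high"])),
            height_ratio_bounds=(float(row["hl_low"]), float(row["hl_high"])),
        )
        for _, row in df.iterrows()
    }


def default_ratio_table() -> dict[str, ShapeModel]:
    return load_ratio_table(None)


# ---------------------------------------------------------------------------
# volume distributions
# ---------------------------------------------------------------------------

_VOLUME_MODES = (
    "per_shape",
    "uniform_envelope",
    "size_conditional_envelope",
    "fixed",
)


@dataclass(frozen=True)
class VolumeDistribution:
    """Sampleable distribution of particle volume (μm³).

    Modes
    -----
    per_shape
        Draw a size from ``size_dist`` and map it through
        :func:`particle_volume` for ``shape``.  ``ratio_policy`` chooses the
        aspect ratios: ``"max"`` (default) fixes them at the upper bounds,
        ``"min"`` at the lower bounds, ``"uniform"`` draws them uniformly
        within bounds per particle.
    uniform_envelope
        Uniform on the global ``envelope_bounds`` (v_min, v_max), typically
        from :func:`envelope_bounds`.
    size_conditional_envelope
        Draw a size, then a volume uniformly between the fiber volume at
        minimum ratios and the fragment volume at maximum ratios *at that
        size* (requires ``ratio_table``).
    fixed
        Degenerate at ``fixed_value``.
    """

    mode: str
    shape: Optional[ShapeModel] = None
    size_dist: Optional[PowerLawSizeDistribution] = None
    envelope_bounds: Optional[tuple[float, float]] = None
    fixed_value: Optional[float] = None
    ratio_policy: str = "max"
    ratio_table: Optional[Mapping[str, ShapeModel]] = None

    def __post_init__(self):
        if self.mode not in _VOLUME_MODES:
            raise ConfigurationError(
                f"unknown volume mode {self.mode!r}; expected one of {_VOLUME_MODES}"
            )
        if self.ratio_policy not in ("max", "min", "uniform"):
            raise ConfigurationError(
                f"unknown ratio_policy {self.ratio_policy!r}"
            )
        if self.mode == "per_shape":
            if self.shape is None or self.size_dist is None:
                raise ConfigurationError(
                    "per_shape volume mode requires 'shape' and 'size_dist'"
                )
        elif self.mode == "uniform_envelope":
            if self.envelope_bounds is None:
                raise ConfigurationError(
                    "uniform_envelope volume mode requires 'envelope_bounds'"
                )
            v_min, v_max = self.envelope_bounds
            if not 0 < v_min < v_max:
                raise ValidationError(
                    f"envelope_bounds={self.envelope_bounds}: require 0 < v_min < v_max"
                )
        elif self.mode == "size_conditional_envelope":
            if self.size_dist is None or self.ratio_table is None:
                raise ConfigurationError(
                    "size_conditional_envelope requires 'size_dist' and 'ratio_table'"
                )
            for k in ("fiber", "fragment"):
                if k not in self.ratio_table:
                    raise ConfigurationError(
                        f"size_conditional_envelope: ratio table missing {k!r}"
                    )
        else:  # fixed
            if self.fixed_value is None or self.fixed_value <= 0:
                raise ValidationError(
                    "fixed volume mode requires a positive 'fixed_value'"
                )


def sample_volumes(vd: VolumeDistribution, n: int, seed=None, rng=None) -> np.ndarray:
    """Draw ``n`` particle volumes (μm³), all strictly positive."""
    if n < 1:
        raise ValidationError("sample_volumes: 'n' must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if vd.mode == "fixed":
        return np.full(n, float(vd.fixed_value))
    if vd.mode == "uniform_envelope":
        v_min, v_max = vd.envelope_bounds
        return rng.uniform(v_min, v_max, n)
    sizes = vd.size_dist.sample(n, rng=rng)
    if vd.mode == "per_shape":
        if vd.ratio_policy == "max":
            wl, hl = vd.shape.max_ratios()
        elif vd.ratio_policy == "min":
            wl, hl = vd.shape.min_ratios()
        else:
            (wl_lo, wl_hi) = vd.shape.width_ratio_bounds
            (hl_lo, hl_hi) = vd.shape.height_ratio_bounds
            wl = rng.uniform(wl_lo, wl_hi, n)
            hl = rng.uniform(hl_lo, hl_hi, n)
        return np.asarray(particle_volume(vd.shape.kind, sizes, wl, hl))
    # size_conditional_envelope
    fiber = vd.ratio_table["fiber"]
    fragment = vd.ratio_table["fragment"]
    lo = particle_volume("fiber", sizes, *fiber.min_ratios())
    hi = particle_volume("fragment", sizes, *fragment.max_ratios())
    return rng.uniform(lo, hi)


def envelope_bounds(
    shapes: Sequence[ShapeModel] | Mapping[str, ShapeModel],
    size_dist: PowerLawSizeDistribution,
) -> tuple[float, float]:
    """Global volume envelope (v_min, v_max) over the size range.

    v_min is the smallest attainable fiber volume (at ``x_min`` with lower
    ratio bounds); v_max the largest attainable fragment volume (at
    ``x_max`` with upper ratio bounds).  Both shapes must be present.
    """
    if isinstance(shapes, Mapping):
        table = dict(shapes)
    else:
        table = {s.kind: s for s in shapes}
    for k in ("fiber", "fragment"):
        if k not in table:
            raise ConfigurationError(f"envelope_bounds: missing required shape {k!r}")
    v_min = particle_volume(
        "fiber", size_dist.x_min, *table["fiber"].min_ratios()
    )
    v_max = particle_volume(
        "fragment", size_dist.x_max, *table["fragment"].max_ratios()
    )
    if not v_min < v_max:
        raise ValidationError(
            f"envelope_bounds: degenerate envelope (v_min={v_min} >= v_max={v_max})"
        )
    return float(v_min), float(v_max)
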