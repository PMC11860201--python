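"""Monte Carlo engine, summaries, sensitivity analysis, and reporting.

A :class:`ScenarioConfig` binds every symbol of the exposure model to a
distribution (or point value), chooses a volume model, and fixes the
iteration count and seed.  :func:`run_simulation` draws all inputs
independently, computes per-iteration exposure concentration, ADD, HQ
and ECR for each receptor, and retains every stochastic draw so that
:func:`sensitivity_analysis` can attribute output variance to inputs via
normalized squared Spearman rank correlations ("contribution to
variance", the convention of spreadsheet Monte Carlo tools).

Receptors share the concentration-side draws within an iteration
(common random numbers), so adult/child contrasts are not inflated by
sampling noise; intake parameters with identical specs (exposure
frequency, by default) are likewise shared, while body weight and water
intake are drawn per receptor.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sps

from .distributions import DistributionSpec, sample
from .exceptions import ConfigurationError, ValidationError
from .exposure_risk import (
    ExposureParams,
    ReceptorParams,
    ToxicityValues,
    average_daily_dose,
    excess_cancer_risk,
    exposure_concentration,
    hazard_quotient,
)
from .shape_volume import (
    ShapeModel,
    VolumeDistribution,
    default_ratio_table,
    envelope_bounds,
    sample_volumes,
)
from .size_distribution import PowerLawSizeDistribution

__all__ = [
    "ReceptorSpec",
    "ScenarioConfig",
    "RiskResult",
    "SensitivityReport",
    "run_simulation",
    "percentile",
    "exceedance_probability",
    "sensitivity_analysis",
    "write_report",
]

logger = logging.getLogger("mprisk")

METRICS = ("ECR", "HQ", "ADD")
DENSITY_UNITS = ("g/cm3", "mg/cm3")


def _point(value: float, label: str) -> DistributionSpec:
    return DistributionSpec("point", {"value": float(value)}, label=label)


def _as_spec(value, label: str) -> DistributionSpec:
    if isinstance(value, DistributionSpec):
        return value
    return _point(float(value), label)


@dataclass(frozen=True)
class ReceptorSpec:
    """Distribution specs and point values for one receptor's intake."""

    label: str
    cr_w: DistributionSpec
    ef: DistributionSpec
    ed: float
    bw: DistributionSpec
    at: float

    def __post_init__(self):
        if self.ed <= 0 or self.at <= 0:
            raise ValidationError(f"receptor {self.label!r}: ed and at must be > 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one Monte Carlo risk run.

    Every exposure symbol is bound exactly once: C_mp, rho, R (as
    distribution specs), L1 and L2 (specs or point values), the volume
    model, per-receptor intake specs, and the toxicity values.

    ``density_unit`` states the unit of the numbers drawn for rho:
    ``"g/cm3"`` uses them as-is; ``"mg/cm3"`` takes them literally as
    mg/cm³ (i.e. divides by 1000 before the mass computation).  See the
    methods note for why both readings are supported.
    """

    c_mp: DistributionSpec
    rho: DistributionSpec
    dehp_content: DistributionSpec
    l1: DistributionSpec
    l2: DistributionSpec
    volume: VolumeDistribution
    receptors: Mapping[str, ReceptorSpec]
    toxicity: ToxicityValues
    density_unit: str = "g/cm3"
    n_iterations: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.density_unit not in DENSITY_UNITS:
            raise ConfigurationError(
                f"unknown density_unit {self.density_unit!r}; "
                f"expected one of {DENSITY_UNITS}"
            )
        if not self.receptors:
            raise ConfigurationError("scenario binds no receptors")
        object.__setattr__(self, "receptors", dict(self.receptors))
        object.__setattr__(self, "l1", _as_spec(self.l1, "L1"))
        object.__setattr__(self, "l2", _as_spec(self.l2, "L2"))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        vol = self.volume
        vol_d: dict = {"mode": vol.mode, "ratio_policy": vol.ratio_policy}
        if vol.shape is not None:
            vol_d["shape"] = vol.shape.kind
        if vol.size_dist is not None:
            vol_d["size"] = {
                "alpha": vol.size_dist.alpha,
                "x_min": vol.size_dist.x_min,
                "x_max": vol.size_dist.x_max,
            }
        if vol.envelope_bounds is not None:
            vol_d["envelope_bounds"] = list(vol.envelope_bounds)
        if vol.fixed_value is not None:
            vol_d["value"] = vol.fixed_value
        if vol.ratio_table is not None:
            vol_d["ratio_table"] = {
                k: {
                    "wl": list(m.width_ratio_bounds),
                    "hl": list(m.height_ratio_bounds),
                }
                for k, m in sorted(vol.ratio_table.items())
            }
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "density_unit": self.density_unit,
            "inputs": {
                "C_mp": self.c_mp.to_dict(),
                "rho": self.rho.to_dict(),
                "R": self.dehp_content.to_dict(),
                "L1": self.l1.to_dict(),
                "L2": self.l2.to_dict(),
            },
            "volume": vol_d,
            "toxicity": {"RfD0": self.toxicity.rfd0, "SF0": self.toxicity.sf0},
            "receptors": {
                label: {
                    "CR_w": r.cr_w.to_dict(),
                    "EF": r.ef.to_dict(),
                    "ED": r.ed,
                    "BW": r.bw.to_dict(),
                    "AT": r.at,
                }
                for label, r in self.receptors.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        try:
            inputs = d["inputs"]
            vol_d = d["volume"]
            tox_d = d["toxicity"]
            rec_d = d["receptors"]
        except KeyError as e:
            raise ConfigurationError(f"scenario config: missing section {e}") from None
        for sym in ("C_mp", "rho", "R", "L1", "L2"):
            if sym not in inputs:
                raise ConfigurationError(f"scenario config: unbound symbol {sym!r}")

        size_dist = None
        if "size" in vol_d:
            s = vol_d["size"]
            size_dist = PowerLawSizeDistribution(
                alpha=float(s["alpha"]),
                x_min=float(s["x_min"]),
                x_max=float(s["x_max"]),
            )
        ratio_table = None
        if "ratio_table" in vol_d:
            ratio_table = {
                k: ShapeModel(k, tuple(v["wl"]), tuple(v["hl"]))
                for k, v in vol_d["ratio_table"].items()
            }
        mode = vol_d.get("mode")
        shape = None
        if "shape" in vol_d:
            table = ratio_table if ratio_table is not None else default_ratio_table()
            try:
                shape = table[vol_d["shape"]]
            except KeyError:
                raise ConfigurationError(
                    f"scenario config: shape {vol_d['shape']!r} not in ratio table"
                ) from None
        env = vol_d.get("envelope_bounds")
        if env is None and mode == "uniform_envelope":
            table = ratio_table if ratio_table is not None else default_ratio_table()
            env = envelope_bounds(table, size_dist)
        if mode == "size_conditional_envelope" and ratio_table is None:
            ratio_table = default_ratio_table()
        volume = VolumeDistribution(
            mode=mode,
            shape=shape,
            size_dist=size_dist,
            envelope_bounds=tuple(env) if env is not None else None,
            fixed_value=vol_d.get("value"),
            ratio_policy=vol_d.get("ratio_policy", "max"),
            ratio_table=ratio_table,
        )
        receptors = {
            label: ReceptorSpec(
                label=label,
                cr_w=DistributionSpec.from_dict(r["CR_w"], label=f"CR_w[{label}]"),
                ef=DistributionSpec.from_dict(r["EF"], label=f"EF[{label}]"),
                ed=float(r["ED"]),
                bw=DistributionSpec.from_dict(r["BW"], label=f"BW[{label}]"),
                at=float(r["AT"]),
            )
            for label, r in rec_d.items()
        }
        return cls(
            c_mp=DistributionSpec.from_dict(inputs["C_mp"], label="C_mp"),
            rho=DistributionSpec.from_dict(inputs["rho"], label="rho"),
            dehp_content=DistributionSpec.from_dict(inputs["R"], label="R"),
            l1=DistributionSpec.from_dict(inputs["L1"], label="L1"),
            l2=DistributionSpec.from_dict(inputs["L2"], label="L2"),
            volume=volume,
            receptors=receptors,
            toxicity=ToxicityValues(
                rfd0=float(tox_d["RfD0"]), sf0=float(tox_d["SF0"])
            ),
            density_unit=d.get("density_unit", "g/cm3"),
            n_iterations=int(d.get("n_iterations", 50_000)),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_overrides(self, n_iterations=None, seed=None) -> "ScenarioConfig":
        kw = {}
        if n_iterations is not None:
            kw["n_iterations"] = int(n_iterations)
        if seed is not None:
            kw["seed"] = int(seed)
        return replace(self, **kw) if kw else self


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class RiskResult:
    """Per-iteration draws and per-receptor dose/risk vectors.

    ``shared_inputs`` holds the draws common to all receptors (C_mp, rho,
    R, V, L1, L2, and EF when shared); ``receptor_inputs[label]`` the
    receptor-specific draws (CR_w, BW, and EF when not shared);
    ``metrics[label]`` the vectors ADD, HQ, ECR.
    """

    n_iterations: int
    seed: int
    config_hash: str
    shared_inputs: dict[str, np.ndarray]
    receptor_inputs: dict[str, dict[str, np.ndarray]]
    metrics: dict[str, dict[str, np.ndarray]]
    c_w: np.ndarray = field(default=None, repr=False)

    def receptor_labels(self) -> list[str]:
        return list(self.metrics)

    def metric(self, metric: str, receptor: str) -> np.ndarray:
        if metric not in METRICS:
            raise ValidationError(
                f"unknown metric {metric!r}; expected one of {METRICS}"
            )
        if receptor not in self.metrics:
            raise ValidationError(
                f"unknown receptor {receptor!r}; "
                f"expected one of {list(self.metrics)}"
            )
        return self.metrics[receptor][metric]

    def inputs_for(self, receptor: str) -> dict[str, np.ndarray]:
        """All input draws relevant to one receptor's outputs."""
        if receptor not in self.receptor_inputs:
            raise ValidationError(f"unknown receptor {receptor!r}")
        out = dict(self.shared_inputs)
        out.update(self.receptor_inputs[receptor])
        return out

    # -- text round trip ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for k, v in self.shared_inputs.items():
            cols[k] = v
        for label, d in self.receptor_inputs.items():
            for k, v in d.items():
                cols[f"{label}.{k}"] = v
        for label, d in self.metrics.items():
            for k, v in d.items():
                cols[f"{label}.{k}"] = v
        if self.c_w is not None:
            cols["C_w"] = self.c_w
        return pd.DataFrame(cols)

    def save(self, directory) -> None:
        """Write draws.csv plus meta.json into ``directory``."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(d / "draws.csv", index=False)
        meta = {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "shared_inputs": list(self.shared_inputs),
            "receptors": {
                label: list(di) for label, di in self.receptor_inputs.items()
            },
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, directory) -> "RiskResult":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text(encoding="utf-8"))
        df = pd.read_csv(d / "draws.csv")
        shared = {k: df[k].to_numpy() for k in meta["shared_inputs"]}
        rec_in = {
            label: {k: df[f"{label}.{k}"].to_numpy() for k in keys}
            for label, keys in meta["receptors"].items()
        }
        metrics = {
            label: {
                m: df[f"{label}.{m}"].to_numpy()
                for m in METRICS
                if f"{label}.{m}" in df
            }
            for label in meta["receptors"]
        }
        return cls(
            n_iterations=int(meta["n_iterations"]),
            seed=int(meta["seed"]),
            config_hash=meta["config_hash"],
            shared_inputs=shared,
            receptor_inputs=rec_in,
            metrics=metrics,
            c_w=df["C_w"].to_numpy() if "C_w" in df else None,
        )


@dataclass
class SensitivityReport:
    """Contribution-to-variance decomposition of one output metric.

    ``spearman`` maps each varying input to its rank correlation with the
    metric; ``contribution_pct`` to ``100·r²/Σr²`` signed by r.  Constant
    inputs appear with 0.  Absolute contributions sum to 100.
    """

    receptor: str
    metric: str
    spearman: dict[str, float]
    contribution_pct: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "input": k,
                "spearman_r": self.spearman[k],
                "contribution_pct": self.contribution_pct[k],
            }
            for k in self.contribution_pct
        ]
        df = pd.DataFrame(rows)
        return df.reindex(
            df["contribution_pct"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def run_simulation(config: ScenarioConfig) -> RiskResult:
    """Run the Monte Carlo risk simulation described by ``config``.

    All inputs are drawn independently from a single seeded generator in a
    fixed order, so results are bit-reproducible for a given config.
    """
    n = config.n_iterations
    rng = np.random.default_rng(config.seed)
    logger.info(
        "running %d iterations (seed=%d, volume mode=%s, density unit=%s)",
        n,
        config.seed,
        config.volume.mode,
        config.density_unit,
    )

    shared: dict[str, np.ndarray] = {}
    shared["C_mp"] = sample(config.c_mp, n, rng=rng)
    shared["rho"] = sample(config.rho, n, rng=rng)
    shared["R"] = sample(config.dehp_content, n, rng=rng)
    shared["V"] = sample_volumes(config.volume, n, rng=rng)
    shared["L1"] = sample(config.l1, n, rng=rng)
    shared["L2"] = sample(config.l2, n, rng=rng)

    # EF is shared across receptors when every receptor uses the same spec
    # (common random numbers); otherwise it is drawn per receptor.
    ef_specs = [r.ef for r in config.receptors.values()]
    ef_shared = all(
        s.family == ef_specs[0].family and s.parameters == ef_specs[0].parameters
        for s in ef_specs[1:]
    )
    if ef_shared:
        shared["EF"] = sample(ef_specs[0], n, rng=rng)

    rho_g_cm3 = shared["rho"] / (1e3 if config.density_unit == "mg/cm3" else 1.0)
    c_w, _, _ = exposure_concentration(
        ExposureParams(
            c_mp=shared["C_mp"],
            rho=rho_g_cm3,
            volume_um3=shared["V"],
            content=shared["R"],
            l1=shared["L1"],
            l2=shared["L2"],
        )
    )

    receptor_inputs: dict[str, dict[str, np.ndarray]] = {}
    metrics: dict[str, dict[str, np.ndarray]] = {}
    for label, spec in config.receptors.items():
        own: dict[str, np.ndarray] = {}
        own["CR_w"] = sample(spec.cr_w, n, rng=rng)
        if not ef_shared:
            own["EF"] = sample(spec.ef, n, rng=rng)
        own["BW"] = sample(spec.bw, n, rng=rng)
        params = ReceptorParams(
            label=label,
            cr_w=own["CR_w"],
            ef=shared["EF"] if ef_shared else own["EF"],
            ed=spec.ed,
            bw=own["BW"],
            at=spec.at,
        )
        add = average_daily_dose(c_w, params)
        metrics[label] = {
            "ADD": add,
            "HQ": hazard_quotient(add, config.toxicity),
            "ECR": excess_cancer_risk(add, config.toxicity),
        }
        receptor_inputs[label] = own

    return RiskResult(
        n_iterations=n,
        seed=config.seed,
        config_hash=config.config_hash(),
        shared_inputs=shared,
        receptor_inputs=receptor_inputs,
        metrics=metrics,
        c_w=np.asarray(c_w),
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def percentile(result: RiskResult, metric: str, receptor: str, q: float) -> float:
    """Linear-interpolation quantile of a metric vector; ``q`` in [0, 1]."""
    if not 0 <= q <= 1:
        raise ValidationError("percentile: 'q' must lie in [0, 1]")
    return float(np.quantile(result.metric(metric, receptor), q))


def exceedance_probability(
    result: RiskResult, metric: str, receptor: str, threshold: float
) -> float:
    """Fraction of iterations with metric strictly above ``threshold``."""
    return float(np.mean(result.metric(metric, receptor) > threshold))


def sensitivity_analysis(
    result: RiskResult, receptor: str, metric: str = "ECR"
) -> SensitivityReport:
    """Contribution-to-variance sensitivity of ``metric`` for one receptor.

    Each varying input's Spearman rank correlation r with the metric is
    normalized as ``100·r²/Σr²`` and signed by r; inputs with zero
    variance are reported with 0 contribution.
    """
    y = result.metric(metric, receptor)
    inputs = result.inputs_for(receptor)
    varying = {k: v for k, v in inputs.items() if np.ptp(v) > 0}
    if not varying:
        raise ValidationError(
            "sensitivity_analysis: no varying inputs with nonzero variance"
        )
    spearman: dict[str, float] = {}
    for k, v in inputs.items():
        if k in varying and np.ptp(y) > 0:
            r = float(_sps.spearmanr(v, y).statistic)
        else:
            r = 0.0
        spearman[k] = r
    total = sum(r * r for r in spearman.values())
    contribution = {
        k: (100.0 * r * r / total * (1.0 if r >= 0 else -1.0)) if total > 0 else 0.0
        for k, r in spearman.items()
    }
    return SensitivityReport(
        receptor=receptor,
        metric=metric,
        spearman=spearman,
        contribution_pct=contribution,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

DEFAULT_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)
DEFAULT_ECR_THRESHOLDS = (1e-6, 1e-4)
DEFAULT_HQ_THRESHOLDS = (1.0,)


def write_report(
    result: RiskResult,
    directory,
    config: Optional[ScenarioConfig] = None,
    quantiles=DEFAULT_QUANTILES,
    ecr_thresholds=DEFAULT_ECR_THRESHOLDS,
    hq_thresholds=DEFAULT_HQ_THRESHOLDS,
) -> dict[str, Path]:
    """Write summary CSVs plus run metadata into ``directory``.

    Files: ``percentiles.csv`` (metric, receptor, one column per
    quantile), ``exceedance.csv`` (metric, receptor, threshold,
    probability), ``sensitivity.csv`` (receptor, input, spearman_r,
    contribution_pct for ECR), and ``run_metadata.json`` (config echo,
    seed, iteration count).  Output is deterministic: two runs with the
    same config produce byte-identical files.
    """
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create report directory {d}: {e}") from e

    paths: dict[str, Path] = {}

    rows = []
    for receptor in result.receptor_labels():
        for metric in ("ECR", "HQ", "ADD"):
            row = {"metric": metric, "receptor": receptor}
            vec = result.metric(metric, receptor)
            for q in quantiles:
                row[f"q{q * 100:g}"] = float(np.quantile(vec, q))
            row["mean"] = float(vec.mean())
            rows.append(row)
    paths["percentiles"] = d / "percentiles.csv"
    pd.DataFrame(rows).to_csv(paths["percentiles"], index=False)

    rows = []
    for receptor in result.receptor_labels():
        for metric, thresholds in (("ECR", ecr_thresholds), ("HQ", hq_thresholds)):
            for t in thresholds:
                rows.append(
                    {
                        "metric": metric,
                        "receptor": receptor,
                        "threshold": t,
                        "probability": exceedance_probability(
                            result, metric, receptor, t
                        ),
                    }
                )
    paths["exceedance"] = d / "exceedance.csv"
    pd.DataFrame(rows).to_csv(paths["exceedance"], index=False)

    frames = []
    for receptor in result.receptor_labels():
        try:
            rep = sensitivity_analysis(result, receptor, metric="ECR")
        except ValidationError:  # fully deterministic scenario
            continue
        f = rep.to_frame()
        f.insert(0, "receptor", receptor)
        frames.append(f)
    paths["sensitivity"] = d / "sensitivity.csv"
    if frames:
        sens_df = pd.concat(frames, ignore_index=True)
    else:
        sens_df = pd.DataFrame(
            columns=["receptor", "input", "spearman_r", "contribution_pct"]
        )
    sens_df.to_csv(paths["sensitivity"], index=False)

    meta = {
        "n_iterations": result.n_iterations,
        "seed": result.seed,
        "config_hash": result.config_hash,
    }
    if config is not None:
        meta["config"] = config.to_dict()
    paths["metadata"] = d / "run_metadata.json"
    paths["metadata"].write_text(
        json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8"
    )
    logger.info("report written to %s", d)
    return paths
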