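import numpy as np
import pytest

from mprisk import (
    DistributionSpec,
    PowerLawSizeDistribution,
    ScenarioConfig,
    ToxicityValues,
    VolumeDistribution,
    default_ratio_table,
)
from mprisk.simulation import ReceptorSpec


@pytest.fixture(scope="session")
def ratio_table():
    return default_ratio_table()


@pytest.fixture(scope="session")
def size_dist():
    """The aggregate 20-5000 μm size spectrum used throughout."""
    return PowerLawSizeDistribution(alpha=1.74, x_min=20.0, x_max=5000.0)


def point(value, label=""):
    return DistributionSpec("point", {"value": float(value)}, label=label)


def point_receptor(label="adult", cr_w=1.95, ef=345.0, ed=25.0, bw=70.0, at=9125.0):
    return ReceptorSpec(
        label=label,
        cr_w=point(cr_w, "CR_w"),
        ef=point(ef, "EF"),
        ed=ed,
        bw=point(bw, "BW"),
        at=at,
    )


def point_scenario(
    c_mp=10.0,
    rho=1.38,
    content=0.3,
    l1=0.0,
    l2=0.0025,
    volume=1e6,
    n_iterations=10,
    seed=0,
    density_unit="g/cm3",
    receptors=None,
):
    """Scenario with every symbol at a point value; used as a deterministic
    composition oracle for the Monte Carlo engine."""
    if receptors is None:
        receptors = {"adult": point_receptor()}
    return ScenarioConfig(
        c_mp=point(c_mp, "C_mp"),
        rho=point(rho, "rho"),
        dehp_content=point(content, "R"),
        l1=point(l1, "L1"),
        l2=point(l2, "L2"),
        volume=VolumeDistribution(mode="fixed", fixed_value=volume),
        receptors=receptors,
        toxicity=ToxicityValues(rfd0=0.02, sf0=0.014),
        density_unit=density_unit,
        n_iterations=n_iterations,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
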