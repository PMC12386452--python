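import numpy as np
import pytest
from dataclasses import replace

from redoxsim import (
    EnzymePools,
    ModelSpec,
    PathwayMask,
    RateConstants,
    default_spec,
)
from redoxsim.steady import pathway_capacities


@pytest.fixture
def spec() -> ModelSpec:
    return default_spec()


def random_spec(rng: np.random.Generator) -> ModelSpec:
    """Random parameterization: default pools/rates scaled by log-uniform
    factors in [0.2, 5], a random mask with at least one active pathway,
    and an influx strictly below the scavenging capacity."""
    lu = lambda: float(np.exp(rng.uniform(np.log(0.2), np.log(5.0))))
    rates = RateConstants(
        kCAT=0.034 * lu(), kPRDX=0.26 * lu(), kTXN=0.23 * lu(),
        kTXNRD=0.31 * lu(), kGSR=0.08 * lu(), kGPX=67.0 * lu(),
    )
    pools = EnzymePools(
        CAT=0.001 * lu(), GPX=0.05 * lu(), GSR=0.05 * lu(), TXNRD=0.025 * lu(),
        PRDX_total=0.15 * lu(), TXN_total=0.025 * lu(), GSH_total=3.0 * lu(),
    )
    while True:
        mask = PathwayMask(*(bool(b) for b in rng.integers(0, 2, size=3)))
        if mask.prdx_txn_active or mask.cat_active or mask.gpx_gsh_active:
            break
    base = ModelSpec(rates=rates, pools=pools, mask=mask, h2o2_influx=0.0)
    cap_cat, cap_gpx, cap_prdx = pathway_capacities(base)
    if cap_cat == float("inf"):
        influx = float(10.0 ** rng.uniform(-6, -4))
    else:
        influx = float(rng.uniform(0.05, 0.5)) * (cap_gpx + cap_prdx)
    return replace(base, h2o2_influx=influx)
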