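"""Network kinetics: defaults, derivatives, masking, integration."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redoxsim import (
    EnzymePools,
    ModelSpec,
    PathwayMask,
    RateConstants,
    RedoxState,
    default_spec,
    derivatives,
    simulate,
    spec_from_config,
)
from redoxsim.model import reduced_state

ALL_OFF = PathwayMask(False, False, False)


def literal_rhs(s: RedoxState, spec: ModelSpec) -> dict:
    """Independent transcription of the seven published rate equations,
    term by term, with the pathway masks applied to each pathway's terms."""
    r, p, m = spec.rates, spec.pools, spec.mask
    cat = 1.0 if m.cat_active else 0.0
    gpx = 1.0 if m.gpx_gsh_active else 0.0
    prdx = 1.0 if m.prdx_txn_active else 0.0
    return {
        "H2O2": spec.h2o2_influx
        - cat * r.kCAT * s.H2O2 * p.CAT
        - gpx * r.kGPX * s.H2O2 * s.GSH * p.GPX
        - prdx * r.kPRDX * s.H2O2 * s.PRDX_red,
        "GSH": gpx * (-r.kGPX * s.H2O2 * s.GSH * p.GPX + r.kGSR * s.GSSG * p.GSR),
        "GSSG": gpx * (r.kGPX * s.H2O2 * s.GSH * p.GPX - r.kGSR * s.GSSG * p.GSR),
        "PRDX_red": prdx * (-r.kPRDX * s.H2O2 * s.PRDX_red + r.kTXN * s.TXN_red * s.PRDX_ox),
        "PRDX_ox": prdx * (r.kPRDX * s.H2O2 * s.PRDX_red - r.kTXN * s.TXN_red * s.PRDX_ox),
        "TXN_red": prdx * (-r.kTXN * s.TXN_red * s.PRDX_ox + r.kTXNRD * s.TXN_ox * p.TXNRD),
        "TXN_ox": prdx * (r.kTXN * s.TXN_red * s.PRDX_ox - r.kTXNRD * s.TXN_ox * p.TXNRD),
    }


class TestDefaults:
    def test_published_parameter_set(self):
        s = default_spec()
        assert s.rates == RateConstants(0.034, 0.26, 0.23, 0.31, 0.08, 67.0)
        assert s.pools.GSH_total == 3.0
        assert s.pools == EnzymePools(0.001, 0.05, 0.05, 0.025, 0.15, 0.025, 3.0)
        assert s.mask == PathwayMask(True, True, True)
        assert s.h2o2_influx == 1e-5

    @pytest.mark.parametrize("field,value", [("kCAT", 0.0), ("kGPX", -1.0), ("kTXN", math.nan)])
    def test_rate_constants_must_be_positive_finite(self, field, value):
        with pytest.raises(ValueError, match=field):
            RateConstants(**{field: value})

    def test_pools_reject_negative(self):
        with pytest.raises(ValueError, match="GSH_total"):
            EnzymePools(GSH_total=-1.0)


class TestConfig:
    def test_flat_key_overrides(self):
        s = spec_from_config({"kGPX": 50.0, "GSH": 1.5, "H2O2_IN": 2e-5})
        assert s.rates.kGPX == 50.0
        assert s.pools.GSH_total == 1.5
        assert s.h2o2_influx == 2e-5
        # untouched keys keep defaults
        assert s.rates.kCAT == 0.034 and s.pools.CAT == 0.001

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError, match="kFOO"):
            spec_from_config({"kFOO": 1.0})


class TestDerivatives:
    def test_quiet_reduced_state_only_gains_influx(self, spec):
        d = derivatives(reduced_state(spec.pools), spec)
        assert d.H2O2 == spec.h2o2_influx == 1e-5
        for f in ("GSH", "GSSG", "PRDX_red", "PRDX_ox", "TXN_red", "TXN_ox"):
            assert getattr(d, f) == 0.0

    def test_gssg_production_rate_hand_value(self, spec):
        # kGPX * H2O2 * GSH * GPX = 67 * 0.1 * 3.0 * 0.05 = 1.005 mM/ms
        s = RedoxState(0.1, 3.0, 0.0, 0.15, 0.0, 0.025, 0.0)
        d = derivatives(s, spec)
        assert d.GSSG == pytest.approx(1.005, rel=1e-12)
        assert d.GSH == pytest.approx(-1.005, rel=1e-12)

    def test_all_pathways_masked_leaves_only_influx(self, spec):
        s = RedoxState(0.7, 1.0, 2.0, 0.1, 0.05, 0.01, 0.015)
        d = derivatives(s, replace(spec, mask=ALL_OFF))
        assert d.H2O2 == spec.h2o2_influx
        assert all(
            getattr(d, f) == 0.0
            for f in ("GSH", "GSSG", "PRDX_red", "PRDX_ox", "TXN_red", "TXN_ox")
        )

    def test_negative_concentration_names_offender(self, spec):
        s = RedoxState(0.1, -0.5, 0.0, 0.15, 0.0, 0.025, 0.0)
        with pytest.raises(ValueError, match="GSH"):
            derivatives(s, spec)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_matches_literal_equation_transcription(self, data):
        """Property: derivatives equals an independently coded transcription
        of the published equations on random states, specs and masks, and
        each couple's reduced+oxidized derivatives sum to exactly zero."""
        conc = st.floats(0.0, 10.0, allow_nan=False)
        s = RedoxState(*(data.draw(conc) for _ in range(7)))
        factor = st.floats(0.1, 10.0)
        spec = ModelSpec(
            rates=RateConstants(
                kCAT=0.034 * data.draw(factor), kPRDX=0.26 * data.draw(factor),
                kTXN=0.23 * data.draw(factor), kTXNRD=0.31 * data.draw(factor),
                kGSR=0.08 * data.draw(factor), kGPX=67.0 * data.draw(factor),
            ),
            pools=EnzymePools(),
            mask=PathwayMask(*(data.draw(st.booleans()) for _ in range(3))),
            h2o2_influx=data.draw(st.floats(0.0, 1e-3)),
        )
        d = derivatives(s, spec)
        oracle = literal_rhs(s, spec)
        for f, expected in oracle.items():
            assert getattr(d, f) == pytest.approx(expected, rel=1e-12, abs=1e-300)
        assert d.GSH + d.GSSG == 0.0
        assert d.PRDX_red + d.PRDX_ox == 0.0
        assert d.TXN_red + d.TXN_ox == 0.0


class TestSimulate:
    def test_glutathione_conservation_over_long_run(self, spec):
        traj = simulate(spec, t_end=1e6, n_output=50)
        gsh = traj.values[:, 1] + traj.values[:, 2]
        assert np.all(np.abs(gsh - 3.0) <= 1e-9 * 3.0)
        prdx = traj.values[:, 3] + traj.values[:, 4]
        txn = traj.values[:, 5] + traj.values[:, 6]
        assert np.all(np.abs(prdx - 0.15) <= 1e-9 * 0.15)
        assert np.all(np.abs(txn - 0.025) <= 1e-9 * 0.025)
        assert traj.values.min() >= 0.0  # clamped output

    def test_zero_influx_reduced_state_is_fixed_point(self, spec):
        quiet = replace(spec, h2o2_influx=0.0)
        traj = simulate(quiet, t_end=1e4, n_output=20)
        assert np.all(traj.values == traj.values[0])
        assert traj.values[0, 0] == 0.0

    def test_cat_only_reaches_closed_form_steady_level(self, spec):
        cat_only = replace(spec, mask=PathwayMask(False, True, False))
        traj = simulate(cat_only, t_end=1e6, n_output=20)
        # influx/(kCAT*CAT) = 1e-5 / 3.4e-5
        assert traj.final_state.H2O2 == pytest.approx(1e-5 / 3.4e-5, rel=1e-4)

    def test_inactive_couple_frozen_at_init(self, spec):
        no_gpx = replace(spec, mask=PathwayMask(True, True, False))
        traj = simulate(no_gpx, t_end=1e5, n_output=20)
        assert np.all(traj.values[:, 1] == 3.0)  # GSH untouched
        assert np.all(traj.values[:, 2] == 0.0)  # GSSG untouched

    def test_linear_limit_matches_scalar_closed_form(self):
        """With a huge glutathione pool the couple never depletes and H2O2
        follows the scalar linear ODE dH/dt = influx - k_tot * H."""
        pools = EnzymePools(GSH_total=3000.0)
        spec = ModelSpec(pools=pools)
        r = spec.rates
        k_tot = r.kCAT * pools.CAT + r.kGPX * pools.GPX * pools.GSH_total + r.kPRDX * pools.PRDX_total
        t_end = 8.0 / k_tot
        traj = simulate(spec, t_end=t_end, n_output=40, rtol=1e-10, atol=1e-16)
        expected = spec.h2o2_influx / k_tot * (1.0 - np.exp(-k_tot * traj.times[1:]))
        assert np.allclose(traj.values[1:, 0], expected, rtol=1e-4, atol=0.0)

    def test_init_violating_conservation_rejected(self, spec):
        bad = RedoxState(0.0, 2.0, 0.5, 0.15, 0.0, 0.025, 0.0)  # GSH+GSSG != 3.0
        with pytest.raises(ValueError, match="conservation"):
            simulate(spec, t_end=10.0, init=bad)

    def test_trajectory_csv_round_trip(self, spec, tmp_path):
        import pandas as pd

        traj = simulate(spec, t_end=100.0, n_output=10)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "time_ms", "H2O2", "GSH", "GSSG", "PRDX_red", "PRDX_ox", "TXN_red", "TXN_ox",
        ]
        assert len(df) == 10
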