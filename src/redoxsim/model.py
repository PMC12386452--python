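"""Mass-action kinetics of cellular H2O2 neutralization.

The network couples a constant H2O2 influx (e.g. mitochondrial leakage) to
three removal pathways:

* catalase (CAT), a direct decomposer, first order in H2O2 and in CAT;
* peroxiredoxin (PRDX), oxidized while reducing H2O2 and re-reduced by
  thioredoxin (TXN), itself recycled by thioredoxin reductase (TXNRD);
* glutathione peroxidase (GPX), consuming reduced glutathione (GSH) to
  GSSG, recycled by glutathione reductase (GSR).

Three conserved redox couples (GSH/GSSG, PRDX/PRDX_ox, TXN/TXN_ox) carry
the recycling dynamics; the enzymes CAT, GPX, GSR and TXNRD are treated as
constant pools.  Units are mM and ms throughout: second-order rate
constants in mM^-1 ms^-1, the trimolecular GPX constant in mM^-2 ms^-1,
the influx in mM ms^-1.

Each pathway carries an on/off mask so loss-of-function ("knockout")
variants can be simulated: an inactive pathway contributes neither to H2O2
removal nor to its couple's turnover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "EnzymePools",
    "PathwayMask",
    "ModelSpec",
    "RedoxState",
    "Trajectory",
    "default_spec",
    "spec_from_config",
    "reduced_state",
    "derivatives",
    "simulate",
    "IntegrationError",
    "CONFIG_KEYS",
]

#: relative tolerance for the conservation check on initial states
_CONSERVATION_RTOL = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails to advance."""


def _check_positive(obj, allow_zero: bool = False) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite, got {v!r}")
        if v < 0 or (v == 0 and not allow_zero):
            kind = "non-negative" if allow_zero else "strictly positive"
            raise ValueError(f"{type(obj).__name__}.{f.name} must be {kind}, got {v!r}")


@dataclass(frozen=True)
class RateConstants:
    """Second-order rate constants (GPX: third-order), per-mM per-ms."""

    kCAT: float = 0.034
    kPRDX: float = 0.26
    kTXN: float = 0.23
    kTXNRD: float = 0.31
    kGSR: float = 0.08
    kGPX: float = 67.0  # mM^-2 ms^-1 (trimolecular: H2O2 * GSH * GPX)

    def __post_init__(self) -> None:
        _check_positive(self)


@dataclass(frozen=True)
class EnzymePools:
    """Constant enzyme concentrations and conserved couple totals, mM.

    ``PRDX_total``, ``TXN_total`` and ``GSH_total`` are the conserved sums
    of the reduced and oxidized forms of each couple.
    """

    CAT: float = 0.001
    GPX: float = 0.05
    GSR: float = 0.05
    TXNRD: float = 0.025
    PRDX_total: float = 0.15
    TXN_total: float = 0.025
    GSH_total: float = 3.0

    def __post_init__(self) -> None:
        _check_positive(self, allow_zero=True)


@dataclass(frozen=True)
class PathwayMask:
    """Which neutralization systems are operational."""

    prdx_txn_active: bool = True
    cat_active: bool = True
    gpx_gsh_active: bool = True


@dataclass(frozen=True)
class ModelSpec:
    """Fully parameterized model for one cell line."""

    rates: RateConstants = field(default_factory=RateConstants)
    pools: EnzymePools = field(default_factory=EnzymePools)
    mask: PathwayMask = field(default_factory=PathwayMask)
    h2o2_influx: float = 1e-5  # mM ms^-1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h2o2_influx) and self.h2o2_influx >= 0):
            raise ValueError(f"h2o2_influx must be >= 0, got {self.h2o2_influx!r}")


@dataclass(frozen=True)
class RedoxState:
    """Concentrations (mM) of H2O2 and the three redox couples.

    Also used for the time-derivative of a state, whose fields may be
    negative; non-negativity is checked where it is a precondition, not at
    construction.
    """

    H2O2: float
    GSH: float
    GSSG: float
    PRDX_red: float
    PRDX_ox: float
    TXN_red: float
    TXN_ox: float

    def check_nonnegative(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(
                    f"negative concentration: RedoxState.{f.name} = {getattr(self, f.name)!r} mM"
                )

    def check_conservation(self, pools: EnzymePools, rtol: float = _CONSERVATION_RTOL) -> None:
        for total, a, b in (
            (pools.GSH_total, self.GSH, self.GSSG),
            (pools.PRDX_total, self.PRDX_red, self.PRDX_ox),
            (pools.TXN_total, self.TXN_red, self.TXN_ox),
        ):
            if abs((a + b) - total) > rtol * max(total, 1e-12):
                raise ValueError(
                    f"state violates conservation: {a} + {b} != total {total} mM"
                )


def reduced_state(pools: EnzymePools, h2o2: float = 0.0) -> RedoxState:
    """Fully reduced (pre-stress) state: all couples in reduced form."""
    return RedoxState(
        H2O2=h2o2,
        GSH=pools.GSH_total,
        GSSG=0.0,
        PRDX_red=pools.PRDX_total,
        PRDX_ox=0.0,
        TXN_red=pools.TXN_total,
        TXN_ox=0.0,
    )


def default_spec() -> ModelSpec:
    """The reference parameterization: literature rate constants and pools,
    all three pathways active, influx 1e-5 mM/ms."""
    return ModelSpec()


def derivatives(state: RedoxState, spec: ModelSpec) -> RedoxState:
    """Time-derivative (mM/ms per field) of the full seven-species state.

    An inactive pathway contributes zero both to H2O2 removal and to its
    couple's turnover, so the couple is frozen at its current composition.
    The reduced+oxidized derivative of each couple sums to exactly zero.
    """
    state.check_nonnegative()
    r, p, m = spec.rates, spec.pools, spec.mask

    v_cat = r.kCAT * state.H2O2 * p.CAT if m.cat_active else 0.0
    v_gpx = r.kGPX * state.H2O2 * state.GSH * p.GPX if m.gpx_gsh_active else 0.0
    v_gsr = r.kGSR * state.GSSG * p.GSR if m.gpx_gsh_active else 0.0
    v_prdx = r.kPRDX * state.H2O2 * state.PRDX_red if m.prdx_txn_active else 0.0
    v_txn = r.kTXN * state.TXN_red * state.PRDX_ox if m.prdx_txn_active else 0.0
    v_txnrd = r.kTXNRD * state.TXN_ox * p.TXNRD if m.prdx_txn_active else 0.0

    return RedoxState(
        H2O2=spec.h2o2_influx - v_cat - v_gpx - v_prdx,
        GSH=-v_gpx + v_gsr,
        GSSG=v_gpx - v_gsr,
        PRDX_red=-v_prdx + v_txn,
        PRDX_ox=v_prdx - v_txn,
        TXN_red=-v_txn + v_txnrd,
        TXN_ox=v_txn - v_txnrd,
    )


# -- trajectory container -------------------------------------------------

_STATE_COLUMNS = ("H2O2", "GSH", "GSSG", "PRDX_red", "PRDX_ox", "TXN_red", "TXN_ox")


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution of the network ODE.

    ``times`` is strictly increasing (ms); ``values`` is an
    ``(n_samples, 7)`` array with columns ``H2O2, GSH, GSSG, PRDX_red,
    PRDX_ox, TXN_red, TXN_ox`` in mM.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.values.shape != (self.times.size, len(_STATE_COLUMNS)):
            raise ValueError("trajectory values shape mismatch")

    def state_at(self, i: int) -> RedoxState:
        return RedoxState(*self.values[i])

    @property
    def final_state(self) -> RedoxState:
        return self.state_at(-1)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(_STATE_COLUMNS))
        df.insert(0, "time_ms", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _reduced_rhs(spec: ModelSpec):
    """RHS over the 4 free variables (H2O2, GSSG, PRDX_ox, TXN_ox);
    reduced forms recovered from the conserved totals, which makes the
    conservation laws exact by construction."""
    r, p, m = spec.rates, spec.pools, spec.mask
    influx = spec.h2o2_influx
    prdx_on, cat_on, gpx_on = m.prdx_txn_active, m.cat_active, m.gpx_gsh_active

    def rhs(t, y):
        H, GSSG, Pox, Tox = y
        GSH = p.GSH_total - GSSG
        P = p.PRDX_total - Pox
        T = p.TXN_total - Tox
        v_cat = r.kCAT * H * p.CAT if cat_on else 0.0
        v_gpx = r.kGPX * H * GSH * p.GPX if gpx_on else 0.0
        v_gsr = r.kGSR * GSSG * p.GSR if gpx_on else 0.0
        v_prdx = r.kPRDX * H * P if prdx_on else 0.0
        v_txn = r.kTXN * T * Pox if prdx_on else 0.0
        v_txnrd = r.kTXNRD * Tox * p.TXNRD if prdx_on else 0.0
        return (
            influx - v_cat - v_gpx - v_prdx,
            v_gpx - v_gsr,
            v_prdx - v_txn,
            v_txn - v_txnrd,
        )

    return rhs


def _expand(y: np.ndarray, pools: EnzymePools) -> np.ndarray:
    """Map (n, 4) reduced solution to (n, 7) full state, clamping the tiny
    negative excursions the integrator may produce (never below -1e-12)."""
    H, GSSG, Pox, Tox = y.T
    full = np.column_stack(
        [
            H,
            pools.GSH_total - GSSG,
            GSSG,
            pools.PRDX_total - Pox,
            Pox,
            pools.TXN_total - Tox,
            Tox,
        ]
    )
    if full.min() < -1e-12:
        bad = _STATE_COLUMNS[int(np.argmin(full.min(axis=0)))]
        raise IntegrationError(
            f"integrator produced {bad} = {full.min():.3e} mM < -1e-12"
        )
    return np.maximum(full, 0.0)


def simulate(
    spec: ModelSpec,
    t_end: float,
    init: RedoxState | None = None,
    n_output: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the network on [0, t_end] ms with a stiff-capable solver.

    Parameters
    ----------
    spec : ModelSpec
        Parameterization, including the pathway mask and influx.
    t_end : float
        Integration horizon in ms; must be positive.
    init : RedoxState, optional
        Initial state; defaults to the fully reduced state with zero H2O2.
        Must satisfy the couple conservation laws of ``spec.pools`` to
        within 1e-9 relative.
    n_output : int
        Number of equally spaced output samples (including t=0).

    Notes
    -----
    The integrator works on the 4 free variables (H2O2, GSSG, PRDX_ox,
    TXN_ox); reduced forms are recovered from totals, so the conservation
    sums hold to machine precision at every sample.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if init is None:
        init = reduced_state(spec.pools)
    init.check_nonnegative()
    init.check_conservation(spec.pools)

    y0 = [init.H2O2, init.GSSG, init.PRDX_ox, init.TXN_ox]
    t_eval = np.linspace(0.0, t_end, max(int(n_output), 2))
    sol = solve_ivp(
        _reduced_rhs(spec),
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(f"integration failed near t = {t_fail:g} ms: {sol.message}")
    return Trajectory(times=sol.t, values=_expand(sol.y.T, spec.pools))


# -- flat-key configuration ----------------------------------------------

#: flat config keys (matching the published symbol table) -> (group, field)
CONFIG_KEYS = {
    "kCAT": ("rates", "kCAT"),
    "kPRDX": ("rates", "kPRDX"),
    "kTXN": ("rates", "kTXN"),
    "kTXNRD": ("rates", "kTXNRD"),
    "kGSR": ("rates", "kGSR"),
    "kGPX": ("rates", "kGPX"),
    "CAT": ("pools", "CAT"),
    "PRDX": ("pools", "PRDX_total"),
    "TXN": ("pools", "TXN_total"),
    "TXNRD": ("pools", "TXNRD"),
    "GSH": ("pools", "GSH_total"),
    "GPX": ("pools", "GPX"),
    "GSR": ("pools", "GSR"),
    "H2O2_IN": ("influx", None),
}


def spec_from_config(config: dict | None, mask: PathwayMask | None = None) -> ModelSpec:
    """Build a ModelSpec from a flat key/value mapping.

    Keys follow the published symbol table (kCAT, ..., kGPX for rate
    constants; CAT, PRDX, TXN, TXNRD, GSH, GPX, GSR for concentrations;
    H2O2_IN for the influx).  Omitted keys keep their defaults; unknown
    keys are rejected.
    """
    config = dict(config or {})
    rate_kw: dict[str, float] = {}
    pool_kw: dict[str, float] = {}
    influx = ModelSpec.__dataclass_fields__["h2o2_influx"].default
    for key, value in config.items():
        if key not in CONFIG_KEYS:
            raise KeyError(f"unknown parameter key: {key!r}")
        group, attr = CONFIG_KEYS[key]
        if group == "rates":
            rate_kw[attr] = float(value)
        elif group == "pools":
            pool_kw[attr] = float(value)
        else:
            influx = float(value)
    return ModelSpec(
        rates=RateConstants(**rate_kw),
        pools=EnzymePools(**pool_kw),
        mask=mask if mask is not None else PathwayMask(),
        h2o2_influx=influx,
    )
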