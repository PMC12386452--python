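"""Steady-state H2O2 extraction: numeric relaxation and analytic flux balance.

The per-cell-line readout of the pipeline is the steady-state H2O2
concentration under a constant influx.  Two independent routes compute it:

``find_steady_numeric``
    integrates the network until every concentration derivative has
    relaxed below a relative threshold;

``find_steady_analytic``
    solves the scalar flux-balance residual

        R(H) = influx - [cat] kCAT CAT H - [gpx] kGPX GPX H GSH*(H)
                      - [prdx] kPRDX H PRDX*(H) = 0

    where GSH*(H) and PRDX*(H) are the quasi-equilibrium compositions of
    the recycling couples at a fixed H2O2 level H.  At steady state the
    GSH couple balances its oxidation and reduction legs, giving

        GSH*(H) = kGSR GSR GSH_total / (kGPX GPX H + kGSR GSR),

    and eliminating TXN from the PRDX/TXN equilibria leaves a quadratic in
    the reduced-PRDX concentration whose physical root lies in
    [0, PRDX_total].  R is strictly decreasing in H, so the root is unique
    and safely bracketed.

The recycling legs impose hard capacities as H grows: the GPX/GSH flux
saturates at kGSR*GSR*GSH_total, and the PRDX/TXN flux at the series
combination of its TXN->PRDX transfer and TXNRD recycling legs,
kTXN*kTXNRD*TXNRD*TXN_total*PRDX_total / (kTXN*PRDX_total + kTXNRD*TXNRD).
With catalase inactive, an influx at or above the summed active
capacities admits no steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import (
    IntegrationError,
    ModelSpec,
    RedoxState,
    Trajectory,
    derivatives,
    reduced_state,
    simulate,
)

__all__ = [
    "SteadyStateResult",
    "NoSteadyStateError",
    "find_steady_numeric",
    "find_steady_analytic",
    "pathway_capacities",
]

#: floor (mM) used when normalizing derivatives of near-zero concentrations
_DERIV_FLOOR = 1e-12


class NoSteadyStateError(RuntimeError):
    """Influx exceeds the scavenging capacity of the active pathways."""


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady-state H2O2 and the per-pathway removal fluxes.

    ``h2o2_ss`` is in mM (reported downstream in arbitrary units, since
    expression ratios proxy protein amounts); fluxes in mM/ms.  At a
    converged steady state the three fluxes sum to the influx; inactive
    pathways carry exactly zero flux.
    """

    h2o2_ss: float
    flux_cat: float
    flux_gpx: float
    flux_prdx: float
    converged: bool
    t_reached: float  # ms (NaN for the analytic route)
    method: str  # "numeric" | "analytic"


def pathway_capacities(spec: ModelSpec) -> tuple[float, float, float]:
    """Maximum sustainable removal flux (mM/ms) of (cat, gpx, prdx).

    Catalase is unsaturable in this model (capacity inf when active with a
    positive pool).  The GPX/GSH flux is capped by the GSR recycling leg;
    the PRDX/TXN flux by the series combination of the TXN transfer and
    TXNRD recycling legs (as H -> inf, PRDX is fully oxidized and the
    couple equilibria give flux = c*PT*b*TT/(c*PT + b) with b =
    kTXNRD*TXNRD, c = kTXN).  A pathway with any essential factor at zero
    has capacity 0.
    """
    r, p, m = spec.rates, spec.pools, spec.mask
    cap_cat = math.inf if (m.cat_active and r.kCAT * p.CAT > 0) else 0.0
    cap_gpx = (
        r.kGSR * p.GSR * p.GSH_total
        if (m.gpx_gsh_active and r.kGPX * p.GPX > 0)
        else 0.0
    )
    b = r.kTXNRD * p.TXNRD
    c = r.kTXN
    if m.prdx_txn_active and r.kPRDX > 0 and p.PRDX_total > 0 and b > 0 and c > 0 and p.TXN_total > 0:
        cap_prdx = c * p.PRDX_total * b * p.TXN_total / (c * p.PRDX_total + b)
    else:
        cap_prdx = 0.0
    return cap_cat, cap_gpx, cap_prdx


def _gsh_eq(H: float, spec: ModelSpec) -> float:
    """Quasi-equilibrium reduced glutathione at fixed H2O2 level H."""
    r, p = spec.rates, spec.pools
    denom = r.kGPX * p.GPX * H + r.kGSR * p.GSR
    if denom == 0.0:
        return p.GSH_total  # no turnover at all: couple stays reduced
    return r.kGSR * p.GSR * p.GSH_total / denom


def _prdx_eq(H: float, spec: ModelSpec) -> float:
    """Quasi-equilibrium reduced peroxiredoxin at fixed H2O2 level H.

    Smaller root of  a c P^2 - (a c P_T + b c T_T + a b) P + b c T_T P_T = 0
    with a = kPRDX*H, b = kTXNRD*TXNRD, c = kTXN; evaluated in the
    numerically stable 2C/(B+sqrt(...)) form.
    """
    r, p = spec.rates, spec.pools
    a = r.kPRDX * H
    b = r.kTXNRD * p.TXNRD
    c = r.kTXN
    PT, TT = p.PRDX_total, p.TXN_total
    if a == 0.0 or PT == 0.0:
        return PT  # no oxidation: couple stays reduced
    if b == 0.0 or c == 0.0 or TT == 0.0:
        return 0.0  # no recycling: couple ends fully oxidized
    A = a * c
    B = a * c * PT + b * c * TT + a * b
    C = b * c * TT * PT
    disc = B * B - 4.0 * A * C
    return 2.0 * C / (B + math.sqrt(max(disc, 0.0)))


def _fluxes(H: float, spec: ModelSpec) -> tuple[float, float, float]:
    """Pathway removal fluxes (cat, gpx, prdx) at quasi-equilibrium."""
    r, p, m = spec.rates, spec.pools, spec.mask
    f_cat = r.kCAT * p.CAT * H if m.cat_active else 0.0
    f_gpx = r.kGPX * p.GPX * H * _gsh_eq(H, spec) if m.gpx_gsh_active else 0.0
    f_prdx = r.kPRDX * H * _prdx_eq(H, spec) if m.prdx_txn_active else 0.0
    return f_cat, f_gpx, f_prdx


def _residual(H: float, spec: ModelSpec) -> float:
    return spec.h2o2_influx - sum(_fluxes(H, spec))


def find_steady_analytic(spec: ModelSpec) -> SteadyStateResult:
    """Steady-state H2O2 from the flux-balance residual (bracketed brentq).

    Raises
    ------
    NoSteadyStateError
        If no pathway is active with a positive influx, or catalase is
        inactive and the influx meets or exceeds the summed saturation
        capacities of the active recycling pathways.
    """
    if spec.h2o2_influx == 0.0:
        return SteadyStateResult(0.0, 0.0, 0.0, 0.0, True, math.nan, "analytic")

    cap_cat, cap_gpx, cap_prdx = pathway_capacities(spec)
    if cap_cat == 0.0 and spec.h2o2_influx >= cap_gpx + cap_prdx:
        raise NoSteadyStateError(
            "influx exceeds scavenging capacity: "
            f"influx {spec.h2o2_influx:g} mM/ms >= capacity "
            f"{cap_gpx + cap_prdx:g} mM/ms with catalase inactive"
        )

    r, p, m = spec.rates, spec.pools, spec.mask
    slope0 = (
        (r.kCAT * p.CAT if m.cat_active else 0.0)
        + (r.kGPX * p.GPX * p.GSH_total if m.gpx_gsh_active else 0.0)
        + (r.kPRDX * p.PRDX_total if m.prdx_txn_active else 0.0)
    )
    # grow the bracket geometrically from the initial-slope estimate;
    # R is strictly decreasing so the first sign change brackets the root
    H_hi = spec.h2o2_influx / slope0
    while _residual(H_hi, spec) > 0.0:
        H_hi *= 2.0
        if H_hi > 1e18:  # pragma: no cover - capacity check above prevents this
            raise NoSteadyStateError("failed to bracket the flux-balance root")
    H = brentq(_residual, 0.0, H_hi, args=(spec,), xtol=1e-30, rtol=1e-14)
    f_cat, f_gpx, f_prdx = _fluxes(H, spec)
    return SteadyStateResult(H, f_cat, f_gpx, f_prdx, True, math.nan, "analytic")


def _state_fluxes(state: RedoxState, spec: ModelSpec) -> tuple[float, float, float]:
    r, p, m = spec.rates, spec.pools, spec.mask
    f_cat = r.kCAT * p.CAT * state.H2O2 if m.cat_active else 0.0
    f_gpx = r.kGPX * p.GPX * state.H2O2 * state.GSH if m.gpx_gsh_active else 0.0
    f_prdx = r.kPRDX * state.H2O2 * state.PRDX_red if m.prdx_txn_active else 0.0
    return f_cat, f_gpx, f_prdx


def _relaxed(state: RedoxState, spec: ModelSpec, rel_tol: float) -> bool:
    d = derivatives(state, spec)
    for name in ("H2O2", "GSH", "GSSG", "PRDX_red", "PRDX_ox", "TXN_red", "TXN_ox"):
        value = getattr(state, name)
        if abs(getattr(d, name)) > rel_tol * max(abs(value), _DERIV_FLOOR):
            return False
    return True


def find_steady_numeric(
    spec: ModelSpec,
    rel_tol: float = 1e-9,
    t_max: float = 1e8,
    init: RedoxState | None = None,
) -> SteadyStateResult:
    """Integrate until all derivatives relax below ``rel_tol`` per ms
    (relative to each concentration, floored at 1e-12 mM) or ``t_max``.

    Integration proceeds in geometrically growing windows; if ``t_max`` is
    reached without convergence the last state is retained with
    ``converged=False``.  An influx that exceeds the scavenging capacity
    (possible only with catalase inactive) raises ``NoSteadyStateError``
    rather than integrating a divergent trajectory.
    """
    if rel_tol <= 0 or t_max <= 0:
        raise ValueError("rel_tol and t_max must be positive")

    cap_cat, cap_gpx, cap_prdx = pathway_capacities(spec)
    if spec.h2o2_influx > 0 and cap_cat == 0.0 and spec.h2o2_influx >= cap_gpx + cap_prdx:
        raise NoSteadyStateError(
            "influx exceeds scavenging capacity: H2O2 grows without bound "
            "with catalase inactive and recycling pathways saturated"
        )

    state = reduced_state(spec.pools) if init is None else init
    t_now = 0.0
    window = 1e3  # ms; grows geometrically
    while t_now < t_max:
        if _relaxed(state, spec, rel_tol):
            f = _state_fluxes(state, spec)
            return SteadyStateResult(state.H2O2, *f, True, t_now, "numeric")
        window = min(window, t_max - t_now)
        traj = simulate(spec, window, init=state, n_output=2)
        state = traj.final_state
        t_now += window
        window *= 4.0
    converged = _relaxed(state, spec, rel_tol)
    f = _state_fluxes(state, spec)
    return SteadyStateResult(state.H2O2, *f, converged, t_now, "numeric")


def steady_result_frame(results, **extra):
    """Tabulate SteadyStateResult objects (helper for CSV export)."""
    import pandas as pd

    rows = []
    for key, res in results.items():
        row = {"key": key, **extra}
        row.update(
            h2o2_ss=res.h2o2_ss,
            flux_cat=res.flux_cat,
            flux_gpx=res.flux_gpx,
            flux_prdx=res.flux_prdx,
            converged=res.converged,
            t_reached_ms=res.t_reached,
            method=res.method,
        )
        rows.append(row)
    return pd.DataFrame(rows)
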