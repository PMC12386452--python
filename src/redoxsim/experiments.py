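"""Knockout grid over cell-line profiles and RS/RR group comparison.

Each cell-line profile is run through a fixed grid of pathway-knockout
conditions (all systems active, each system alone, and the pairwise
combinations); steady-state H2O2 is recorded per line and condition,
aggregated as mean +/- SD per tissue, and compared between radiosensitive
(RS) and radioresistant (RR) groups with a two-sided Welch test
(Mann-Whitney available as an option).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CellLineProfile
from .model import ModelSpec, PathwayMask, RateConstants
from .steady import NoSteadyStateError, find_steady_analytic, find_steady_numeric

__all__ = [
    "CONDITION_GRID",
    "GroupComparison",
    "run_grid",
    "aggregate_by_tissue",
    "compare_rs_rr",
    "compare_all",
    "load_classification",
]

#: ordered knockout grid: (condition name, pathway mask); the mask fields
#: are (prdx_txn_active, cat_active, gpx_gsh_active)
CONDITION_GRID: tuple[tuple[str, PathwayMask], ...] = (
    ("all_active", PathwayMask(True, True, True)),
    ("prdx_only", PathwayMask(True, False, False)),
    ("cat_only", PathwayMask(False, True, False)),
    ("gpx_only", PathwayMask(False, False, True)),
    ("prdx_cat", PathwayMask(True, True, False)),
    ("cat_gpx", PathwayMask(False, True, True)),
    ("prdx_gpx", PathwayMask(True, False, True)),
)


def run_grid(
    profiles: list[CellLineProfile],
    grid: tuple[tuple[str, PathwayMask], ...] = CONDITION_GRID,
    base_rates: RateConstants | None = None,
    influx: float = 1e-5,
) -> pd.DataFrame:
    """Steady-state H2O2 for every profile x condition.

    The analytic flux-balance solution is used; when it reports no steady
    state (influx above the active pathways' capacity) the row is recorded
    as non-converged with NaN rather than failing the grid.  Deterministic
    given its inputs.

    Returns a frame with columns
    ``line,tissue,label,condition,h2o2_ss,flux_cat,flux_gpx,flux_prdx,converged``.
    """
    if base_rates is None:
        base_rates = RateConstants()
    rows = []
    for profile in profiles:
        for name, mask in grid:
            spec = ModelSpec(
                rates=base_rates, pools=profile.pools, mask=mask, h2o2_influx=influx
            )
            try:
                res = find_steady_analytic(spec)
            except NoSteadyStateError:
                res = None
            rows.append(
                {
                    "line": profile.name,
                    "tissue": profile.tissue,
                    "label": profile.label,
                    "condition": name,
                    "h2o2_ss": res.h2o2_ss if res else math.nan,
                    "flux_cat": res.flux_cat if res else math.nan,
                    "flux_gpx": res.flux_gpx if res else math.nan,
                    "flux_prdx": res.flux_prdx if res else math.nan,
                    "converged": bool(res.converged) if res else False,
                }
            )
    columns = [
        "line", "tissue", "label", "condition",
        "h2o2_ss", "flux_cat", "flux_gpx", "flux_prdx", "converged",
    ]
    return pd.DataFrame(rows, columns=columns)


def aggregate_by_tissue(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) of steady-state H2O2 over the
    converged lines of each tissue x condition group.

    Single-line groups get SD 0 and ``single_line=True`` (with a warning),
    mirroring how error bars degenerate for n=1.  Order-free: any row
    permutation of ``results`` yields the same table.
    """
    conv = results[results["converged"]]
    rows = []
    for (tissue, condition), grp in conv.groupby(["tissue", "condition"], sort=True):
        vals = grp["h2o2_ss"].to_numpy()
        single = vals.size == 1
        if single:
            warnings.warn(
                f"group ({tissue!r}, {condition!r}) has a single line; SD reported as 0",
                stacklevel=2,
            )
        rows.append(
            {
                "tissue": tissue,
                "condition": condition,
                "mean": float(vals.mean()),
                "sd": 0.0 if single else float(vals.std(ddof=1)),
                "n": int(vals.size),
                "single_line": single,
            }
        )
    return pd.DataFrame(rows, columns=["tissue", "condition", "mean", "sd", "n", "single_line"])


@dataclass(frozen=True)
class GroupComparison:
    """RS-vs-RR summary for one tissue x condition cell."""

    tissue: str
    condition: str
    n_rr: int
    n_rs: int
    mean_rr: float
    mean_rs: float
    sd_rr: float
    sd_rs: float
    p_value: float
    significant: bool  # p_value < alpha


def compare_rs_rr(
    results: pd.DataFrame,
    tissue: str,
    condition: str,
    test: str = "welch",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided comparison of steady-state H2O2 between the RR and RS
    groups of one tissue under one condition.

    ``test`` is "welch" (unequal-variance t) or "mannwhitney".  Both label
    groups need at least two converged lines.
    """
    if test not in ("welch", "mannwhitney"):
        raise ValueError("test must be 'welch' or 'mannwhitney'")
    sub = results[
        (results["tissue"] == tissue)
        & (results["condition"] == condition)
        & results["converged"]
    ]
    rr = sub.loc[sub["label"] == "RR", "h2o2_ss"].to_numpy()
    rs = sub.loc[sub["label"] == "RS", "h2o2_ss"].to_numpy()
    for name, vals in (("RR", rr), ("RS", rs)):
        if vals.size < 2:
            raise ValueError(
                f"group {name} has {vals.size} converged line(s) for "
                f"({tissue!r}, {condition!r}); need >= 2"
            )
    if test == "welch":
        stat = stats.ttest_ind(rr, rs, equal_var=False)
        p = float(stat.pvalue)
        if math.isnan(p) and np.ptp(rr) == 0 and np.ptp(rs) == 0 and rr[0] == rs[0]:
            p = 1.0  # both groups constant and identical: no evidence of difference
    else:
        p = float(stats.mannwhitneyu(rr, rs, alternative="two-sided").pvalue)
    return GroupComparison(
        tissue=tissue,
        condition=condition,
        n_rr=int(rr.size),
        n_rs=int(rs.size),
        mean_rr=float(rr.mean()),
        mean_rs=float(rs.mean()),
        sd_rr=float(rr.std(ddof=1)),
        sd_rs=float(rs.std(ddof=1)),
        p_value=p,
        significant=bool(p < alpha),
    )


def compare_all(
    results: pd.DataFrame,
    test: str = "welch",
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Run :func:`compare_rs_rr` over every tissue x condition with at
    least two converged lines per label group.

    ``fdr=True`` adds Benjamini-Hochberg adjusted p-values across the grid
    (off by default; significance then uses the adjusted values).
    """
    rows = []
    conv = results[results["converged"]]
    for (tissue, condition), grp in conv.groupby(["tissue", "condition"], sort=True):
        sizes = grp["label"].value_counts()
        if sizes.get("RR", 0) < 2 or sizes.get("RS", 0) < 2:
            continue
        cmp = compare_rs_rr(results, tissue, condition, test=test, alpha=alpha)
        rows.append(vars(cmp))
    out = pd.DataFrame(
        rows,
        columns=[
            "tissue", "condition", "n_rr", "n_rs",
            "mean_rr", "mean_rs", "sd_rr", "sd_rs", "p_value", "significant",
        ],
    )
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")
        out["p_adjusted"] = p_adj
        out["significant"] = reject
    return out


# -- radiosensitivity classification fixture ------------------------------

# Lung, breast and colorectal cancer cell lines with literature-derived
# radiosensitive (RS) / radioresistant (RR) labels, as used to group the
# simulation readouts.  NOTE: one radiosensitive breast row could not be
# recovered from the source text (which states sixteen breast lines but
# legibly lists fifteen); MDA-MB-468, a commonly radiosensitive-classified
# breast line, stands in as a synthetic reconstruction of that entry.
_CLASSIFICATION: tuple[tuple[str, str, str], ...] = (
    # lung: 7 RR + 7 RS
    ("A549", "lung", "RR"),
    ("H1703", "lung", "RR"),
    ("H661", "lung", "RR"),
    ("H1299", "lung", "RR"),
    ("H1339", "lung", "RR"),
    ("H292", "lung", "RR"),
    ("H358", "lung", "RR"),
    ("H23", "lung", "RS"),
    ("H441", "lung", "RS"),
    ("H1650", "lung", "RS"),
    ("H522", "lung", "RS"),
    ("HCC827", "lung", "RS"),
    ("H69", "lung", "RS"),
    ("H460", "lung", "RS"),
    # breast: 8 RR + 8 RS
    ("MCF-7", "breast", "RR"),
    ("SK-BR-3", "breast", "RR"),
    ("ZR-751", "breast", "RR"),
    ("HCC1428", "breast", "RR"),
    ("T47D", "breast", "RR"),
    ("HS578T", "breast", "RR"),
    ("UACC-812", "breast", "RR"),
    ("MDA-MB-175VII", "breast", "RR"),
    ("MDA-MB-361", "breast", "RS"),
    ("HCC70", "breast", "RS"),
    ("MDA-MB-231", "breast", "RS"),
    ("BT474", "breast", "RS"),
    ("JIMT-1", "breast", "RS"),
    ("CAL-51", "breast", "RS"),
    ("HCC1395", "breast", "RS"),
    ("MDA-MB-468", "breast", "RS"),  # synthetic stand-in entry (see note above)
    # colorectal: 7 RR + 5 RS
    ("HT115", "colorectal", "RR"),
    ("DLD-1", "colorectal", "RR"),
    ("Lovo", "colorectal", "RR"),
    ("HT29", "colorectal", "RR"),
    ("Caco-2", "colorectal", "RR"),
    ("SW480", "colorectal", "RR"),
    ("MDST8", "colorectal", "RR"),
    ("Colo-201", "colorectal", "RS"),
    ("Colo-205", "colorectal", "RS"),
    ("Colo-320", "colorectal", "RS"),
    ("HCT116", "colorectal", "RS"),
    ("SW48", "colorectal", "RS"),
)


def load_classification() -> dict[str, tuple[str, str]]:
    """Packaged radiosensitivity classification: line -> (tissue, label).

    42 entries: 14 lung (7 RR / 7 RS), 16 breast (8 RR / 8 RS) and 12
    colorectal (7 RR / 5 RS) cancer cell lines.
    """
    return {name: (tissue, lab) for name, tissue, lab in _CLASSIFICATION}
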