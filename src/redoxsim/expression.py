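"""Expression-scaled parameterization of the enzyme pools.

Per-cell-line enzyme concentrations are obtained by scaling a reference
parameter set with transcript abundance ratios: for each enzyme family,
the factor is the line's aggregated expression divided by that of a
designated reference line (for which all factors are 1 by construction).
Glutathione is a metabolite with no transcript, so its total is never
expression-scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import EnzymePools

__all__ = [
    "ExpressionTable",
    "GeneMap",
    "CellLineProfile",
    "ENZYMES",
    "default_gene_map",
    "read_expression",
    "read_metadata",
    "aggregate_genes",
    "scale_pools",
    "profiles_to_frame",
    "profiles_to_csv",
    "read_profiles",
]

#: scalable enzyme quantities, in export order; PRDX and TXN scale the
#: conserved couple totals, the rest scale constant enzyme pools
ENZYMES = ("CAT", "GPX", "GSR", "TXNRD", "PRDX", "TXN")

_ENZYME_TO_POOL_FIELD = {
    "CAT": "CAT",
    "GPX": "GPX",
    "GSR": "GSR",
    "TXNRD": "TXNRD",
    "PRDX": "PRDX_total",
    "TXN": "TXN_total",
}


@dataclass(frozen=True)
class ExpressionTable:
    """Gene-by-cell-line abundance matrix (unit-agnostic, e.g. TPM-like).

    ``data`` has gene symbols as the index and cell-line names as columns;
    ``tissue`` and ``label`` optionally map line -> tissue / RS-RR label.
    """

    data: pd.DataFrame
    tissue: dict[str, str] = field(default_factory=dict)
    label: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols: {dups}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate cell-line names: {dups}")
        values = self.data.to_numpy()
        if np.isnan(values).any():
            g, l = np.argwhere(np.isnan(values))[0]
            raise ValueError(f"missing value at gene {idx[g]!r}, line {cols[l]!r}")
        if (values < 0).any():
            g, l = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at gene {idx[g]!r}, line {cols[l]!r}: {values[g, l]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def lines(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass(frozen=True)
class GeneMap:
    """Enzyme family -> member gene symbols, with an aggregation rule.

    ``mapping`` assigns each scalable enzyme a non-empty list of distinct
    gene symbols; ``rules`` assigns each enzyme "sum" or "mean".
    """

    mapping: dict[str, list[str]]
    rules: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for enzyme, symbols in self.mapping.items():
            if not symbols:
                raise ValueError(f"enzyme {enzyme!r} maps to no gene symbols")
            if len(set(symbols)) != len(symbols):
                raise ValueError(f"enzyme {enzyme!r} has duplicate symbols")
        for enzyme, rule in self.rules.items():
            if rule not in ("sum", "mean"):
                raise ValueError(f"aggregation rule for {enzyme!r} must be sum|mean")

    def rule(self, enzyme: str) -> str:
        return self.rules.get(enzyme, "sum")

    @property
    def all_symbols(self) -> list[str]:
        out: list[str] = []
        for enzyme in self.mapping:
            out.extend(self.mapping[enzyme])
        return out

    @classmethod
    def from_yaml(cls, path) -> "GeneMap":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mapping, rules = {}, {}
        for enzyme, entry in raw.items():
            if isinstance(entry, dict):
                mapping[enzyme] = list(entry["genes"])
                if "rule" in entry:
                    rules[enzyme] = entry["rule"]
            else:
                mapping[enzyme] = list(entry)
        return cls(mapping=mapping, rules=rules)


def default_gene_map() -> GeneMap:
    """Family members summed per enzyme; config-overridable.

    CAT and GSR are single genes; GPX1-4 cover the cytosolic/membrane
    peroxidases; PRDX1-6 and TXNRD1-3 span their families; TXN plus the
    mitochondrial TXN2 cover thioredoxin.
    """
    return GeneMap(
        mapping={
            "CAT": ["CAT"],
            "GPX": ["GPX1", "GPX2", "GPX3", "GPX4"],
            "GSR": ["GSR"],
            "TXNRD": ["TXNRD1", "TXNRD2", "TXNRD3"],
            "PRDX": ["PRDX1", "PRDX2", "PRDX3", "PRDX4", "PRDX5", "PRDX6"],
            "TXN": ["TXN", "TXN2"],
        },
        rules={e: "sum" for e in ENZYMES},
    )


def read_metadata(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a `line,tissue,label` sidecar CSV -> (tissue map, label map)."""
    meta = pd.read_csv(path, dtype=str)
    required = {"line", "tissue", "label"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if meta["line"].duplicated().any():
        dups = sorted(meta.loc[meta["line"].duplicated(), "line"])
        raise ValueError(f"duplicate lines in metadata: {dups}")
    tissue = dict(zip(meta["line"], meta["tissue"]))
    label = dict(zip(meta["line"], meta["label"]))
    return tissue, label


def read_expression(path, format: str | None = None, metadata=None) -> ExpressionTable:
    """Parse a wide expression matrix (first column gene symbols, remaining
    columns cell lines).

    ``format`` is "wide_csv" or "wide_tsv"; inferred from the extension
    when omitted.  ``metadata`` optionally names a `line,tissue,label`
    sidecar CSV.  Duplicated genes or lines, negative values and missing
    values are all errors (no imputation).
    """
    path = Path(path)
    if format is None:
        format = "wide_tsv" if path.suffix.lower() in (".tsv", ".txt") else "wide_csv"
    if format not in ("wide_csv", "wide_tsv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == "wide_tsv" else ","
    # pandas silently renames duplicated columns, so check the raw header
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    line_names = header[1:]
    dup = sorted({n for n in line_names if line_names.count(n) > 1})
    if dup:
        raise ValueError(f"duplicate cell-line names: {dup}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.astype(float)
    tissue: dict[str, str] = {}
    label: dict[str, str] = {}
    if metadata is not None:
        tissue, label = read_metadata(metadata)
    return ExpressionTable(data=df, tissue=tissue, label=label)


def aggregate_genes(
    table: ExpressionTable, gene_map: GeneMap | None = None, missing: str = "error"
) -> pd.DataFrame:
    """Collapse gene-level abundance to an enzyme-by-line matrix.

    ``missing`` controls unmapped symbols: "error" raises, "drop" skips
    them (an enzyme with zero resolvable symbols is always an error).
    """
    if gene_map is None:
        gene_map = default_gene_map()
    if missing not in ("error", "drop"):
        raise ValueError("missing must be 'error' or 'drop'")
    rows = {}
    for enzyme, symbols in gene_map.mapping.items():
        present = [s for s in symbols if s in table.data.index]
        absent = [s for s in symbols if s not in table.data.index]
        if absent and missing == "error":
            raise KeyError(f"gene symbols not in table for {enzyme}: {absent}")
        if not present:
            raise KeyError(f"enzyme {enzyme!r} has no resolvable gene symbols")
        sub = table.data.loc[present]
        rows[enzyme] = sub.sum(axis=0) if gene_map.rule(enzyme) == "sum" else sub.mean(axis=0)
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class CellLineProfile:
    """Expression-scaled parameterization for one cell line.

    ``scaling`` maps each enzyme to its abundance ratio against the
    reference line; ``pools`` is the base parameter set with the six
    scalable quantities multiplied by those factors (GSH_total unscaled).
    """

    name: str
    tissue: str
    label: str  # "RS" | "RR" | "unknown"
    scaling: dict[str, float]
    pools: EnzymePools


def scale_pools(
    base: EnzymePools,
    enzyme_expr: pd.DataFrame,
    reference_line: str,
    tissue: dict[str, str] | None = None,
    label: dict[str, str] | None = None,
) -> list[CellLineProfile]:
    """Ratio-normalize enzyme abundance against ``reference_line`` and
    scale the base pools entry-wise.

    The reference line's factors are exactly 1 (its pools equal ``base``);
    a zero abundance in the reference is an error since the ratio is
    undefined.  Zero abundance in a non-reference line propagates to a
    zero pool (that pathway then contributes nothing).
    """
    tissue = tissue or {}
    label = label or {}
    missing_enzymes = [e for e in ENZYMES if e not in enzyme_expr.index]
    if missing_enzymes:
        raise KeyError(f"enzyme rows missing from abundance matrix: {missing_enzymes}")
    if reference_line not in enzyme_expr.columns:
        raise KeyError(f"reference line {reference_line!r} not in abundance matrix")
    ref = enzyme_expr[reference_line]
    for enzyme in ENZYMES:
        if ref[enzyme] <= 0:
            raise ValueError(
                f"reference line {reference_line!r} has non-positive abundance for {enzyme}"
            )
    profiles = []
    for line in enzyme_expr.columns:
        if line == reference_line:
            factors = {e: 1.0 for e in ENZYMES}
        else:
            factors = {e: float(enzyme_expr.at[e, line] / ref[e]) for e in ENZYMES}
        pools = replace(
            base, **{_ENZYME_TO_POOL_FIELD[e]: getattr(base, _ENZYME_TO_POOL_FIELD[e]) * factors[e] for e in ENZYMES}
        )
        profiles.append(
            CellLineProfile(
                name=str(line),
                tissue=str(tissue.get(line, "unknown")),
                label=str(label.get(line, "unknown")),
                scaling=factors,
                pools=pools,
            )
        )
    return profiles


def profiles_to_frame(profiles: list[CellLineProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"line": p.name, "tissue": p.tissue, "label": p.label}
        row.update({f"f_{e}": p.scaling[e] for e in ENZYMES})
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_to_csv(profiles: list[CellLineProfile], path) -> None:
    """Write `line,tissue,label,f_CAT,...,f_TXN` with full float precision."""
    profiles_to_frame(profiles).to_csv(path, index=False, float_format="%.17g")


def read_profiles(path, base: EnzymePools | None = None) -> list[CellLineProfile]:
    """Re-read a profiles CSV written by :func:`profiles_to_csv`."""
    if base is None:
        base = EnzymePools()
    df = pd.read_csv(path)
    profiles = []
    for _, row in df.iterrows():
        factors = {e: float(row[f"f_{e}"]) for e in ENZYMES}
        pools = replace(
            base, **{_ENZYME_TO_POOL_FIELD[e]: getattr(base, _ENZYME_TO_POOL_FIELD[e]) * factors[e] for e in ENZYMES}
        )
        profiles.append(
            CellLineProfile(
                name=str(row["line"]),
                tissue=str(row["tissue"]),
                label=str(row["label"]),
                scaling=factors,
                pools=pools,
            )
        )
    return profiles
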