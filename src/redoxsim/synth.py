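"""Synthetic CCLE-like expression matrices with controlled group structure.

The generator emulates the inputs the pipeline consumes — a wide
gene-by-cell-line abundance matrix plus a `line,tissue,label` metadata
table — without any download.  Per gene, abundance across lines is
log-normal around a per-gene baseline; radioresistant (RR) lines receive
a configurable multiplicative effect on the genes of chosen enzyme
families (applied on the natural scale before noise, matching the
ratio-based scaling the pipeline performs).  An optional reference line
(an HCT116 analog) sits exactly at baseline, so its scaling factors are
exactly 1.  All randomness flows from a single integer seed through
``numpy.random.default_rng``, so output is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ENZYMES, ExpressionTable, GeneMap, default_gene_map

__all__ = ["SynthConfig", "generate", "write_synthetic_csvs", "end_to_end_effect_check"]

REFERENCE_LINE = "HCT116"


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults give 20 lines per tissue, half labelled RR, log-normal
    line-to-line noise with sigma 0.2 on the log scale, and no RR effect
    (the null configuration).  ``rr_effect`` maps enzyme family names
    (CAT, GPX, GSR, TXNRD, PRDX, TXN) to multiplicative factors applied
    to RR lines' member genes.
    """

    n_lines_per_tissue: int = 20
    tissues: tuple[str, ...] = ("lung", "breast", "colorectal")
    genes: tuple[str, ...] | None = None  # default: the gene-map symbols
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    rr_effect: dict[str, float] = field(default_factory=dict)
    noise_log_sd: float = 0.2
    rr_fraction: float = 0.5
    seed: int = 0
    include_reference: bool = True
    gene_map: GeneMap | None = None

    def __post_init__(self) -> None:
        if self.n_lines_per_tissue < 1:
            raise ValueError("n_lines_per_tissue must be >= 1")
        if not (0.0 <= self.rr_fraction <= 1.0):
            raise ValueError("rr_fraction must be in [0, 1]")
        if self.noise_log_sd < 0 or self.baseline_log_sd < 0:
            raise ValueError("log-scale sigmas must be non-negative")
        for enzyme, factor in self.rr_effect.items():
            if enzyme not in ENZYMES:
                raise ValueError(f"rr_effect key {enzyme!r} is not an enzyme family")
            if not (factor > 0 and math.isfinite(factor)):
                raise ValueError(f"rr_effect[{enzyme!r}] must be positive, got {factor!r}")
        if self.genes is not None and len(self.genes) == 0:
            raise ValueError("gene list must be non-empty")


def _gene_to_enzyme(gene_map: GeneMap) -> dict[str, str]:
    rev: dict[str, str] = {}
    for enzyme, symbols in gene_map.mapping.items():
        for s in symbols:
            rev[s] = enzyme
    return rev


def generate(config: SynthConfig) -> tuple[ExpressionTable, dict[str, tuple[str, str]]]:
    """Draw one synthetic expression table plus its metadata map.

    Per tissue, the first ``round(n * rr_fraction)`` lines are labelled RR
    and the rest RS (a deterministic assignment; only the abundances are
    random).  Returns ``(table, metadata)`` with metadata mapping
    line -> (tissue, label); the reference line, when included, carries
    tissue "reference" and label "unknown".
    """
    gene_map = config.gene_map or default_gene_map()
    genes = list(config.genes) if config.genes is not None else list(dict.fromkeys(gene_map.all_symbols))
    if not genes:
        raise ValueError("gene list must be non-empty")
    rev = _gene_to_enzyme(gene_map)

    rng = np.random.default_rng(config.seed)
    log_baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=len(genes))
    log_effect = np.array(
        [math.log(config.rr_effect.get(rev.get(g, ""), 1.0)) for g in genes]
    )

    columns: dict[str, np.ndarray] = {}
    metadata: dict[str, tuple[str, str]] = {}
    for tissue in config.tissues:
        n = config.n_lines_per_tissue
        n_rr = round(n * config.rr_fraction)
        for i in range(n):
            label = "RR" if i < n_rr else "RS"
            name = f"{tissue.upper()}-{i + 1:03d}"
            mu = log_baseline + (log_effect if label == "RR" else 0.0)
            columns[name] = np.exp(rng.normal(mu, config.noise_log_sd))
            metadata[name] = (tissue, label)
    if config.include_reference:
        columns[REFERENCE_LINE] = np.exp(log_baseline)  # exactly at baseline, no noise
        metadata[REFERENCE_LINE] = ("reference", "unknown")

    df = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    tissue_map = {line: tl[0] for line, tl in metadata.items()}
    label_map = {line: tl[1] for line, tl in metadata.items()}
    return ExpressionTable(data=df, tissue=tissue_map, label=label_map), metadata


def write_synthetic_csvs(config: SynthConfig, expression_path, metadata_path) -> None:
    """Write the generated matrix and metadata in the dialect
    :func:`redoxsim.expression.read_expression` consumes."""
    table, metadata = generate(config)
    table.data.to_csv(expression_path, float_format="%.17g")
    meta = pd.DataFrame(
        [{"line": line, "tissue": t, "label": l} for line, (t, l) in metadata.items()]
    )
    meta.to_csv(metadata_path, index=False)


def end_to_end_effect_check(
    config: SynthConfig,
    conditions: tuple[str, ...] = ("all_active", "gpx_only"),
    test: str = "welch",
    alpha: float = 0.05,
):
    """Full pipeline on one synthetic draw: generate -> scale -> knockout
    grid -> RS/RR comparison.

    Returns a dict mapping ``(tissue, condition)`` to
    :class:`~redoxsim.experiments.GroupComparison`.  Requires
    ``include_reference=True`` (the scaling needs a reference line) and at
    least two lines per label group per tissue.
    """
    from .experiments import CONDITION_GRID, compare_rs_rr, run_grid
    from .expression import aggregate_genes, scale_pools
    from .model import EnzymePools

    if not config.include_reference:
        raise ValueError("pipeline check requires include_reference=True")
    table, _ = generate(config)
    enzyme_expr = aggregate_genes(table, config.gene_map or default_gene_map())
    profiles = scale_pools(
        EnzymePools(), enzyme_expr, REFERENCE_LINE, tissue=table.tissue, label=table.label
    )
    grid = tuple((n, m) for n, m in CONDITION_GRID if n in conditions)
    results = run_grid([p for p in profiles if p.label in ("RS", "RR")], grid=grid)
    out = {}
    for tissue in config.tissues:
        for name, _mask in grid:
            out[(tissue, name)] = compare_rs_rr(results, tissue, name, test=test, alpha=alpha)
    return out
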