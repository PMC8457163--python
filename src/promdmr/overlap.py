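"""Sharing of DMR-associated genes between the two cell types."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .dmr import DMRSet


@dataclass(frozen=True)
class VennSummary:
    n_a: int
    n_b: int
    n_shared: int
    pct_a_shared: Optional[float]  # 100 * n_shared / n_a, half-up to 1 decimal; None if n_a == 0
    pct_b_shared: Optional[float]
    labels: tuple[str, str]


def _pct_half_up(numerator: int, denominator: int) -> Optional[float]:
    if denominator == 0:
        return None
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def overlap_summary(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    labels: tuple[str, str] = ("nonneuron", "neuron"),
) -> VennSummary:
    """Exact set intersection of two gene lists with half-up percentages.

    Gene symbols are compared case-sensitively; inputs are deduplicated
    defensively.  An empty side yields a ``None`` percentage (undefined, not 0).
    """
    a, b = set(genes_a), set(genes_b)
    shared = len(a & b)
    return VennSummary(
        n_a=len(a),
        n_b=len(b),
        n_shared=shared,
        pct_a_shared=_pct_half_up(shared, len(a)),
        pct_b_shared=_pct_half_up(shared, len(b)),
        labels=labels,
    )


def _gene_directions(dmrs: DMRSet) -> dict[str, str]:
    """Per-gene direction within one cell type; 'mixed' if its DMRs disagree."""
    out: dict[str, str] = {}
    for d in dmrs.dmrs:
        prev = out.get(d.gene_symbol)
        if prev is None:
            out[d.gene_symbol] = d.direction
        elif prev != d.direction:
            out[d.gene_symbol] = "mixed"
    return out


def direction_concordance(dmrs_a: DMRSet, dmrs_b: DMRSet) -> pd.DataFrame:
    """One row per gene with DMRs in both sets: directions and concordance.

    ``concordant`` is True only when both sides agree on a single direction;
    a gene carrying both hyper- and hypomethylated DMRs within one cell type
    is flagged 'mixed' and counted non-concordant.
    """
    dir_a = _gene_directions(dmrs_a)
    dir_b = _gene_directions(dmrs_b)
    rows = []
    for gene in sorted(set(dir_a) & set(dir_b)):
        da, db = dir_a[gene], dir_b[gene]
        rows.append(
            {
                "gene_symbol": gene,
                "direction_a": da,
                "direction_b": db,
                "concordant": da == db and da != "mixed",
            }
        )
    return pd.DataFrame(rows, columns=["gene_symbol", "direction_a", "direction_b", "concordant"])
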