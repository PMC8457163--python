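"""Expression of DMR-associated genes: pH exclusion, reliability filter, Welch tests.

The pipeline order is fixed: low-pH subjects are removed first, then probe
reliability is assessed on the retained subjects, then per-probe Welch tests
compare cases against controls at a nominal (uncorrected) alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .dmr import welch_t
from .formats_io import SampleSheet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """probes x subjects log2 expression with a probe -> gene map."""

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    probe_to_gene: dict[str, str]
    sheet: SampleSheet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError("expression matrix dimensions inconsistent")
        missing = [p for p in self.probe_ids if p not in self.probe_to_gene]
        if missing:
            raise ValidationError(f"probes without a gene mapping: {missing[:5]}")
        sheet_ids = set(self.sheet.sample_ids)
        if any(s not in sheet_ids for s in self.sample_ids):
            raise ValidationError("expression samples absent from sheet")

    def group_columns(self, group: str) -> np.ndarray:
        return self.sheet.group_mask(self.sample_ids, group)

    def _replace(self, values: np.ndarray, probe_ids: list[str], sample_ids: list[str]):
        return ExpressionMatrix(
            values=values,
            probe_ids=probe_ids,
            sample_ids=sample_ids,
            probe_to_gene=self.probe_to_gene,
            sheet=self.sheet.subset(sample_ids) if sample_ids != self.sample_ids else self.sheet,
        )


@dataclass(frozen=True)
class WelchResult:
    probe_id: str
    gene_symbol: str
    t: float
    df: float
    p: float
    mean_CT: float
    mean_SZ: float
    significant: bool


def exclude_low_ph(matrix: ExpressionMatrix, cutoff: float = 6.0) -> ExpressionMatrix:
    """Drop subjects with brain pH below *cutoff*; missing pH is also dropped.

    Raises if either group would be emptied (the group comparison becomes
    impossible).
    """
    keep: list[str] = []
    n_missing = 0
    for sid in matrix.sample_ids:
        ph = matrix.sheet.ph_of(sid)
        if ph is None:
            n_missing += 1
            continue
        if ph >= cutoff:
            keep.append(sid)
    if n_missing:
        logger.info("exclude_low_ph: %d subjects dropped for missing pH", n_missing)
    n_removed = len(matrix.sample_ids) - len(keep)
    logger.info("exclude_low_ph: removed %d of %d subjects", n_removed, len(matrix.sample_ids))
    kept_groups = {matrix.sheet.group_of(s) for s in keep}
    for group in ("CT", "SZ"):
        if group not in kept_groups:
            raise ValueError(f"pH filter removed every {group} subject; test impossible")
    cols = [matrix.sample_ids.index(s) for s in keep]
    return matrix._replace(matrix.values[:, cols], list(matrix.probe_ids), keep)


def filter_reliable(
    matrix: ExpressionMatrix,
    min_expressed_fraction: float = 0.8,
    floor: float = 5.0,
) -> ExpressionMatrix:
    """Keep probes detected above *floor* in >= *min_expressed_fraction* of each group."""
    ct = matrix.group_columns("CT")
    sz = matrix.group_columns("SZ")
    keep_rows = []
    for i in range(matrix.values.shape[0]):
        row = matrix.values[i]
        ok = True
        for mask in (ct, sz):
            frac = np.mean(row[mask] > floor)
            if frac < min_expressed_fraction:
                ok = False
                break
        if ok:
            keep_rows.append(i)
    if not keep_rows:
        logger.warning("filter_reliable: no probe passed the reliability filter")
    return matrix._replace(
        matrix.values[keep_rows, :],
        [matrix.probe_ids[i] for i in keep_rows],
        list(matrix.sample_ids),
    )


def test_dmr_gene_expression(
    matrix: ExpressionMatrix,
    dmr_genes: Sequence[str],
    alpha: float = 0.05,
) -> list[WelchResult]:
    """Per-probe Welch tests (SZ vs CT) restricted to probes of *dmr_genes*.

    The matrix is expected to be pH- and reliability-filtered already.  Genes
    absent from the matrix are logged and skipped.  No multiple-testing
    correction is applied: significance is the nominal two-sided p < alpha.
    """
    wanted = set(dmr_genes)
    present = {matrix.probe_to_gene[p] for p in matrix.probe_ids}
    absent = sorted(wanted - present)
    if absent:
        logger.info("test_dmr_gene_expression: %d genes absent from matrix: %s",
                    len(absent), absent[:10])
    rows = [i for i, p in enumerate(matrix.probe_ids) if matrix.probe_to_gene[p] in wanted]
    if not rows:
        return []
    sz = matrix.group_columns("SZ")
    ct = matrix.group_columns("CT")
    vals = matrix.values[rows, :]
    t, df, _ = welch_t(vals[:, sz], vals[:, ct], axis=1)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    mean_ct = vals[:, ct].mean(axis=1)
    mean_sz = vals[:, sz].mean(axis=1)
    results = []
    for j, i in enumerate(rows):
        pid = matrix.probe_ids[i]
        results.append(
            WelchResult(
                probe_id=pid,
                gene_symbol=matrix.probe_to_gene[pid],
                t=float(t[j]),
                df=float(df[j]),
                p=float(p[j]),
                mean_CT=float(mean_ct[j]),
                mean_SZ=float(mean_sz[j]),
                significant=bool(p[j] < alpha),
            )
        )
    return results


def count_significant_genes(results: Sequence[WelchResult]) -> int:
    """Distinct genes among significant probes (several probes may share a gene)."""
    return len({r.gene_symbol for r in results if r.significant})
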