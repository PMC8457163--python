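"""Windowed DMR calling from case-control probe-level signal.

The region statistic is a Stouffer combination of per-probe Welch t values:
within each promoter, every run of ``min_probes`` consecutive probes (adjacent
probe gap <= ``max_gap_bp``) forms a window with score

    S = sum(t_i) / sqrt(m)

treating each t as a standard-normal z under the null.  Window significance is
either the analytic two-sided normal tail 2*Phi(-|S|) or an empirical
label-permutation p-value based on the per-promoter distribution of max |S|
(a maxT null, which absorbs within-promoter probe correlation that the
analytic null ignores).  Overlapping significant windows are merged into one
DMR spanning their union, keeping the best window's p-value and score; the
DMR direction (hyper- vs hypomethylated in cases) is the sign of the mean
case-minus-control difference over the merged probe span.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special

from .formats_io import ProbeSignalMatrix, PromoterUniverse, ValidationError

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-12  # deterministic handling of zero-variance (noise-free) probes


@dataclass(frozen=True)
class ProbeStat:
    probe_id: str
    t_value: float
    mean_diff: float  # mean(SZ) - mean(CT), log2 signal
    df: float


@dataclass(frozen=True)
class DMR:
    dmr_id: str
    chrom: str
    start: int
    end: int
    promoter_id: str
    gene_symbol: str
    n_probes: int
    score: float
    p_value: float
    direction: str  # {"hyper", "hypo"}: methylation change in cases
    cell_type: str


@dataclass
class DMRSet:
    dmrs: list[DMR]
    threshold_p: float
    threshold_label: str  # {"stringent", "relaxed"}
    cell_type: str

    def __post_init__(self) -> None:
        for d in self.dmrs:
            if d.p_value > self.threshold_p:
                raise ValidationError(
                    f"DMR {d.dmr_id} has p={d.p_value} above set threshold {self.threshold_p}"
                )
            if d.cell_type != self.cell_type:
                raise ValidationError(
                    f"DMR {d.dmr_id} cell_type {d.cell_type!r} != set cell_type {self.cell_type!r}"
                )

    def __len__(self) -> int:
        return len(self.dmrs)

    def promoter_ids(self) -> list[str]:
        return sorted({d.promoter_id for d in self.dmrs})


# ---------------------------------------------------------------------------
# Welch t core (shared with expression integration)
# ---------------------------------------------------------------------------

def welch_t(
    case: np.ndarray, ctrl: np.ndarray, axis: int = -1, var_floor: float = VAR_FLOOR
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t of case vs control along *axis*.

    Returns ``(t, df, mean_diff)`` with Welch-Satterthwaite degrees of freedom.
    Sample variances are floored at *var_floor* so noise-free fixtures yield
    finite statistics deterministically.
    """
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    n1, n2 = case.shape[axis], ctrl.shape[axis]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples, got {n1} and {n2}")
    m1 = case.mean(axis=axis)
    m2 = ctrl.mean(axis=axis)
    v1 = np.maximum(case.var(axis=axis, ddof=1), var_floor)
    v2 = np.maximum(ctrl.var(axis=axis, ddof=1), var_floor)
    se2_1 = v1 / n1
    se2_2 = v2 / n2
    se2 = se2_1 + se2_2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1))
    return t, df, m1 - m2


def probe_stats(matrix: ProbeSignalMatrix) -> list[ProbeStat]:
    """Per-probe Welch t of SZ vs CT log2 signal (mean_diff = SZ - CT)."""
    sz = matrix.group_columns("SZ")
    ct = matrix.group_columns("CT")
    t, df, diff = welch_t(matrix.values[:, sz], matrix.values[:, ct], axis=1)
    return [
        ProbeStat(pid, float(t[i]), float(diff[i]), float(df[i]))
        for i, pid in enumerate(matrix.probe_ids)
    ]


# ---------------------------------------------------------------------------
# Window machinery
# ---------------------------------------------------------------------------

def _windows_for_promoter(
    starts: np.ndarray, ends: np.ndarray, min_probes: int, max_gap_bp: int
) -> list[tuple[int, int]]:
    """Index ranges [i, i+min_probes) of valid windows over position-sorted probes."""
    n = len(starts)
    wins = []
    for i in range(n - min_probes + 1):
        gaps = starts[i + 1 : i + min_probes] - ends[i : i + min_probes - 1]
        if np.all(gaps <= max_gap_bp):
            wins.append((i, i + min_probes))
    return wins


def _merge_windows(
    wins: Sequence[tuple[int, int]],
    scores: Sequence[float],
    pvals: Sequence[float],
) -> list[tuple[int, int, float, float]]:
    """Merge probe-index-overlapping windows; keep each merged run's best p.

    Returns (span_lo, span_hi, score, p) per merged DMR; ties on p break to
    larger |score|, then leftmost window, for determinism.
    """
    order = sorted(range(len(wins)), key=lambda i: wins[i][0])
    merged: list[tuple[int, int, float, float]] = []
    cur_lo, cur_hi = wins[order[0]]
    cur_best = order[0]
    for i in order[1:]:
        lo, hi = wins[i]
        if lo < cur_hi:  # shares >= 1 probe with current run
            cur_hi = max(cur_hi, hi)
            if (pvals[i], -abs(scores[i]), wins[i][0]) < (
                pvals[cur_best],
                -abs(scores[cur_best]),
                wins[cur_best][0],
            ):
                cur_best = i
        else:
            merged.append((cur_lo, cur_hi, scores[cur_best], pvals[cur_best]))
            cur_lo, cur_hi, cur_best = lo, hi, i
    merged.append((cur_lo, cur_hi, scores[cur_best], pvals[cur_best]))
    return merged


def _analytic_p(score: np.ndarray) -> np.ndarray:
    # two-sided standard-normal tail, stable far into the tail
    return special.erfc(np.abs(score) / math.sqrt(2.0))


def _permutation_masks(
    n_samples: int, n_case: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_samples, n_perm) 0/1 matrix; each column a random case-label assignment."""
    u = rng.random((n_samples, n_perm))
    order = np.argsort(u, axis=0, kind="stable")
    w = np.zeros((n_samples, n_perm))
    np.put_along_axis(w, order[:n_case, :], 1.0, axis=0)
    return w


def _permuted_t(
    values: np.ndarray, w_case: np.ndarray, var_floor: float = VAR_FLOOR
) -> np.ndarray:
    """Welch t for every probe (rows) under every relabeling (columns of w_case)."""
    n = values.shape[1]
    n1 = int(round(w_case[:, 0].sum()))
    n2 = n - n1
    x_sum = values.sum(axis=1, keepdims=True)
    x2_sum = (values**2).sum(axis=1, keepdims=True)
    s1 = values @ w_case
    q1 = (values**2) @ w_case
    s2 = x_sum - s1
    q2 = x2_sum - q1
    m1, m2 = s1 / n1, s2 / n2
    v1 = np.maximum((q1 - n1 * m1**2) / (n1 - 1), var_floor)
    v2 = np.maximum((q2 - n2 * m2**2) / (n2 - 1), var_floor)
    return (m1 - m2) / np.sqrt(v1 / n1 + v2 / n2)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def call_dmrs(
    stats: Sequence[ProbeStat],
    universe: PromoterUniverse,
    *,
    min_probes: int = 4,
    max_gap_bp: int = 300,
    threshold_p: float = 1e-5,
    threshold_label: str = "relaxed",
    null: str = "analytic",
    n_perm: int = 1000,
    seed: int = 0,
    cell_type: str = "neuron",
    matrix: Optional[ProbeSignalMatrix] = None,
    perm_block: int = 64,
) -> DMRSet:
    """Call DMRs per promoter from per-probe Welch statistics.

    Parameters
    ----------
    null
        ``"analytic"`` uses the two-sided normal tail of the Stouffer score;
        ``"permutation"`` uses a per-promoter max-|S| label-permutation null
        (add-one corrected) and requires the raw ``matrix``.
    perm_block
        Number of promoters sharing one drawn set of label permutations;
        blocks are re-drawn independently, keeping promoters in different
        blocks independent under the null.
    """
    if null not in ("analytic", "permutation"):
        raise ValueError(f"unknown null {null!r}")
    if null == "permutation":
        if matrix is None:
            raise ValueError("permutation null requires the probe signal matrix")
        if n_perm < 100:
            raise ValueError(f"n_perm must be >= 100, got {n_perm}")

    by_id = {s.probe_id: s for s in stats}
    probe_meta = {p.probe_id: p for p in universe.probes}
    unknown = [pid for pid in by_id if pid not in probe_meta]
    if unknown:
        raise ValidationError(f"probes not in universe: {unknown[:5]}...")

    promoters = universe.promoter_by_id()
    by_prom = universe.probes_by_promoter()

    # keep only promoters whose probes all have stats, position-sorted
    prom_items: list[tuple[str, list]] = []
    n_skipped = 0
    for pid, probes in by_prom.items():
        probes = [p for p in probes if p.probe_id in by_id]
        if len(probes) < min_probes:
            n_skipped += 1
            continue
        prom_items.append((pid, probes))
    if n_skipped:
        logger.info("call_dmrs: skipped %d promoters with < %d probes", n_skipped, min_probes)
    prom_items.sort(key=lambda kv: (promoters[kv[0]].chrom, promoters[kv[0]].start))

    if null == "permutation":
        row_of = {pid: i for i, pid in enumerate(matrix.probe_ids)}
        case_mask = matrix.group_columns("SZ")
        n_case = int(case_mask.sum())
        n_samples = len(matrix.sample_ids)
        rng = np.random.default_rng(seed)

    candidates: list[DMR] = []
    dmr_counter = 0
    block = prom_items if null == "analytic" else None

    def process_promoters(items, w_case=None):
        nonlocal dmr_counter
        for pid, probes in items:
            starts = np.array([p.start for p in probes])
            ends = np.array([p.end for p in probes])
            wins = _windows_for_promoter(starts, ends, min_probes, max_gap_bp)
            if not wins:
                continue
            t_obs = np.array([by_id[p.probe_id].t_value for p in probes])
            diffs = np.array([by_id[p.probe_id].mean_diff for p in probes])
            sqrt_m = math.sqrt(min_probes)
            s_obs = np.array([t_obs[lo:hi].sum() / sqrt_m for lo, hi in wins])
            if null == "analytic":
                pvals = _analytic_p(s_obs)
            else:
                rows = [row_of[p.probe_id] for p in probes]
                t_perm = _permuted_t(matrix.values[rows, :], w_case)
                s_perm = np.stack(
                    [t_perm[lo:hi, :].sum(axis=0) / sqrt_m for lo, hi in wins]
                )
                max_null = np.abs(s_perm).max(axis=0)  # (n_perm,)
                pvals = np.array(
                    [
                        (1.0 + np.count_nonzero(max_null >= abs(s))) / (n_perm + 1.0)
                        for s in s_obs
                    ]
                )
            keep = pvals < threshold_p
            if not keep.any():
                continue
            kept_wins = [w for w, k in zip(wins, keep) if k]
            kept_scores = s_obs[keep].tolist()
            kept_p = pvals[keep].tolist()
            prom = promoters[pid]
            for lo, hi, score, p in _merge_windows(kept_wins, kept_scores, kept_p):
                dmr_counter += 1
                span_diff = diffs[lo:hi].mean()
                candidates.append(
                    DMR(
                        dmr_id=f"{cell_type}_dmr_{dmr_counter:05d}",
                        chrom=prom.chrom,
                        start=int(starts[lo]),
                        end=int(ends[hi - 1]),
                        promoter_id=pid,
                        gene_symbol=prom.gene_symbol,
                        n_probes=hi - lo,
                        score=float(score),
                        p_value=float(p),
                        direction="hyper" if span_diff >= 0 else "hypo",
                        cell_type=cell_type,
                    )
                )

    if null == "analytic":
        process_promoters(prom_items)
    else:
        for i in range(0, len(prom_items), perm_block):
            w_case = _permutation_masks(n_samples, n_case, n_perm, rng)
            process_promoters(prom_items[i : i + perm_block], w_case)

    return DMRSet(
        dmrs=candidates,
        threshold_p=threshold_p,
        threshold_label=threshold_label,
        cell_type=cell_type,
    )


def dmr_genes(dmrs: DMRSet, universe: PromoterUniverse) -> list[str]:
    """Sorted unique gene symbols of promoters bearing at least one DMR."""
    by_id = universe.promoter_by_id()
    return sorted({by_id[d.promoter_id].gene_symbol for d in dmrs.dmrs})
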