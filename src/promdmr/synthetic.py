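"""Synthetic datasets with the statistical structure the pipeline assumes.

Emulates a promoter methylation-enrichment tiling-array study of sorted brain
nuclei: two subject groups (CT control, SZ case) x two cell types (neuron,
nonneuron), promoter-tiled probes with within-promoter correlated Gaussian
noise on the log2 scale, planted differentially methylated promoters partially
shared between cell types, GWAS-style locus sets under neutral / enriched /
depleted regimes, and a matched expression dataset of the same subjects with
planted differential genes and a brain-pH covariate.  Every planted signal is
recorded in a ground-truth table so recovery can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .formats_io import (
    CELL_TYPES,
    IntervalSet,
    Probe,
    ProbeSignalMatrix,
    Promoter,
    PromoterUniverse,
    Sample,
    SampleSheet,
    ValidationError,
)

_PROMOTERS_PER_CHROM = 500
_PROMOTER_GAP_BP = 1000


@dataclass(frozen=True)
class PlantedDMR:
    promoter_id: str
    cell_type: str
    direction: str  # {"hyper", "hypo"}
    effect_delta: float  # signed log2-signal shift applied to case samples
    probe_span: tuple[int, int]  # [lo, hi) index range within the promoter's probes


@dataclass(frozen=True)
class PlantedDEGene:
    gene_symbol: str
    expression_log2fc: float  # signed case-minus-control shift


@dataclass
class TruthTable:
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    de_genes: list[PlantedDEGene] = field(default_factory=list)

    def planted_promoters(self, cell_type: Optional[str] = None) -> set[str]:
        return {
            r.promoter_id
            for r in self.planted_dmrs
            if cell_type is None or r.cell_type == cell_type
        }


@dataclass
class SimConfig:
    """Study-design knobs for the generators.

    Defaults mirror the structure of the emulated study — two groups of 35
    subjects each, two cell-type layers, promoter-tiled probes — at a
    2 000-promoter scale (the real array covers 25 500 promoters; the layout
    is preserved, the count is reduced).
    """

    n_promoters: int = 2000
    probes_per_promoter: int = 8
    promoter_width_bp: int = 1000
    n_case: int = 35
    n_control: int = 35
    noise_sd: float = 0.5  # marginal sd of log2 signal noise
    probe_correlation: float = 0.3  # exchangeable within-promoter noise correlation
    dmr_fraction: float = 0.05  # fraction of promoters planted per cell type
    effect_delta: float = 0.5  # |log2 shift| on planted promoters (1.0 x noise_sd)
    shared_dmr_fraction: float = 0.6  # plants common to both cell types
    ph_mean: float = 6.5
    ph_sd: float = 0.25
    low_ph_fraction: float = 0.1  # subjects forced below the pH QC cutoff
    expression_log2fc: float = 1.5
    expression_noise_sd: float = 0.5
    de_fraction: float = 0.2  # fraction of planted-DMR genes made differentially expressed
    unreliable_fraction: float = 0.1  # expression probes pinned at the noise floor
    expression_floor: float = 5.0  # log2 noise floor for reliability calls
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_promoters", "probes_per_promoter", "n_case", "n_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.dmr_fraction <= 1.0):
            raise ValueError("dmr_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.probe_correlation < 1.0):
            raise ValueError("probe_correlation must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Universe
# ---------------------------------------------------------------------------

def generate_universe(cfg: SimConfig) -> PromoterUniverse:
    """Non-overlapping promoters on synthetic chromosomes, evenly tiled probes.

    The layout is deterministic (no randomness is consumed): promoter i sits at
    a fixed offset on chromosome ``chr{1 + i // 500}`` and carries
    ``probes_per_promoter`` evenly spaced probes strictly inside its interval.
    """
    promoters: list[Promoter] = []
    probes: list[Probe] = []
    width = cfg.promoter_width_bp
    spacing = width // cfg.probes_per_promoter
    probe_w = max(1, min(50, spacing // 2))
    for i in range(cfg.n_promoters):
        chrom = f"chr{1 + i // _PROMOTERS_PER_CHROM}"
        slot = i % _PROMOTERS_PER_CHROM
        start = _PROMOTER_GAP_BP + slot * (width + _PROMOTER_GAP_BP)
        pid = f"PROM{i + 1:06d}"
        promoters.append(
            Promoter(
                promoter_id=pid,
                chrom=chrom,
                start=start,
                end=start + width,
                strand="+" if i % 2 == 0 else "-",
                gene_symbol=f"GENE{i + 1:06d}",
            )
        )
        for j in range(cfg.probes_per_promoter):
            p_start = start + j * spacing + (spacing - probe_w) // 2
            probes.append(
                Probe(
                    probe_id=f"{pid}_P{j + 1:02d}",
                    promoter_id=pid,
                    chrom=chrom,
                    start=p_start,
                    end=p_start + probe_w,
                )
            )
    return PromoterUniverse(promoters=promoters, probes=probes)


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

def _generate_subjects(cfg: SimConfig, cell_type: Optional[str]) -> SampleSheet:
    """Subject roster shared by the methylation and expression generators.

    Brain pH follows Normal(ph_mean, ph_sd) truncated above 6.0, except for a
    ``low_ph_fraction`` tail drawn uniformly in [5.5, 5.95] so the pH filter is
    always exercised by a known subject subset.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
    samples: list[Sample] = []
    for group, n in (("CT", cfg.n_control), ("SZ", cfg.n_case)):
        low = rng.random(n) < cfg.low_ph_fraction
        ph = np.clip(rng.normal(cfg.ph_mean, cfg.ph_sd, size=n), 6.05, None)
        ph_low = rng.uniform(5.5, 5.95, size=n)
        ph = np.where(low, ph_low, ph)
        for i in range(n):
            samples.append(Sample(f"{group}{i + 1:02d}", group, cell_type, float(ph[i])))
    return SampleSheet(samples)


# ---------------------------------------------------------------------------
# Methylation matrices with planted DMRs
# ---------------------------------------------------------------------------

def generate_methylation_dataset(
    universe: PromoterUniverse, cfg: SimConfig
) -> tuple[dict[str, ProbeSignalMatrix], TruthTable]:
    """Per-cell-type probe matrices with planted promoter-level group effects.

    Probe signal = per-probe baseline + group effect (signed ``effect_delta``
    added to case samples over the planted probe span) + correlated Gaussian
    noise: an exchangeable within-promoter component of weight
    ``sqrt(probe_correlation)`` plus an independent probe component, scaled to
    marginal sd ``noise_sd``.  A ``shared_dmr_fraction`` of plants is common to
    both cell types with the same direction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))
    by_prom = universe.probes_by_promoter()
    prom_ids = [p.promoter_id for p in universe.promoters]
    n_prom = len(prom_ids)

    n_plant = int(round(cfg.dmr_fraction * n_prom))
    if cfg.dmr_fraction > 0 and n_plant < 1:
        warnings.warn("dmr_fraction too small for this universe; planting nothing")
    truth = TruthTable()
    plants: dict[str, list[tuple[str, str, float]]] = {ct: [] for ct in CELL_TYPES}
    if n_plant >= 1:
        n_shared = int(round(cfg.shared_dmr_fraction * n_plant))
        n_excl = n_plant - n_shared
        chosen = rng.choice(n_prom, size=min(n_prom, n_shared + 2 * n_excl), replace=False)
        shared = chosen[:n_shared]
        excl_a = chosen[n_shared : n_shared + n_excl]
        excl_b = chosen[n_shared + n_excl : n_shared + 2 * n_excl]
        shared_sign = rng.choice([-1.0, 1.0], size=len(shared))
        for ct, excl in (("neuron", excl_a), ("nonneuron", excl_b)):
            excl_sign = rng.choice([-1.0, 1.0], size=len(excl))
            for idx, sign in list(zip(shared, shared_sign)) + list(zip(excl, excl_sign)):
                pid = prom_ids[int(idx)]
                delta = float(sign) * cfg.effect_delta
                span = (0, len(by_prom[pid]))
                plants[ct].append((pid, "hyper" if delta > 0 else "hypo", delta))
                truth.planted_dmrs.append(
                    PlantedDMR(pid, ct, "hyper" if delta > 0 else "hypo", delta, span)
                )

    probe_ids = [p.probe_id for p in universe.probes]
    prom_pos = {pid: i for i, pid in enumerate(prom_ids)}
    prom_index_of_probe = np.array([prom_pos[p.promoter_id] for p in universe.probes])
    probe_rows = {pid: i for i, pid in enumerate(probe_ids)}

    n_samples = cfg.n_control + cfg.n_case
    case_cols = np.arange(cfg.n_control, n_samples)  # CT first, SZ second

    matrices: dict[str, ProbeSignalMatrix] = {}
    rho = cfg.probe_correlation
    for ct in CELL_TYPES:
        baseline = rng.normal(0.0, 1.0, size=len(probe_ids))
        z_prom = rng.standard_normal((n_prom, n_samples))
        z_probe = rng.standard_normal((len(probe_ids), n_samples))
        noise = cfg.noise_sd * (
            np.sqrt(rho) * z_prom[prom_index_of_probe, :] + np.sqrt(1.0 - rho) * z_probe
        )
        values = baseline[:, None] + noise
        for pid, _direction, delta in plants[ct]:
            rows = [probe_rows[p.probe_id] for p in by_prom[pid]]
            values[np.ix_(rows, case_cols)] += delta
        sheet = _generate_subjects(cfg, ct)
        matrices[ct] = ProbeSignalMatrix(
            values=values,
            probe_ids=list(probe_ids),
            sample_ids=sheet.sample_ids,
            sheet=sheet,
        )
    return matrices, truth


# ---------------------------------------------------------------------------
# GWAS-style loci
# ---------------------------------------------------------------------------

def generate_gwas_loci(
    universe: PromoterUniverse,
    n_loci: int,
    regime: str,
    truth: TruthTable,
    seed: int,
    enrichment_weight: float = 5.0,
) -> IntervalSet:
    """Locus intervals placed over promoters under a null or alternative regime.

    neutral   loci over uniformly chosen promoters;
    enriched  planted-DMR promoters carry sampling weight ``enrichment_weight``;
    depleted  planted-DMR promoters are excluded from placement entirely.
    """
    if regime not in ("neutral", "enriched", "depleted"):
        raise ValueError(f"unknown regime {regime!r}")
    if n_loci > len(universe.promoters):
        raise ValueError("n_loci exceeds the number of promoters")
    rng = np.random.default_rng(seed)
    planted = truth.planted_promoters()
    promoters = universe.promoters
    if regime == "depleted":
        pool = [p for p in promoters if p.promoter_id not in planted]
        if not pool:
            raise ValueError("depleted regime impossible: every promoter carries a plant")
        if n_loci > len(pool):
            raise ValueError("n_loci exceeds the number of unplanted promoters")
        idx = rng.choice(len(pool), size=n_loci, replace=False)
        chosen = [pool[i] for i in idx]
    else:
        weights = np.ones(len(promoters))
        if regime == "enriched":
            for i, p in enumerate(promoters):
                if p.promoter_id in planted:
                    weights[i] = enrichment_weight
        # Efraimidis-Spirakis weighted sampling without replacement
        keys = rng.random(len(promoters)) ** (1.0 / weights)
        chosen = [promoters[i] for i in np.argsort(-keys)[:n_loci]]
    intervals = sorted((p.chrom, p.start, p.end) for p in chosen)
    return IntervalSet(name=regime, intervals=intervals)


# ---------------------------------------------------------------------------
# Expression of the same subjects
# ---------------------------------------------------------------------------

def generate_expression_dataset(
    universe: PromoterUniverse, cfg: SimConfig, truth: TruthTable
):
    """Expression matrix for the same subject roster, with planted DE genes.

    Each gene gets 1-2 probes; differentially expressed genes are drawn from
    the planted-DMR genes (fraction ``de_fraction``) and shifted by a signed
    ``expression_log2fc`` in cases; a ``unreliable_fraction`` of probes is
    pinned at the noise floor so the reliability filter has known targets.
    DE plants are appended to ``truth.de_genes``.
    """
    from .expression import ExpressionMatrix  # deferred: avoid import cycle

    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2,)))
    sheet = _generate_subjects(cfg, None)
    by_id = universe.promoter_by_id()
    planted_genes = sorted({by_id[pid].gene_symbol for pid in truth.planted_promoters()})
    n_de = int(round(cfg.de_fraction * len(planted_genes)))
    de_idx = rng.choice(len(planted_genes), size=n_de, replace=False) if n_de else []
    fc_of: dict[str, float] = {}
    for i in de_idx:
        sign = float(rng.choice([-1.0, 1.0]))
        gene = planted_genes[int(i)]
        fc = sign * cfg.expression_log2fc
        if fc != 0.0:
            fc_of[gene] = fc
            truth.de_genes.append(PlantedDEGene(gene, fc))

    probe_ids: list[str] = []
    probe_to_gene: dict[str, str] = {}
    rows: list[np.ndarray] = []
    n_samples = len(sheet.samples)
    case_cols = np.array([s.group == "SZ" for s in sheet.samples])
    unreliable: list[str] = []
    for prom in universe.promoters:
        gene = prom.gene_symbol
        for k in range(int(rng.integers(1, 3))):
            pid = f"EXPR_{gene}_{k + 1}"
            probe_ids.append(pid)
            probe_to_gene[pid] = gene
            if rng.random() < cfg.unreliable_fraction:
                # pinned at/below the detection floor in every subject
                row = cfg.expression_floor - np.abs(rng.normal(0.0, 0.1, size=n_samples))
                unreliable.append(pid)
            else:
                baseline = rng.uniform(
                    cfg.expression_floor + 2.5, cfg.expression_floor + 5.5
                )
                row = baseline + rng.normal(0.0, cfg.expression_noise_sd, size=n_samples)
                if gene in fc_of:
                    row = row + np.where(case_cols, fc_of[gene], 0.0)
            rows.append(row)
    matrix = ExpressionMatrix(
        values=np.vstack(rows),
        probe_ids=probe_ids,
        sample_ids=sheet.sample_ids,
        probe_to_gene=probe_to_gene,
        sheet=sheet,
    )
    return matrix, sheet, unreliable
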