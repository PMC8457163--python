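import numpy as np
import pytest

from promdmr import (
    Probe,
    ProbeSignalMatrix,
    Promoter,
    PromoterUniverse,
    Sample,
    SampleSheet,
    SimConfig,
    generate_methylation_dataset,
    generate_universe,
)


@pytest.fixture
def tiny_universe() -> PromoterUniverse:
    """Two promoters on one chromosome, four probes each."""
    promoters = [
        Promoter("prom1", "chr1", 1000, 2000, "+", "GENE_A"),
        Promoter("prom2", "chr1", 3000, 4000, "-", "GENE_B"),
    ]
    probes = []
    for p in promoters:
        for j in range(4):
            start = p.start + j * 250 + 100
            probes.append(Probe(f"{p.promoter_id}_P{j+1}", p.promoter_id, p.chrom, start, start + 50))
    return PromoterUniverse(promoters=promoters, probes=probes)


@pytest.fixture
def small_sheet() -> SampleSheet:
    samples = [Sample(f"CT{i+1:02d}", "CT", "neuron", 6.5) for i in range(3)] + [
        Sample(f"SZ{i+1:02d}", "SZ", "neuron", 6.5) for i in range(3)
    ]
    return SampleSheet(samples)


@pytest.fixture
def small_matrix(tiny_universe, small_sheet) -> ProbeSignalMatrix:
    """Deterministic fixture: CT columns are [4,5,6], SZ columns are [1,2,3] per probe."""
    probe_ids = [p.probe_id for p in tiny_universe.probes]
    row = np.array([4.0, 5.0, 6.0, 1.0, 2.0, 3.0])  # CT then SZ
    values = np.tile(row, (len(probe_ids), 1))
    return ProbeSignalMatrix(
        values=values,
        probe_ids=probe_ids,
        sample_ids=small_sheet.sample_ids,
        sheet=small_sheet,
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Strong-effect small dataset with plants in both cell types, for integration tests."""
    cfg = SimConfig(
        n_promoters=60,
        probes_per_promoter=8,
        n_case=15,
        n_control=15,
        dmr_fraction=0.2,
        effect_delta=1.5,
        noise_sd=0.5,
        probe_correlation=0.3,
        seed=42,
    )
    universe = generate_universe(cfg)
    matrices, truth = generate_methylation_dataset(universe, cfg)
    return cfg, universe, matrices, truth
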