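# promdmr

Cell-type-specific promoter methylation analysis for case–control
methylation-enrichment (MBD-capture) tiling-array studies, such as promoter-wide
DNA methylation profiling of NeuN-sorted neuronal and non-neuronal nuclei from
postmortem brain. The package takes probe-level log2 enrichment signal over a
promoter universe and provides, as a tested reusable pipeline:

1. **Windowed DMR calling** per cell type — per-probe Welch *t* statistics of
   case (SZ) vs control (CT) signal, combined over windows of *m* consecutive
   probes with a Stouffer score `S = Σ tᵢ / √m`, with either an analytic
   two-sided normal tail `p = 2Φ(−|S|)` or an empirical label-permutation
   max-|S| (maxT) null that absorbs within-promoter probe correlation.
   Overlapping significant windows merge into one differentially methylated
   region (DMR) with a hyper/hypo direction given by the sign of the mean
   case-minus-control difference.
2. **Cross-cell-type overlap** of DMR-associated genes (the genes whose
   promoters contain ≥ 1 DMR), reported as Venn counts and sharing
   percentages, plus per-gene direction concordance between cell types.
3. **Expression integration** — low-brain-pH subject exclusion, a
   floor/fraction reliability filter, and per-probe Welch tests of
   DMR-associated genes at a nominal α.
4. **GWAS-locus resampling test** — the observed count of DMR-bearing
   promoters intersecting a trait's loci is compared against *B* random draws
   of equally many promoters sampled uniformly without replacement from the
   array's promoter universe ("promoter-based random sampling"). Both
   one-sided empirical p-values use the add-one rule
   `p = (1 + #{null ≥ obs}) / (B + 1)`; under this scheme the null count is
   exactly hypergeometric, which the tests exploit as a closed-form oracle.
5. **Synthetic data** — a generator that emulates the assumed study structure
   (two groups × two cell types, promoter-tiled probes with exchangeable
   within-promoter noise correlation, planted DMRs partially shared between
   cell types, GWAS-style loci under neutral/enriched/depleted regimes,
   matched expression with planted differential genes and a pH covariate),
   with an exhaustive ground-truth table for recovery scoring.

It is aimed at epigenomics analysts who need a transparent, calibratable
re-implementation of this analysis style to validate on synthetic data or
apply to their own promoter-array matrices.

## Worked example

```python
from promdmr import (SimConfig, generate_universe, generate_methylation_dataset,
                     generate_gwas_loci, probe_stats, call_dmrs, dmr_genes,
                     overlap_summary, test_enrichment)

cfg = SimConfig(n_promoters=300, n_case=35, n_control=35,
                dmr_fraction=0.1, effect_delta=0.5, seed=11)
universe = generate_universe(cfg)
matrices, truth = generate_methylation_dataset(universe, cfg)

sets, genes = {}, {}
for ct in ("neuron", "nonneuron"):
    stats = probe_stats(matrices[ct])
    sets[ct] = call_dmrs(stats, universe, threshold_p=1e-5, cell_type=ct)
    genes[ct] = dmr_genes(sets[ct], universe)
    print(f"{ct}: {len(sets[ct])} DMRs over {len(genes[ct])} genes")

venn = overlap_summary(genes["nonneuron"], genes["neuron"])
print(f"shared genes: {venn.n_shared} "
      f"({venn.pct_a_shared}% of nonneuronal, {venn.pct_b_shared}% of neuronal)")

loci = generate_gwas_loci(universe, 75, "depleted", truth, seed=12)
res = test_enrichment(sets["nonneuron"], universe, loci, B=10000, seed=13)
print(f"observed overlap {res.observed_overlap}/{res.k}, "
      f"p_enrich={res.p_enrich:.4f}, p_deplete={res.p_deplete:.4f}")
```

Output:

```
neuron: 30 DMRs over 30 genes
nonneuron: 32 DMRs over 32 genes
shared genes: 18 (56.3% of nonneuronal, 60.0% of neuronal)
observed overlap 0/32, p_enrich=1.0000, p_deplete=0.0003
```

Thirty promoters per cell type were planted with a 1-noise-sd methylation
shift (60% shared between cell types); the caller recovers them at the relaxed
threshold `P < 10⁻⁵`. The locus set was placed in the *depleted* regime
(loci never touch planted promoters), and the resampling test flags the
depletion: none of the 32 DMR promoters intersects a locus, while random
32-promoter draws almost always do (`p_deplete = 0.0003`, the minimum
attainable with B = 10 000 being 1/10001 ≈ 0.0001).

A shell workflow is available through the `promdmr` CLI
(`simulate`, `call-dmrs`, `overlap`, `expression`, `gwas-test`); see
`promdmr --help`.

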