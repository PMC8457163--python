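# Methods

## Data model

The unit of annotation is a **promoter universe**: promoters
(0-based half-open intervals with a strand and one gene symbol each) and the
array probes tiled inside them. All overlap computations are strand-agnostic;
a single coordinate convention (BED, 0-based half-open) is used everywhere to
avoid off-by-one drift between modules. Probe-level data are matrices of log2
methylation-enrichment signal (probes × samples) with a sample sheet carrying
group (CT control / SZ case), cell type (neuron / nonneuron, from NeuN-style
nuclei sorting), and brain pH. The enrichment readout is treated as already
normalized; raw-intensity processing is out of scope.

## DMR statistic

Per probe, the group difference is summarized by Welch's *t* (unequal
variances, Welch–Satterthwaite df), with sample variances floored at
ε = 10⁻¹² so noise-free synthetic fixtures remain finite and deterministic.
Within each promoter, every run of `min_probes` (default 4) consecutive
probes whose adjacent gaps are ≤ `max_gap_bp` (default 300 bp) forms a
window scored by the Stouffer combination

    S = Σᵢ tᵢ / √m ,

treating each *t* as standard normal under the null. Window significance is
either

- **analytic**: `p = 2Φ(−|S|)` (erfc-based, stable in the far tail), or
- **permutation**: a per-promoter maxT null — group labels are randomly
  reassigned B times, per-probe *t* and all window scores are recomputed, and
  each window's p-value is the add-one tail frequency of the permuted
  max-|S|: `p = (1 + #{maxₚₑᵣₘ ≥ |S|}) / (B + 1)`.

The permutation null conditions on the realized data and therefore absorbs
within-promoter probe correlation that the analytic null ignores; with
independent probes the two agree closely (typically within ~0.1 dex;
individual promoters fluctuate with the realized between-probe sample
correlation, whose scale is 1/√n). Windows passing the threshold
(`p < threshold_p`; relaxed default 10⁻⁵, stringent default 10⁻⁷ — the
stringent value is a configuration knob, chosen only to be stricter than the
relaxed one) are merged when they share probes; the merged DMR spans their
union, keeps the best window's p and score (ties break to larger |S|, then
leftmost), and its direction is the sign of the mean case-minus-control
difference over the merged span (hyper ≥ 0, hypo < 0). Promoters with fewer
than `min_probes` probes are skipped and counted in the log. Raw p-value
thresholds define the sets; an optional Benjamini–Hochberg column would be
cosmetic here and is not used for set membership.

### Permutation vectorization

Permutation calling processes promoters in blocks (default 64) that share one
drawn set of B label assignments, turning the per-permutation group sums into
two matrix products. Promoters in different blocks use independently drawn
permutations. Sharing within a block leaves each promoter's test exactly
valid (the permutation matrix is independent of the data) and introduces only
a small covariance between same-block promoters via the randomness of the
estimated critical value; at B = 1000 and block 64 this inflates the variance
of a genome-wide false-positive rate by well under 1%, which the calibration
test budget tolerates.

## Cross-cell-type overlap

DMR-associated genes (gene symbols of promoters holding ≥ 1 DMR,
deduplicated) are intersected exactly, case-sensitively. Sharing percentages
are `100·|A∩B|/|A|` rounded half-up to one decimal (Decimal arithmetic, so
e.g. 41/69 → 59.4 and 41/59 → 69.5 exactly); an empty side yields an
undefined marker (`None`), never 0. Direction concordance reports, per gene
present in both cell types, the within-cell-type direction ('mixed' if a
gene's DMRs disagree) and whether both sides agree on a single direction.

## Expression integration

Order is fixed: (1) subjects with brain pH below the cutoff (default 6.0, a
conventional postmortem-tissue QC bound; the filter's mechanics, not the
exact value, are what matters) or with missing pH are removed — erroring if a
group empties; (2) probes are kept only if their signal exceeds a detection
floor (default log2 = 5.0) in ≥ 80% of subjects of *each* group, a
reproducible stand-in for array detection calls; (3) probes mapping to the
DMR-associated genes are tested by the same Welch machinery with
t-distribution tails, two-sided, at nominal α = 0.05 and no multiple-testing
correction. The two filters commute when reliability is assessed on the
post-pH subject set, which the suite asserts. Several probes may map to one
gene; significant probes are also summarized as a distinct-gene count.

## GWAS-locus resampling

The observed statistic is promoter-level and binary: the number of distinct
DMR-bearing promoters whose interval intersects (≥ 1 bp) any locus of a
trait. A promoter with several DMRs counts once, keeping the statistic
exchangeable with the null draws, which sample the same number k of
promoters uniformly without replacement from the full universe (a hook
exists for weighted/matched sampling, but unmatched uniform sampling is the
default frame). Under uniform sampling the null count is exactly
Hypergeometric(N, m, k) with m the loci-overlapping promoters, which the
tests use as an oracle. Enrichment and depletion are always reported as two
separate one-sided add-one empirical p-values; these are valid (conservative
under discreteness) and bounded below by 1/(B+1). Scan runs over multiple
DMR sets × traits derive per-combination seeds from the master seed via
`SeedSequence` spawn keys.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, at a reduced
default scale of 2 000 promoters × 8 probes (the emulated array class covers
25 500 promoters; the layout — promoter width 1 kb, evenly spaced probes,
non-overlapping placement on synthetic chromosomes — is preserved at
test-friendly cost). Defaults: 35 cases and 35 controls (the emulated study's
group sizes), noise sd 0.5 on the log2 scale, exchangeable within-promoter
noise correlation ρ = 0.3 (the simplest model of the probe non-independence
that enrichment capture induces), planted-DMR fraction 5% per cell type with
effect |Δ| = 0.5 (1.0 × noise sd, a calibration choice — no empirical
effect-size distribution is available) applied over the full probe span, and
60% of plants shared between cell types with identical direction, mirroring
the ~59–70% gene-level sharing regime the overlap code should be exercised
in. Brain pH is Normal(6.5, 0.25) truncated above 6.0 with an explicit
low-pH tail (10% of subjects uniform in [5.5, 5.95]); the distribution only
needs to exercise the pH filter deterministically. Expression gives each
gene 1–2 probes, baselines well above the detection floor, noise sd 0.5,
differential expression (|log2FC| = 1.5, random sign) planted in 20% of
planted-DMR genes, and 10% of probes pinned at the noise floor as known
reliability-filter targets. GWAS-style loci are promoter intervals chosen
uniformly (neutral), with weight 5 on planted promoters
(enriched, Efraimidis–Spirakis weighted sampling without replacement), or
excluding planted promoters entirely (depleted — a constructive guarantee).
Every planted signal is recorded in the truth table; subjects are drawn from
a dedicated seed stream so the methylation and expression datasets describe
the same roster.

What the generator does **not** emulate: raw hybridization intensities, dye
or batch effects, probe GC/affinity bias, hydroxymethylation
cross-reactivity, linkage structure among GWAS loci, or promoter length/CpG
heterogeneity. Passing recovery and calibration tests therefore demonstrates
the pipeline's statistical correctness under its stated noise model, not
performance on real arrays.

## Determinism and numerics

Every stochastic stage takes a seed; generators draw from fixed
`SeedSequence` spawn keys of the master seed, so reruns are byte-identical,
and derived seeds stay below 2³¹. Matrix TSVs are written with `%.17g` and
read with round-trip float parsing, making write→read exact for float64; DMR
tables carry 6 significant digits for scores and p-values. Ties in window
merging break deterministically (best p, then larger |S|, then leftmost).

## Validation suite sizes

The acceptance battery runs a 2 000-promoter null dataset (permutation null,
B = 1000) for type-I calibration, a 400-promoter dataset (B = 1999,
threshold 10⁻³) for planted-effect recovery against an independent
brute-force simulation oracle of 120 single-promoter replicates, and
100 end-to-end replicates each of the depleted and neutral locus regimes
(300 promoters, B = 2000); these sizes give Monte-Carlo standard errors
small enough for the stated 99%-binomial and 3-SE bounds while keeping the
whole battery under a minute on one CPU.

## Known limitations

- The exact region statistic of the emulated analysis style is not public;
  the Stouffer-combined windowed Welch-t with an optional maxT permutation
  null is this package's own, chosen for transparency and calibratability.
- One gene per promoter record is assumed (bidirectional promoters would
  need duplicate records).
- The analytic null ignores probe correlation and is anti-conservative when
  ρ > 0; use the permutation null for inference, the analytic null for
  speed and screening.
- Uniform resampling does not match on promoter length or CpG content; the
  weighted-sampling hook is the extension point for matched nulls.
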