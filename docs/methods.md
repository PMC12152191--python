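# Methods

## The analysis problem

A pooled CRISPR knockout dropout screen infects a cell population with a
guide library (here modelled on a drug-target/kinase/phosphatase design:
~10 sgRNAs per gene plus dedicated safe-harbor and non-targeting
negative controls), grows the pool under selection-free conditions, and
sequences the integrated guide cassettes at successive timepoints.
Guides against genes required for growth become under-represented over
time. `dropout3d` scores such screens run **in parallel in two growth
conditions** — 2D monolayer and 3D suspension culture — and isolates
the genes required exclusively for 3D growth, the condition most
closely tied to transformation-like behaviour of immortalized cells.

## Scoring model

### Normalization and enrichment

Read counts are normalized per sample by median-of-ratios size factors
(the DESeq-family estimator): for every guide with positive counts in
all samples of a comparison, the ratio of its count to its geometric
mean across samples is formed, and a sample's factor is the median of
these ratios, rescaled so factors have geometric mean 1. When fewer
than `min_eligible` (default 100) guides qualify, the method falls
back to total-count scaling with a warning — the median-of-ratios
estimator is not meaningful on a handful of guides. Factors are
computed per comparison, over exactly the samples that comparison uses.

For endpoint day t ∈ {7, 14} and the day-0 baseline of the same
condition, the per-replicate log2 fold enrichment of guide *g* is

    log2FE_r(g) = log2( (n_end,r(g) + ψ) / (n_base,r(g) + ψ) )

with normalized counts *n* and pseudocount ψ = 0.5 (configurable).
Replicates are paired by replicate number when both timepoints carry
the same replicate labels (the dishes-seeded-in-duplicate design);
otherwise each endpoint replicate is compared against the mean of the
normalized baselines. The reported log2FE is the arithmetic mean of
the per-replicate values; per-replicate values are retained. A fixed
pseudocount is the one scale-sensitive term in this ratio, so the
scaling-invariance of median-ratio normalization is exact only in the
ψ → 0 limit; at ψ = 0.5 and realistic depths the deviation is ~1e-3
log2 units at worst.

### Effect sizes and the phenotype score

The control set is the union of safe and non-targeting guides. A
guide's effect size is its control-centred enrichment,

    pZ(g) = log2FE(g) − median{ log2FE(c) : c ∈ controls },

which forces the control population's median to exactly zero in every
comparison and makes all downstream scores invariant to adding a
constant to every guide's enrichment. A gene's effect size is the
median pZ of its guides (midpoint convention for even counts),

    U_gene = median{ pZ(g) : g targets the gene },

and the phenotype score standardizes it against the controls with a
pooled variance:

    S_var = Var_gene · (N_exp − 1) + Var_ctrl · (N_ctrl − 1)
    T = (U_gene − U_ctrl) / sqrt( S_var / N_exp + S_var / N_ctrl )

where Var_gene and Var_ctrl are sample variances (divisor n − 1) of
the gene's and the controls' pZ values, N_exp is the gene's guide
count and N_ctrl the average number of guides per targeting gene in
the screen (targeting guides / targeting genes; controls, which have
no gene, are excluded from this average). Var_ctrl is taken over all
individual control-guide pZ values, symmetric to Var_gene at the
single-guide level.

Note the pooled sum of squares S_var itself — not a variance — enters
both denominator terms. This differs from a textbook Welch statistic
(Var_gene/N_exp + Var_ctrl/N_ctrl); we implement the pooled form as
the primary definition and expose the Welch form behind `welch=True`
for sensitivity analysis. Genes with a single guide receive U_gene but
no T (Var_gene is undefined); degenerate inputs with S_var ≤ 0
(possible only for exactly constant pZ values) yield NaN rather than
an arbitrary number. No p-value is attached to T.

### Dropout calling and exclusivity

A gene is called a dropout in a comparison iff

* U_gene < −0.1 (strict), and
* at least 3 of its guides individually dropped out, where a guide is
  "dropped" iff pZ ≤ −0.1 (inclusive, so a guide exactly at the
  threshold counts).

The per-guide criterion has no unique published definition; we use the
same magnitude as the gene gate and expose it (`guide_drop_max`) in the
call configuration. With ~10 guides per gene the median gate
U_gene < −0.1 already implies about half the guides sit below −0.1, so
the ≥3-guides gate mainly protects genes with few scored guides.

The four call sets (2D/3D × day 7/14) are partitioned:

* **3D-exclusive** = (3D_D7 ∩ 3D_D14) \ (2D_D7 ∪ 2D_D14)
* **2D-exclusive** = (2D_D7 ∩ 2D_D14) \ (3D_D7 ∪ 3D_D14)
* **shared** = called in all four comparisons
* **other** = called somewhere but fitting no class
* **none** = never called

Exclusivity requires calls on *both* days of one condition and on
*neither* day of the other (a union-over-days variant is available via
`both_days=False`). The five labels are mutually exclusive and cover
the gene universe. Membership tables and exclusive-intersection counts
feed an optional UpSet-style rendering.

### Prioritization cascade

Downstream triage consumes annotation tables rather than recomputing
them, because pathway enrichment and survival fitting depend on
external tools, background sets and cohorts that are inputs here:

1. **Pathway filter** — keep genes present in ≥ 9 of the top 20
   pathways of a ranked binary gene × pathway membership matrix
   (column order = significance rank; both knobs configurable).
2. **Survival filter** — keep genes with hazard ratio > 1 and
   p < 0.05, both strict; genes without statistics are excluded with a
   warning, never silently passed.
3. **Proliferation signature** — samples of an expression cohort are
   scored as the mean z-score (ddof = 1; median variant by flag) over
   a 19-gene proliferation signature (MCM/cyclin/E2F1/PCNA/MKI67
   family); any gene's expression can then be tested for Pearson
   correlation with the score (correlation, least-squares slope,
   two-sided p).

Each stage's output is a subset of its input and stages are
idempotent; a stage whose table is missing is skipped with an explicit
notice in the report.

## Guide quantification

Reads are assigned by exact spacer matching: at each candidate start
position the 18-mer window is tried, then the 17-mer, first hit wins;
candidate positions are a configured offset ± a shift window (on-target
offset first), or every position left-to-right in SCAN mode. Matching
is case-insensitive, gzip input is detected by magic bytes, reads too
short for the window are unassigned (not errors), and a truncated FASTQ
quartet is reported with its record number. No mismatch tolerance is
offered: with unique 17–18-mers, exact matching is deterministic and
conservation (assigned + unassigned = total) holds by construction.
The spacer's offset within the sequenced amplicon depends on the vector
and trimming, so it is a user parameter with SCAN as the fallback.

## The synthetic screen generator

The generator emulates the study design at configurable scale: classes
of neutral, common-essential, 2D-exclusive-essential and
3D-exclusive-essential genes with 10 guides each, 750 + 750 safe and
non-targeting controls (scaled down in tests), duplicate samples at
days 0/7/14 in both conditions, ~1000 cells/guide plating coverage.

Per guide *i* with per-day log2 fitness effect f_ic in condition c:

* baseline library abundance a_i ~ log-normal(0, 0.25);
* each (condition, replicate) lineage is plated once at day 0 through
  a multinomial bottleneck of `coverage × n_guides` cells; all of the
  lineage's timepoints are sampled from that plated population,
  mirroring a dish seeded once and harvested repeatedly;
* expected relative abundance at day t ∝ cells_i · 2^(f_ic · t),
  renormalized to sum to 1 (competitive growth: share lost by depleted
  guides accrues to the rest, which makes control-centred scoring
  non-trivial);
* reads are Poisson around `depth × n_guides × p_i × g_i`, where
  g_i ~ Gamma(1/φ, φ) with mean 1 is a guide-specific amplification
  propensity and φ the configured dispersion (default 0.1). Marginally
  each count is negative binomial with dispersion φ. Because
  amplification efficiency is a property of the spacer sequence, the
  factor persists across samples: it inflates the spread of counts
  without corrupting within-guide fold changes. Per-sample
  overdispersion sources such as PCR jackpotting are deliberately not
  modelled (see limitations).

Essential effects are heterogeneous between guides,
f ~ Normal(effect, effect_sd) truncated above at 0, with defaults
effect = −0.4 log2/day and effect_sd = 0.15. The default effect
corresponds to a deep dropout (≈ 1/7 relative abundance by day 7);
effect_sd = 0.15 gives most guides of an essential gene a strong
phenotype and a minority a weak one, exercising the ≥3-guides-dropped
gate. Multiplicity of infection and antibiotic selection are not
simulated: the post-selection library is the day-0 state, as in the
screening protocol the design follows.

`evaluate_recovery` scores a partition against the ledger: each truth
class maps to one expected label (neutral→none, common→shared,
2D→2D-exclusive, 3D→3D-exclusive) and sensitivity / specificity /
precision are tallied per class, alongside the full confusion table.

### What passing tests do and do not show

The generator reproduces the *structure* of a pooled screen —
competitive renormalization, plating bottleneck, count overdispersion,
guide-potency heterogeneity, control-guide anchoring — but not every
noise source of real data: PCR jackpotting, guide synthesis errors,
Cas9-activity dropout, batch effects between timepoint harvests and
condition-specific growth-rate differences are absent. Recovery rates
near 100% at the default settings therefore demonstrate correctness of
the scoring and calling logic under the modelled noise, not expected
performance on real screens, where replicate-to-replicate log2FE
spread is typically larger and hit lists correspondingly noisier. The
dispersion default is chosen for test discrimination, not as a claim
about any particular dataset.

## Numerical choices and problem sizes

* Pseudocount 0.5; size-factor fallback threshold 100 eligible guides;
  medians use the midpoint convention; sample variances use ddof = 1.
* Guides in the library but missing from a count file are an error
  (zero-filling masks quantification bugs) unless explicitly permitted.
* Scores are NaN, never silently dropped, when undefined; genes whose
  guides all lack finite enrichment are excluded and listed.
* Test and acceptance runs use reduced-scale screens — 160 genes
  (100 neutral + 20 per essential class), 10 guides/gene, 50 + 50
  controls, depth 500, two replicates — chosen so the whole suite and
  the acceptance script each complete in seconds while keeping every
  design feature (both conditions, three days, duplicates, both
  control classes) present.

## Known limitations

* The pooled-S_var phenotype score is implemented as defined, not as a
  calibrated test statistic; its null distribution is not standard
  normal and no FDR machinery is attached.
* Exact-match quantification undercounts libraries with sequencing
  error rates high enough to corrupt 17–18-mers at meaningful rates.
* The prioritization stages trust their annotation inputs; pathway
  ranking, survival fitting and cohort curation are upstream concerns.
* The library model permits genes with fewer than 10 guides (real
  libraries are not perfectly balanced); single-guide genes get no T.
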