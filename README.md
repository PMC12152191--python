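# dropout3d

Analysis of pooled CRISPR knockout **dropout screens run in parallel in
2D and 3D growth conditions**, built for the question: *which genes does
a cell need to grow in 3D culture that it does not need in 2D?* Genes
in that set are candidate drivers of transformation-like growth and
attractive early-therapy targets, because most normal cells grow in 2D
but rarely in 3D.

The package takes a guide library (17–18 nt spacers, ~10 sgRNAs/gene,
safe + non-targeting controls), a sample sheet (condition × day ×
replicate) and either FASTQ files or a guide × sample count table, and
produces control-normalized guide effects, gene phenotype scores,
per-comparison dropout calls, a condition-exclusivity partition, and a
prioritization of hits against pathway and patient-survival
annotations. A synthetic-screen generator with a ground-truth ledger
makes the whole pipeline testable without any sequencing data.

## The score

For each comparison (day 7 or 14 vs day 0, per condition), counts are
normalized by median-of-ratios size factors and each guide gets a
replicate-averaged log2 fold enrichment. Guide effects are centred on
the negative controls,

```
pZ(g)  = log2FE(g) − median(log2FE of safe ∪ non-targeting guides)
U_gene = median pZ over the gene's guides
```

and the gene phenotype score pools guide and control variability:

```
S_var = Var_gene·(N_exp − 1) + Var_ctrl·(N_ctrl − 1)
T     = (U_gene − U_ctrl) / sqrt(S_var/N_exp + S_var/N_ctrl)
```

with N_exp the gene's guide count and N_ctrl the screen's average
guides-per-gene. A gene is called a **dropout** when U_gene < −0.1 and
≥ 3 of its guides have pZ ≤ −0.1; genes called in 3D on both days but
in neither 2D comparison are **3D-exclusive** (and symmetrically for
2D; genes called everywhere are shared essentials). See
`docs/methods.md` for definitions, assumptions and limitations.

## Worked example

```python
from dropout3d import (ScreenModel, SimConfig, evaluate_recovery,
                       simulate_library, simulate_screen)

config = SimConfig(n_neutral=40, n_common_essential=8, n_2d_essential=8,
                   n_3d_essential=8, n_safe=40, n_nontargeting=40, seed=42)
library, truth = simulate_library(config)
counts, design = simulate_screen(library, truth, config)

results = ScreenModel(counts, library, design).fit()
print(results.summary())
```

```
Pooled CRISPR dropout screen — phenotype scoring
====================================================
guides: 720  (targeting 640, controls 80)
genes: 64   samples: 12
pseudocount: 0.5   paired: True   welch: False

comparison       n_genes   u_ctrl  var_ctrl  n_ctrl    med u    med T
---------------------------------------------------------------------
2D_D7_vs_D0           64   -0.000    0.0039   10.00   -0.005   -0.042
2D_D14_vs_D0          64    0.000    0.0037   10.00   -0.003   -0.023
3D_D7_vs_D0           64    0.000    0.0052   10.00   -0.010   -0.081
3D_D14_vs_D0          64    0.000    0.0047   10.00   -0.014   -0.110
```

The control median (u_ctrl) is zero in every comparison by
construction; the slightly negative median U and T reflect the 24
truly essential genes among the 64. Calling dropouts and checking the
result against the simulator's ledger:

```python
calls = results.call_dropouts()
print(calls.label_counts())
metrics = evaluate_recovery(calls.partition, truth)
print({k: round(v, 2) for k, v in metrics.sensitivity.items()})
print(sorted(calls.genes("3D_exclusive"))[:4])
```

```
{'3D_exclusive': 8, '2D_exclusive': 8, 'shared': 8, 'other': 0, 'none': 40}
{'neutral': 1.0, 'common_essential': 1.0, 'essential_2D': 1.0, 'essential_3D': 1.0}
['ESS3D0001', 'ESS3D0002', 'ESS3D0003', 'ESS3D0004']
```

All eight 3D-essential spike-ins land in the 3D-exclusive class, all
eight common essentials in the shared class, and no neutral gene is
called — the partition recovers the ground truth exactly at this noise
level. Hits would then flow into the annotation cascade
(`dropout3d.cascade`): pathway-membership filter (≥ 9 of the top 20
ranked pathways), then survival filter (HR > 1, p < 0.05), with an
expression cohort scored against the built-in 19-gene proliferation
signature for correlation checks.

The same workflow is available from the shell:

```
dropout3d simulate --config sim.yaml --out screen/
dropout3d score    --counts screen/counts.tsv --library screen/library.tsv \
                   --samples screen/samples.tsv --out screen/scores/
dropout3d call     --counts screen/counts.tsv --library screen/library.tsv \
                   --samples screen/samples.tsv --out screen/calls/
dropout3d count    --library lib.tsv --offset 10 --out counts.tsv s1=reads1.fq.gz
```

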