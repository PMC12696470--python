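# soytol

Dual-method saline-alkaline tolerance evaluation for crop cultivar panels,
coupled to transcriptome-based candidate-gene discovery.

Saline-alkaline soils (high NaCl plus NaHCO3, elevated pH) stress
glycophyte crops such as soybean. Breeders screen cultivars by measuring a
panel of physiological indicators — antioxidant enzymes (SOD, CAT, POD),
soluble protein (SP), total antioxidant capacity (AOC), and the damage /
osmolyte markers MDA and proline (Pro) — under control and stress
conditions, then rank the cultivars by a composite of the indicator
*change rates*. `soytol` implements that evaluation model and the
downstream molecular pipeline for whoever wants to run it on their own
panel or study its statistical behaviour on simulated data.

## The model

For cultivar *i* and indicator *j*, the change rate is
x_ij = (mean stress − mean control) / mean control. Change rates are
min–max standardized with direction handling:

- positive indicators (SOD, CAT, POD, SP, AOC):
  X_ij = (x_ij − min_j) / (max_j − min_j)
- negative indicators (MDA, Pro), whose smaller change indicates
  tolerance: X_ij = (max_j − x_ij) / (max_j − min_j)

Two rankings are computed from the same standardized matrix and
cross-validated against each other:

1. **Membership-function composite** — U_ij = X_ij, comprehensive value
   u_i = Σ_j w_j U_ij with equal weights by default (entropy weights
   w_j ∝ 1 − e_j, e_j the column's normalized Shannon entropy, are an
   option).
2. **TOPSIS** — relative closeness C_i = D_i⁻ / (D_i⁺ + D_i⁻) to the
   per-column ideal A⁺ = (max_j X_ij) and anti-ideal A⁻ = (min_j X_ij),
   with Euclidean distances.

Concordance between the two orderings is reported as closed-form Spearman
ρ = 1 − 6Σd²/(n(n²−1)) on the permutation ranks, Kendall τ, and the count
of rank reversals.

Downstream, an expression study (gene × sample FPKM-like matrix over
cultivar × tissue groups) is processed by:

- threshold differential expression per group (log2 Welch t-test,
  Benjamini–Hochberg FDR; a DEG has linear fold change > 1.5 and
  FDR < 0.05) and the cross-group Venn intersection yielding the *shared*
  gene set;
- a from-scratch weighted co-expression core: soft-threshold selection by
  the scale-free topology fit index, unsigned adjacency |cor|^β,
  topological overlap (TOM), average-linkage module detection with a
  minimum module size of 30 and eigengene merging at similarity 0.25,
  module eigengene–trait correlation, and top-30 intramodular-connectivity
  hub (core) genes;
- **candidate genes**: hub genes of trait-linked modules that are also in
  the shared differential set.

A seeded synthetic-data module (`soytol.simulate`) generates physiological
panels with a planted tolerance gradient and expression studies with
planted modules, DEG sets and hub genes, so every stage is testable with
known ground truth.

## Worked example

Run the fully simulated demonstration study (9 cultivars × 7 indicators ×
3 replicates; 1000 genes over 4 cultivar × tissue groups with three
trait-linked modules, 39 shared DEGs and 13 planted hub-and-shared
candidates):

```python
from soytol.pipeline import demo_config, run_pipeline
report = run_pipeline(demo_config(seed=1, out_dir="demo"))
print(open("demo/report.txt").read())
```

prints

```
soytol pipeline report
seed: 1  config hash: daf6fd154ee4847e

tolerance ranking (membership): cv09 > cv08 > cv07 > cv06 > cv05 > cv04 > cv03 > cv02 > cv01
tolerance ranking (TOPSIS):     cv09 > cv08 > cv07 > cv06 > cv05 > cv04 > cv03 > cv02 > cv01
concordance: rho=1.0000 tau=1.0000 reversals=0

DEGs per group: QN52_above: 80up/80down, QN52_below: 80up/80down, JD49_above: 80up/80down, JD49_below: 80up/80down
shared DEGs: 39

soft power: 20; modules: {1: 121, 2: 121, 3: 121, 4: 121, 5: 60, 6: 50, 7: 40} (unassigned: 366)
trait-linked modules: [2, 3, 5, 6, 7]
candidate genes (13): g00001, g00002, g00003, g00004, g00005, g00061, g00062, g00063, g00064, g00111, g00112, g00113, g00114
```

Reading the output: the two ranking methods both recover the planted
tolerance gradient (cv09 most tolerant) with zero reversals at this low
noise level. Each of the four groups yields its planted 80 up- and 80
down-regulated genes, and the four-way intersection is exactly the planted
39-gene shared set. Module detection finds the three planted co-expression
modules (60/50/40 genes; labels 5–7 after size-ordering, behind four
condition-contrast modules formed by the group-specific DEG blocks), and
the hub ∩ shared intersection returns exactly the 13 planted candidate
genes. The same stages are available individually from the `soytol` CLI
(`simulate`, `physiology`, `rank`, `deg`, `coexpress`, `candidates`,
`validate`, `run`) and as library functions.

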