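# extraqc

Quality control and protocol ranking for **intracellular-metabolomics
extraction benchmarks** measured with targeted quantification kits.

When the same biological material is extracted with several solvent
protocols and quantified on a targeted panel (hundreds of metabolites
across small-molecule and lipid classes, each with its own limit of
detection), the practical questions are: *which protocol detects the most
metabolites, how repeatable are its yields, and which protocol is optimal
for a given metabolite or class?*  `extraqc` answers them from the
quantification export alone, for benchmark designs of the form
tissues x extraction protocols x replicates.

## What it computes

For each tissue-by-protocol group:

* **Above-LOD coverage** — a metabolite counts as detectable when at least
  2 replicates have a valid concentration above its LOD; counts are
  reported per metabolite class and summarised per tissue as
  median/range across protocols.
* **Replicate repeatability** — the coefficient of variation
  CV = sd/mean per metabolite across replicates; groups are summarised by
  the number of metabolites with CV < 30% and by median ± MAD of the CVs.
* **Sum of concentrations (SOC)** — the per-replicate total concentration
  and its CV, a single global repeatability/efficiency figure.  Units
  (pmol/10^6 cells vs pmol/mg) are never pooled; tissue masses can be
  compared to cell inputs via `mass_to_cell_equivalents` (e.g. 30 mg of
  liver at hepatocellularity (139 ± 25)·10^6 cells/g ≙ (4.17 ± 0.75)·10^6
  cells).
* **Variance structure** — metabolites below LOD everywhere are dropped,
  zeros replaced by 120% of the smallest measured value, data
  log2-transformed and Pareto-scaled, then decomposed by PCA; each
  component is tested for association with tissue, protocol and per-solvent
  indicators (Kruskal–Wallis, Benjamini–Hochberg across the whole table,
  significant if adjusted p < 0.05).
* **Optimal protocols per metabolite** — one-way ANOVA on log2
  concentrations over protocols, Tukey HSD post-hoc (Tukey–Kramer for
  unbalanced groups), compact letter display, and the *optimal set*: the
  top-median protocol plus every protocol not significantly lower.
  Counting optimal-set membership over metabolites ranks the protocols per
  tissue.

A synthetic-data module generates benchmark-shaped datasets (default: 630
metabolites in 23 classes, 4 tissues x 10 protocols x 3 replicates, tissue
as dominant variance factor, solvent-driven lipid effects, LOD censoring at
a known quantile) with a ground-truth effect table, so every stage is
testable without any external download.

## Worked example

```python
from extraqc import SyntheticSpec, generate_dataset
from extraqc.qc_metrics import count_above_lod, summarize_above_lod
from extraqc.preprocess_pca import preprocess, run_pca, associate_components
from extraqc.ranking import rank_protocols

dataset, truth = generate_dataset(SyntheticSpec(n_metabolites=60, seed=11))
print(summarize_above_lod(count_above_lod(dataset)))

matrix = preprocess(dataset)
pca = run_pca(matrix, n_components=10)
assoc = associate_components(pca, dataset.samples, protocols=dataset.protocols)
print(assoc[assoc.significant].sort_values("p_adjusted").head(4))

print(rank_protocols(dataset, "liver").head(4))
```

prints (60 metabolites, 120 samples):

```
     tissue  median  min  max
        HEK    43.0   41   51
       HL60    41.5   37   50
bone_marrow    37.0   32   47
      liver    40.0   36   50

component       factor  statistic      p_value   p_adjusted  significant
      PC2       tissue 111.421983 5.423702e-24 5.423702e-22         True
      PC1       tissue 107.474601 3.835005e-23 1.917503e-21         True
      PC3       tissue 103.327824 2.991166e-22 9.970555e-21         True
      PC4 solvent_MeOH  82.068209 1.314703e-19 3.286758e-18         True

protocol  n_metabolites_optimal  n_metabolites_top_median
     P02                     49                        14
     P01                     49                         8
     P08                     48                         9
     P07                     47                        12
```

Reading it: every tissue detects roughly 32–51 of the 60 simulated
metabolites depending on protocol; the leading principal components are
tissue-driven (as generated), with a methanol-solvent signature on PC4; and
the isopropanol/MTBE protocols (P01/P02, P07/P08) top the liver ranking —
each is in the optimal set for ~49 of 60 metabolites — matching the
generator's solvent-polarity effects.

The same pipeline is available from the shell:

```bash
extraqc simulate --seed 42 --out-dir sim/          # wide.csv, long.csv, truth.csv
extraqc parse --input sim/wide.csv --out long.csv  # MetIDQ-style wide -> tidy long
extraqc qc   --input long.csv --out-dir qc/
extraqc pca  --input long.csv --components 10 --out-dir pca/
extraqc rank --input long.csv --tissue liver --out-dir rank/
extraqc report --out-dir report/ --seed 42         # full bundle + report.md + manifest.json
```

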