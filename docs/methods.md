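# Methods

## Scope and data model

`extraqc` evaluates intracellular-metabolite **extraction protocols** from
targeted-quantification exports. An input dataset is a samples-by-metabolites
concentration matrix with three annotation layers: a per-cell measurement
status flag (valid, below LOD, below/above the quantification limits,
invalid, not measured), a per-metabolite class and limit of detection (LOD),
and per-sample design metadata (tissue, protocol, replicate index, unit
basis). The benchmark design the package targets is a full cross of sample
types x extraction protocols with a small number of replicates (typically
3), spanning a 630-metabolite panel in 23 classes (14 small-molecule + 9
lipid classes after the vendor-side merges of lyso-/phosphatidylcholines
into glycerophospholipids and the three glycosylated ceramide classes into
glycosylceramides).

Two unit bases coexist — pmol per 10^6 cells for cell suspensions and pmol
per mg for tissue inputs. Units are carried as metadata and never converted
implicitly; any computation that would pool concentrations across bases
raises. The one sanctioned bridge is `mass_to_cell_equivalents`, which turns
a tissue input mass into a cell-count equivalent via a cellularity figure
(cells per gram): 30 mg of liver at a hepatocellularity of (65–185)·10^6
cells/g corresponds to (1.95–5.55)·10^6 cells, or (4.17 ± 0.75)·10^6 at
(139 ± 25)·10^6 cells/g, with the sd propagated linearly.

Censored measurements keep their exported numeric value (which may be 0)
together with their status flag; each analysis stage applies its own
censoring rule. This accommodates both export dialects (zeros vs
measured-but-flagged values) without loss at parse time.

## QC metrics

**Above-LOD coverage.** A record is *detectable* when its status is valid
and its concentration strictly exceeds the metabolite's LOD; a metabolite is
*above LOD* in a tissue-by-protocol group when at least `min_above`
(default 2) replicates are detectable. The per-record criterion combines
the exported flag with a concentration/LOD comparison so dialects without
status flags degrade gracefully. Coverage is reported per class (stacked
composition) and summarised per tissue as median and range across
protocols.

**Replicate CV.** The coefficient of variation uses the sample standard
deviation (n−1) over the mean on the raw concentration scale — a CV on
log-transformed data would not be a coefficient of variation. CVs of
replicate vectors with zero mean or fewer than two entries are undefined
and reported missing (excluded from counts and medians, with a warning).
Group summaries are the count of metabolites with CV below a threshold
(default 0.30) and median ± MAD of the CV distribution; the MAD default
uses the normal-consistency constant 1.4826 (the R `mad()` convention the
upstream analysis ecosystem uses), with `mad_scale=1` available for the
plain MAD. Histograms can be restricted to above-LOD metabolites; including
censored metabolites mainly populates the high-CV tail.

**Sum of concentrations (SOC).** The per-replicate total concentration and
its CV across replicates give a single global repeatability/efficiency
figure per group. Default censoring is `valid_only`; `all_measured` (every
exported value except not-measured cells) is exposed because the literal
"sum over all concentrations" reading is defensible, but summing below-LOD
noise is rarely meaningful.

## Preprocessing and PCA

Fixed order: (1) drop metabolites below LOD in *every* group present;
(2) replace zeros by 1.2x the smallest positive value of that metabolite
("measured" is read as "positive" — including zeros would make the rule
vacuous); (3) log2; (4) Pareto scaling (centre, divide by sqrt of the n−1
standard deviation; constant columns become zeros with a warning).

PCA is an SVD of the preprocessed matrix with no further standardisation.
The sign of each component is fixed by requiring its largest-magnitude
loading to be positive, making scores and loadings reproducible across
backends and row orderings. Explained-variance fractions are s_i^2 / Σs^2.
Top-loading rankings (default k=15 per component) break ties
lexicographically by metabolite id.

Component-factor association uses the Kruskal-Wallis test (tie-corrected H,
chi-squared p with k−1 df) of component scores grouped by each factor:
tissue, protocol, and one binary contains/doesn't indicator per solvent tag
taken from the protocol descriptors. Benjamini-Hochberg correction is
applied jointly across the whole component-by-factor table, restricted to
the first 10 components; joint correction is the conservative choice given
the table is inspected as a whole. Significance means adjusted p < alpha
(default 0.05). Constant factors are skipped with a warning. A caveat worth
knowing: a solvent present in only one protocol of a single-tissue design
yields a 3-vs-27 group split whose Kruskal-Wallis p-value cannot reach
table-wide significance; solvent-level conclusions need the multi-tissue
design (12-vs-108 splits in the full 4-tissue benchmark).

The H statistic, ANOVA F and BH adjustment are implemented in-package (they
are the package's explicit numerical contract) and are cross-checked in the
test suite against scipy and statsmodels to 1e-10 on randomised inputs.

## Protocol ranking

Per metabolite and tissue, protocols with >= 2 above-LOD replicates enter a
one-way ANOVA on log2 concentrations; metabolites with fewer than two
eligible protocols are reported "not rankable" with the reason. Post-hoc
all-pairs comparisons use Tukey's HSD with the Tukey-Kramer standard error
for unequal group sizes (censoring makes imbalance routine); p-values come
from the studentized-range distribution at (k, N−k). The significance
pattern is converted to a compact letter display by the standard
insert-and-absorb construction — groups share a letter iff not
significantly different — with letters assigned in order of descending
group median, so `a` always marks the best group. The **optimal set** is
the top-median protocol plus every protocol sharing a letter with it.
Medians are reported on the raw concentration scale (the argmax is
unchanged by the monotone log2). The tissue-level ranking counts, per
protocol, the metabolites whose optimal set contains it, tie-broken by
top-median counts then label. Alpha defaults to 0.05 and is configurable;
no correction is applied across metabolites (each metabolite is a separate
question), which should be remembered when reading cross-metabolite counts.

## Synthetic benchmark generator

The generator produces study-shaped datasets with known ground truth:

    log2 C(m,t,p,r) = mu_m + tau_{m,t} + pi_{p,class(m)} + eps

* `mu_m` uniform on `baseline_log2_mean_range` (default (−4, 14) log2 pmol,
  matching the several-orders-of-magnitude spread of real targeted panels);
* `tau ~ N(0, tissue_effect_sd)` (default 2 log2 units — tissue is the
  dominant variance factor), drawn once per metabolite-tissue pair;
* `pi` deterministic class-specific protocol effects; the default gives
  apolar-solvent protocols (IPA/MTBE) +1 log2 unit on lipid classes and
  methanol-containing protocols −0.75, a caricature of solvent polarity
  driving lipid recovery; small-molecule classes are solvent-insensitive;
* `eps ~ N(0, replicate_sd)` (default 0.5 log2 units).

Defaults mirror the benchmark design: 630 metabolites apportioned to the 23
classes by largest-remainder rounding (242 triacylglycerols, 90
glycerophospholipids), 4 tissues x 10 protocols x 3 replicates, the liver
tissue on the per-mg unit basis. Each metabolite's LOD is placed at the
exact `lod_quantile` (default 0.25) of its marginal concentration
distribution — an equal-weight mixture of normals over protocols on the
log2 scale, solved by bisection — so the expected censoring fraction equals
the quantile by construction. Below-LOD values keep their true magnitude
and are flagged, exercising the downstream-censoring contract. Output is
deterministic given the spec seed (independent substreams for baselines,
tissue effects and noise).

What the generator does **not** emulate: correlated metabolite panels
(covariance beyond the shared tissue effect), heteroscedastic replicate
noise near the LOD, batch/plate effects, missing-not-at-random censoring,
or isobaric-lipid summing. Tests passing on this generator therefore
demonstrate the pipeline's decision logic and statistical behaviour under a
clean factorial model, not robustness to those real-data pathologies.

## Problem sizes in tests and acceptance

The test suite and `scripts/acceptance.py` run the stochastic checks at
deliberately modest sizes chosen to exercise the claims without waste:
parameter recovery and null calibration on 200 metabolites (10 protocols x
3 replicates, replicate sd 0.5; recovery at a +4 log2 effect, null at 0);
association power on 100 seeded datasets of 30 metabolites under the full
4-tissue design; permutation calibration with 100 label shuffles; kernel
cross-checks on 1000 random instances. The Tukey step dominates runtime
(each studentized-range evaluation costs milliseconds), which is why the
full 630-metabolite default spec is used for generator-level checks but not
inside the ANOVA loops.

## Numerical and interface choices

* Percentages in composition tables are rounded half-up to one decimal
  (Decimal arithmetic, not banker's rounding).
* Long-table CSV is the canonical exchange format; write-then-read is the
  identity on valid datasets (tested across seeds). Wide exports accept CSV
  and XLSX with a companion status table; absent flags are inferred by the
  concentration/LOD comparison.
* Number parsing is locale-independent (decimal point only; thousands
  separators are a format error).
* All tabular outputs are deterministic: fixed sort orders, fixed float
  `repr`, LF line endings; same config + seed gives byte-identical files.
* The report manifest echoes the fully-resolved config, its SHA-256, the
  seed, and library versions, so any output can be traced to its inputs.
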