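# Methods

`cernet` infers lncRNA-associated competing-endogenous-RNA (ceRNA) structure
from tumour/normal expression cohorts and interaction tables, and carries the
result through dense-cluster detection, regulatory-axis reporting, and
survival / immune-infiltration association.  This note records the models,
the parameters that matter, the numerical conventions, and what the bundled
simulations do and do not demonstrate.

## The ceRNA model and the triple criteria

Under the ceRNA hypothesis a lncRNA sequesters a shared miRNA and thereby
de-represses that miRNA's mRNA targets.  The observable signature is a
*triple* (L, M, G): lncRNA L and mRNA G differentially expressed in the same
direction and positively co-expressed, with miRNA M differentially expressed
in the opposite direction and linked to both by interaction evidence.

A triple is emitted when all of the following hold:

1. **Co-expression.**  Pearson r(L, G) > `r_min` (default 0.8, strict) with
   p < `corr_alpha` (default 0.05), computed over tumour samples by default
   (`corr_samples: all` uses the whole cohort).  The p-value is the two-sided
   t transform, t = r sqrt(n-2)/sqrt(1-r^2) on n-2 df.  No multiplicity
   correction is applied across the pair space: the screen is a gate, not an
   inference, and the r > 0.8 requirement dominates it at any realistic n.
2. **Interaction evidence.**  An L-M row in the lncRNA-miRNA table (both
   confidence tiers accepted) and an M-G row with prediction score
   >= `score_min` (default 0.95, inclusive).  Both ends of each row must be
   differentially expressed with opposite directions.  The strict/inclusive
   boundary split (r strictly above 0.8, score at least 0.95) is deliberate
   and tested.
3. **Direction class.**  L and G share a direction, opposite to M; triples
   split into an "up" network (L up, M down, G up) and the mirror "down"
   network.

The two networks are merged into one tripartite graph (lnc-mi and mi-mRNA
edges only; no isolated nodes can arise).  Hubs are the top decile of nodes
by degree: k = ceil(0.10 * n) and every node tying the k-th largest degree is
included — an inclusion-favouring, deterministic tie rule.

## Differential expression

Counts are filtered (count >= 10 in at least min(group sizes) samples,
boundaries inclusive), transformed to log2 counts-per-million with a prior
count of 0.5, and tested per feature with a Welch two-sample t
(Satterthwaite df).  mRNA/lncRNA calls use Benjamini-Hochberg adjusted
p < 0.05; miRNA microarray matrices (already log2) use raw p < 0.05 by
default (`mirna_adjust: BH` available).  Both use |log2FC| > 1.  This stage
deliberately does not reproduce voom/limma moderated statistics: the
package's claims concern the pipeline logic downstream of the DE contract,
and the stage is pluggable behind the `DERecord` record type.  TMM-style
normalization factors are likewise omitted (plain CPM): the simulated
cohorts have no composition bias.  Zero-variance features with equal group
means get p = 1; with unequal means, p = 0.

## MCODE

Implemented from the algorithm's definition.  Vertex weight = k x density of
the highest k-core of the closed neighbourhood N[v] (density = 2E/(n(n-1));
isolated vertices weigh 0).  Complexes grow breadth-first from the
highest-weight unvisited vertex, admitting a neighbour once per complex when
its weight exceeds seed_weight x (1 - node_score_cutoff), to depth
`max_depth`; complexes are vertex-disjoint in assignment order.
Post-processing: haircut reduces a complex to its 2-core (on by default),
fluff is off by default, and complexes that lose their seed or never reach a
`k_core`-core are discarded.  Complex score = density x size.  All ties —
seed order, neighbour order, equal scores — break lexicographically by id,
so results are deterministic.

One parameter needs comment: the conventional "node score cutoff" is a
fraction in [0, 1] (plug-in default 0.2), but published parameterizations
sometimes print it as ">= 2", which is not a valid fraction.  The `paper`
preset uses 0.2; any fraction can be set in the config.  The PPI edge list
is filtered at confidence >= 0.4 on ingest, and clustering runs on the
subgraph induced by the DEmRNAs present in the merged ceRNA network.

## Seed subnetwork and critical molecules

MCODE seed genes are mapped back into the merged network.  The extracted
subnetwork keeps seed mRNAs, miRNAs adjacent to a seed, and lncRNAs that
reach a seed through such a miRNA.  By default an axis L -> M -> G(seed)
must descend from a fully assembled triple — the ceRNA claim is triple-level
— while `edges_only` reproduces the laxer two-edge reading (any L adjacent
to a kept M).  Extraction is idempotent.  The critical set is the exact
intersection of the degree hubs with the subnetwork's nodes.  A packaged
JSON fixture carries a published GBM example (two 25-node lists whose
printed intersection has 9 molecules, and three named MS4A6A axes) so the
worked example runs offline.

## Survival and infiltration

Tumour samples are dichotomized at each gene's median expression (ties at
the median go to the low group; an all-equal vector is a degenerate-input
error).  Groups are compared with (a) the two-group log-rank test —
(sum O1-E1)^2 / sum V over distinct event times with the hypergeometric
variance, chi-square on 1 df — and (b) a univariate Cox proportional-hazards
fit maximizing the Efron partial likelihood by Newton's method (damped
steps, 50-iteration cap; a diverging coefficient is flagged as possible
complete separation).  Efron rather than Breslow tie handling because it is
more accurate at these cohort sizes.  On tie-free data the Cox score test at
beta = 0 equals the log-rank statistic, checked numerically to 1e-6.

Gene-infiltration association is Spearman's rank correlation against each of
24 immune cell-type scores (Pearson available by flag), BH-adjusted across
cell types and reported in descending correlation order.  Spearman is the
default because deconvolution-style scores are bounded and non-normal.

## The synthetic cohort generator

The generator emulates the study design the pipeline targets: 169 tumour and
5 normal RNA-seq samples, with the miRNA matrix generated as Gaussian log2
intensity (microarray-like).  The miRNA matrix shares the cohort's samples;
a real design might profile miRNA in a separate small cohort (e.g. 3 vs 3),
which only makes the miRNA DE stage easier here — raw p < 0.05 at 3 vs 3 is
the harder test and is covered by the threshold configuration, not the
generator.

* **Counts** are negative binomial with common dispersion 0.2 around a base
  mean of 200, desk-scale feature universes (1200 mRNA, 300 lncRNA,
  150 miRNA), and a background DE fraction of 0.10 at |log2FC| = 2.
* **Planted axes** (12 by default, 6 up / 6 down) shift the lncRNA and mRNA
  by |log2FC| = 4 — the magnitude of the 16-fold changes reported for the
  axis molecules this pipeline is calibrated against — and the miRNA by the
  same amount in the opposite direction.  Co-expression is planted through a
  shared standard-normal per-sample factor added on the log2 scale in tumour
  samples; the loading lambda solves lambda^2/(lambda^2 + v) = r_target with
  v the log-count noise variance from the Poisson-Gamma representation,
  v = [trigamma(1/a) + 1/(mu(1-a))]/ln(2)^2 (exact enough that realized
  correlations centre on the 0.9 target).  The miRNA loads negatively on the
  same factor.
* **Interactions**: planted rows always emitted (mi-mRNA scores drawn in
  [0.95, 1]); decoys are Bernoulli draws at 0.02 over the remaining cross
  pairs with scores uniform in [0.5, 1].
* **PPI**: each planted cluster (default: one 8-clique over planted-axis
  mRNAs) is emitted as a clique at confidence 0.99, plus Erdos-Renyi
  background among non-cluster pairs.
* **Survival**: event times exponential with hazard baseline x HR^(above
  median of the prognostic gene), planted HR 1.48; censoring is an
  independent exponential time calibrated so the marginal censored fraction
  equals `censor_rate` (0.3).  An earlier uniform-before-event scheme was
  replaced: it is informative and biases the Cox estimate.
* **Infiltration**: macrophage scores load positively and neutrophil scores
  negatively on the prognostic gene; the other 22 cell types are pure noise.

Everything is a pure function of (config, seed); all randomness derives from
one root seed through named substreams.

**What passing tests show — and don't.**  Recovery of >= 90% of planted axes
with <= 5% decoys demonstrates that the gating logic, thresholds and joins
are implemented correctly under the stated noise model.  It does not
demonstrate that real cohorts satisfy that model: the generator has no
library-size heterogeneity, batch effects, composition bias, isoform
structure, or sequence-level target matching, and real interaction databases
have error modes decoy rows do not imitate.  Calibration results (log-rank
type-I error within [0.03, 0.07]; power > 0.9 at HR 1.48 with n = 2000) are
properties of the tests under exponential survival, not of any particular
dataset.

## Numerical conventions and degenerate inputs

* Pearson on a constant vector: error (undefined correlation).
* Median split with all values equal: degenerate-input error.
* Log-rank with no observed events or an empty group: error.
* Cox non-convergence in 50 iterations or |beta| > 15: `ConvergenceError`
  with the offending coefficient (complete separation manifests this way).
* BH adjustment is statsmodels' `fdr_bh`; k-core numbers are networkx's
  `core_number` (an independent peeling oracle checks both in the suite).
* Reports and tables are written with stable ordering and fixed float
  formats; two runs with the same config and seed are byte-identical.  The
  run report carries no wall-clock information (timings go to stderr logs).

## Problem sizes used by the checks

The bundled test and acceptance runs use the default cohort above
(~1 s per full pipeline run), 1000 replicate null cohorts of n = 100 and 100
replicates at n = 2000 for survival calibration, and 100-200 random
instances for the oracle-equivalence checks.  These sizes give binomial /
Monte-Carlo error comfortably inside every asserted band.

## Known limitations

* Welch-on-logCPM is less powerful than moderated-variance DE at tiny n; at
  3 normals per group, borderline features can miss the BH gate.
* The correlation screen is marginal Pearson; no partial-correlation or
  conditional-mutual-information ceRNA scoring (out of scope).
* MCODE's fluff option admits overlap and is off by default; overlap-allowing
  complex variants beyond fluff are not implemented.
* Survival analysis is univariate with right censoring only — no
  multivariable Cox, time-varying covariates, or competing risks.
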