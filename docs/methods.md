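# Methods

## Scope and design

The package implements a multi-level comparison of two two-condition
single-cell studies. Each analytical step that is a standard operation —
hypergeometric and chi-squared tests, multiple-testing adjustment, PCA and
k-means, betweenness centrality — is delegated to scipy, statsmodels,
scikit-learn, or networkx behind the module surface. The steps that carry the
comparison logic are authored here: the closed-form Poisson likelihood-ratio
test with library-size offset, the shared/contrasting/specific categorization,
signed-path perturbagen scoring, the ligand-target intersection, and the
coverage/concordance/Fisher overlap reports. Upstream cell-cell-communication
prediction models are deliberately not recomputed: their output tables are a
documented TSV interface, and the synthetic generator fabricates tables with
that schema.

## Differential expression model

Counts are modelled per gene as $y_i \sim \mathrm{Poisson}(\mu_i)$ with
$\log \mu_i = \beta_0 + \beta_1 g_i + \log N_i$, $N_i$ the cell's total raw
count. Both the alternative and the null ($\beta_1 = 0$) have closed-form
MLEs — the fitted rate per exposure unit is the group (respectively pooled)
count sum over the exposure sum — so the deviance difference reduces to
$2[S_d \log(\hat r_d/\hat r) + S_c \log(\hat r_c/\hat r)]$ and vectorizes
over genes. A statsmodels Poisson GLM with offset serves as an independent
oracle in the unit tests. Invariance notes: the statistic is exactly invariant
to a global rescaling of the exposures; scaling one group's exposures together
with its counts preserves the fitted rates and fold change but not the
statistic itself (more counts carry more information).

The fold-change estimator is $\log_2((m_d + 1)/(m_c + 1))$ on group means of
total-count-normalized expression; the pseudocount guards zero means and
matches common single-cell toolchain conventions. Genes must be detected in
more than 10 % of cells in at least one group to be tested (configurable);
all-zero genes are excluded and logged. Default adjustment is Bonferroni —
the procedure of the analyses this package mirrors, although those analyses
label the result "FDR" — with BH available; the column is named `p_adj` to
avoid the misnomer. Significance requires adjusted $p < 0.05$ and
$|\log_2\mathrm{FC}| > 0.1$.

The Poisson model ignores overdispersion and per-donor correlation
(mixed-effects and pseudobulk alternatives need more donors than the designs
this targets); the synthetic recovery tests quantify the consequences under
negative-binomial data: type-I error is calibrated (0.03–0.07 at the nominal
5 % level) when the data are Poisson, and modestly anticonservative under
overdispersion — which is why significance is always paired with the
fold-change threshold.

## Categorization

Categories partition the union of tested genes. Genes with
$0.05 \le p_{\text{nominal}} \le 0.5$ in the other study are left
unclassified rather than forced into a specific category (the three published
definitions are non-exhaustive); a zero fold change has no sign and likewise
falls to unclassified; genes tested in only one study are unclassified and
logged. Swapping the studies maps specific_A ↔ specific_B and fixes
shared/contrasting (tested property).

## Clustering and annotation

Clustering is a k-means scan over the top principal components of the
normalized layer with the number of clusters chosen by mean silhouette width
(ties to the smaller k) — the same validity index used to assess cluster
quality, replacing toolchain-bound iterative-resolution algorithms. The
silhouette is computed as $s(i) = (b-a)/\max(a,b)$ with Euclidean distances,
singletons scoring 0, coincident points scoring 0. Annotation scores each
cluster per cell type as the mean over member cells of
$\sum_{g \in \text{pos}} w_g z_g - \sum_{g \in \text{neg}} w_g z_g$ with
$w_g = 1/(\text{number of cell types listing } g)$ — a specificity weighting —
and gene-wise z-scores clipped to $\pm 10$ for numerical stability of
near-constant genes; score ties yield "Unknown". Fine labels can be merged
into broad categories (all neuronal subclusters → "Neurons") with counts
conserved and unmapped labels passing through with a warning.

## Network scoring

Sign propagation multiplies edge signs along simple paths; a node whose
distinct simple paths disagree is ambiguous and never counted. On acyclic
graphs every walk is a simple path, so the achievable sign products follow an
exact recurrence in topological order; cyclic graphs fall back to explicit
simple-path enumeration (intended for the small curated subnetworks this
analysis level works with). The perturbagen score of a node and direction is
the number of observed-sign nodes whose predicted sign opposes their observed
sign; ranking is by score, ties by node name. Betweenness is computed on the
directed unsigned skeleton with the standard $(n-1)(n-2)$ normalization;
hub and central flags use a configurable quantile (default 0.9) because "high
number of connections" has no canonical cut-off; attractors are nodes with
in-degree 0.

## Overlap statistics

Coverage is $100 \cdot |Q \cap R|/|Q|$, reported at full precision with a
round-half-up single-decimal renderer (11/130 → 8.5 %). Concordance compares
fold-change signs on the intersection, excluding zero signs. Overlap
significance is the one-sided (enrichment) Fisher exact test, equal to the
hypergeometric upper tail and symmetric in query and reference; GWAS overlaps
use the intersection of the DE-tested genes with the GWAS universe as
background. Post-mortem neuronal subtypes should be merged into one broad
group (via `merge_celltypes`) before comparison.

## Synthetic data generator

The generator emulates the paired two-study design at desk scale: per arm,
2,000 genes and 600 cells per condition across three cell types
(Neurons 300, Astrocytes 200, Other 100). Choices and what they emulate:

* **Counts**: negative-binomial via gamma-Poisson mixing, per-gene means
  log-normal (median-scale `baseline_mean` = 1.0 count/cell, $\sigma$ = 1),
  dispersion $\theta$ = 2 (variance $\mu + \mu^2/\theta$). One count per gene
  per cell over a 2,000-gene expressed panel matches the few-thousand-UMI
  libraries of the droplet and microwell platforms this mirrors. A dispersion
  above $10^6$ switches to exact Poisson sampling (used by the calibration
  tests).
* **Library size**: per-cell log-normal factor with CV 0.3, exercising the
  DE offset.
* **Planted effects**: `n_shared`/`n_contrasting`/`n_specific_A`/
  `n_specific_B` (defaults 40/40/20/20) genes have their disease-condition
  mean multiplied by $2^{\pm 1.0}$. Shared genes take the same sign in both
  arms, contrasting genes opposite signs, specific genes move in one arm
  only; the sign plan is derived from the seed alone so the two arms pair
  correctly. Planted genes are drawn from genes at or above the median
  baseline mean: an effect planted on a gene that is essentially never
  detected is not a recoverable DEG, and the recovery tests are about the
  method, not about undetectable genes.
* **Cell identity**: each type overexpresses a disjoint 30-gene marker block
  8-fold, giving separable populations for the clustering and annotation
  tests; markers are recorded as ground truth.
* **Mitochondrial content**: genes named `MT-*`; their means are rescaled per
  block so the expected mitochondrial library share is exactly
  `mito_expr_mean_frac` (default 3 %, the scale reported for organoid
  libraries), producing a realistic minority of cells above the 5 % QC cap.
* **Network**: an acyclic signed digraph built from a spanning backbone
  rooted at the planted regulator plus density-controlled extra edges;
  observed node signs are set anti-parallel to the regulator's down-modulation
  propagation, its ground-truth score is computed exhaustively at generation
  time, and the construction retries (seeded) until the single planted
  regulator is the strict top scorer.
* **References**: the post-mortem table contains a controllable fraction of
  the planted DEGs with controllable sign agreement plus non-planted decoys;
  the GWAS list is an independent draw; the GMT collection has one set
  sampled from planted DEGs and three null sets.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects (the mirrored datasets were single-batch), donor-level variance
components, gene-gene correlation beyond the planted programs, and realistic
pathway topology. Passing recovery tests therefore show that the pipeline
recovers planted structure under idealized independence — they do not certify
performance on real tissue data, where donor effects and correlated programs
widen error bands.

## Numerical and procedural choices

* Chi-squared composition tests are Pearson without continuity correction
  (the correction applies only to 2×2 tables and the mirrored statistic is
  uncorrected); any zero expected count is an error.
* Cells are retained when detected genes lie in [200, 8,000] and the
  mitochondrial percentage is strictly below 5 % (raw-count convention for
  the percentage); normalization is total-count scaling to 10,000 plus
  log1p, with raw counts preserved — downstream DE always uses raw counts.
* ORA sorts by (adjusted p, p, set name); rows with fewer than `min_mapped`
  (default 3; a value of 5 matches a stricter published table legend) query
  genes are dropped before adjustment. The ORA universe is the set of genes
  tested for DE in the corresponding analysis, not all annotated genes.
* The ligand/pair intersection defaults to the strict gene-level reading
  (top-ligand targets ∩ significant-pair genes) with an "augmented" switch
  that also admits the targets of ligands appearing in significant pairs —
  the published description is ambiguous between the two, so both are
  implemented and the selection is logged.
* Shared-pathway ranking uses the worse of the two adjusted p-values, ties by
  name — symmetric in the studies by construction.
* All randomness flows from a single seed through named, spawned generator
  streams; pipeline runs are byte-identical under a fixed seed (tested by
  checksum).

## Problem sizes

Defaults were chosen so a full pipeline run completes in seconds on one core:
2,000 genes × 1,200 cells per arm, a 30-node network, 100-instance oracle
sweeps in the tests. The calibration and recovery tests use 2,000 null genes
at 150 cells/group and 40/40/20/20 planted genes at 300 cells/group — the
sizes at which the stated precision/recall and type-I bands are evaluated.

## Known limitations

The Poisson test inherits single-cell pseudoreplication: cells, not donors,
are the unit of replication, so real-data p-values are optimistic. The
annotation scheme is a deliberate simplification of database-driven
annotators and needs curated marker lists. Perturbagen semantics
(simple-path products, ambiguity on conflict) are one consistent reading of
a method whose reference implementation is proprietary; scores on cyclic
graphs are exponential-time in the worst case. Real-data entry points
(MTX triplets, dense TSV) are provided but the cross-study pairing assumes
shared gene symbols and comparable cell-type labels across studies.
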