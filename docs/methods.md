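# Methods

This document records the statistical model, the encoding conventions, the
default parameters, the synthetic-generator design, and the known limitations
of `drivercall`.

## 1. Problem definition

The unit of classification is an altered `(sample, gene)` pair: a gene in a
tumor sample that carries at least one somatic mutation or a nonzero
gene-level copy-number call. Each pair is assigned one of `NEUTRAL`, `TSG`,
`OG` (or `DRIVER` in the binary variant). Pairs matched by no curated
resource remain `UNLABELED`; they are excluded from training and evaluation
and are the natural target of prediction.

## 2. Labeling strategies

| Strategy | Resource | Alterations considered | Classes |
|---|---|---|---|
| `MUTATION_EXACT_BINARY` | mutation-level driver list | mutations only | NEUTRAL / DRIVER |
| `MUTATION_EXACT_TSG_OG` | mutation-level driver list | mutations only | NEUTRAL / TSG / OG |
| `GENE_PAN` | gene-level catalog, PAN rows | mutations and CNV ≠ 0 | NEUTRAL / TSG / OG |
| `GENE_CANCER_SPECIFIC` | gene-level catalog, one cancer type | mutations and CNV ≠ 0 | NEUTRAL / TSG / OG |

Rules common to all strategies:

* Mutation-level driver records are used only if their evidence score is
  **strictly** greater than the threshold (default 15). Records with a missing
  evidence score are kept only when the list is declared pre-curated.
* An exact match requires gene, position, reference and alternate allele to
  agree (case-insensitive alleles). The *gene* is the classification unit: one
  exact match labels the pair even if the pair's other mutations match
  nothing; a same-gene mutation at a different position labels nothing.
* A pair matching both TSG- and OG-labeled driver mutations is set
  `UNLABELED` with a warning; at the gene level, genes tagged with both roles
  (dual-role) are excluded from both sets.
* Neutral-list genes are `NEUTRAL` under every strategy; genes appearing in
  both the neutral and a driver list are dropped from the neutral list loudly.
* Gene-level tags are matched case-insensitively against
  {`tsg`, `possible tsg`} and {`oncogene`, `possible oncogene`}; unknown tags
  are ignored with a warning.

## 3. Interaction network

Edges come from a STRING-style table with per-channel scores on a 0–1000
scale. An edge is retained iff `max(experimental, database) > 700`
(strictly); self-loops are dropped and symmetric duplicates collapsed. The
retained graph is undirected and **unweighted** — scores gate edge existence
but are never edge weights.

Per-gene statistics on this graph:

* degree;
* closeness with the Wasserman–Faust correction, so values are comparable
  across disconnected components;
* exact betweenness (Brandes) with the standard pair normalization;
* hop neighborhoods: the BFS ball of radius *n* (default 1) minus the gene
  itself.

Genes absent from the filtered network receive zero centralities and zero
neighborhood features rather than being dropped.

## 4. Expression model

### 4.1 Normalization

Counts are converted to counts-per-million using total library size as the
offset (no TMM or quantile step). A prior count of 0.5 is added inside all
logarithms. CPM normalization assumes the vast majority of genes are not
changed between conditions; see limitations.

### 4.2 Common dispersion (BCV)

Single-sample contrasts carry no replication, so a per-contrast dispersion is
not estimable. Instead one **common** negative-binomial dispersion φ is
estimated from the whole cohort under a two-group (tumor/normal) means model:
per gene and condition the mean rate is profiled out with the ratio estimator
q = Σy / ΣN (library sizes as offsets), and φ maximizes the summed NB
log-likelihood over all nonzero genes, via bounded 1-D search on log φ over
[10⁻⁶, 4] (tolerance 10⁻⁴ on log φ). BCV = √φ. Estimates at the search
boundary are flagged. The cohort φ is reused for every single-sample contrast,
including future samples scored against a frozen cohort model
(`phi_override`).

### 4.3 Single-sample differential expression

For tumor sample *t* and gene *g*:

* `logFC = log2(cpm_t + 0.5) − log2(mean normal cpm + 0.5)`
* `logCPM = log2(mean cpm over {t} ∪ normals + 0.5)`
* `is_deg = [|logFC| > τ]` with τ = 1 (two-fold) by default.
* A two-sided NB tail p-value of the tumor count against its pooled-normal
  expectation (dispersion φ) is exported for inspection but is **not** a
  model feature.

The paper-style thresholds "fold change > 2" and "|logFC| > 2" conflict; the
package exposes a single configurable τ on |logFC| with default 1.0
(two-fold). The RNA block has 11 features: `logFC`, `logCPM`, `is_deg`,
`degree`, `closeness`, `betweenness`, the three `logFC × centrality`
products, `neigh_FC`, and `neigh_normFC`. `is_deg` is included as an explicit
feature so the multi-omic column manifest is exactly
|SNV| + 11 + 2 + 1 + |miRNA| + 1.

### 4.4 Neighborhood features

With S(g) the 1-hop neighbors of g that have expression data and
|logFC| > τ in the sample:

* `neigh_FC = Σ_{v∈S} logFC_v`, `neigh_normFC = neigh_FC / |S|` (0 if S is
  empty);
* `neigh_CNV_FC` / `neigh_CNV_normFC`: the same sums restricted to neighbors
  with a nonzero copy-number call in the sample.

## 5. Mutation encodings

* **Type one-hot** over a fixed 9-type vocabulary (`missense`, `nonsense`,
  `frameshift_ins`, `frameshift_del`, `inframe_ins`, `inframe_del`, `splice`,
  `silent`, `other`); unknown consequence strings map to `other` loudly.
* **Ordinal predictions** per tool: the k-th category of the declared
  benign-to-damaging order maps to k; missing maps to **0**. So an ordinal is
  0 exactly when the raw prediction is missing — an invariant asserted in the
  tests.
* **Scores** are oriented so larger = more damaging (SIFT raw scores are
  flipped to 1 − s) before any aggregation, so "max" always keeps the most
  damaging evidence.
* **Aggregation** over a pair's multiple mutations: per-tool max (oriented)
  score, per-tool max ordinal, union of Pfam domains. The representative
  mutation type belongs to the mutation with the highest mean oriented score,
  ties broken by a fixed severity order (nonsense first).
* **Onco-domains**: binary bit per configured Pfam accession (defaults
  PF00870, PF00028), set if any mutation of the pair hits it.
* **Feature-set policies**: `all` keeps score columns but drops pairs whose
  score block has missing values (impact tools cannot score every mutation
  type and those scores cannot be imputed); `small` omits score columns and
  keeps every row. Hence |rows(small)| ≥ |rows(all)| always. The policy
  applies only to mutated rows: CNV-only rows in the multi-omic block are
  never dropped and carry a zeroed SNV block with `has_mutation = 0`.

## 6. Models and evaluation

Three from-scratch ensembles expose the scikit-learn API; each base estimator
trains on a class-balanced bootstrap (every class down-sampled with
replacement to the minority-class count, independently per estimator):

* `balanced_bagging`: bagged CART trees;
* `balanced_random_forest`: per-tree √p feature subsampling;
* `easy_ensemble`: AdaBoost learners (10 shallow trees each) per balanced
  resample.

The environment's package set does not include an off-the-shelf
imbalanced-ensemble library, and the balanced-bootstrap invariant is asserted
directly on the sampler, so the in-package implementation is both necessary
and more transparent.

Samples are split 70:30 (seeded permutation of the sorted sample list); all
pairs of a sample land on one side. Hyperparameter tuning (grid over
`n_estimators` × `max_depth`) uses stratified group K-fold grouped by sample —
stricter than pair-level CV, which would leak patients across folds — scored
by macro-F1 (driver-class F1 in the binary problem). Metrics are computed
from the confusion matrix; classes with zero support get NaN ("undefined")
rather than 0. One-vs-rest PR and ROC point sets are exported.

Controls:

* **Permuted labels**: retrain on uniformly permuted training labels, test
  labels untouched; honest F1 collapses toward chance.
* **Network randomization**: `node_label` permutes node identities;
  `degree_preserving` applies double-edge swaps (10×|E| attempts). The
  reported control is the mean held-out TSG/OG F1 over 3 independent
  randomized networks per mode; both modes must reduce F1 relative to the
  true network if network features genuinely contribute.

Ranking: driver score = 1 − P(NEUTRAL); per-sample descending sort, ties
lexicographic. Precision@k averages over samples; an exclusion set (e.g.
training genes) is removed from both numerator and candidate list.

## 7. Synthetic-cohort generator

The generator emulates the statistical structure the classifier exploits
without imitating any real cohort's marginals. Defaults (the package's stated
study conditions): 100 samples (80 tumor / 20 normal), 300 genes, 15 TSG + 15
OG + 60 neutral, BCV 0.4, planted |logFC| 2.0, driver oriented scores
U(0.7, 1.0) vs benign U(0, 0.5), 15 % missing scores, role-signed CNV
(TSG loss / OG gain) at elevated driver rates, onco-miRNA block, and
driver/neutral resource lists containing deliberate decoys (sub-threshold
evidence rows, a dual-role gene, an unknown tag).

Design points worth spelling out:

* **Network**: preferential attachment (m = 2), drivers sampled with weight ∝
  degree^bias (default 1), so drivers are hub-biased but not exclusively hubs.
  Sub-threshold decoy edges are written to the network file to exercise the
  reader's score filter.
* **Counts**: NB with log-normal gene baselines, library sizes
  U(0.5 × 10⁶, 2 × 10⁶), dispersion BCV². Expression effects are split into
  (a) *cohort-constitutive programs* — neighbor co-deregulation around each
  driver (probability 0.7 per neighbor, |logFC| 1.5) and a background decoy
  program (25 % of genes, random sign, |logFC| 2.0) applied identically in
  every tumor sample — and (b) the driver's *own* per-sample effect, present
  only when the driver is altered in the sample and expressed
  (probability 0.7). The constitutive part is absorbed by the two-group mean
  model, so the common-dispersion estimate recovers the true BCV
  (0.44 measured for truth 0.4); an earlier draft with per-sample
  heterogeneity everywhere inflated BCV to ~0.59 and was redesigned.
* **Why the heavy decoy program**: with clean expression the classifier can
  memorize per-gene expression fingerprints and network randomization stops
  hurting. Background decoys mimic driver-like fold changes in neutral and
  unlabeled genes, so hubness and neighborhood co-deregulation — properties of
  the true wiring — are needed to separate drivers from decoys. This makes the
  network-randomization control informative.
* **Parameter-recovery runs** (`simulate_nb_counts`) plant fold changes in a
  small fraction of genes (2.5 %) because CPM normalization assumes most genes
  unchanged; planting 15 % of the library biases every logFC by ~0.5 log2
  units — a property of CPM, not an estimator bug. Recovery is assessed on the
  per-gene mean of single-sample logFC across tumor samples, since one
  single-sample logFC at BCV 0.4 carries ~0.6 log2 units of noise by design.
* The toy worked example uses libraries that sum to exactly 1000 reads so
  every CPM, logFC and neighborhood value is hand-checkable; its expected
  label tables and neighborhood values are shipped as literal files under
  `tests/data/`.

## 8. Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| `string_score_cutoff` | 700 | edge kept iff max(channel scores) > cutoff |
| `evidence_threshold` | 15 | mutation-driver rows kept iff evidence > threshold |
| `hops` | 1 | neighborhood radius |
| `tau` | 1.0 | DEG threshold on \|logFC\| (two-fold) |
| `logcpm_prior` | 0.5 | prior count in log2 transforms |
| `split_ratio` | 0.70 | train fraction of samples |
| `cv_folds` | 5 | grouped CV folds for tuning |
| `feature_set` | `all` | missing-score policy (`all` / `small`) |
| tools | SIFT, PolyPhen2, FATHMM | score+prediction columns per tool |
| `cancer_domains` | PF00870, PF00028 | onco-domain bits |
| grid | n_estimators ∈ {50,100,200}, max_depth ∈ {None,10,20} | tuning grid |

## 9. Limitations

* **CPM-only normalization** is biased when a large expressed fraction of the
  transcriptome shifts in one direction (no TMM); the generator's recovery
  runs respect this assumption, real cohorts may not.
* **A single common dispersion** ignores gene-wise dispersion trends; the
  exported NB p-values are therefore calibration-free summaries, which is why
  they are not model features.
* **Evaluation labels are resource-derived**, not biologically verified
  per-sample; an `UNLABELED` prediction can be a true discovery or a false
  positive, and precision@k against curated lists undercounts novel drivers.
* **Controls are necessary, not sufficient**: passing the permuted-label and
  network-randomization controls rules out gross leakage but does not prove
  the features are causally meaningful.
* The probability outputs are ensemble vote averages and are **not
  calibrated**.
* Cancer-type-specific labeling requires the resource to carry rows for that
  cancer type; there is no back-off to PAN rows by design (silent back-off
  would blur the strategy semantics).
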