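# comorbinet

Disease comorbidity network analysis from patient visit records: build a
thresholded Disease Comorbidity Network (DCN) from diagnosis codes,
characterize its topology and community structure, validate comorbidity
strength against shared genes/pathways, and predict disease occurrence from
visit trajectories. A synthetic cohort generator with planted, recoverable
structure (comorbidity modules, hierarchical nesting, hub diseases,
gene-sharing coupling, temporal risk rules) stands in for clinical data.

## Method summary

* **Pair statistics** — patient-level contingency counts per disease pair;
  relative risk `RR = C·N/(P_i·P_j)` and the Φ-correlation
  `(C·N − P_i·P_j)/sqrt(P_i·P_j·(N−P_i)·(N−P_j))` (the Pearson correlation of
  the binary patient-indicator vectors). A published but inconsistent Φ
  numerator variant is available behind `printed_formula=True`.
* **Network** — keep pairs with co-occurrence > 5, RR > 1 and Φ > 0 (strict,
  configurable); edge weight is the co-occurrence count.
* **Topology** — degree, normalized betweenness, clustering (cc1), closeness
  within components (cc2); degree/weight histograms with a log-binned
  heavy-tail slope; Pearson correlations among the measures (the
  degree↔cc1 < 0 signature of hierarchical modularity).
* **Communities** — weighted modularity and an in-package multi-level greedy
  (BGLL/Louvain) optimizer, seeded and deterministic, with optional restarts;
  ICD-chapter composition reports per community.
* **Molecular validation** — shared gene/pathway counts, Jaccard/cosine set
  similarities, PCCs against RR/Φ, and binned mean-strength curves.
* **Trajectory prediction** — features are diseases seen strictly before the
  index visit (target excluded); balanced benchmarks; logistic regression,
  linear SVM, random forest (180 trees) and a two-hidden-layer MLP under
  10-fold patient-grouped stratified CV; risk-disease rankings from
  coefficients / impurity importances.

## CLI

```bash
# synthetic cohort with planted comorbidity modules
comorbinet simulate --n-patients 2000 --n-diseases 50 --n-modules 5 \
    --boost 5 --seed 7 --out cohort.csv

# DCN from records (any patient_id,visit_index,icd10_code delimited file)
comorbinet network --records cohort.csv --out edges.tsv --graphml dcn.graphml

# topology profile + measure correlations
comorbinet topology --edges edges.tsv --out profile.tsv --correlations corr.tsv

# Louvain communities + chapter composition
comorbinet communities --edges edges.tsv --seed 17 --out partition.tsv \
    --composition composition.tsv

# molecular validation (pairs.tsv is written by the pipeline's network stage)
comorbinet validate --pairs pairs.tsv --genes disease_gene.tsv \
    --pathways pathway_gene.tsv --out report.tsv

# trajectory prediction
comorbinet predict --records cohort.csv --target A000 --n-pos 200 --n-neg 200 \
    --seed 7 --out metrics.tsv --risk-factors top.tsv

# full pipeline from one config (see examples/demo.yaml)
comorbinet run --config examples/demo.yaml
```

The pipeline writes every stage as plain text plus a `manifest.json` with
SHA-256 checksums; re-running an identical config reproduces identical
checksums.

## Data formats

* records: `patient_id,visit_index,icd10_code` (comma or tab; codes
  normalized to ≤4 characters, dot removed; rows with missing codes dropped
  and counted)
* molecular tables: `disease,gene` and `pathway,gene` two-column files;
  disease→pathway links are derived by ≥1 shared gene (configurable)
* networks: TSV edge lists (`disease_i  disease_j  weight  rr  phi`) or GraphML
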