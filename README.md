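# ccinet

Receptor-stratified cell–cell interaction (CCI) network analysis for
single-cell RNA-seq.

Some immune receptors are *homotypic*: they bind the same molecule on
another cell, so the cells that express the receptor can engage one
another and may form their own interaction network. SLAMF7 on CSF and
blood immune cells is the motivating example. `ccinet` asks whether the
communication structure among receptor-positive cells differs from that
among receptor-negative cells: it partitions cells by marker-gene
positivity (≥ 1 transcript by default), infers a ligand–receptor
interaction network among annotated cell types separately in each
partition, and compares the two networks quantitatively.

## Method

For one partition, every ordered cell-type pair (s, r) — including
s = r — and every ligand–receptor pair (L, R) gets the statistic

```
score(s, r, L, R) = ½ · ( mean_{cells of s} L̃  +  mean_{cells of r} R̃ )
```

where `L̃`, `R̃` are counts library-size-normalized to 10,000 per cell.
The pair is tested only when L is detected in ≥ 10% of sender cells and
R in ≥ 10% of receiver cells. Significance comes from a cluster-label
permutation null (1000 shared label shuffles per run) with the add-one
estimator `p = (1 + #{permuted ≥ observed}) / (N + 1)`, so p is never 0.

Significant interactions aggregate into a directed weighted graph per
partition (edge weight = number of significant interactions). The two
graphs are compared through:

* **node measures** — PageRank (damping 0.85), influencer
  (out-strength fraction), listener (in-strength fraction), mediator
  (betweenness with edge distance 1/weight) — and their exact deltas;
* **edge measures** — each pair's percentage of its network's
  interactions, and a log odds ratio
  `ln[((a+½)/(A−a+½)) / ((b+½)/(B−b+½))]` with the Haldane–Anscombe
  correction, positive when the edge is enriched among
  receptor-positive cells;
* **enrichment** — per topology measure and direction, the ligand
  and/or receptor genes on enriched edges incident to nodes with
  matching deltas are tested for gene-set over-representation
  (exact hypergeometric tail, BH-corrected) against the LR-panel
  background.

A seeded negative-binomial generator produces synthetic datasets with
the same structure (cell types × cohorts × compartments, mitochondrial
genes, a sparse homotypic marker, QC violators) and can plant a
homotypic ligand upregulation in marker-positive cells of one type, so
every stage is testable without external data.

## Worked example

```python
from ccinet import apply_qc, subset_compartment
from ccinet.model import CCIModel, DifferentialCCI
from ccinet.scoring import ScoringParams
from ccinet.simulate import SimConfig, generate_dataset

cfg = SimConfig(seed=1, marker_prevalence=0.3, effect_multiplier=4.0,
                effect_cell_type="B cell", cells_per_type=100)
matrix, annotation, lr_pairs, truth = generate_dataset(cfg)
matrix, report = apply_qc(matrix)                      # 200–5800 counts, ≤5% mito
annotation = annotation[annotation.barcode.isin(matrix.barcodes)]
matrix, annotation = subset_compartment(matrix, annotation, "CSF")

model = CCIModel(matrix, annotation, lr_pairs, ScoringParams(seed=1))
partition = model.stratify("SLAMF7")                   # ≥1 transcript = positive
res_pos = model.fit(partition, "positive")
res_neg = model.fit(partition, "negative")
diff = DifferentialCCI(res_pos, res_neg).fit()
print(diff.summary(top=5))
```

Output (abridged):

```
Differential cell-cell interaction network
==============================================
significant interactions: plus=184  minus=137

node measures (delta = plus - minus):
             pagerank_plus  pagerank_minus  delta_pagerank  ...
B cell              0.2674          0.1849          0.0825  ...
CD4 T cell          0.1118          0.1198         -0.0080  ...

top 5 edges by |log odds ratio|:
 sender    receiver  count_plus  count_minus  log_odds_ratio   direction
 B cell Granulocyte           6            1           1.198  up_in_plus
 B cell  CD8 T cell           6            1           1.198  up_in_plus
 B cell  CD4 T cell           5            1           1.025  up_in_plus
 B cell      B cell           5            1           1.025  up_in_plus
NK cell  CD4 T cell           1            2          -0.814 up_in_minus
```

The generator planted a 4× upregulation of five homotypic ligands in
SLAMF7⁺ B cells; the comparison recovers it: B cells carry the largest
positive PageRank delta (0.083) and every strongly enriched edge sends
from or returns to B cells, while the unaffected types sit near zero.

The same pipeline runs from the shell:

```sh
ccinet simulate --seed 1 --out-dir data/
ccinet run-all --config config.yaml        # QC → subset → stratify → score± → compare → enrich
```

writing interaction tables (TSV), both networks (GraphML + edge lists),
node/edge comparison tables, the enrichment table and a JSON manifest
that records every parameter and seed.

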