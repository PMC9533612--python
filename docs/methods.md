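# Methods

## Problem and model

`ccinet` compares cell–cell communication structure between two
partitions of the same single-cell dataset: cells positive for a
homotypic receptor gene (≥ `min_marker_count` transcripts, default 1)
and cells negative for it. Because a homotypic receptor binds itself on
other cells, receptor-positive cells can plausibly form their own
interaction network; the package quantifies how that network differs
from the receptor-negative one.

The pipeline order is fixed: cell-level QC → compartment subset →
marker stratification → per-partition interaction scoring → network
comparison → gene-set enrichment. Cell-type labels are an input
(upstream clustering/annotation is out of scope), as is the
ligand–receptor panel and the gene-set collection.

## QC gates

Cells are removed when their total transcript count is *less than*
`min_total` (200) or *more than* `max_total` (5800), or when *more
than* `max_mito_frac` (5%) of transcripts come from genes whose symbol
starts with `mito_prefix` ("MT-", case-insensitive, so "mt-" matches).
The inequalities are strict on the removal side — totals of exactly 200
or 5800 and a mitochondrial fraction of exactly 5% are retained — which
is the literal reading of the usual wording of these filters; users
wanting the inclusive convention shift a threshold by one count.
Fractions are computed on raw counts, before normalization. Genes are
never filtered. `make_qc_fixture` materialises all four total
boundaries (199/200/5800/5801) and the three fraction boundaries
(4.9/5.0/5.1%, realised at total 1000 where they are integral — the
full total×fraction cross is not representable in integer counts) with
known keep/drop labels.

## Interaction scoring

The statistic is the arithmetic mean of the sender-cluster ligand mean
and the receiver-cluster receptor mean on counts normalized to
`normalization_scale` (10,000) per cell, with no log transform.
Within-type pairs (sender = receiver) are tested: they are exactly the
interactions a homotypic receptor motivates.

Defaults — 1000 permutations, a 10% expressing-fraction gate, α = 0.05,
`min_cells_per_type` = 10 — follow the published scheme of the
permutation-based CCI tools this re-implements; the run manifest flags
them as assumed defaults because the study workflow this mirrors does
not restate them. Every constant is an overridable `ScoringParams`
field.

Numerical choices:

* One label shuffle per permutation round is shared by all statistics,
  preserving their correlation under the null and costing one matrix
  product per round.
* The add-one estimator keeps p in (0, 1]; implementations that report
  p = 0 differ by exactly this convention.
* Ties are counted into the upper tail (`permuted ≥ observed`), the
  conservative direction.
* Raw permutation p-values gate significance by default;
  `use_bh=True` switches the gate to BH q-values and is recorded in
  the manifest.
* Types below `min_cells_per_type` are excluded from the tested
  universe (recorded in `attrs`/manifest); fewer than two eligible
  types is an error, not an empty result.
* Partition streams derive from `(seed, sha256(label))`, so scoring
  one partition never perturbs the other's permutations.

`exact_permutation_p` enumerates all `C(n, n_sender)` two-type label
assignments (n ≤ 12) in exact rational arithmetic and is the oracle the
sampled test is validated against; it is never used in the pipeline
itself.

## Network comparison

Edge weight is the *count* of significant interactions, not a sum of
scores, because the downstream comparison is about interaction
frequency. PageRank uses damping 0.85, uniform teleport, uniform
dangling redistribution, and power iteration to absolute L1 tolerance
1e-12 (validated against a dense linear solve and networkx).
Influencer/listener are out-/in-strength over the network total;
mediator is betweenness with edge distance 1/weight, normalized to
[0, 1]. An edgeless graph yields all-zero measures with a warning.

The per-pair log odds ratio contrasts `a` of the plus network's `A`
significant interactions with `b` of `B`, with the Haldane–Anscombe 0.5
correction so one-sided edges stay finite. It is evaluated as a
difference of logits, which makes swap-antisymmetry exact in floating
point. Node sets are unioned and missing nodes get zero measures, so
every delta is defined. Both networks empty is an error.

## Enrichment

No published rule maps topology measures to genes in the workflow this
package mirrors, so the hit-set construction is this package's own
documented proxy: for `up_in_plus` and measure *m*, hits are ligand
genes (influencer), receptor genes (listener) or both (mediator,
pagerank) of significant plus-partition interactions on edges with
positive log odds ratio incident — outgoing, incoming, or either,
respectively — to nodes with positive delta of *m*; `up_in_minus`
mirrors it. The background universe is the LR panel's genes (only they
can be hits; a transcriptome-wide background would only dilute the
tail). The test is the exact hypergeometric upper tail P(X ≥ overlap),
one-sided over-representation only, BH-corrected within each
(measure, direction).

## Synthetic data generator

The generator emulates a two-cohort (6 donors each), two-compartment
(CSF/PBMC) immune scRNA-seq study with up to 11 plausible immune
subsets. Counts are negative binomial parameterized by (mean, size);
genes "off" in a type are exactly zero. Per-(gene, type) on/off
programs are Bernoulli(`expression_prob`); `shared_programs=True` draws
one program for all types, which makes type labels exchangeable — the
regime in which permutation p-values are uniform and type-I error is
measurable. Defaults: 300 background genes, 10 always-on mitochondrial
genes with mean 2.0 (≈ 2% mitochondrial fraction), 30 LR pairs,
nb_mean 8, size 2, expression_prob 0.35 — chosen to give per-cell
totals near 1000, safely inside the QC gates, at desk scale.

The marker gene (default `SLAMF7`, default prevalence 0.0512 — the
observed CSF fraction the package's motivating analysis reports) is
Bernoulli presence × NB magnitude truncated at 1, so positivity equals
prevalence by construction and, with `effect_multiplier=1`, is
independent of all other genes: the two partitions are then
exchangeable and all comparative statistics are null-centred.

The planted effect is a homotypic circuit: the LR panel contains the
marker self-pair plus `n_homotypic_pairs` (5) ligand=receptor
self-pairs expressed in *every* type at baseline (so the baseline
interaction statistic is type-uniform and rarely significant), and
`effect_multiplier` scales those genes' means only in marker-positive
cells of `effect_cell_type`. In the positive partition this elevates
both the sending and the receiving end of every edge touching the
effect type — the signature a self-ligand creates — which is what the
recovery analyses detect as a dominant positive PageRank delta on that
node. `qc_noise` forces a fraction of cells to violate exactly one QC
gate (total resampled to 199 or 5801, or mitochondrial counts raised to
≈ 5.5%), flagged in the ground truth.

What the generator does **not** emulate: gene–gene correlation beyond
shared programs, doublets, batch/donor effects (cohort and compartment
labels do not alter generative parameters by default), or realistic
pathway structure. Passing tests therefore demonstrate statistical
correctness of the machinery under the stated model, not performance on
real tissue.

## Problem sizes in the validation runs

The acceptance analyses use 6 cell types at 100–150 cells per type per
cohort per compartment (≈ 2,400–3,600 cells; 1,200+ after QC and CSF
subsetting), 30 LR pairs, 1000 permutations (500 for the 20-seed null
sweep, where only the sign structure of log odds ratios matters), 3
seeds pooled for the type-I experiment (> 3,000 tested interactions)
and 20 seeds for the null and recovery sweeps; the marker-fraction
check uses 6,000 CSF cells. These sizes keep each sweep in seconds
while leaving the binomial error of every estimated rate well inside
its acceptance band.

## Known limitations

* Multi-subunit ligand/receptor complexes are not modeled; pairs are
  strictly gene-to-gene.
* No consensus over multiple scoring methods; one permutation scheme
  is implemented directly.
* Centrality deltas carry no uncertainty estimates (no bootstrap);
  the null sweep characterises their spread empirically instead.
* The 2-D measure→gene proxy for enrichment is a design choice, not an
  inference of any published ranking.
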