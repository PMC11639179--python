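# gislasso

Knowledge-guided feature selection for gene expression data: per-gene
relevance scores derived from biological ontologies, used as
feature-specific L1 penalties in a weighted-LASSO generalized linear model.

## The problem

LASSO-regularized models are the workhorse of embedded feature selection in
transcriptomics, but they rank genes purely by their quantitative
contribution to the prediction task. When many genes are nearly collinear —
co-expressed genes usually are — the LASSO picks among them arbitrarily,
and the selected panel may carry little biological meaning. `gislasso`
biases that choice toward genes with documented biology, without ever
overriding predictive power: prior knowledge only modulates *how strongly*
each coefficient is shrunk.

## The score and the model

Each knowledge base (GO, HPO, ...) is a DAG of terms. Every term *t* in
ontology *k* gets a structure-based information content

```
ic_struct(t) = depth(t) / max_depth_k * (1 - log(desc(t) + 1) / log(total_terms_k))
```

with depth the longest path from a root, `desc` the number of distinct
descendants: 0 for roots, 1 for childless terms at maximal depth, in [0, 1]
everywhere. A gene's direct (most specific) annotations are unfolded to
their full ancestor closures, giving a binary gene × term matrix **B** and
its IC-weighted counterpart **W**. The Gene Information Score is the mean
of the positive entries of the gene's row of **W**:

```
GIS(g) = mean{ W[g, t] : W[g, t] > 0 }          (GIS = 0: no prior knowledge)
```

Penalties decrease in relevance via `wGIS(g) = 1 / (1 + shape · GIS(g))`
(default shape 1, so wGIS ∈ [0.5, 1]), and the model minimizes

```
(1/n) Σᵢ [ b(ηᵢ) − yᵢ ηᵢ ]  +  λ Σⱼ wGIS(j) · |βⱼ|
```

by cyclic coordinate descent (IRLS outer loop for logistic responses).
All-unit penalties (or shape 0) recover the standard LASSO exactly.

## Worked example

Everything below runs on synthetic inputs generated by
`gislasso.simulate` — no downloads.

```python
import numpy as np
from gislasso import build_matrices, compute_gis, penalty_transform, unfold, fit
from gislasso.simulate import make_ontology, make_annotations, make_expression

onto = make_ontology(200, depth_target=7, seed=1)
data = make_expression(144, 50, informative=[(0, 2.0), (1, 1.5)], seed=1)
ann = make_annotations(data.gene_ids, onto, frac_unannotated=0.2, seed=1)

matrices = build_matrices(unfold(ann, [onto]), [onto])
gis = compute_gis(matrices)
pen = penalty_transform(gis, shape=1.0)
model = fit(data, lam=0.05, penalties=pen, family="binomial")
```

This prints (via the obvious summaries):

```
ontology: 200 terms, max depth 7
GIS: min 0.000, median 0.362, max 0.476; 10 genes without prior knowledge
penalties: min 0.678, max 1.000
selected 4 of 50 genes: ['G00000', 'G00001', 'G00010', 'G00034']
converged in 7 IRLS iterations
```

The two informative genes (`G00000`, `G00001`) are selected together with
two background genes; the 10 unannotated genes carry the maximal penalty
1.0, annotated genes as little as 0.678.

The same pipeline is available from the shell:

```
gislasso ontology-stats onto.obo --out term_stats.tsv
gislasso gis --obo onto.obo --annotations ann.tsv --out gis.tsv
gislasso fit --expr expr.tsv --labels label --penalties gis.tsv --lam 0.1 --out coef.tsv
gislasso cv  --expr expr.tsv --labels label --penalties gis.tsv \
             --lam-grid 0.01 --lam-grid 0.05 --lam-grid 0.2 --out cv.tsv
gislasso simulate multicollinearity --reps 100 --seed 1 --out sim/
gislasso run config.yaml
```

## Sensitivity studies

`gislasso.simulate` also ships the two study harnesses used in the test
suite: `run_multicollinearity` duplicates one feature into ten noisy copies
(Gaussian noise, sd 0.01) and counts, across 100 paired repetitions, which
block members a logistic weighted LASSO selects under five penalty
scenarios (NO_GIS, GIS1–GIS4); `run_predictive_power` perturbs single
features' penalties and tracks coefficient magnitudes and selection
frequencies. See `docs/methods.md` for the full protocol definitions.

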