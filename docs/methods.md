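# Methods

## Term information content

An ontology is modelled as a DAG over its non-obsolete terms, with edges
restricted to a configurable set of relationship types (default `is_a` and
`part_of`). Two conventions are deliberately fixed and recorded in every
run report:

* **Depth** is the length in edges of the *longest* path from any root
  (a term with no parents under the filter) to the term; roots sit at
  depth 0. Longest-path depth makes `max_depth` equal to the DAG height,
  so the depth ratio in the information content is exactly 1 for the
  deepest terms. Multi-rooted DAGs take the maximum over roots.
* **Logarithm base** is natural; the score only uses the ratio
  `log(desc+1)/log(total_terms)`, which is base-invariant.

`ic_struct(t) = depth(t)/max_depth × (1 − log(desc(t)+1)/log(total_terms))`
is 0 exactly for roots, 1 exactly for childless terms at maximal depth,
strictly increasing in depth at fixed descendant count and strictly
decreasing in descendant count at fixed depth. Ontologies with fewer than
two terms or zero height carry no structural information and are rejected
(`DegenerateOntologyError`) rather than silently scored zero.

Obsolete terms are excluded from the term count and all statistics;
annotations pointing at them are remapped through `replaced_by` when the
tag exists and dropped with a warning otherwise.

## Annotation unfolding and the gene score

A gene's direct annotations are its most specific terms. Unfolding
replaces each direct term with `{term} ∪ ancestors(term)`; the direct term
itself is kept in the closure — it carries the highest information content
of its lineage, and dropping it would discard the strongest signal.
Unfolding is idempotent.

The binary matrix **B** (genes × pooled terms of all supplied ontologies)
and the weighted matrix **W** (= **B** scaled columnwise by `ic_struct`)
are stored sparse. The Gene Information Score is the arithmetic mean of
the *positive* entries of the gene's row of **W**: terms with zero
information content (roots, which every unfolded gene hits) drop out of
both numerator and denominator. The 0/0 case — a gene with no positive
entries — is defined as GIS = 0, read as "no prior biological
information". The mean pools terms of all ontologies into one average
(term-count-weighted); a per-ontology breakdown is available for
diagnostics via the matrices themselves.

The penalty transform is the one-parameter family
`w(g) = 1/(1 + shape · GIS(g))`, shape ≥ 0. Shape 1 maps [0, 1] onto
[0.5, 1]; shape 0 degenerates to unit penalties (standard LASSO). The
shape is tunable jointly with λ in the cross-validation grid.

## The solver

The objective is the 1/n-scaled GLM negative log-likelihood plus
`λ Σ w_j |β_j|`. Although the penalty is sometimes written without
absolute-value bars, the L1 reading is the only one that defines a convex
selection operator, and it is what is implemented. λ therefore lives on
the mean-loss scale: multiply by n to translate to sum-loss conventions
(e.g. a sum-loss `C` parameterization corresponds to `λ = 1/(n·C)`).

* Gaussian responses: cyclic coordinate descent with exact residual
  updates and an unpenalized intercept.
* Binomial responses: outer IRLS quadratic approximation (probabilities
  clipped at 1e-5) around the same weighted inner solver, with
  step-halving so the true penalized objective is non-increasing across
  outer iterations even where the quadratic model overshoots.
* Active set: each full sweep is followed by sweeps restricted to the
  currently nonzero coefficients until they converge, then a full sweep
  re-checks optimality — the usual speed trick, essential when nearly
  duplicated columns make plain cyclic descent crawl.
* Updates run in fixed gene order, so tie-breaking among exactly
  duplicated features is deterministic.
* Convergence: maximum absolute coefficient change < `tol` (default 1e-6),
  `max_sweeps` 10 000; non-convergence returns the model with a warning
  and `converged=False`.

Features are standardized (population sd) before fitting by default;
coefficients are reported back on the original scale, constant columns are
flagged and excluded from penalized updates. Correctness is anchored by
two independent routes that the test suite keeps separate: the
reparameterization identity (a weighted fit equals a standard fit on
columns `X_j / w_j` with coefficients divided back) and external reference
solvers for the all-unit-penalty special case; KKT subgradient conditions
are checked at reported solutions.

Cross-validation is stratified for classification (refolding with a
warning when the smallest class has fewer members than folds), scores
accuracy (classification) or MSE (regression), and breaks exact ties
toward larger λ — the sparser model. Multiclass fitting is one-vs-rest
with prediction by maximal linear score; the choice is recorded in run
metadata.

## Synthetic data

The generators emulate the three input types end to end:

* `make_ontology` grows a single-root DAG term by term, attaching each new
  term to a parent chosen with probability increasing in depth (so the
  target height is actually reached) and adding a second parent with
  probability 0.15 — producing the diamond motifs through which ancestor
  closures must deduplicate.
* `make_annotations` gives an exact fraction of genes no annotations at
  all (so GIS = 0 genes exist by construction) and draws each annotated
  gene's `1 + Poisson(mean − 1)` terms biased toward deep, specific terms.
* `make_expression` draws standard-normal features; for classification the
  classes are exactly balanced and each informative feature's
  class-conditional means are shifted apart by its effect size. With unit
  within-class variances this location model yields a posterior class
  probability that is exactly logistic in the features with coefficients
  equal to the effect sizes, which reconciles "labels follow a logistic
  model" with "balanced classes by construction".

What the generators do *not* emulate: library-size and count noise of real
RNA-seq, gene–gene correlation structure beyond the explicit
noisy-copy/correlation-cap constructions, annotation bias toward
well-studied genes, and multi-ontology disagreement. Passing tests
therefore demonstrate the mechanics and the qualitative selection
behaviour, not real-data performance.

## Sensitivity protocols

The **controlled dataset** builder screens features by Fisher's score
(between-class over within-class variance; perfect separators reported as
∞ with a warning), picks seed features spanning distinct score strata
under a pairwise correlation cap (default |r| < 0.5), and fills with
random features under a looser cap (default |r| < 0.70).

The **multicollinearity study** appends 10 noisy copies (Gaussian noise,
sd 0.01) of one feature and fits a binary logistic weighted LASSO under
five penalty scenarios: NO_GIS (all block penalties 1), GIS1 (copies 1,
original keeps its own), GIS2 (copies evenly spaced in [0.95, 1]), GIS3
([original, 1]) and GIS4 ([0.5, 1]); copy `_1` always carries the smallest
penalty of its scenario, ascending to `_10` (recorded in output
metadata). Each repetition draws fresh copy noise with a counter-derived
seed (`seed + rep`) shared across all scenario × λ cells, so comparisons
are paired. Background (non-block) features keep their own penalties by
default, with a flag to force them to 1.

The **predictive-power study** refits with single-feature penalty
overrides and reports mean |coefficient| and selection frequency per
override × λ. With a fixed dataset the selection frequency over
repetitions would be degenerate (0 or 1), so each repetition either draws
a fresh dataset from a user-supplied factory or, by default, bootstrap
resamples the supplied rows.

Both harnesses fit on the stored feature scale (no re-standardization):
the synthetic expression features are generated standardized, the noise is
added on that scale, and re-scaling the enlarged matrix would shrink each
copy slightly differently — and would rescale a class-separated feature by
its inflated total variance — breaking the paired design. For balanced
classes a re-standardized feature's null-point score gradient is bounded
by 0.5 regardless of effect size, so stronger regularization levels
(λ around 1 on the mean-loss scale) can only ever discriminate on the
stored scale. Default study sizes used in the tests are 144 samples and
30–50 base genes with a strongly separating duplicated feature
(class-mean shift 5 within-class sd), 100 repetitions — sizes a laptop
handles in seconds while leaving the qualitative contrasts
(selection spread under NO_GIS, single low-penalty winner under GIS2)
far from the decision boundary.

## Known limitations

* Only Gaussian and binomial families; no survival or count responses.
* No evidence-code filtering of annotations beyond NOT-qualifier
  exclusion; no OWL input.
* The IRLS objective monotonicity guarantee relies on step-halving with a
  1e-12 slack; the objective path is recorded per outer iteration, not per
  inner sweep.
* GIS treats all supplied ontologies as one pooled term set; ontologies
  with many shallow terms can dilute the score of genes also annotated in
  deeper ontologies.
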