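"""Synthetic ontologies, annotations, expression data, and sensitivity protocols.

Everything needed to exercise the scoring and weighted-LASSO machinery
without external downloads: random term DAGs, random most-specific gene
annotations, expression matrices with controlled signal, a Fisher's-score /
correlation-filtered "controlled dataset" builder, and two experiment
harnesses:

* a multicollinearity study that duplicates one feature into near-exact
  noisy copies and measures which block members a weighted-LASSO logistic
  model selects under graded penalty scenarios, over paired repetitions;
* a predictive-power study that perturbs single features' penalties and
  tracks coefficient magnitudes and selection frequencies.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .ontology import Ontology, OntologyTerm
from .wlasso import BINOMIAL, DesignData, WLassoModel, fit

__all__ = [
    "ScenarioSpec",
    "ExperimentResult",
    "SCENARIO_NAMES",
    "make_ontology",
    "make_annotations",
    "make_expression",
    "fisher_score",
    "build_controlled_dataset",
    "add_noisy_copies",
    "run_multicollinearity",
    "run_predictive_power",
]

SCENARIO_NAMES = ("NO_GIS", "GIS1", "GIS2", "GIS3", "GIS4")


@dataclass(frozen=True)
class ScenarioSpec:
    """Penalty assignment for a duplicated-feature block.

    ``original_w`` is the penalty of the original feature; ``copy_ws`` the
    penalties of its noisy copies, ordered so that copy _1 gets the smallest
    value and copy _n the largest.
    """

    name: str
    original_w: float
    copy_ws: np.ndarray

    @classmethod
    def for_name(
        cls, name: str, original_w: float, n_copies: int = 10
    ) -> "ScenarioSpec":
        """Build one of the five canonical penalty scenarios.

        NO_GIS: no prior knowledge anywhere in the block (all penalties 1,
        standard LASSO on the block).  GIS1: copies know nothing (penalty
        1), the original keeps its own penalty.  GIS2/GIS3/GIS4: copy
        penalties evenly spaced over [0.95, 1], [original_w, 1] and
        [0.5, 1] respectively, endpoints included.
        """
        if name == "NO_GIS":
            return cls(name, 1.0, np.ones(n_copies))
        if name == "GIS1":
            return cls(name, original_w, np.ones(n_copies))
        if name == "GIS2":
            return cls(name, original_w, np.linspace(0.95, 1.0, n_copies))
        if name == "GIS3":
            return cls(name, original_w, np.linspace(original_w, 1.0, n_copies))
        if name == "GIS4":
            return cls(name, original_w, np.linspace(0.5, 1.0, n_copies))
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")


@dataclass
class ExperimentResult:
    """Selection counts for a duplicated-feature block across repetitions."""

    feature_labels: list[str]
    selection_counts: np.ndarray
    reps: int
    lam: float
    scenario: ScenarioSpec
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_labels,
                "n_selected": self.selection_counts.astype(int),
                "reps": self.reps,
                "lam": self.lam,
                "scenario": self.scenario.name,
            }
        )


# ---------------------------------------------------------------------------
# generators


def make_ontology(
    n_terms: int,
    max_children: int = 4,
    depth_target: int = 6,
    seed: int = 0,
    ontology_id: str = "SYN",
) -> Ontology:
    """Random single-root term DAG with occasional multi-parent edges.

    Terms are attached one at a time to an existing parent chosen with
    probability increasing in depth (so the DAG actually reaches
    ``depth_target``), capped at ``max_children`` children per node; with
    probability 0.15 a term gains a second parent, creating the diamond
    motifs real ontologies have.  Deterministic per seed.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    if max_children < 1 or depth_target < 1:
        raise ValueError("max_children and depth_target must be positive")
    rng = np.random.default_rng(seed)
    ids = [f"{ontology_id}:{i:07d}" for i in range(n_terms)]
    parent_map: dict[str, set[str]] = {ids[0]: set()}
    depth = {ids[0]: 0}
    n_children = {ids[0]: 0}
    for i in range(1, n_terms):
        cand = [
            t for t in parent_map
            if n_children[t] < max_children and depth[t] < depth_target
        ]
        if not cand:  # all capacity used below depth_target: allow any node
            cand = [t for t in parent_map if n_children[t] < max_children]
        if not cand:
            raise ValueError(
                "infeasible shape: max_children too small for n_terms"
            )
        weights = np.array([depth[t] + 1.0 for t in cand])
        parent = cand[rng.choice(len(cand), p=weights / weights.sum())]
        parents = {parent}
        if len(parent_map) > 2 and rng.random() < 0.15:
            extra_cand = [t for t in cand if t != parent]
            if extra_cand:
                parents.add(extra_cand[rng.integers(len(extra_cand))])
        tid = ids[i]
        parent_map[tid] = parents
        depth[tid] = max(depth[p] for p in parents) + 1
        n_children[tid] = 0
        for p in parents:
            n_children[p] += 1
    terms = [
        OntologyTerm(term_id=t, parents={"is_a": set(ps)})
        for t, ps in parent_map.items()
    ]
    return Ontology(ontology_id, terms)


def make_annotations(
    gene_ids: Sequence[str],
    ontology: Ontology,
    mean_terms_per_gene: float = 3.0,
    frac_unannotated: float = 0.2,
    seed: int = 0,
) -> AnnotationSet:
    """Random most-specific annotations biased toward deep (specific) terms.

    Exactly ``round(frac_unannotated * n_genes)`` genes receive no terms at
    all, so zero-information genes exist by construction.  Annotated genes
    draw ``1 + Poisson(mean_terms_per_gene - 1)`` distinct terms with
    sampling probability proportional to ``depth + 1``.
    """
    if mean_terms_per_gene <= 0:
        raise ValueError("mean_terms_per_gene must be positive")
    if not 0 <= frac_unannotated < 1:
        raise ValueError("frac_unannotated must be in [0, 1)")
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    n_un = int(round(frac_unannotated * len(gene_ids)))
    unannotated = set(
        rng.choice(len(gene_ids), size=n_un, replace=False).tolist()
    )
    term_ids = sorted(ontology.graph)
    weights = np.array([ontology.depth[t] + 1.0 for t in term_ids])
    prob = weights / weights.sum()
    direct: dict[str, dict[str, set[str]]] = {}
    for i, gene in enumerate(gene_ids):
        if i in unannotated:
            direct[gene] = {}
            continue
        k = 1 + rng.poisson(mean_terms_per_gene - 1.0)
        k = min(k, len(term_ids))
        chosen = rng.choice(len(term_ids), size=k, replace=False, p=prob)
        direct[gene] = {
            ontology.ontology_id: {term_ids[j] for j in chosen}
        }
    return AnnotationSet(gene_ids=gene_ids, direct=direct)


def make_expression(
    n_samples: int,
    n_genes: int,
    informative: Sequence[tuple[int, float]] = (),
    family: str = "binomial",
    seed: int = 0,
) -> DesignData:
    """Synthetic expression matrix with a controlled set of informative genes.

    Features are standard normal.  For classification, classes are exactly
    balanced and each informative gene's class-conditional means are shifted
    apart by its effect size; with unit variances this makes the posterior
    class probability exactly logistic in the features, with coefficients
    equal to the effect sizes.  For regression the response is the linear
    signal plus unit Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    for idx, _ in informative:
        if not 0 <= idx < n_genes:
            raise ValueError(f"informative index {idx} out of range")
    X = rng.standard_normal((n_samples, n_genes))
    gene_ids = [f"G{j:05d}" for j in range(n_genes)]
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    if family == "binomial":
        n1 = n_samples // 2
        y = np.zeros(n_samples, dtype=int)
        y[n_samples - n1 :] = 1
        for idx, effect in informative:
            X[:, idx] += np.where(y == 1, effect / 2.0, -effect / 2.0)
    elif family == "gaussian":
        y = rng.standard_normal(n_samples)
        for idx, effect in informative:
            y = y + effect * X[:, idx]
    else:
        raise ValueError(f"unknown family {family!r}")
    return DesignData(X=X, y=y, sample_ids=sample_ids, gene_ids=gene_ids)


# ---------------------------------------------------------------------------
# feature screening / controlled dataset


def fisher_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher's discriminant score of each feature for a binary response.

    sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c var_cj, with class sizes n_c,
    per-class means/variances and the overall mean mu_j.  Features with
    zero pooled within-class variance get +inf with a warning (perfect
    separators).
    """
    import warnings

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("fisher_score requires exactly two classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        nc = Xc.shape[0]
        num += nc * (Xc.mean(axis=0) - mu) ** 2
        den += nc * Xc.var(axis=0)
    zero = den == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} feature(s) have zero within-class variance; "
            "score reported as infinity"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(zero, np.inf, num / np.where(zero, 1.0, den))
    return score


def build_controlled_dataset(
    data: DesignData,
    n_seed_features: int = 5,
    corr_cap_seed: float = 0.5,
    n_fill: int = 995,
    corr_cap_fill: float = 0.70,
    seed: int = 0,
    strata: Sequence[float] | None = None,
) -> tuple[DesignData, list[str]]:
    """Low-correlation feature subset with seed features of graded signal.

    Picks ``n_seed_features`` spanning distinct Fisher's-score strata
    (quantile bands unless explicit boundaries are given) whose pairwise
    Pearson correlations stay below ``corr_cap_seed``, then randomly fills
    with ``n_fill`` further features correlated < ``corr_cap_seed`` with
    every seed feature and < ``corr_cap_fill`` with every other fill
    feature.  Deterministic per seed.  Returns the subset and the seed
    feature ids (ordered by increasing score).
    """
    rng = np.random.default_rng(seed)
    scores = fisher_score(data.X, data.y)
    finite = np.where(np.isfinite(scores), scores, np.nanmax(scores[np.isfinite(scores)]))
    order = np.argsort(finite)
    if strata is None:
        bounds = np.linspace(0, len(order), n_seed_features + 1).astype(int)
        strata_idx = [order[bounds[i] : bounds[i + 1]] for i in range(n_seed_features)]
    else:
        edges = [-np.inf, *strata, np.inf]
        strata_idx = [
            np.flatnonzero((finite >= lo) & (finite < hi))
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        if len(strata_idx) != n_seed_features:
            raise ValueError("strata boundaries must define n_seed_features bands")

    Xs = (data.X - data.X.mean(0)) / np.where(data.X.std(0) > 0, data.X.std(0), 1.0)
    n = data.n

    def corr(j: int, chosen: list[int]) -> np.ndarray:
        if not chosen:
            return np.zeros(0)
        return np.abs(Xs[:, chosen].T @ Xs[:, j]) / n

    seeds: list[int] = []
    for band in strata_idx:
        band = band.copy()
        rng.shuffle(band)
        placed = False
        for j in band:
            if j in seeds:
                continue
            if (corr(j, seeds) < corr_cap_seed).all():
                seeds.append(int(j))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"no feature in score stratum satisfies the {corr_cap_seed} "
                "correlation cap with the already-selected seed features"
            )

    pool = [j for j in range(data.q) if j not in seeds]
    rng.shuffle(pool)
    fill: list[int] = []
    for j in pool:
        if len(fill) == n_fill:
            break
        if (corr(j, seeds) < corr_cap_seed).all() and (
            corr(j, fill) < corr_cap_fill
        ).all():
            fill.append(j)
    if len(fill) < n_fill:
        raise ValueError(
            f"correlation caps unsatisfiable: only {len(fill)} of {n_fill} "
            f"fill features found ({len(pool)} candidates examined)"
        )
    keep = seeds + fill
    subset = DesignData(
        X=data.X[:, keep],
        y=data.y,
        sample_ids=list(data.sample_ids),
        gene_ids=[data.gene_ids[j] for j in keep],
    )
    return subset, [data.gene_ids[j] for j in seeds]


def add_noisy_copies(
    data: DesignData,
    gene_id: str,
    n_copies: int = 10,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> DesignData:
    """Append near-exact copies of one feature: original + N(0, noise_sd^2).

    The original column is relabelled ``<gene>_0`` and the copies
    ``<gene>_1`` ... ``<gene>_n``, mirroring the duplicated-block layout of
    the multicollinearity study.
    """
    if gene_id not in data.gene_ids:
        raise KeyError(f"unknown gene {gene_id!r}")
    rng = np.random.default_rng(seed)
    j = data.gene_ids.index(gene_id)
    col = data.X[:, j][:, None]
    copies = col + noise_sd * rng.standard_normal((data.n, n_copies))
    gene_ids = list(data.gene_ids)
    gene_ids[j] = f"{gene_id}_0"
    gene_ids += [f"{gene_id}_{k}" for k in range(1, n_copies + 1)]
    return DesignData(
        X=np.hstack([data.X, copies]),
        y=data.y,
        sample_ids=list(data.sample_ids),
        gene_ids=gene_ids,
    )


# ---------------------------------------------------------------------------
# experiment harnesses


def _block_labels(gene_id: str, n_copies: int) -> list[str]:
    return [f"{gene_id}_{k}" for k in range(n_copies + 1)]


def run_multicollinearity(
    data: DesignData,
    gene_id: str,
    scenarios: Sequence[str | ScenarioSpec],
    lam_list: Sequence[float] = (0.20, 0.25, 0.50, 1.0),
    reps: int = 100,
    seed: int = 0,
    original_w: float = 1.0,
    base_penalties: np.ndarray | None = None,
    n_copies: int = 10,
    noise_sd: float = 0.01,
    force_unit_background: bool = False,
    **fit_kwargs,
) -> list[ExperimentResult]:
    """Duplicated-feature selection study under graded penalty scenarios.

    For each repetition a fresh set of noisy copies of ``gene_id`` is drawn
    with a counter-derived seed (``seed + rep``), shared across all
    (lambda, scenario) combinations so comparisons are paired.  A binary
    weighted-LASSO logistic model is fitted with the block's penalties set
    by the scenario (the original feature keeps ``original_w`` unless the
    scenario overrides it) and every other feature keeping its own penalty
    from ``base_penalties`` (all ones if absent, or forced to one with
    ``force_unit_background``).  Selection of each block member is counted
    across repetitions.
    """
    specs = [
        s if isinstance(s, ScenarioSpec) else ScenarioSpec.for_name(s, original_w, n_copies)
        for s in scenarios
    ]
    if base_penalties is None or force_unit_background:
        base = np.ones(data.q)
    else:
        base = np.asarray(base_penalties, dtype=float)
        if base.shape[0] != data.q:
            raise ValueError("base_penalties not aligned with data.gene_ids")
    j_orig = data.gene_ids.index(gene_id)

    counts = {
        (spec.name, lam): np.zeros(n_copies + 1)
        for spec in specs
        for lam in lam_list
    }
    fit_opts = {"tol": 1e-5, "max_sweeps": 2000}
    fit_opts.update(fit_kwargs)
    for rep in range(reps):
        rep_seed = seed + rep
        enlarged = add_noisy_copies(
            data, gene_id, n_copies=n_copies, noise_sd=noise_sd, seed=rep_seed
        )
        labels = _block_labels(gene_id, n_copies)
        block_idx = [enlarged.gene_ids.index(lbl) for lbl in labels]
        for spec in specs:
            pen = np.concatenate([base, spec.copy_ws])
            pen[j_orig] = spec.original_w
            for lam in lam_list:
                model = fit(
                    enlarged, lam, penalties=pen, family=BINOMIAL, **fit_opts
                )
                sel = model.beta[block_idx] != 0
                counts[(spec.name, lam)] += sel
    results = []
    for spec in specs:
        for lam in lam_list:
            results.append(
                ExperimentResult(
                    feature_labels=_block_labels(gene_id, n_copies),
                    selection_counts=counts[(spec.name, lam)],
                    reps=reps,
                    lam=float(lam),
                    scenario=spec,
                    seed=seed,
                )
            )
    return results


def run_predictive_power(
    data: DesignData,
    penalty_perturbations: Sequence[tuple[str, float]],
    lam_list: Sequence[float] = (0.20, 0.25, 0.50, 1.0),
    reps: int = 100,
    seed: int = 0,
    base_penalties: np.ndarray | None = None,
    data_factory: Callable[[int], DesignData] | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Effect of single-feature penalty overrides on coefficients/selection.

    For every (gene, penalty override) configuration and every lambda, the
    model is refitted over ``reps`` repetitions; each repetition uses either
    a fresh dataset from ``data_factory(rep_seed)`` or, by default, a
    bootstrap resample of the supplied rows (the data are otherwise fixed,
    so repetition variability must come from the sampling).  Reported per
    configuration: mean |coefficient| of the perturbed feature and its
    selection frequency.
    """
    base = (
        np.ones(data.q)
        if base_penalties is None
        else np.asarray(base_penalties, dtype=float)
    )
    for g, w in penalty_perturbations:
        if g not in data.gene_ids:
            raise KeyError(f"unknown gene {g!r}")
        if not 0 < w <= 1:
            raise ValueError(f"penalty override for {g!r} must be in (0, 1]")
    fit_opts = {"tol": 1e-5, "max_sweeps": 2000}
    fit_opts.update(fit_kwargs)
    rows = []
    for gene, w_override in penalty_perturbations:
        j = data.gene_ids.index(gene)
        pen = base.copy()
        pen[j] = w_override
        for lam in lam_list:
            abs_beta = np.zeros(reps)
            selected = np.zeros(reps, dtype=bool)
            for rep in range(reps):
                rep_seed = seed + rep
                if data_factory is not None:
                    d = data_factory(rep_seed)
                else:
                    rng = np.random.default_rng(rep_seed)
                    idx = rng.integers(0, data.n, size=data.n)
                    d = DesignData(
                        X=data.X[idx],
                        y=np.asarray(data.y)[idx],
                        sample_ids=[data.sample_ids[i] for i in idx],
                        gene_ids=list(data.gene_ids),
                    )
                model = fit(d, lam, penalties=pen, family=BINOMIAL, **fit_opts)
                abs_beta[rep] = abs(model.beta[j])
                selected[rep] = model.beta[j] != 0
            rows.append(
                {
                    "gene_id": gene,
                    "w_override": float(w_override),
                    "lam": float(lam),
                    "mean_abs_beta": float(abs_beta.mean()),
                    "selection_freq": float(selected.mean()),
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)
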