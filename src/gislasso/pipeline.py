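"""Expression-file reading, run configuration, and the end-to-end pipeline.

The pipeline ties the stages together: parse ontologies, read and unfold
annotations, build annotation matrices, score genes (GIS -> penalties), fit
or cross-validate the weighted-LASSO model, and write every artifact (term
statistics, per-gene scores, CV table, coefficients, selection sets, JSON
run report) into an output directory.  Runs are deterministic given the
same inputs and seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import build_matrices, read_annotations, unfold
from .gis import compute_gis, penalty_transform
from .ontology import DEFAULT_RELATIONSHIPS, parse_obo
from .wlasso import (
    DesignData,
    cross_validate,
    fit,
    fit_multiclass,
    get_family,
)

__all__ = ["RunConfig", "read_expression", "read_penalties", "pipeline_run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    obo_paths: list[str]
    annotation_paths: list[str]
    expression_path: str
    label_column: str
    out_dir: str
    annotation_format: str = "tsv"
    relationship_filter: tuple[str, ...] = tuple(sorted(DEFAULT_RELATIONSHIPS))
    lam_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.5, 1.0)
    shape_grid: tuple[float, ...] = (1.0,)
    cv_folds: int = 5
    family: str = "binomial"
    multiclass: bool = False
    seed: int = 0
    min_overlap: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def validate(self) -> None:
        for p in [*self.obo_paths, *self.annotation_paths, self.expression_path]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def read_expression(path, label_column: str) -> DesignData:
    """Read a samples x genes expression table (CSV/TSV) into DesignData.

    First column holds sample ids; ``label_column`` is split off as the
    response; remaining columns must be numeric gene values.  The delimiter
    is sniffed from the extension (.csv -> comma, otherwise tab).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    genes_in_header = header[1:]
    dupes = {g for g in genes_in_header if genes_in_header.count(g) > 1}
    if dupes:
        raise ValueError(f"duplicate gene column(s): {sorted(dupes)}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    y = df[label_column].to_numpy()
    expr = df.drop(columns=[label_column])
    bad = []
    for col in expr.columns:
        coerced = pd.to_numeric(expr[col], errors="coerce")
        if coerced.isna().any() and not expr[col].isna().all():
            for idx in expr.index[coerced.isna()]:
                bad.append(f"({idx}, {col}) = {expr.at[idx, col]!r}")
        expr[col] = coerced
    if bad:
        raise ValueError("non-numeric expression cells: " + "; ".join(bad[:20]))
    return DesignData(
        X=expr.to_numpy(dtype=float),
        y=y,
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in expr.columns],
    )


def read_penalties(path) -> tuple[list[str], dict[str, float]]:
    """Read a per-gene penalty TSV (as written by the ``gis`` command)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "wgis" not in df.columns:
        raise ValueError("penalty file needs 'gene_id' and 'wgis' columns")
    return list(df["gene_id"].astype(str)), dict(
        zip(df["gene_id"].astype(str), df["wgis"].astype(float))
    )


def pipeline_run(config: RunConfig) -> Path:
    """Run ontology -> annotations -> GIS -> fit/CV and write all artifacts.

    Genes present in the expression data but absent from the annotations get
    GIS = 0, hence the maximal penalty: absent knowledge is treated as no
    knowledge, not missing data.  A gene-identifier overlap below
    ``config.min_overlap`` triggers a warning; zero overlap is an error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ontologies = [
        parse_obo(p, relationship_filter=set(config.relationship_filter))
        for p in config.obo_paths
    ]
    # ontologies must have distinct ids for pooled columns
    seen: dict[str, int] = {}
    for o in ontologies:
        if o.ontology_id in seen:
            o.ontology_id = f"{o.ontology_id}_{seen[o.ontology_id]}"
        seen[o.ontology_id] = seen.get(o.ontology_id, 0) + 1

    term_stats = pd.concat(
        [o.term_statistics().assign(ontology_id=o.ontology_id) for o in ontologies],
        ignore_index=True,
    )
    term_stats.to_csv(out / "term_stats.tsv", sep="\t", index=False)

    ann = None
    for p in config.annotation_paths:
        part = read_annotations(p, format=config.annotation_format)
        if ann is None:
            ann = part
        else:
            for g, buckets in part.direct.items():
                tgt = ann.direct.setdefault(g, {})
                for k, terms in buckets.items():
                    tgt.setdefault(k, set()).update(terms)
            ann.gene_ids = sorted(ann.direct)
    ann = unfold(ann, ontologies)

    data = read_expression(config.expression_path, config.label_column)
    overlap = set(data.gene_ids) & set(ann.gene_ids)
    frac = len(overlap) / len(data.gene_ids)
    if not overlap:
        raise ValueError(
            "no gene identifiers shared between expression and annotations"
        )
    if frac < config.min_overlap:
        warnings.warn(
            f"only {frac:.1%} of expression genes have annotations "
            f"(floor {config.min_overlap:.0%})"
        )

    matrices = build_matrices(ann, ontologies)
    gis = compute_gis(matrices)
    # expression genes missing from the annotation sources score 0
    for g in data.gene_ids:
        gis.gis.setdefault(g, 0.0)
    gis.gene_ids = list(data.gene_ids)

    family = get_family(config.family)
    rng = np.random.default_rng(config.seed)
    cv_seed = int(rng.integers(2**31 - 1))

    if config.multiclass:
        # penalty shape fixed at the default for one-vs-rest runs
        shape = config.shape_grid[0]
        pen = penalty_transform(gis, shape=shape)
        lam = config.lam_grid[0]
        cv_table = None
        model = fit_multiclass(data, lam, penalties=pen, family=family)
        coef_rows = [
            {"gene_id": g, "class": str(m.label), "beta": b, "selected": b != 0}
            for m in model.models
            for g, b in zip(m.gene_ids, m.beta)
        ]
        best = (lam, shape)
        n_iter = [m.n_iter for m in model.models]
        converged = all(m.converged for m in model.models)
    else:
        y = data.y
        if family.name == "binomial" and not np.isin(np.unique(y), [0, 1]).all():
            classes = np.unique(y)
            if len(classes) != 2:
                raise ValueError(
                    "binary fit requires 2 classes; use multiclass: true"
                )
            data = DesignData(
                X=data.X,
                y=(y == classes[1]).astype(int),
                sample_ids=data.sample_ids,
                gene_ids=data.gene_ids,
            )
        cv_table, best = cross_validate(
            data,
            lam_grid=config.lam_grid,
            shape_grid=config.shape_grid,
            gis=gis,
            k_folds=config.cv_folds,
            seed=cv_seed,
            family=family,
        )
        lam, shape = best
        pen = penalty_transform(gis, shape=shape)
        model = fit(data, lam, penalties=pen, family=family)
        coef_rows = [
            {"gene_id": g, "class": "binary", "beta": b, "selected": b != 0}
            for g, b in zip(model.gene_ids, model.beta)
        ]
        n_iter = [model.n_iter]
        converged = model.converged

    wgis = penalty_transform(gis, shape=best[1])
    n_terms = {
        g: int(matrices.B[matrices.genes.index(g)].nnz)
        for g in gis.gene_ids
        if g in matrices.genes
    }
    gis_frame = gis.to_frame(n_terms=n_terms)
    gis_frame["wgis"] = [wgis.w[g] for g in gis.gene_ids]
    gis_frame.to_csv(out / "gis.tsv", sep="\t", index=False)

    if cv_table is not None:
        cv_table.to_csv(out / "cv_table.tsv", sep="\t", index=False)
    pd.DataFrame(coef_rows).to_csv(out / "coefficients.tsv", sep="\t", index=False)

    report = {
        "version": __version__,
        "seed": config.seed,
        "cv_seed": cv_seed,
        "lam": best[0],
        "shape": best[1],
        "family": family.name,
        "n_iter": n_iter,
        "converged": converged,
        "conventions": {
            "depth": "longest path from any root, roots at depth 0",
            "relationship_filter": list(config.relationship_filter),
            "standardized_features": True,
            "loss_scale": "1/n-scaled negative log-likelihood",
            "log_base": "natural (base-invariant ratio)",
        },
        "config": {
            "obo_paths": config.obo_paths,
            "annotation_paths": config.annotation_paths,
            "expression_path": config.expression_path,
            "label_column": config.label_column,
            "lam_grid": list(config.lam_grid),
            "shape_grid": list(config.shape_grid),
            "cv_folds": config.cv_folds,
            "multiclass": config.multiclass,
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline artifacts written to %s", out)
    return out
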