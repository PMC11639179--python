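"""Gene-to-term annotations: reading, DAG unfolding, and annotation matrices.

A gene's direct annotations are the most specific ontology terms it is
associated with.  Unfolding replaces each direct term with its full ancestor
closure (the term itself plus every ancestor in the ontology DAG), producing
the complete annotation list the gene implicitly carries.  From the unfolded
lists two genes x terms matrices are built over the pooled terms of all
supplied ontologies: the binary matrix B (membership) and the weighted
matrix W = B scaled columnwise by each term's structural information
content.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ontology import Ontology

__all__ = ["AnnotationSet", "AnnotationMatrices", "read_annotations", "unfold",
           "build_matrices"]

logger = logging.getLogger(__name__)

#: key used for direct annotations before they are resolved to an ontology
UNRESOLVED = ""

# GAF 2.x column positions (0-based)
_GAF_GENE_COL = 2      # DB Object Symbol
_GAF_QUALIFIER_COL = 3
_GAF_TERM_COL = 4
_GAF_NCOLS = 17


@dataclass
class AnnotationSet:
    """Direct and unfolded gene annotations.

    ``direct`` maps gene -> ontology id -> most-specific term ids; terms read
    from a file that has no ontology context sit under the ``UNRESOLVED``
    key until :func:`unfold` assigns them.  ``unfolded`` maps gene -> set of
    ``(ontology_id, term_id)`` pairs after ancestor closure (None before
    unfolding).
    """

    gene_ids: list[str]
    direct: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    unfolded: dict[str, set[tuple[str, str]]] | None = None

    def direct_terms(self, gene_id: str) -> set[str]:
        """All direct term ids of a gene, regardless of ontology bucket."""
        out: set[str] = set()
        for terms in self.direct.get(gene_id, {}).values():
            out |= terms
        return out

    def n_direct(self, gene_id: str) -> int:
        return len(self.direct_terms(gene_id))


def read_annotations(path, format: str = "tsv") -> AnnotationSet:
    """Read gene->term annotations from a GAF 2.x or two-column TSV file.

    GAF rows whose qualifier contains ``NOT`` are skipped (negated
    annotations), as are ``!`` comment lines.  Malformed rows are skipped
    with a warning carrying the count.  Duplicate gene-term pairs collapse.
    """
    if format not in ("gaf", "tsv"):
        raise ValueError(f"unknown annotation format {format!r}")
    direct: dict[str, dict[str, set[str]]] = {}
    n_bad = 0
    n_rows = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gaf":
                if len(fields) < _GAF_TERM_COL + 1:
                    n_bad += 1
                    continue
                if "NOT" in fields[_GAF_QUALIFIER_COL].split("|"):
                    continue
                gene, term = fields[_GAF_GENE_COL], fields[_GAF_TERM_COL]
            else:
                if len(fields) < 2:
                    n_bad += 1
                    continue
                gene, term = fields[0], fields[1]
            if not gene or not term:
                n_bad += 1
                continue
            direct.setdefault(gene, {}).setdefault(UNRESOLVED, set()).add(term)
            n_rows += 1
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed annotation rows in {path}")
    if n_rows == 0:
        raise ValueError(f"no usable annotation rows in {path}")
    return AnnotationSet(gene_ids=sorted(direct), direct=direct)


def unfold(annotations: AnnotationSet, ontologies: list[Ontology]) -> AnnotationSet:
    """Fill ``unfolded`` with the ancestor closure of every direct term.

    Each direct term is resolved against the supplied ontologies (first
    match wins; replaced_by followed for obsolete ids) and expanded to
    ``{term} | ancestors(term)`` under that ontology's relationship filter.
    Unresolvable terms are dropped with a logged count.  Idempotent: the
    closure of a closure is itself.
    """
    by_id = {o.ontology_id: o for o in ontologies}
    unfolded: dict[str, set[tuple[str, str]]] = {}
    resolved_direct: dict[str, dict[str, set[str]]] = {}
    n_dropped = 0
    for gene in annotations.gene_ids:
        closure: set[tuple[str, str]] = set()
        buckets: dict[str, set[str]] = {}
        for okey, terms in annotations.direct.get(gene, {}).items():
            for term in terms:
                onto, tid = None, None
                if okey in by_id:  # already bucketed under a known ontology
                    rid = by_id[okey].resolve(term)
                    if rid is not None:
                        onto, tid = by_id[okey], rid
                else:
                    for cand in ontologies:
                        rid = cand.resolve(term)
                        if rid is not None:
                            onto, tid = cand, rid
                            break
                if onto is None:
                    n_dropped += 1
                    continue
                buckets.setdefault(onto.ontology_id, set()).add(tid)
                closure.add((onto.ontology_id, tid))
                closure.update(
                    (onto.ontology_id, a) for a in onto.ancestors(tid)
                )
        unfolded[gene] = closure
        resolved_direct[gene] = buckets
    if n_dropped:
        logger.warning("dropped %d unresolvable direct annotations", n_dropped)
    return AnnotationSet(
        gene_ids=list(annotations.gene_ids),
        direct=resolved_direct,
        unfolded=unfolded,
    )


class AnnotationMatrices:
    """Sparse binary (B) and weighted (W) annotation matrices.

    Rows are genes in a fixed order; columns are the pooled
    ``(ontology_id, term_id)`` pairs of all supplied ontologies.  W carries
    ``B * ic_struct(term)`` entrywise, so W > 0 exactly where a gene is
    annotated to a term with positive information content.
    """

    def __init__(
        self,
        genes: list[str],
        terms: list[tuple[str, str]],
        B: sp.spmatrix,
        W: sp.spmatrix,
    ) -> None:
        if len(set(terms)) != len(terms):
            raise ValueError("pooled term column labels must be unique")
        self.genes = list(genes)
        self.terms = list(terms)
        self.B = sp.csr_matrix(B)
        self.W = sp.csr_matrix(W)
        if self.B.shape != (len(self.genes), len(self.terms)):
            raise ValueError("B shape does not match gene/term labels")
        if self.W.shape != self.B.shape:
            raise ValueError("B and W shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.B.shape

    def row(self, gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Dense (binary, weighted) rows for one gene."""
        i = self.genes.index(gene_id)
        return (
            np.asarray(self.B[i].todense()).ravel(),
            np.asarray(self.W[i].todense()).ravel(),
        )

    def to_mtx(self, prefix: str) -> None:
        """Export W as Matrix Market plus row/column label TSVs."""
        import scipy.io as sio

        sio.mmwrite(f"{prefix}_W.mtx", sp.coo_matrix(self.W))
        sio.mmwrite(f"{prefix}_B.mtx", sp.coo_matrix(self.B))
        pd.Series(self.genes, name="gene_id").to_csv(
            f"{prefix}_genes.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.terms, columns=["ontology_id", "term_id"]).to_csv(
            f"{prefix}_terms.tsv", sep="\t", index=False
        )


def build_matrices(
    annotations: AnnotationSet, ontologies: list[Ontology]
) -> AnnotationMatrices:
    """Build B and W over the pooled term columns of all ontologies.

    Requires unfolded annotations (run :func:`unfold` first); raises on an
    empty gene list.
    """
    if annotations.unfolded is None:
        raise ValueError("annotations must be unfolded before building matrices")
    if not annotations.gene_ids:
        raise ValueError("empty gene list")
    columns: list[tuple[str, str]] = []
    ic: list[float] = []
    for onto in ontologies:
        for tid in sorted(onto.graph):
            columns.append((onto.ontology_id, tid))
            ic.append(onto.ic_struct(tid))
    col_index = {c: j for j, c in enumerate(columns)}
    ic_arr = np.asarray(ic)

    rows, cols = [], []
    for i, gene in enumerate(annotations.gene_ids):
        for pair in annotations.unfolded.get(gene, ()):
            j = col_index.get(pair)
            if j is not None:
                rows.append(i)
                cols.append(j)
    data = np.ones(len(rows))
    B = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(annotations.gene_ids), len(columns))
    ).tocsr()
    W = B.multiply(ic_arr[None, :]).tocsr()
    return AnnotationMatrices(annotations.gene_ids, columns, B, W)
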