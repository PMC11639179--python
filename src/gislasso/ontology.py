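"""Ontology DAGs and structure-based term information content.

A biomedical ontology (GO, HPO, ...) is a controlled vocabulary whose terms
form a directed acyclic graph under typed relationships such as ``is_a`` and
``part_of``.  This module parses OBO flat files into :class:`Ontology`
objects, computes per-term structural statistics (depth as longest path from
a root, number of distinct descendants) and scores every term with a
structure-based information content

    ic_struct(t) = depth(t) / max_depth * (1 - log(desc(t) + 1) / log(total_terms))

which is 0 for roots, 1 for childless terms at maximal depth, and lies in
[0, 1] everywhere else.  The log ratio makes the logarithm base irrelevant;
natural logs are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "DEFAULT_RELATIONSHIPS",
    "OntologyTerm",
    "Ontology",
    "DegenerateOntologyError",
    "OntologyCycleError",
    "parse_obo",
    "compute_depth",
    "count_descendants",
    "ic_struct",
]

#: Relationship types considered for the DAG structure unless overridden.
DEFAULT_RELATIONSHIPS = frozenset({"is_a", "part_of"})


class DegenerateOntologyError(ValueError):
    """Raised when an ontology has no exploitable structure.

    Scoring requires at least two non-obsolete terms and a positive maximum
    depth; flat or singleton vocabularies carry no depth information and are
    rejected rather than silently scored zero.
    """


class OntologyCycleError(ValueError):
    """Raised when the relationship-filtered graph contains a cycle."""


@dataclass
class OntologyTerm:
    """A single ontology term.

    ``parents`` maps a relationship-type label (e.g. ``"is_a"``) to the set
    of parent term ids reachable through that relationship.
    """

    term_id: str
    name: str = ""
    parents: dict[str, set[str]] = field(default_factory=dict)
    obsolete: bool = False
    replaced_by: str | None = None

    def __post_init__(self) -> None:
        for rel, ids in self.parents.items():
            if self.term_id in ids:
                raise ValueError(
                    f"term {self.term_id!r} lists itself as a {rel!r} parent"
                )

    def parent_ids(self, relationship_filter: Iterable[str]) -> set[str]:
        """Parent ids restricted to the given relationship types."""
        out: set[str] = set()
        for rel in relationship_filter:
            out |= self.parents.get(rel, set())
        return out


class Ontology:
    """A typed term DAG with cached structural statistics.

    Parameters
    ----------
    ontology_id
        Label for the knowledge base (used to namespace pooled term columns).
    terms
        The terms, obsolete ones included (they are excluded from every
        statistic but kept so annotations can be remapped via replaced_by).
    relationship_filter
        Relationship-type labels whose edges define the DAG structure.
    """

    def __init__(
        self,
        ontology_id: str,
        terms: Iterable[OntologyTerm],
        relationship_filter: Iterable[str] = DEFAULT_RELATIONSHIPS,
    ) -> None:
        self.ontology_id = str(ontology_id)
        self.relationship_filter = frozenset(relationship_filter)
        if not self.relationship_filter:
            raise ValueError("relationship_filter must be non-empty")
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.term_id in self.terms:
                raise ValueError(f"duplicate term id {term.term_id!r}")
            self.terms[term.term_id] = term

        self._graph = self._build_graph()
        self.depth = compute_depth(self)
        self.n_descendants = count_descendants(self)
        self.max_depth = max(self.depth.values(), default=0)
        self.total_terms = self._graph.number_of_nodes()

    def _build_graph(self) -> nx.DiGraph:
        """Parent -> child digraph over non-obsolete terms, filtered edges."""
        g = nx.DiGraph()
        for tid, term in self.terms.items():
            if term.obsolete:
                continue
            g.add_node(tid)
        for tid, term in self.terms.items():
            if term.obsolete:
                continue
            for pid in term.parent_ids(self.relationship_filter):
                # edges to unknown or obsolete parents are dropped
                if pid in g:
                    g.add_edge(pid, tid)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyCycleError(
                f"cycle detected in filtered ontology graph involving "
                f"term {cycle[0][0]!r}"
            )
        return g

    # -- structure access -------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """The parent->child DAG over non-obsolete terms (read-only use)."""
        return self._graph

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._graph

    def roots(self) -> set[str]:
        return {t for t in self._graph if self._graph.in_degree(t) == 0}

    def ancestors(self, term_id: str) -> set[str]:
        """All terms lying on some path from a root to ``term_id`` (exclusive)."""
        if term_id not in self._graph:
            raise KeyError(f"unknown or obsolete term {term_id!r}")
        return nx.ancestors(self._graph, term_id)

    def resolve(self, term_id: str) -> str | None:
        """Map a term id to a usable non-obsolete id, following replaced_by.

        Returns None when the id is unknown or obsolete without replacement.
        """
        seen: set[str] = set()
        tid = term_id
        while tid not in self._graph:
            term = self.terms.get(tid)
            if term is None or term.replaced_by is None or tid in seen:
                return None
            seen.add(tid)
            tid = term.replaced_by
        return tid

    def ic_struct(self, term_id: str) -> float:
        return ic_struct(self, term_id)

    def term_statistics(self):
        """Per-term (depth, n_descendants, ic_struct) as a pandas DataFrame."""
        import pandas as pd

        rows = [
            (t, self.depth[t], self.n_descendants[t], self.ic_struct(t))
            for t in sorted(self._graph)
        ]
        return pd.DataFrame(
            rows, columns=["term_id", "depth", "n_descendants", "ic_struct"]
        )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_parent_map(
        cls,
        ontology_id: str,
        parent_map: Mapping[str, Iterable[str]],
        relationship: str = "is_a",
        relationship_filter: Iterable[str] = DEFAULT_RELATIONSHIPS,
    ) -> "Ontology":
        """Build an ontology from a ``{child: [parents]}`` mapping.

        Convenience constructor for synthetic and toy DAGs; every mentioned
        id becomes a term, edges all carry ``relationship``.
        """
        ids = set(parent_map)
        for parents in parent_map.values():
            ids.update(parents)
        terms = [
            OntologyTerm(
                term_id=tid,
                parents={relationship: set(parent_map.get(tid, ()))},
            )
            for tid in sorted(ids)
        ]
        return cls(ontology_id, terms, relationship_filter)


def parse_obo(
    path,
    relationship_filter: Iterable[str] = DEFAULT_RELATIONSHIPS,
    ontology_id: str | None = None,
) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Obsolete terms are retained on the object (so annotation remapping via
    their ``replaced_by`` tag is possible) but excluded from the DAG, the
    term count, and all statistics.  Edges are restricted to
    ``relationship_filter``.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    terms: list[OntologyTerm] = []
    for tid, data in graph.nodes(data=True):
        parents: dict[str, set[str]] = {}
        for pid in data.get("is_a", []):
            parents.setdefault("is_a", set()).add(pid)
        for entry in data.get("relationship", []):
            # OBO relationship lines read as "<type> <target id>"
            parts = entry.split()
            if len(parts) >= 2:
                parents.setdefault(parts[0], set()).add(parts[1])
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        replaced = data.get("replaced_by") or None
        if isinstance(replaced, list):
            replaced = replaced[0] if replaced else None
        terms.append(
            OntologyTerm(
                term_id=tid,
                name=data.get("name", ""),
                parents=parents,
                obsolete=obsolete,
                replaced_by=replaced,
            )
        )
    if ontology_id is None:
        ontology_id = str(graph.graph.get("ontology", "") or "ontology")
    return Ontology(ontology_id, terms, relationship_filter)


def compute_depth(ontology: Ontology) -> dict[str, int]:
    """Depth of every non-obsolete term: longest path (in edges) from a root.

    Roots (terms without parents under the relationship filter) have depth 0;
    in multi-rooted DAGs the maximum over all root-to-term paths is taken.
    """
    g = ontology.graph
    depth: dict[str, int] = {}
    for tid in nx.topological_sort(g):
        preds = list(g.predecessors(tid))
        depth[tid] = 0 if not preds else max(depth[p] for p in preds) + 1
    return depth


def count_descendants(ontology: Ontology) -> dict[str, int]:
    """Number of distinct non-obsolete terms having each term as ancestor."""
    g = ontology.graph
    return {tid: len(nx.descendants(g, tid)) for tid in g}


def ic_struct(ontology: Ontology, term_id: str) -> float:
    """Structure-based information content of a term, in [0, 1].

    Combines the term's relative depth with the (log-scaled) fraction of the
    vocabulary below it: deep, specific terms score high; roots score 0.

    Raises
    ------
    KeyError
        If the term is unknown or obsolete.
    DegenerateOntologyError
        If the ontology has fewer than two terms or zero maximum depth.
    """
    if term_id not in ontology.graph:
        raise KeyError(f"unknown or obsolete term {term_id!r}")
    if ontology.total_terms < 2 or ontology.max_depth < 1:
        raise DegenerateOntologyError(
            f"ontology {ontology.ontology_id!r} has total_terms="
            f"{ontology.total_terms}, max_depth={ontology.max_depth}; "
            "no structural information to score"
        )
    depth_factor = ontology.depth[term_id] / ontology.max_depth
    desc = ontology.n_descendants[term_id]
    spec_factor = 1.0 - math.log(desc + 1) / math.log(ontology.total_terms)
    return depth_factor * spec_factor
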