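import numpy as np
import pytest

from gislasso import Ontology


@pytest.fixture
def chain_ontology():
    """A <- B <- C is_a chain."""
    return Ontology.from_parent_map("CH", {"B": ["A"], "C": ["B"]})


@pytest.fixture
def diamond_ontology():
    """A -> {B, C} -> D plus a longer chain A -> E -> F -> D."""
    return Ontology.from_parent_map(
        "DI",
        {"B": ["A"], "C": ["A"], "D": ["B", "C", "F"], "E": ["A"], "F": ["E"]},
    )


@pytest.fixture
def star_ontology():
    """Root with three childless depth-1 leaves (every leaf has IC 1)."""
    return Ontology.from_parent_map(
        "ST", {"L1": ["R"], "L2": ["R"], "L3": ["R"]}
    )


TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: T:0001
name: root

[Term]
id: T:0002
name: middle
is_a: T:0001

[Term]
id: T:0003
name: leaf
is_a: T:0002
relationship: regulates T:0001
"""


@pytest.fixture
def toy_obo(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


def random_parent_map(rng: np.random.Generator, n_terms: int) -> dict:
    """Random DAG as {child: [parents]} with ids t0..t{n-1}; edges i<j only."""
    parent_map = {"t0": []}
    for j in range(1, n_terms):
        k = int(rng.integers(1, min(3, j) + 1))
        parents = rng.choice(j, size=k, replace=False)
        parent_map[f"t{j}"] = [f"t{p}" for p in parents]
    return parent_map


def brute_force_depth(parent_map: dict) -> dict:
    """Longest root-to-term path length by exhaustive path enumeration."""
    def depth(t):
        parents = parent_map.get(t, [])
        if not parents:
            return 0
        return 1 + max(depth(p) for p in parents)

    return {t: depth(t) for t in parent_map}


def brute_force_descendants(parent_map: dict) -> dict:
    """Distinct-descendant counts via recursive child reachability."""
    children = {t: set() for t in parent_map}
    for child, parents in parent_map.items():
        for p in parents:
            children[p].add(child)

    def reach(t):
        out = set()
        for c in children[t]:
            out.add(c)
            out |= reach(c)
        return out

    return {t: len(reach(t)) for t in parent_map}
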