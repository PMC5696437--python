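"""Rooted clock trees with node ages.

Topologies are inputs (newick or dendropy trees); only small rooted trees
are expected.  Internal nodes are addressed by the frozenset of tip names
they subtend, which is unambiguous on a fixed rooted topology.  Tips have
age 0; internal-node ages increase rootward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy

Clade = frozenset


@dataclass
class ClockTree:
    """Postorder-indexed rooted topology. Node i's children precede it."""

    taxa: tuple[str, ...]            # tip names, index = node id for tips
    children: list[list[int]]        # per node; empty for tips
    clades: list[Clade]              # tip-name set subtended by each node

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def node_for_clade(self, clade: Sequence[str] | Clade) -> int:
        key = frozenset(clade)
        for i, c in enumerate(self.clades):
            if c == key:
                return i
        raise KeyError(f"no node subtends exactly {sorted(key)}")

    @classmethod
    def from_newick(cls, newick: str) -> "ClockTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "ClockTree":
        taxa: list[str] = []
        children: list[list[int]] = []
        clades: list[Clade] = []
        index: dict[int, int] = {}
        # first pass: tips in leaf order
        for leaf in tree.leaf_node_iter():
            index[id(leaf)] = len(taxa)
            taxa.append(leaf.taxon.label.replace(" ", "_"))
            children.append([])
            clades.append(frozenset([taxa[-1]]))
        # internal nodes in postorder
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            kids = [index[id(c)] for c in node.child_nodes()]
            index[id(node)] = len(children)
            children.append(kids)
            clades.append(frozenset().union(*(clades[k] for k in kids)))
        if len(children[-1]) < 2:
            raise ValueError("root must have at least two children")
        return cls(taxa=tuple(taxa), children=children, clades=clades)

    def ages_vector(self, ages: Mapping[Clade, float]) -> list[float]:
        """Expand a clade->age mapping to a per-node age list (tips 0)."""
        out = [0.0] * self.n_nodes
        for i in self.internal_nodes:
            key = self.clades[i]
            if key not in ages:
                raise KeyError(f"missing age for clade {sorted(key)}")
            out[i] = float(ages[key])
        self.validate_ages(out)
        return out

    def validate_ages(self, ages: Sequence[float]) -> None:
        for i in self.internal_nodes:
            if ages[i] < 0:
                raise ValueError("negative node age")
            for c in self.children[i]:
                if ages[c] >= ages[i]:
                    raise ValueError(
                        "non-ultrametric age assignment: child at least as old as parent"
                    )

    def branch_durations(self, ages: Sequence[float]) -> list[tuple[int, float]]:
        """(child, parent_age - child_age) for every non-root node."""
        parent = [-1] * self.n_nodes
        for i in self.internal_nodes:
            for c in self.children[i]:
                parent[c] = i
        return [
            (i, ages[parent[i]] - ages[i])
            for i in range(self.n_nodes)
            if parent[i] >= 0
        ]

    def to_newick(self, ages: Mapping[Clade, float] | None = None) -> str:
        vec = self.ages_vector(ages) if ages is not None else None

        def render(i: int) -> str:
            if not self.children[i]:
                return self.taxa[i]
            inner = ",".join(render(c) for c in self.children[i])
            return f"({inner})"

        def render_bl(i: int, parent_age: float) -> str:
            bl = parent_age - vec[i]
            if not self.children[i]:
                return f"{self.taxa[i]}:{bl:g}"
            inner = ",".join(render_bl(c, vec[i]) for c in self.children[i])
            return f"({inner}):{bl:g}"

        if vec is None:
            return render(self.root) + ";"
        inner = ",".join(render_bl(c, vec[self.root]) for c in self.children[self.root])
        return f"({inner});"
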