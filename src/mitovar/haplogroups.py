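"""Haplogroup assignment from a PhyloTree-style tree of defining variants.

Each node of the tree carries the variant labels that define its branch; a
sample is assigned to the node maximizing ``matched / expected`` over the
defining variants accumulated along the root path (a simplified
Kulczynski-style score).  Private variants are never penalized.  Ties break
toward the deeper node, then lexicographically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field


@dataclass
class HaploNode:
    name: str
    parent: str | None
    defining_variants: list = field(default_factory=list)


@dataclass
class HaploTree:
    nodes: dict  # name -> HaploNode
    root: str

    def path_variants(self, node_name: str) -> list:
        """All defining variants on the root -> node path."""
        out = []
        name = node_name
        seen = set()
        while name is not None:
            if name in seen:
                raise ValueError("cycle in haplogroup tree")
            seen.add(name)
            node = self.nodes[name]
            out = list(node.defining_variants) + out
            name = node.parent
        return out

    def depth(self, node_name: str) -> int:
        d = 0
        name = self.nodes[node_name].parent
        while name is not None:
            d += 1
            name = self.nodes[name].parent
        return d


@dataclass
class HaplogroupAssignment:
    sample_id: str
    haplogroup: str
    matched: int
    expected: int
    score: float
    runner_up: str | None = None
    runner_up_score: float = 0.0
    tie: bool = False


def _check_label(label: str):
    if "!" in label:
        raise ValueError(
            f"back-mutation notation {label!r} not supported by this parser"
        )


def load_tree(path) -> HaploTree:
    """Load a tree from TSV (``node parent defining_variants``) or JSON."""
    path = str(path)
    nodes: dict = {}
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        for entry in payload["nodes"]:
            nodes[entry["name"]] = HaploNode(
                name=entry["name"],
                parent=entry.get("parent") or None,
                defining_variants=list(entry.get("defining_variants", [])),
            )
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["node", "parent"]:
                raise ValueError("tree TSV must start with columns: node parent")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                name = parts[0]
                parent = parts[1] if len(parts) > 1 and parts[1] else None
                variants = (
                    [v for v in parts[2].split(",") if v]
                    if len(parts) > 2 and parts[2]
                    else []
                )
                nodes[name] = HaploNode(name, parent, variants)
    if not nodes:
        raise ValueError("empty haplogroup tree")
    roots = [n for n in nodes.values() if n.parent is None]
    if len(roots) != 1:
        raise ValueError(f"tree must have exactly one root, found {len(roots)}")
    for node in nodes.values():
        if node.parent is not None and node.parent not in nodes:
            raise ValueError(f"node {node.name!r} has unknown parent {node.parent!r}")
        for label in node.defining_variants:
            _check_label(label)
    tree = HaploTree(nodes=nodes, root=roots[0].name)
    for name in nodes:
        tree.path_variants(name)  # raises on cycles
    return tree


def bundled_tree() -> HaploTree:
    from importlib.resources import files

    return load_tree(str(files("mitovar") / "data" / "haplotree.tsv"))


def score_node(sample_variants: set, tree: HaploTree, node_name: str):
    """(matched, expected, score) for one node's root path."""
    expected = tree.path_variants(node_name)
    matched = sum(1 for v in expected if v in sample_variants)
    score = matched / len(expected) if expected else 0.0
    return matched, len(expected), score


def assign_haplogroup(sample_variants, tree: HaploTree, sample_id: str = "") -> HaplogroupAssignment:
    """Best-scoring node wins; ties break by depth then name."""
    sample_set = set(sample_variants)
    scored = []
    for name in tree.nodes:
        matched, expected, score = score_node(sample_set, tree, name)
        scored.append((score, tree.depth(name), name, matched, expected))
    # best: highest score, then deepest, then lexicographically first;
    # an all-zero profile lands at the root
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best = scored[0]
    if best[0] == 0.0:
        matched, expected, score = score_node(sample_set, tree, tree.root)
        return HaplogroupAssignment(
            sample_id=sample_id, haplogroup=tree.root,
            matched=matched, expected=expected, score=score,
        )
    tie = len(scored) > 1 and scored[1][0] == best[0] and scored[1][1] == best[1]
    runner = next((s for s in scored[1:] if s[2] != best[2]), None)
    return HaplogroupAssignment(
        sample_id=sample_id,
        haplogroup=best[2],
        matched=best[3],
        expected=best[4],
        score=best[0],
        runner_up=runner[2] if runner else None,
        runner_up_score=runner[0] if runner else 0.0,
        tie=tie,
    )


def macro_haplogroup(tree: HaploTree, node_name: str, macros=("M", "N")) -> str | None:
    """The first ancestor (or self) among the macro-haplogroup names."""
    name = node_name
    while name is not None:
        if name in macros:
            return name
        name = tree.nodes[name].parent
    return None
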