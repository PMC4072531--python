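"""Shared helpers: sequence/tree simulators and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from sirphylo.io_core import PhyloTree, ProteinSequence, TreeNode
from sirphylo.msa import MultipleAlignment
from sirphylo.tree_infer import SubstitutionModel, discrete_gamma_rates

AA = "ARNDCQEGHILKMFPSTWYV"


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA), n))


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply exactly n_subs substitutions at distinct positions."""
    out = list(seq)
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        choices = [c for c in AA if c != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def evolve_codes(codes: np.ndarray, model: SubstitutionModel, t: float,
                 rng: np.random.Generator) -> np.ndarray:
    if t <= 0:
        return codes.copy()
    P = model.transition_matrix(t)
    cum = P[codes].cumsum(axis=1)
    return (rng.random(len(codes))[:, None] > cum).sum(axis=1)


def simulate_alignment(tree: PhyloTree, model: SubstitutionModel, n_cols: int,
                       rng: np.random.Generator,
                       alpha: float | None = None) -> MultipleAlignment:
    """Gap-free alignment simulated down the tree; optional per-site gamma
    rates drawn from the discrete categories."""
    if alpha is None:
        site_rates = np.ones(n_cols)
    else:
        cats = discrete_gamma_rates(alpha, 4)
        site_rates = cats[rng.integers(len(cats), size=n_cols)]
    root = rng.choice(20, n_cols, p=model.stationary_frequencies)
    rows: dict[str, np.ndarray] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            rows[node.name] = seq
            return
        for child in node.children:
            t = child.length or 0.0
            out = seq.copy()
            for rate in set(site_rates.tolist()):
                mask = site_rates == rate
                out[mask] = evolve_codes(seq[mask], model, t * rate, rng)
            walk(child, out)

    walk(tree.root, root)
    ids = sorted(rows)
    return MultipleAlignment(ids, ["".join(AA[i] for i in rows[k]) for k in ids])


def random_binary_tree(names: list[str], rng: np.random.Generator,
                       blen=(0.05, 0.5)) -> PhyloTree:
    """Random unrooted binary topology with uniform branch lengths."""
    assert len(names) >= 3
    order = list(names)
    rng.shuffle(order)

    def bl() -> float:
        return float(rng.uniform(*blen))

    root = TreeNode()
    for name in order[:3]:
        root.add_child(TreeNode(name, length=bl()))
    tree = PhyloTree(root, rooted=False)
    for name in order[3:]:
        edges = tree.edges()
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        idx = parent.children.index(target)
        mid = TreeNode(length=target.length / 2)
        target.length = target.length / 2
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(TreeNode(name, length=bl()))
    return tree


def additive_distances(tree: PhyloTree):
    """Path-length distance matrix (independent of neighbor joining)."""
    leaves = tree.leaves()
    names = [l.name for l in leaves]
    parent = {}
    for node in tree.postorder():
        for c in node.children:
            parent[id(c)] = node
    n = len(leaves)
    D = np.zeros((n, n))
    for i, a in enumerate(leaves):
        anc = {}
        node, d = a, 0.0
        anc[id(node)] = 0.0
        while id(node) in parent:
            d += node.length or 0.0
            node = parent[id(node)]
            anc[id(node)] = d
        for j, b in enumerate(leaves):
            if i == j:
                continue
            node, d = b, 0.0
            while id(node) not in anc:
                d += node.length or 0.0
                node = parent[id(node)]
            D[i, j] = d + anc[id(node)]
    return names, D


def all_unrooted_topologies(names: list[str]) -> list[PhyloTree]:
    """Exhaustive enumeration by stepwise leaf insertion (3, 15, 105...)."""
    base = PhyloTree(
        TreeNode(children=[TreeNode(n, length=0.1) for n in names[:3]]),
        rooted=False,
    )
    trees = [base]
    for name in names[3:]:
        grown = []
        for tree in trees:
            for k in range(len(tree.edges())):
                new = tree.copy()
                target = new.edges()[k]
                parent = target.parent
                idx = parent.children.index(target)
                mid = TreeNode(length=0.1)
                parent.children[idx] = mid
                mid.parent = parent
                mid.add_child(target)
                mid.add_child(TreeNode(name, length=0.1))
                grown.append(new)
        trees = grown
    return trees


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
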