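"""Collapse repeat-class profiles into a putative species tree.

Repeat units are first assigned to sequence classes (the "a/b/c"-style
major groups of the repeat tree), either by manual clade anchors or by
k-medoids on patristic distances. Each species is then encoded as a
count vector over classes, and the species tree is the minimum-cost
Steiner tree connecting the observed profiles in the unit-step lattice,
where one step is a single-domain event: a tandem duplication (+1 to a
class already present), a loss (−1), or an innovation (+1 to a class with
count zero — duplication with divergence founding a new class). All unit
costs default to 1, so an edge's cost is the L1 distance between its
endpoint profiles.

Candidate Steiner points are restricted to the Hanan grid (the cartesian
product of observed per-class counts); instances with at most
``max_exact_terminals`` distinct profiles are solved exactly by the
Dreyfus–Wagner dynamic program, larger ones by a greedy shortest-path
insertion heuristic (flagged in the output). Multi-step edges are expanded
into chains of unit-step nodes; any node whose profile matches no observed
species is flagged predicted — these are the method's inferred undiscovered
or extinct intermediates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_core import PhyloTree, ValidationError

__all__ = [
    "RepeatClassLabeling",
    "SpeciesProfile",
    "CollapsedNode",
    "CollapsedEdge",
    "CollapsedSpeciesTree",
    "assign_repeat_classes",
    "build_species_profiles",
    "profile_edit_distance",
    "collapse_to_species_tree",
    "predict_missing_intermediates",
]


# ---------------------------------------------------------------------------
# Class assignment
# ---------------------------------------------------------------------------


@dataclass
class RepeatClassLabeling:
    """Mapping repeat-unit id -> class label, plus the class definitions
    (anchor leaves or medoid unit ids)."""

    labels: dict[str, str]
    class_defs: dict[str, list[str]]


def _patristic_matrix(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    leaves = tree.leaves()
    names = [l.name for l in leaves]
    n = len(names)
    index = {id(l): k for k, l in enumerate(leaves)}
    dist = np.zeros((n, n))
    # distances from each leaf by tree traversal through parent links
    parent = {}
    for node in tree.postorder():
        for child in node.children:
            parent[id(child)] = node
    for k, leaf in enumerate(leaves):
        # path lengths to all nodes
        d: dict[int, float] = {id(leaf): 0.0}
        # climb to root collecting path
        node = leaf
        while id(node) in parent:
            up = parent[id(node)]
            d[id(up)] = d[id(node)] + (node.length or 1.0)
            node = up
        # descend from every ancestor
        for other_k, other in enumerate(leaves):
            if other_k == k:
                continue
            node = other
            total = 0.0
            while id(node) not in d:
                total += node.length or 1.0
                node = parent[id(node)]
            dist[k, other_k] = total + d[id(node)]
    return names, dist


def _class_names(n: int) -> list[str]:
    out = []
    for i in range(n):
        label = ""
        x = i
        while True:
            label = chr(ord("a") + x % 26) + label
            x = x // 26 - 1
            if x < 0:
                break
        out.append(label)
    return out


def assign_repeat_classes(
    tree: PhyloTree,
    anchors: Optional[dict[str, Sequence[str]]] = None,
    k: Optional[int] = None,
    seed: int = 0,
) -> RepeatClassLabeling:
    """Assign every leaf (repeat unit) of the repeat tree to a class.

    Manual mode (``anchors``: class label -> anchor leaf names): each class
    is the smallest clade containing its anchors; clades must be disjoint
    and cover all leaves. Automatic mode (``k``): k-medoids (PAM) on
    patristic distances, deterministic given the seed; classes are named
    a, b, c, ... in order of first appearance along the leaf order.
    """
    leaf_names = tree.leaf_names()
    if len(set(leaf_names)) != len(leaf_names):
        raise ValidationError("repeat tree has duplicate leaf names")
    if (anchors is None) == (k is None):
        raise ValidationError("provide exactly one of anchors or k")

    if anchors is not None:
        below: dict[int, frozenset] = {}
        for node in tree.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
        labels: dict[str, str] = {}
        clades: dict[str, frozenset] = {}
        for cls, anchor_leaves in anchors.items():
            anchor_set = set(anchor_leaves)
            missing = anchor_set - set(leaf_names)
            if missing:
                raise ValidationError(f"unknown anchor leaves {sorted(missing)}")
            best = None
            for node in tree.postorder():
                if anchor_set <= below[id(node)]:
                    if best is None or len(below[id(node)]) < len(best):
                        best = below[id(node)]
            clades[cls] = best
        for c1, c2 in itertools.combinations(clades, 2):
            inter = clades[c1] & clades[c2]
            if inter:
                raise ValidationError(
                    f"anchor clades {c1!r} and {c2!r} overlap "
                    f"(not monophyletic): {sorted(inter)}"
                )
        covered = frozenset().union(*clades.values()) if clades else frozenset()
        uncovered = set(leaf_names) - covered
        if uncovered:
            raise ValidationError(
                f"anchor clades do not cover leaves {sorted(uncovered)}"
            )
        for cls, clade in clades.items():
            for name in clade:
                labels[name] = cls
        return RepeatClassLabeling(labels, {c: sorted(v) for c, v in clades.items()})

    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(leaf_names):
        raise ValidationError("k exceeds the number of leaves")
    names, dist = _patristic_matrix(tree)
    rng = np.random.default_rng(seed)
    n = len(names)
    # PAM: greedy build, then swap until no improvement
    medoids: list[int] = []
    first = int(np.argmin(dist.sum(axis=1)))
    medoids.append(first)
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -1
        medoids.append(int(np.argmax(gains)))
    improved = True
    while improved:
        improved = False
        cost = dist[:, medoids].min(axis=1).sum()
        for mi in range(k):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = cand
                trial_cost = dist[:, trial].min(axis=1).sum()
                if trial_cost < cost - 1e-12:
                    medoids, cost = trial, trial_cost
                    improved = True
    assign = np.argmin(dist[:, medoids], axis=1)
    # deterministic class naming: order of first appearance in leaf order
    seen_order: list[int] = []
    for a in assign:
        if a not in seen_order:
            seen_order.append(int(a))
    cls_names = _class_names(k)
    cluster_to_class = {c: cls_names[i] for i, c in enumerate(seen_order)}
    labels = {names[i]: cluster_to_class[int(assign[i])] for i in range(n)}
    class_defs = {
        cluster_to_class[c]: [names[medoids[c]]] for c in range(k) if c in cluster_to_class
    }
    return RepeatClassLabeling(labels, class_defs)


# ---------------------------------------------------------------------------
# Species profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-species count vector over repeat classes. A zero vector is a
    legitimate state (repeat-less linked proteins occur)."""

    species: str
    counts: tuple[tuple[str, int], ...]  # sorted (class, count>0) pairs

    @staticmethod
    def from_dict(species: str, counts: dict[str, int]) -> "SpeciesProfile":
        for cls, c in counts.items():
            if c < 0:
                raise ValidationError(f"negative count for class {cls!r}")
        return SpeciesProfile(
            species, tuple(sorted((c, v) for c, v in counts.items() if v > 0))
        )

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def total(self) -> int:
        return sum(v for _, v in self.counts)


def build_species_profiles(
    labeling: RepeatClassLabeling,
    units: Sequence,
    include_degenerate: bool = False,
) -> list[SpeciesProfile]:
    """Count labeled units per (species, class).

    Degenerate units are excluded by default, mirroring the exclusion of
    atypical repeats from class groupings; species whose units are all
    unlabeled or degenerate keep an explicit zero profile.
    """
    species_seen: list[str] = []
    counts: dict[str, dict[str, int]] = {}
    unit_ids = {}
    for unit in units:
        uid = getattr(unit, "unit_id", None) or f"{unit.protein_id}_{unit.ordinal}"
        unit_ids[uid] = unit
        if unit.species is None:
            if uid in labeling.labels:
                raise ValidationError(f"labeled unit {uid!r} has no species metadata")
            continue
        if unit.species not in counts:
            counts[unit.species] = {}
            species_seen.append(unit.species)
        if unit.degenerate and not include_degenerate:
            continue
        cls = labeling.labels.get(uid)
        if cls is None:
            continue
        counts[unit.species][cls] = counts[unit.species].get(cls, 0) + 1
    return [SpeciesProfile.from_dict(sp, counts[sp]) for sp in species_seen]


def profile_edit_distance(u: SpeciesProfile, v: SpeciesProfile) -> int:
    """Minimum number of unit-cost single-domain steps (dup/loss/innov)
    transforming one profile into the other: the L1 distance."""
    du, dv = u.as_dict(), v.as_dict()
    classes = set(du) | set(dv)
    return int(sum(abs(du.get(c, 0) - dv.get(c, 0)) for c in classes))


# ---------------------------------------------------------------------------
# Steiner-tree collapse
# ---------------------------------------------------------------------------


@dataclass
class CollapsedNode:
    node_id: int
    profile: tuple[tuple[str, int], ...]
    predicted: bool
    species: list[str] = field(default_factory=list)

    def profile_dict(self) -> dict[str, int]:
        return dict(self.profile)


@dataclass
class CollapsedEdge:
    parent: int
    child: int
    events: list[tuple[str, str]]  # (event in dup|loss|innov, class)

    @property
    def cost(self) -> int:
        return len(self.events)


@dataclass
class CollapsedSpeciesTree:
    nodes: dict[int, CollapsedNode]
    edges: list[CollapsedEdge]
    total_cost: int
    rooted: bool
    exact: bool

    def predicted_nodes(self) -> list[CollapsedNode]:
        return [n for n in self.nodes.values() if n.predicted]

    def neighbors(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in self.nodes}
        for e in self.edges:
            adj[e.parent].append(e.child)
            adj[e.child].append(e.parent)
        return adj


def _vec(profile: dict[str, int], classes: list[str]) -> tuple[int, ...]:
    return tuple(profile.get(c, 0) for c in classes)


def _l1(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    return sum(abs(x - y) for x, y in zip(a, b))


def _dreyfus_wagner(points: list[tuple[int, ...]], terminals: list[int],
                    D: Optional[np.ndarray] = None):
    """Exact minimum Steiner tree on the complete graph over ``points``
    with L1 weights (a metric, so one walk relaxation per subset suffices).
    ``D`` may carry an epsilon-perturbed metric used to break ties among
    co-optimal trees; the returned cost is the perturbed one (callers
    recompute the integer event cost from the edges).
    Returns (cost, edges) with edges as index pairs into ``points``."""
    n = len(points)
    if D is None:
        arr = np.asarray(points, dtype=np.int64)
        D = np.abs(arr[:, None, :] - arr[None, :, :]).sum(axis=-1).astype(float)
    t = len(terminals)
    if t == 1:
        return 0, []
    others = terminals[1:]
    full = (1 << (t - 1)) - 1
    dp: dict[int, np.ndarray] = {}
    best_sub: dict[int, np.ndarray] = {}
    walk_from: dict[int, np.ndarray] = {}
    for si, term in enumerate(others):
        dp[1 << si] = D[term].copy()
    for mask in range(1, full + 1):
        if mask & (mask - 1) == 0:
            continue  # singleton, handled above
        merged = np.full(n, np.inf)
        subs = np.zeros(n, dtype=np.int64)
        sub = (mask - 1) & mask
        while sub > 0:
            comp = mask ^ sub
            if sub <= comp:
                combined = dp[sub] + dp[comp]
                better = combined < merged
                merged[better] = combined[better]
                subs[better] = sub
            sub = (sub - 1) & mask
        tot = merged[:, None] + D
        argmin_u = np.argmin(tot, axis=0)
        dp[mask] = tot[argmin_u, np.arange(n)]
        best_sub[mask] = subs
        walk_from[mask] = argmin_u
    root = terminals[0]
    cost = dp[full][root]

    edges: list[tuple[int, int]] = []

    def expand(mask: int, v: int) -> None:
        if mask & (mask - 1) == 0:
            term = others[mask.bit_length() - 1]
            if term != v:
                edges.append((term, v))
            return
        u = int(walk_from[mask][v])
        if u != v:
            edges.append((u, v))
        sub = int(best_sub[mask][u])
        expand(sub, u)
        expand(mask ^ sub, u)

    expand(full, root)
    return float(cost), edges


def _greedy_steiner(points: list[tuple[int, ...]], terminals: list[int]):
    """Shortest-path insertion heuristic: grow the tree by repeatedly
    attaching the nearest remaining terminal to the nearest tree point,
    creating intermediate lattice points as needed."""
    tree_points: dict[tuple[int, ...], int] = {}
    edges: list[tuple[int, int]] = []
    all_points = list(points)

    def point_id(p: tuple[int, ...]) -> int:
        for idx, q in enumerate(all_points):
            if q == p:
                return idx
        all_points.append(p)
        return len(all_points) - 1

    remaining = list(terminals)
    start = remaining.pop(0)
    tree_points[points[start]] = start
    cost = 0
    while remaining:
        best = None
        for term in remaining:
            for tp, tp_id in tree_points.items():
                d = _l1(points[term], tp)
                key = (d, points[term], tp)
                if best is None or key < best[0]:
                    best = (key, term, tp_id, tp)
        (_, term, attach_id, attach_point) = best
        cost += _l1(points[term], attach_point)
        edges.append((attach_id, term))
        tree_points[points[term]] = term
        remaining.remove(term)
    return cost, edges, all_points


def collapse_to_species_tree(
    profiles: Sequence[SpeciesProfile],
    root_hint: Optional[str] = None,
    max_exact_terminals: int = 6,
) -> CollapsedSpeciesTree:
    """Construct the parsimonious species tree over repeat-class profiles.

    Returns a tree whose nodes carry profiles (observed species attached
    where profiles match) and whose edges each carry exactly one
    single-domain event after unit-step expansion; nodes with no observed
    species are flagged predicted. Rooted at ``root_hint``'s profile when
    given, otherwise anchored arbitrarily and marked unrooted.
    """
    if len(profiles) < 2:
        raise ValidationError("collapse requires at least 2 species profiles")
    classes = sorted({c for p in profiles for c, _ in p.counts})
    if not classes:
        raise ValidationError("all profiles are empty; nothing to collapse")
    by_vec: dict[tuple[int, ...], list[str]] = {}
    for p in profiles:
        by_vec.setdefault(_vec(p.as_dict(), classes), []).append(p.species)
    terminal_vecs = sorted(by_vec)
    # Hanan grid: cartesian product of observed per-class count values
    per_class_values = [
        sorted({v[ci] for v in terminal_vecs}) for ci in range(len(classes))
    ]
    grid = [tuple(p) for p in itertools.product(*per_class_values)]
    grid_index = {p: i for i, p in enumerate(grid)}
    terminals = [grid_index[v] for v in terminal_vecs]

    if len(terminals) == 1:
        # all species share one profile: a single (trivially rooted) node
        vec = terminal_vecs[0]
        profile = tuple(
            (classes[ci], vec[ci]) for ci in range(len(classes)) if vec[ci] > 0
        )
        node = CollapsedNode(0, profile, False, list(by_vec[vec]))
        return CollapsedSpeciesTree(
            nodes={0: node}, edges=[], total_cost=0,
            rooted=root_hint is not None, exact=True,
        )

    exact = len(terminals) <= max_exact_terminals
    if exact:
        # epsilon tie-break among equally parsimonious trees: penalize
        # edges touching class-poor profiles, so ancestors that retain
        # more domain classes are preferred (re-founding a lost class
        # needs an independent innovation, the rarest event)
        arr = np.asarray(grid, dtype=np.int64)
        zeros = (arr == 0).sum(axis=1).astype(float)
        base = np.abs(arr[:, None, :] - arr[None, :, :]).sum(axis=-1).astype(float)
        eps = 1e-6 / max(len(grid), 1)
        Dw = base + eps * (zeros[:, None] + zeros[None, :])
        np.fill_diagonal(Dw, 0.0)
        _, raw_edges = _dreyfus_wagner(grid, terminals, Dw)
        points = list(grid)
    else:
        _, raw_edges, points = _greedy_steiner(grid, terminals)

    # Build adjacency over used points, drop self-loops, contract
    # pass-through (degree-2, non-terminal) points.
    term_set = set(terminals)
    adj: dict[int, set[int]] = {}
    for a, b in raw_edges:
        if a == b:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    changed = True
    while changed:
        changed = False
        for v in list(adj):
            if v not in adj or v in term_set or len(adj[v]) != 2:
                continue
            a, b = sorted(adj[v])
            adj[a].discard(v)
            adj[b].discard(v)
            del adj[v]
            adj[a].add(b)
            adj[b].add(a)
            changed = True
    if not adj:
        adj = {terminals[0]: set(), terminals[1]: set()}
        adj[terminals[0]].add(terminals[1])
        adj[terminals[1]].add(terminals[0])

    # choose root/anchor
    root_vertex = terminals[0]
    rooted = False
    if root_hint is not None:
        hint_vec = None
        for p in profiles:
            if p.species == root_hint:
                hint_vec = _vec(p.as_dict(), classes)
                break
        if hint_vec is None:
            raise ValidationError(f"root_hint species {root_hint!r} not in profiles")
        root_vertex = grid_index[hint_vec] if exact else terminals[
            terminal_vecs.index(hint_vec)
        ]
        rooted = True

    # orient by BFS from root and expand edges into unit steps
    observed_vecs = set(terminal_vecs)
    nodes: dict[int, CollapsedNode] = {}
    edges: list[CollapsedEdge] = []
    vec_to_new: dict[tuple[int, ...], int] = {}
    next_id = itertools.count()

    def get_node(vec: tuple[int, ...]) -> int:
        if vec in vec_to_new:
            return vec_to_new[vec]
        nid = next(next_id)
        vec_to_new[vec] = nid
        profile = tuple(
            (classes[ci], vec[ci]) for ci in range(len(classes)) if vec[ci] > 0
        )
        nodes[nid] = CollapsedNode(
            node_id=nid,
            profile=profile,
            predicted=vec not in observed_vecs,
            species=list(by_vec.get(vec, [])),
        )
        return nid

    def unit_path(u: tuple[int, ...], v: tuple[int, ...]):
        """Canonical unit-step chain u -> v: losses first (classes in
        order), then gains; each gain into a zero-count class is an
        innovation."""
        steps: list[tuple[str, str, tuple[int, ...]]] = []
        cur = list(u)
        for ci in range(len(classes)):
            while cur[ci] > v[ci]:
                cur[ci] -= 1
                steps.append(("loss", classes[ci], tuple(cur)))
        for ci in range(len(classes)):
            while cur[ci] < v[ci]:
                ev = "innov" if cur[ci] == 0 else "dup"
                cur[ci] += 1
                steps.append((ev, classes[ci], tuple(cur)))
        return steps

    get_node(points[root_vertex])
    parent_map: dict[int, int] = {}
    queue = [root_vertex]
    seen = {root_vertex}
    while queue:
        v = queue.pop(0)
        for u in sorted(adj.get(v, ())):
            if u in seen:
                continue
            seen.add(u)
            queue.append(u)
            pv = points[v]
            pu = points[u]
            prev_id = get_node(pv)
            for ev, cls, vec in unit_path(pv, pu):
                nid = get_node(vec)
                edges.append(CollapsedEdge(prev_id, nid, [(ev, cls)]))
                prev_id = nid

    total = sum(e.cost for e in edges)
    return CollapsedSpeciesTree(
        nodes=nodes, edges=edges, total_cost=total, rooted=rooted, exact=exact
    )


def predict_missing_intermediates(tree: CollapsedSpeciesTree) -> list[dict]:
    """Report every predicted (unobserved) profile with its incident edges
    and the nearest observed species by edit distance."""
    observed = [
        (n, SpeciesProfile("", n.profile)) for n in tree.nodes.values() if not n.predicted
    ]
    out = []
    adj = tree.neighbors()
    for node in tree.nodes.values():
        if not node.predicted:
            continue
        prof = SpeciesProfile("", node.profile)
        best = None
        for obs_node, obs_prof in observed:
            d = profile_edit_distance(prof, obs_prof)
            for sp in obs_node.species:
                key = (d, sp)
                if best is None or key < best:
                    best = key
        out.append(
            {
                "node_id": node.node_id,
                "profile": node.profile_dict(),
                "degree": len(adj[node.node_id]),
                "incident": sorted(adj[node.node_id]),
                "nearest_observed_species": best[1] if best else None,
                "nearest_observed_distance": best[0] if best else None,
            }
        )
    out.sort(key=lambda d: d["node_id"])
    return out
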