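"""Forward simulator of repeat-domain evolution with ground truth.

Emulates the architecture of a bifunctional synthetase: two slowly evolving
catalytic-domain flanks joined by a linker of fixed-length repeat domains
separated by fast-evolving spacers. Along a (simulated or supplied) species
tree, each domain independently undergoes tandem duplication, loss, or
class-founding duplication-with-divergence ("innovation") at configurable
per-domain rates (a Gillespie walk per branch). Sequences then evolve along
the resulting unit genealogy under a reversible amino-acid model with three
relative-rate tiers — slow flanks, moderate domains, fast spacers — the
rate structure that makes repeat domains informative at both shallow and
deep timescales while flanks are too slow and spacers too fast.

Every run emits machine-readable truth (species tree, event log, unit
genealogy, per-leaf architectures with exact protein coordinates), so the
detection, alignment, tree-inference, and collapse stages can all be scored
against known answers. The whole module is deterministic given the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_core import (
    AA20,
    PhyloTree,
    ProteinSequence,
    TreeNode,
    ValidationError,
    logger,
    parse_newick,
    write_fasta,
    write_newick,
)
from .species_collapse import _class_names
from .tree_infer import SubstitutionModel, load_model

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_species_tree",
    "simulate_repeat_evolution",
    "evolve_sequences",
    "emit_dataset",
    "simulate_dataset",
    "replay_architectures",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Rates are per domain per unit time; branch lengths of the species tree
    are in the same time units. ``burst_factor`` controls the extra
    divergence given once to a class-founding copy: each unit of
    burst_factor adds 0.1 expected substitutions per site. The relative
    rate tiers default to flank 0.1, domain 1.0, spacer 5.0 — slow flanks,
    informative domains, saturating spacers.
    """

    seed: int = 0
    n_species: Optional[int] = 8
    species_tree: Optional[str] = None  # Newick; overrides birth-death settings
    speciation: float = 1.0
    extinction: float = 0.0
    crown_age: float = 1.0
    lambda_dup: float = 0.5
    lambda_loss: float = 0.2
    lambda_innov: float = 0.1
    burst_factor: float = 3.0
    rate_flank: float = 0.1
    rate_domain: float = 1.0
    rate_spacer: float = 5.0
    domain_length: int = 50
    spacer_length: tuple[int, int] = (10, 40)
    flank_length: int = 60
    root_architecture: tuple[str, ...] = ("a",)
    root_class_divergence: float = 0.75
    enforce_rate_order: bool = True

    def __post_init__(self) -> None:
        for name in ("lambda_dup", "lambda_loss", "lambda_innov", "speciation",
                     "extinction", "rate_flank", "rate_domain", "rate_spacer"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        ordered = self.rate_flank < self.rate_domain < self.rate_spacer
        if not ordered:
            if self.enforce_rate_order:
                raise ValidationError(
                    "rate tiers must satisfy rate_flank < rate_domain < "
                    "rate_spacer (set enforce_rate_order=False to override)"
                )
            logger.warning("rate tiers are not in flank < domain < spacer order")
        if self.domain_length < 1 or self.flank_length < 1:
            raise ValidationError("domain_length and flank_length must be >= 1")
        lo, hi = self.spacer_length
        if not (1 <= lo <= hi):
            raise ValidationError("spacer_length must be a valid (lo, hi) range")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated proteins."""

    species_tree: PhyloTree
    root_architecture: list[tuple[str, str]]  # (unit_id, class)
    architectures: dict[str, list[tuple[str, str]]]  # node name -> ordered units
    events: list[dict]  # branch, time, event, unit_id, class
    genealogy: list[dict]  # parent_unit, child_unit, kind, branch
    leaf_units: list[dict] = field(default_factory=list)  # coordinates etc.
    n_classes: int = 0


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


def _name_nodes(tree: PhyloTree) -> None:
    counter = itertools.count(1)
    leaf_counter = itertools.count(1)
    for node in tree.preorder():
        if node.is_leaf:
            if not node.name:
                node.name = f"S{next(leaf_counter)}"
        elif not node.name:
            node.name = f"N{next(counter)}"


def _grow_crown(cfg: SimConfig, rng: np.random.Generator) -> Optional[PhyloTree]:
    """One unconditioned birth-death run from a crown of two lineages."""
    root = TreeNode(length=None)
    first = TreeNode()
    second = TreeNode()
    root.add_child(first)
    root.add_child(second)
    active: list[tuple[TreeNode, float]] = [(first, 0.0), (second, 0.0)]
    t = 0.0
    T = cfg.crown_age
    while active:
        n = len(active)
        total = n * (cfg.speciation + cfg.extinction)
        if total == 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= T:
            break
        idx = int(rng.integers(n))
        node, birth = active.pop(idx)
        node.length = t - birth
        if rng.random() < cfg.speciation / (cfg.speciation + cfg.extinction):
            left, right = TreeNode(), TreeNode()
            node.add_child(left)
            node.add_child(right)
            active.append((left, t))
            active.append((right, t))
        else:
            node.name = "__dead__"
    if not active:
        return None
    for node, birth in active:
        node.length = T - birth
    tree = PhyloTree(root, rooted=True)
    # prune extinct lineages
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder()):
            if node.is_leaf and node.name == "__dead__" and node.parent is not None:
                node.parent.remove_child(node)
                changed = True
    tree.suppress_unifurcations()
    if len(tree.root.children) < 2 or tree.n_leaves() < 2:
        return None
    return tree


def simulate_species_tree(cfg: SimConfig, rng: np.random.Generator,
                          max_tries: int = 10000) -> PhyloTree:
    """An ultrametric species tree: supplied Newick (pass-through) or a
    birth-death run conditioned on the extant leaf count by rejection
    sampling (``cfg.n_species = None`` returns the first surviving run
    unconditioned)."""
    if cfg.species_tree is not None:
        tree = parse_newick(cfg.species_tree)
        _name_nodes(tree)
        return tree
    for _ in range(max_tries):
        tree = _grow_crown(cfg, rng)
        if tree is None:
            continue
        if cfg.n_species is None or tree.n_leaves() == cfg.n_species:
            _name_nodes(tree)
            return tree
    raise ValidationError(
        f"could not draw a tree with {cfg.n_species} extant species in "
        f"{max_tries} tries; adjust speciation/extinction/crown_age"
    )


# ---------------------------------------------------------------------------
# Repeat birth/death along the tree
# ---------------------------------------------------------------------------


def simulate_repeat_evolution(
    tree: PhyloTree, cfg: SimConfig, rng: np.random.Generator
) -> SimTruth:
    """Gillespie walk of domain duplication / loss / innovation per branch.

    Each extant domain independently duplicates in tandem (same class), is
    lost, or founds a new class at the configured rates. Unit ids are
    re-instantiated at each speciation so every (branch, unit) lineage is
    uniquely identified; the genealogy records the copy structure.
    """
    uid_counter = itertools.count()
    class_counter = itertools.count()
    root_classes: list[str] = []
    for cls in cfg.root_architecture:
        next(class_counter)
        root_classes.append(cls)
    # continue class naming after the root classes
    used = set(root_classes)
    names_stream = (c for c in _class_names(1000) if c not in used)

    def new_uid() -> str:
        return f"u{next(uid_counter)}"

    genealogy: list[dict] = []
    events: list[dict] = []
    architectures: dict[str, list[tuple[str, str]]] = {}

    root = tree.root
    root_arch = []
    for cls in cfg.root_architecture:
        uid = new_uid()
        root_arch.append((uid, cls))
        genealogy.append(
            {"parent_unit": None, "child_unit": uid, "kind": "root",
             "branch": root.name}
        )
    architectures[root.name] = list(root_arch)
    n_classes = len(set(root_classes))

    lam = cfg.lambda_dup + cfg.lambda_loss + cfg.lambda_innov

    def walk(node: TreeNode) -> None:
        nonlocal n_classes
        for child in node.children:
            arch: list[tuple[str, str]] = []
            for puid, cls in architectures[node.name]:
                uid = new_uid()
                genealogy.append(
                    {"parent_unit": puid, "child_unit": uid,
                     "kind": "speciation", "branch": child.name}
                )
                arch.append((uid, cls))
            T = child.length or 0.0
            t = 0.0
            while arch and lam > 0:
                rate = len(arch) * lam
                t += rng.exponential(1.0 / rate)
                if t >= T:
                    break
                idx = int(rng.integers(len(arch)))
                puid, cls = arch[idx]
                u = rng.random() * lam
                if u < cfg.lambda_dup:
                    uid = new_uid()
                    arch.insert(idx + 1, (uid, cls))
                    genealogy.append(
                        {"parent_unit": puid, "child_unit": uid, "kind": "dup",
                         "branch": child.name}
                    )
                    events.append(
                        {"branch": child.name, "time": t, "event": "dup",
                         "unit_id": uid, "class": cls, "parent_unit": puid}
                    )
                elif u < cfg.lambda_dup + cfg.lambda_loss:
                    arch.pop(idx)
                    events.append(
                        {"branch": child.name, "time": t, "event": "loss",
                         "unit_id": puid, "class": cls, "parent_unit": None}
                    )
                else:
                    new_cls = next(names_stream)
                    n_classes += 1
                    uid = new_uid()
                    arch.insert(idx + 1, (uid, new_cls))
                    genealogy.append(
                        {"parent_unit": puid, "child_unit": uid, "kind": "innov",
                         "branch": child.name}
                    )
                    events.append(
                        {"branch": child.name, "time": t, "event": "innov",
                         "unit_id": uid, "class": new_cls, "parent_unit": puid}
                    )
            architectures[child.name] = arch
            walk(child)

    walk(root)
    return SimTruth(
        species_tree=tree,
        root_architecture=root_arch,
        architectures=architectures,
        events=events,
        genealogy=genealogy,
        n_classes=n_classes,
    )


def replay_architectures(truth: SimTruth) -> dict[str, list[tuple[str, str]]]:
    """Reconstruct every node's architecture from the root architecture,
    genealogy and event log alone (conservation check)."""
    spec_map: dict[str, list[tuple[str, str, str]]] = {}
    for row in truth.genealogy:
        if row["kind"] == "speciation":
            spec_map.setdefault(row["branch"], []).append(
                (row["parent_unit"], row["child_unit"], None)
            )
    events_by_branch: dict[str, list[dict]] = {}
    for ev in truth.events:
        events_by_branch.setdefault(ev["branch"], []).append(ev)
    for branch in events_by_branch:
        events_by_branch[branch].sort(key=lambda e: e["time"])

    out: dict[str, list[tuple[str, str]]] = {
        truth.species_tree.root.name: list(truth.root_architecture)
    }

    def walk(node: TreeNode) -> None:
        for child in node.children:
            mapping = dict(
                (p, c) for p, c, _ in spec_map.get(child.name, [])
            )
            arch = [(mapping[uid], cls) for uid, cls in out[node.name]]
            for ev in events_by_branch.get(child.name, []):
                if ev["event"] == "loss":
                    arch = [(u, c) for u, c in arch if u != ev["unit_id"]]
                else:
                    pos = [i for i, (u, _) in enumerate(arch)
                           if u == ev["parent_unit"]]
                    arch.insert(pos[0] + 1, (ev["unit_id"], ev["class"]))
            out[child.name] = arch
            walk(child)

    walk(truth.species_tree.root)
    return out


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _draw_stationary(model: SubstitutionModel, length: int,
                     rng: np.random.Generator) -> np.ndarray:
    return rng.choice(20, size=length, p=model.stationary_frequencies)


def _evolve(codes: np.ndarray, model: SubstitutionModel, t: float,
            rng: np.random.Generator) -> np.ndarray:
    if t <= 0 or len(codes) == 0:
        return codes.copy()
    P = model.transition_matrix(t)
    cum = P[codes].cumsum(axis=1)
    r = rng.random(len(codes))
    return (r[:, None] > cum).sum(axis=1).astype(codes.dtype)


def _decode(codes: np.ndarray) -> str:
    return "".join(AA20[c] for c in codes)


def evolve_sequences(
    truth: SimTruth,
    model: Optional[SubstitutionModel] = None,
    cfg: SimConfig = SimConfig(),
    rng: Optional[np.random.Generator] = None,
) -> list[ProteinSequence]:
    """Evolve flank, domain, and spacer sequences along the unit genealogy.

    Root segments are drawn from the model's stationary frequencies (root
    domains after the first are diverged copies of the first, so distinct
    root classes are separable); substitutions accrue at rate_domain for
    domains, rate_spacer for spacers, rate_flank for flanks. A
    class-founding copy receives ``0.1 * burst_factor`` extra expected
    substitutions per site at birth. Leaf proteins are
    flank-N | domain (spacer domain)* | flank-C, and unit coordinates are
    recorded in ``truth.leaf_units``.
    """
    model = model or load_model("WAG")
    rng = rng or np.random.default_rng(cfg.seed)
    if model.stationary_frequencies is None:
        raise ValidationError("substitution model lacks stationary frequencies")

    events_by_branch: dict[str, list[dict]] = {}
    for ev in truth.events:
        events_by_branch.setdefault(ev["branch"], []).append(ev)
    for branch in events_by_branch:
        events_by_branch[branch].sort(key=lambda e: e["time"])
    spec_map: dict[str, dict[str, str]] = {}
    for row in truth.genealogy:
        if row["kind"] == "speciation":
            spec_map.setdefault(row["branch"], {})[row["parent_unit"]] = row[
                "child_unit"
            ]

    tree = truth.species_tree
    root = tree.root

    def draw_spacer() -> np.ndarray:
        lo, hi = cfg.spacer_length
        length = int(rng.integers(lo, hi + 1))
        return _draw_stationary(model, length, rng)

    # root state: one founder sequence per class (founders diverged from a
    # common ancestral domain by root_class_divergence); same-class copies
    # are near-identical duplicates of their class founder
    root_arch = truth.root_architecture
    domain_seqs: dict[str, np.ndarray] = {}
    if root_arch:
        base = _draw_stationary(model, cfg.domain_length, rng)
        founders: dict[str, np.ndarray] = {}
        for uid, cls in root_arch:
            if cls not in founders:
                founders[cls] = _evolve(
                    base, model, cfg.root_class_divergence * cfg.rate_domain, rng
                )
                domain_seqs[uid] = founders[cls]
            else:
                domain_seqs[uid] = _evolve(
                    founders[cls], model, 0.05 * cfg.rate_domain, rng
                )
    root_state = {
        "flank_n": _draw_stationary(model, cfg.flank_length, rng),
        "flank_c": _draw_stationary(model, cfg.flank_length, rng),
        "units": [(uid, cls, domain_seqs[uid]) for uid, cls in root_arch],
        "spacers": [draw_spacer() for _ in range(max(len(root_arch) - 1, 0))],
    }

    proteins: list[ProteinSequence] = []
    truth.leaf_units = []

    def advance(state: dict, dt: float) -> dict:
        return {
            "flank_n": _evolve(state["flank_n"], model, dt * cfg.rate_flank, rng),
            "flank_c": _evolve(state["flank_c"], model, dt * cfg.rate_flank, rng),
            "units": [
                (uid, cls, _evolve(seq, model, dt * cfg.rate_domain, rng))
                for uid, cls, seq in state["units"]
            ],
            "spacers": [
                _evolve(sp, model, dt * cfg.rate_spacer, rng)
                for sp in state["spacers"]
            ],
        }

    def walk(node: TreeNode, state: dict) -> None:
        if node.is_leaf:
            residues = []
            pos = 0
            residues.append(_decode(state["flank_n"]))
            pos += len(state["flank_n"])
            for k, (uid, cls, seq) in enumerate(state["units"]):
                if k > 0:
                    sp = state["spacers"][k - 1]
                    residues.append(_decode(sp))
                    pos += len(sp)
                truth.leaf_units.append(
                    {
                        "species": node.name,
                        "protein_id": node.name,
                        "unit_id": uid,
                        "ordinal": k + 1,
                        "class": cls,
                        "start": pos,
                        "end": pos + len(seq),
                        "sequence": _decode(seq),
                    }
                )
                residues.append(_decode(seq))
                pos += len(seq)
            residues.append(_decode(state["flank_c"]))
            proteins.append(
                ProteinSequence(
                    node.name, "".join(residues), "simulated linker protein"
                )
            )
            return
        for child in node.children:
            mapping = spec_map.get(child.name, {})
            child_state = {
                "flank_n": state["flank_n"],
                "flank_c": state["flank_c"],
                "units": [
                    (mapping[uid], cls, seq) for uid, cls, seq in state["units"]
                ],
                "spacers": list(state["spacers"]),
            }
            T = child.length or 0.0
            prev_t = 0.0
            for ev in events_by_branch.get(child.name, []):
                child_state = advance(child_state, ev["time"] - prev_t)
                prev_t = ev["time"]
                units = child_state["units"]
                spacers = child_state["spacers"]
                if ev["event"] == "loss":
                    idx = [i for i, (u, _, _) in enumerate(units)
                           if u == ev["unit_id"]][0]
                    units.pop(idx)
                    if spacers:
                        spacers.pop(min(idx, len(spacers) - 1))
                else:
                    idx = [i for i, (u, _, _) in enumerate(units)
                           if u == ev["parent_unit"]][0]
                    parent_seq = units[idx][2]
                    new_seq = parent_seq.copy()
                    if ev["event"] == "innov":
                        new_seq = _evolve(
                            new_seq, model, 0.1 * cfg.burst_factor, rng
                        )
                    units.insert(idx + 1, (ev["unit_id"], ev["class"], new_seq))
                    spacers.insert(min(idx, max(len(spacers), 0)), draw_spacer())
            child_state = advance(child_state, T - prev_t)
            walk(child, child_state)

    walk(root, root_state)
    proteins.sort(key=lambda p: p.id)
    truth.leaf_units.sort(key=lambda r: (r["species"], r["ordinal"]))
    return proteins


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------


def emit_dataset(out_dir: str | Path, sequences: Sequence[ProteinSequence],
                 truth: SimTruth) -> dict[str, Path]:
    """Write proteins.faa, species_tree.nwk, truth_units.tsv and
    truth_events.tsv; truth coordinates are verified against the FASTA
    slices before writing."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {s.id: s for s in sequences}
    for row in truth.leaf_units:
        seq = by_id.get(row["protein_id"])
        if seq is None or seq.residues[row["start"]:row["end"]] != row["sequence"]:
            raise ValidationError(
                f"truth/FASTA mismatch for unit {row['unit_id']} "
                f"of {row['protein_id']}"
            )
    paths = {
        "proteins": out_dir / "proteins.faa",
        "species_tree": out_dir / "species_tree.nwk",
        "truth_units": out_dir / "truth_units.tsv",
        "truth_events": out_dir / "truth_events.tsv",
    }
    write_fasta(list(sequences), paths["proteins"])
    paths["species_tree"].write_text(
        write_newick(truth.species_tree, annotations="none") + "\n"
    )
    unit_cols = ["species", "protein_id", "unit_id", "ordinal", "class",
                 "start", "end", "sequence"]
    with open(paths["truth_units"], "w") as fh:
        fh.write("\t".join(unit_cols) + "\n")
        for row in truth.leaf_units:
            fh.write("\t".join(str(row[c]) for c in unit_cols) + "\n")
    event_cols = ["branch", "time", "event", "unit_id", "class"]
    with open(paths["truth_events"], "w") as fh:
        fh.write("\t".join(event_cols) + "\n")
        for ev in truth.events:
            vals = [ev["branch"], f"{ev['time']:.9f}", ev["event"],
                    ev["unit_id"], ev["class"]]
            fh.write("\t".join(vals) + "\n")
    return paths


def simulate_dataset(
    cfg: SimConfig, model: Optional[SubstitutionModel] = None
) -> tuple[list[ProteinSequence], SimTruth]:
    """Run the full generator (tree, events, sequences) from one seed."""
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_species_tree(cfg, rng)
    truth = simulate_repeat_evolution(tree, cfg, rng)
    sequences = evolve_sequences(truth, model, cfg, rng)
    return sequences, truth
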