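"""End-to-end orchestration: proteins in, collapsed species tree out.

Mirrors the analysis workflow: a single well-annotated reference species
supplies the catalytic-domain anchors and reference repeat domains (the
role a human sequence plays in practice); every other protein's linker is
located between the anchors, repeat units are called at two stringencies,
all units are multiply aligned, a repeat-level tree is inferred, units are
clustered into classes, species are encoded as class-count profiles, and
the profiles are collapsed into a parsimonious species tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_core import PhyloTree, ProteinSequence, ValidationError
from .msa import MultipleAlignment, progressive_msa
from .repeat_detect import (
    DetectConfig,
    LinkerRegion,
    RepeatUnit,
    detect_degenerate_repeats,
    extract_linker,
)
from .species_collapse import (
    CollapsedSpeciesTree,
    RepeatClassLabeling,
    SpeciesProfile,
    assign_repeat_classes,
    build_species_profiles,
    collapse_to_species_tree,
)
from .tree_infer import load_model, ml_pairwise_distance, neighbor_joining

__all__ = ["PipelineResult", "run_pipeline", "collapsed_species_splits"]


@dataclass
class PipelineResult:
    units: list[RepeatUnit]
    alignment: Optional[MultipleAlignment]
    repeat_tree: Optional[PhyloTree]
    labeling: Optional[RepeatClassLabeling]
    profiles: list[SpeciesProfile]
    collapsed: Optional[CollapsedSpeciesTree]


def run_pipeline(
    proteins: Sequence[ProteinSequence],
    ers_anchor: ProteinSequence,
    prs_anchor: ProteinSequence,
    reference_domains: Sequence[ProteinSequence],
    n_classes: int,
    high_cfg: DetectConfig = DetectConfig(min_score_fraction=0.5),
    low_cfg: DetectConfig = DetectConfig(min_score_fraction=0.3),
    include_low_stringency: bool = True,
    root_hint: Optional[str] = None,
    max_exact_terminals: int = 8,
    seed: int = 0,
) -> PipelineResult:
    """Run detect → align → tree → classes → collapse on a set of proteins.

    ``include_low_stringency`` keeps low-stringency (degenerate-flagged)
    units in the analysis — appropriate when divergence, not true
    degeneracy, is expected to push units below the high threshold.
    Species identity is taken from each protein's id.
    """
    units: list[RepeatUnit] = []
    for prot in proteins:
        linker = extract_linker(prot, ers_anchor, prs_anchor)
        found = detect_degenerate_repeats(
            linker, reference_domains, high_cfg, low_cfg, species=prot.id
        )
        units.extend(found)

    usable = [
        u for u in units if include_low_stringency or not u.degenerate
    ]
    profiles: list[SpeciesProfile]
    if len(usable) < 3:
        return PipelineResult(units, None, None, None, [], None)

    unit_seqs = [
        ProteinSequence(f"{u.species}|{u.ordinal}", u.sequence) for u in usable
    ]
    alignment = progressive_msa(unit_seqs)
    dm = ml_pairwise_distance(alignment, load_model("DAYHOFF"))
    repeat_tree = neighbor_joining(dm)
    labeling = assign_repeat_classes(repeat_tree, k=n_classes, seed=seed)

    # re-key labeling onto unit objects for profile building
    keyed = RepeatClassLabeling(labels=dict(labeling.labels),
                                class_defs=labeling.class_defs)

    class _Keyed:
        def __init__(self, unit: RepeatUnit):
            self.unit_id = f"{unit.species}|{unit.ordinal}"
            self.species = unit.species
            self.protein_id = unit.protein_id
            self.ordinal = unit.ordinal
            self.degenerate = unit.degenerate and not include_low_stringency

    profiles = build_species_profiles(keyed, [_Keyed(u) for u in usable])
    # species with no usable units still get explicit zero profiles
    seen = {p.species for p in profiles}
    for prot in proteins:
        if prot.id not in seen:
            profiles.append(SpeciesProfile.from_dict(prot.id, {}))

    nonzero = [p for p in profiles if p.total() > 0]
    collapsed = None
    if len(nonzero) >= 2:
        collapsed = collapse_to_species_tree(
            nonzero, root_hint=root_hint, max_exact_terminals=max_exact_terminals
        )
    return PipelineResult(units, alignment, repeat_tree, keyed, profiles, collapsed)


def collapsed_species_splits(tree: CollapsedSpeciesTree) -> set[frozenset[str]]:
    """Non-trivial species bipartitions induced by the collapsed tree.

    Each edge splits the node set in two; the species attached to each side
    form the split. Splits are canonicalized as the side excluding the
    lexicographically smallest species, directly comparable with
    ``PhyloTree.bipartitions()`` when the species sets coincide.
    """
    all_species = sorted(
        {sp for node in tree.nodes.values() for sp in node.species}
    )
    if len(all_species) < 4:
        return set()
    ref = all_species[0]
    full = frozenset(all_species)
    adj = tree.neighbors()
    splits: set[frozenset[str]] = set()
    for edge in tree.edges:
        # collect species on the child side of this edge
        stack = [edge.child]
        seen_nodes = {edge.parent, edge.child}
        side: set[str] = set()
        while stack:
            v = stack.pop()
            side.update(tree.nodes[v].species)
            for u in adj[v]:
                if u not in seen_nodes:
                    seen_nodes.add(u)
                    stack.append(u)
        split = frozenset(side)
        if len(split) < 2 or len(split) > len(all_species) - 2:
            continue
        if ref in split:
            split = full - split
        splits.add(split)
    return splits
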