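"""Sequence and tree I/O for the SIR-phylogenetics pipeline.

This module carries the plumbing shared by every stage: validated protein and
nucleotide sequence records, FASTA reading/writing, three-frame translation of
nucleotide linker amplicons, and a minimal Newick dialect whose internal-node
labels are reserved for cross-algorithm branch support (``*`` = supported by
two tree-building algorithms, ``**`` = by all three) or posterior
probabilities.

Coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "SirphyloError",
    "ParseError",
    "ValidationError",
    "ProteinSequence",
    "NucleotideSequence",
    "read_fasta",
    "write_fasta",
    "translate_three_frames",
    "TreeNode",
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "load_config",
    "setup_logging",
    "AA20",
]

logger = logging.getLogger("sirphylo")

#: Canonical amino-acid ordering (PAML order) used by the substitution models.
AA20 = "ARNDCQEGHILKMFPSTWYV"
PROTEIN_ALPHABET = frozenset(AA20 + "X*")
NT_ALPHABET = frozenset("ACGTN")


class SirphyloError(Exception):
    """Base class for all package errors."""


class ParseError(SirphyloError, ValueError):
    """Malformed input file or string."""


class ValidationError(SirphyloError, ValueError):
    """Input violates a documented precondition or invariant."""


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 amino acids plus X (ambiguous) and *.

    Stop characters (``*``) arise only from translation and are never
    silently stripped; downstream repeat detection rejects them inside
    repeat units so that reading-frame errors surface early.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be nonempty")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: residues must be nonempty")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: illegal protein characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NucleotideSequence:
    """A nucleotide sequence over ACGTN, stored uppercase."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be nonempty")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: residues must be nonempty")
        bad = set(self.residues) - NT_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: illegal nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, alphabet: str = "protein"):
    """Read a FASTA file into validated sequence records.

    The id is the first whitespace-delimited token of the header; the rest of
    the header is kept as the description (protein records only). Duplicate
    ids and illegal characters are rejected; parse errors name the offending
    line number.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValidationError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records = []
    seen: set[str] = set()
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has no sequence")
        parts = header.split(None, 1)
        sid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        if sid in seen:
            raise ValidationError(f"{path}:{header_line}: duplicate sequence id {sid!r}")
        seen.add(sid)
        try:
            if alphabet == "protein":
                records.append(ProteinSequence(sid, seq, desc))
            else:
                records.append(NucleotideSequence(sid, seq))
        except ValidationError as exc:
            raise ParseError(f"{path}:{header_line}: {exc}") from exc

    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunk = line.strip()
                allowed = PROTEIN_ALPHABET if alphabet == "protein" else NT_ALPHABET
                bad = set(chunk.upper() if alphabet == "nucleotide" else chunk) - allowed
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal {alphabet} characters "
                        f"{sorted(bad)}"
                    )
                chunks.append(chunk)
    flush()
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence, path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with a fixed 60-column wrap."""
    if not records:
        raise ValidationError("write_fasta: empty record list")
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = f">{rec.id} {desc}".rstrip()
            handle.write(header + "\n")
            res = rec.residues
            for i in range(0, len(res), width):
                handle.write(res[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------


def translate_three_frames(
    nt: NucleotideSequence,
) -> tuple[Optional[ProteinSequence], ...]:
    """Translate a nucleotide sequence in the three forward frames.

    Returns a tuple for frames +1, +2, +3. Trailing partial codons are
    dropped and stop codons rendered as ``*``. Frames too short to yield a
    residue are returned as ``None``; if even frame +1 is empty the input is
    rejected.
    """
    if len(nt) < 3:
        raise ValidationError(
            f"sequence {nt.id!r}: length {len(nt)} < 3, no frame can be translated"
        )
    out: list[Optional[ProteinSequence]] = []
    for frame in range(3):
        usable = (len(nt) - frame) // 3 * 3
        if usable == 0:
            out.append(None)
            continue
        codons = nt.residues[frame : frame + usable]
        aa = str(Seq(codons).translate())
        out.append(
            ProteinSequence(
                f"{nt.id}_frame{frame + 1}", aa, f"frame +{frame + 1} of {nt.id}"
            )
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class TreeNode:
    """A node of a (possibly unrooted) phylogeny.

    ``length`` is the branch length of the edge above the node, ``None``
    when absent (never coerced to zero). ``support`` is the cross-algorithm
    count (1..3) and ``posterior`` a Bayesian bipartition probability; both
    are optional and attached to internal nodes only.
    """

    __slots__ = ("name", "length", "children", "parent", "support", "posterior")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        children: Optional[list["TreeNode"]] = None,
    ) -> None:
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.support: Optional[int] = None
        self.posterior: Optional[float] = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, n_children={len(self.children)})"


class PhyloTree:
    """A phylogeny addressed through its root node.

    Unrooted trees are represented with a trifurcating (degree-3) root
    acting as an anchor; ``rooted`` records whether the root is meaningful.
    """

    def __init__(self, root: TreeNode, rooted: bool = False) -> None:
        self.root = root
        self.rooted = rooted

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[TreeNode]:
        """Every node below the root; each identifies the edge above it."""
        return [n for n in self.postorder() if n is not self.root]

    def find(self, name: str) -> TreeNode:
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(name)

    # -- structure ---------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            new.support = node.support
            new.posterior = node.posterior
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), rooted=self.rooted)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized as the leaf set that
        excludes the lexicographically smallest leaf name."""
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValidationError("duplicate leaf names")
        all_leaves = frozenset(names)
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = below[id(node)]
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            if ref in side:
                side = all_leaves - side
            splits.add(side)
        return splits

    def suppress_unifurcations(self) -> None:
        """Collapse nodes with a single child, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node is self.root:
                    child.parent = None
                    child.length = None
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                    if node.length is not None or child.length is not None:
                        child.length = (node.length or 0.0) + (child.length or 0.0)
                changed = True
                break

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.edges())


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEWICK_SPECIALS = set("(),:;")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (unquoted labels, optional branch lengths,
    internal labels used for support annotations).

    Internal labels ``*`` and ``**`` are decoded as algorithm-support 2 and
    3; a label parseable as a float in [0, 1] is decoded as a posterior.
    Parse errors report the character position.
    """
    pos = 0
    n = len(text)

    def error(msg: str):
        raise ParseError(f"newick position {pos}: {msg}")

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < n and not text[pos].isspace() and text[pos] not in _NEWICK_SPECIALS:
            pos += 1
        return text[start:pos]

    def read_length() -> Optional[float]:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            skip_ws()
            token = read_label()
            try:
                return float(token)
            except ValueError:
                error(f"invalid branch length {token!r}")
        return None

    def read_subtree() -> TreeNode:
        nonlocal pos
        skip_ws()
        if pos >= n:
            error("unexpected end of input")
        if text[pos] == "(":
            pos += 1
            node = TreeNode()
            while True:
                child = read_subtree()
                node.add_child(child)
                skip_ws()
                if pos >= n:
                    error("unbalanced parentheses: missing ')'")
                if text[pos] == ",":
                    pos += 1
                    skip_ws()
                    if pos < n and text[pos] in "),":
                        error("dangling comma")
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                error(f"expected ',' or ')', found {text[pos]!r}")
            skip_ws()
            label = read_label()
            if label:
                node.name = label
                if label == "*":
                    node.support = 2
                elif label == "**":
                    node.support = 3
                else:
                    try:
                        value = float(label)
                        if 0.0 <= value <= 1.0:
                            node.posterior = value
                    except ValueError:
                        pass
            node.length = read_length()
            return node
        if text[pos] in "),;":
            error(f"unexpected {text[pos]!r}")
        node = TreeNode(name=read_label())
        if not node.name:
            error("empty leaf label")
        node.length = read_length()
        return node

    root = read_subtree()
    skip_ws()
    if pos >= n or text[pos] != ";":
        error("missing terminating ';'")
    pos += 1
    skip_ws()
    if pos != n:
        error("trailing characters after ';'")
    return PhyloTree(root, rooted=len(root.children) == 2)


def _format_support(node: TreeNode, scheme: str) -> str:
    if scheme == "stars":
        if node.support == 2:
            return "*"
        if node.support == 3:
            return "**"
        return node.name or ""
    if scheme == "numeric":
        if node.posterior is not None:
            return f"{node.posterior:g}"
        if node.support is not None:
            return str(node.support)
        return node.name or ""
    return node.name or ""


def write_newick(tree: PhyloTree, annotations: str = "stars") -> str:
    """Serialize a tree as Newick, branch lengths to 6 decimals.

    ``annotations`` selects the internal-label scheme: ``"stars"`` writes
    ``*``/``**`` for algorithm support 2/3; ``"numeric"`` writes posteriors
    or raw counts; ``"none"`` writes stored names only.
    """
    if annotations not in ("stars", "numeric", "none"):
        raise ValidationError(f"unknown annotation scheme {annotations!r}")

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            label = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            scheme = annotations if annotations != "none" else "plain"
            label = f"({inner})" + _format_support(node, scheme)
        if node.length is not None:
            label += f":{node.length:.6f}"
        return label

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Configuration & logging
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a TOML configuration file shared by the CLI subcommands."""
    import tomllib

    with open(path, "rb") as handle:
        return tomllib.load(handle)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
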