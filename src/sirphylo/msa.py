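"""Pairwise and progressive multiple alignment of repeat units.

Global alignment uses the Gotoh affine-gap algorithm with a fully
deterministic traceback (ties resolved diagonal > up > left), so identical
inputs always give identical alignments. A gap of length L costs
``gap_open + gap_extend * (L - 1)``. The progressive aligner builds a
neighbor-joining guide tree from pairwise alignment-score distances and
merges profiles bottom-up with sum-of-pairs column scoring.

Percent identity exposes the two denominator conventions commonly seen in
the literature (all columns vs. terminal-gap-excluded); gap/gap columns are
never counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .io_core import AA20, ProteinSequence, ValidationError

__all__ = [
    "MultipleAlignment",
    "score_matrix",
    "global_pairwise_align",
    "percent_identity",
    "progressive_msa",
    "read_alignment_fasta",
]

GAP = "-"

_MATRIX_CACHE: dict[str, tuple[np.ndarray, dict[str, int]]] = {}


def score_matrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    """Load a substitution score matrix (e.g. BLOSUM62, PAM250) as a dense
    array plus a character→index map. Unknown residues map to 'X'."""
    key = name.upper()
    if key not in _MATRIX_CACHE:
        try:
            mat = substitution_matrices.load(key)
        except Exception as exc:
            raise ValidationError(f"unknown substitution matrix {name!r}") from exc
        alphabet = str(mat.alphabet)
        index = {c: i for i, c in enumerate(alphabet)}
        _MATRIX_CACHE[key] = (np.asarray(mat, dtype=float), index)
    return _MATRIX_CACHE[key]


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    fallback = index.get("X", 0)
    return np.fromiter(
        (index.get(c, fallback) for c in seq), dtype=np.intp, count=len(seq)
    )


@dataclass
class MultipleAlignment:
    """A gapped alignment: equal-length rows over residues and '-'.

    Removing gaps from any row reproduces the source sequence; columns that
    are all gaps are disallowed.
    """

    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValidationError("row_ids and rows must have equal length")
        if not self.rows:
            raise ValidationError("alignment must have at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValidationError("alignment rows must all have the same length")
        for j in range(width):
            if all(r[j] == GAP for r in self.rows):
                raise ValidationError(f"alignment column {j} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def pairwise_projection(self, i: int, j: int) -> "MultipleAlignment":
        """The induced pairwise alignment of rows i and j (gap/gap columns
        stripped)."""
        a, b = self.rows[i], self.rows[j]
        cols = [(x, y) for x, y in zip(a, b) if not (x == GAP and y == GAP)]
        return MultipleAlignment(
            [self.row_ids[i], self.row_ids[j]],
            ["".join(x for x, _ in cols), "".join(y for _, y in cols)],
        )


# ---------------------------------------------------------------------------
# Pairwise global alignment (Gotoh)
# ---------------------------------------------------------------------------

_NEG = -1e30


def _gotoh_fill(sa: np.ndarray, sb: np.ndarray, mat: np.ndarray,
                gap_open: float, gap_extend: float):
    """Fill Gotoh matrices. Returns (M, X, Y) of shape (n+1, m+1).

    M: ends in a match/mismatch; X: ends in a gap in b (consumes a, "up");
    Y: ends in a gap in a (consumes b, "left").
    """
    n, m = len(sa), len(sb)
    S = mat[np.ix_(sa, sb)]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - gap_open,
            X[i - 1, 1:] - gap_extend,
        )
        # Y has a horizontal recurrence; resolve with a prefix max:
        #   Y[i,j] = max(max(M,X)[i,j-1] - open, Y[i,j-1] - extend)
        #   B[j] := Y[i,j] + j*extend  =>  B[j] = max(B[j-1], opener[j-1]+j*ext)
        opener = np.maximum(M[i], X[i]) - gap_open
        cand = np.empty(m + 1)
        cand[0] = Y[i, 0]
        cand[1:] = opener[:-1] + js * gap_extend
        B = np.maximum.accumulate(cand)
        Y[i, 1:] = B[1:] - js * gap_extend
    return M, X, Y


def global_pairwise_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[MultipleAlignment, float]:
    """Optimal Needleman–Wunsch/Gotoh global alignment with affine gaps.

    Returns the two-row alignment and its score. The traceback is
    deterministic: on ties it prefers diagonal, then up (gap in ``b``),
    then left (gap in ``a``).
    """
    if not a.residues or not b.residues:
        raise ValidationError("global_pairwise_align: empty input sequence")
    mat, index = score_matrix(matrix_name)
    sa = _encode(a.residues, index)
    sb = _encode(b.residues, index)
    M, X, Y = _gotoh_fill(sa, sb, mat, gap_open, gap_extend)
    n, m = len(sa), len(sb)
    score = max(M[n, m], X[n, m], Y[n, m])

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    # state: which matrix the current cell value came from
    eps = 1e-9
    if M[n, m] >= score - eps:
        state = "M"
    elif X[n, m] >= score - eps:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a.residues[i - 1])
            out_b.append(b.residues[j - 1])
            prev = M[i, j] - mat[sa[i - 1], sb[j - 1]]
            i, j = i - 1, j - 1
            if M[i, j] >= prev - eps:
                state = "M"
            elif X[i, j] >= prev - eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            out_a.append(a.residues[i - 1])
            out_b.append(GAP)
            if M[i - 1, j] - gap_open >= X[i, j] - eps:
                state = "M"
            elif X[i - 1, j] - gap_extend >= X[i, j] - eps:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b.residues[j - 1])
            if M[i, j - 1] - gap_open >= Y[i, j] - eps:
                state = "M"
            elif Y[i, j - 1] - gap_extend >= Y[i, j] - eps:
                state = "Y"
            else:
                state = "X"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    aln = MultipleAlignment(
        [a.id, b.id], ["".join(reversed(out_a)), "".join(reversed(out_b))]
    )
    return aln, float(score)


def alignment_score(aln: MultipleAlignment, matrix_name: str = "BLOSUM62",
                    gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Sum-of-pairs score of an existing alignment under the affine scheme
    used by :func:`global_pairwise_align` (gap/gap columns score zero)."""
    mat, index = score_matrix(matrix_name)
    total = 0.0
    for i in range(aln.n_rows):
        for j in range(i + 1, aln.n_rows):
            a, b = aln.rows[i], aln.rows[j]
            in_gap_a = in_gap_b = False
            for x, y in zip(a, b):
                if x == GAP and y == GAP:
                    continue
                if x == GAP:
                    total -= gap_extend if in_gap_a else gap_open
                    in_gap_a, in_gap_b = True, False
                elif y == GAP:
                    total -= gap_extend if in_gap_b else gap_open
                    in_gap_b, in_gap_a = True, False
                else:
                    total += mat[index.get(x, index["X"]), index.get(y, index["X"])]
                    in_gap_a = in_gap_b = False
    return total


# ---------------------------------------------------------------------------
# Percent identity
# ---------------------------------------------------------------------------


def percent_identity(
    aln: MultipleAlignment, mode: str = "exclude_terminal_gaps"
) -> float:
    """Percent identity of a two-row alignment.

    ``all_columns`` counts every column that is not gap/gap;
    ``exclude_terminal_gaps`` additionally drops columns lying in a leading
    or trailing gap run of either row.
    """
    if aln.n_rows != 2:
        raise ValidationError("percent_identity requires exactly 2 rows")
    if mode not in ("all_columns", "exclude_terminal_gaps"):
        raise ValidationError(f"unknown mode {mode!r}")
    a, b = aln.rows
    width = aln.n_columns
    lo, hi = 0, width
    if mode == "exclude_terminal_gaps":
        for row in (a, b):
            first = len(row) - len(row.lstrip(GAP))
            last = len(row.rstrip(GAP))
            lo = max(lo, first)
            hi = min(hi, last)
    counted = identical = 0
    for j in range(lo, hi):
        x, y = a[j], b[j]
        if x == GAP and y == GAP:
            continue
        counted += 1
        if x == y and x != GAP:
            identical += 1
    if counted == 0:
        raise ValidationError("percent_identity: no countable columns")
    return 100.0 * identical / counted


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


def _profile_counts(rows: list[str], index: dict[str, int], n_sym: int) -> np.ndarray:
    """Per-column residue count matrix (columns × alphabet); gaps excluded."""
    width = len(rows[0])
    counts = np.zeros((width, n_sym))
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                counts[j, index.get(c, index["X"])] += 1
    return counts


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    mat: np.ndarray,
    index: dict[str, int],
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Profile-profile global alignment; column score is the mean pairwise
    substitution score over non-gap residue pairs."""
    n_sym = mat.shape[0]
    ca = _profile_counts(rows_a, index, n_sym)
    cb = _profile_counts(rows_b, index, n_sym)
    na = ca.sum(axis=1)
    nb = cb.sum(axis=1)
    raw = ca @ mat @ cb.T
    denom = np.outer(np.maximum(na, 1), np.maximum(nb, 1))
    S = raw / denom

    n, m = len(na), len(nb)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - gap_open,
            X[i - 1, 1:] - gap_extend,
        )
        opener = np.maximum(M[i], X[i]) - gap_open
        cand = np.empty(m + 1)
        cand[0] = Y[i, 0]
        cand[1:] = opener[:-1] + js * gap_extend
        B = np.maximum.accumulate(cand)
        Y[i, 1:] = B[1:] - js * gap_extend

    # deterministic traceback, diagonal > up > left
    eps = 1e-9
    i, j = n, m
    best = max(M[i, j], X[i, j], Y[i, j])
    state = "M" if M[i, j] >= best - eps else ("X" if X[i, j] >= best - eps else "Y")
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ops.append("D")
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if M[i, j] >= prev - eps:
                state = "M"
            elif X[i, j] >= prev - eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            ops.append("U")
            if M[i - 1, j] - gap_open >= X[i, j] - eps:
                state = "M"
            elif X[i - 1, j] - gap_extend >= X[i, j] - eps:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            ops.append("L")
            if M[i, j - 1] - gap_open >= Y[i, j] - eps:
                state = "M"
            elif Y[i, j - 1] - gap_extend >= Y[i, j] - eps:
                state = "Y"
            else:
                state = "X"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    ops.reverse()

    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ia])
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
        if op in ("D", "L"):
            for k, row in enumerate(rows_b):
                out_b[k].append(row[ib])
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(
    units: Sequence[ProteinSequence],
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> MultipleAlignment:
    """Progressive multiple alignment of repeat-unit sequences.

    The guide tree is neighbor joining on pairwise alignment-score
    distances (1 − score / min(self-score)); profiles are merged in
    postorder of the guide tree.
    """
    if len(units) < 2:
        raise ValidationError("progressive_msa requires at least 2 sequences")
    ids = [u.id for u in units]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sequence ids in progressive_msa input")
    mat, index = score_matrix(matrix_name)

    n = len(units)
    self_scores = [
        float(sum(mat[index.get(c, index["X"]), index.get(c, index["X"])]
                  for c in u.residues))
        for u in units
    ]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, s = global_pairwise_align(
                units[i], units[j], matrix_name, gap_open, gap_extend
            )
            d = 1.0 - s / max(min(self_scores[i], self_scores[j]), 1e-9)
            dist[i, j] = dist[j, i] = max(d, 0.0)

    if n == 2:
        aln, _ = global_pairwise_align(units[0], units[1], matrix_name,
                                       gap_open, gap_extend)
        return aln

    from .tree_infer import DistanceMatrix, neighbor_joining

    guide = neighbor_joining(DistanceMatrix(list(ids), dist))
    by_id = {u.id: u for u in units}

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [by_id[node.name].residues]
        parts = [merge(c) for c in node.children]
        ids_acc, rows_acc = parts[0]
        for ids_b, rows_b in parts[1:]:
            rows_acc, rows_b = _align_profiles(
                rows_acc, rows_b, mat, index, gap_open, gap_extend
            )
            ids_acc = ids_acc + ids_b
            rows_acc = rows_acc + rows_b
        return ids_acc, rows_acc

    out_ids, out_rows = merge(guide.root)
    # restore input order for readability
    order = {sid: k for k, sid in enumerate(out_ids)}
    out = MultipleAlignment(
        [sid for sid in ids], [out_rows[order[sid]] for sid in ids]
    )
    return out


def read_alignment_fasta(path) -> MultipleAlignment:
    """Import an externally computed alignment from aligned FASTA."""
    from pathlib import Path

    records = []
    header = None
    chunks: list[str] = []
    with open(Path(path)) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    if not records:
        raise ValidationError(f"{path}: no alignment records")
    return MultipleAlignment([r[0] for r in records], [r[1] for r in records])
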