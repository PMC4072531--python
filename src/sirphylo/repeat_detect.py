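"""Dot-matrix repeat detection in synthetase linker regions.

A Pustell-style dot plot slides an odd-length window along both sequences
and marks coordinate pairs whose ungapped window score, under a chosen
substitution matrix (PAM250 by default), reaches a fraction of the window's
maximum attainable self-score. Runs of marks parallel to the main diagonal
betray repeat copies; the boundary caller anchors a fixed-length
(50-residue by default) frame on each run at the position maximizing the
summed score against a reference domain, automating the manual
boundary-designation step this analysis traditionally requires.

Degenerate repeats — units recognizable only at low stringency with little
residual homology to canonical domains — are flagged by running the caller
at two stringencies and marking units found only at the lower one.

The linker itself is located between the two conserved catalytic-domain
anchors (C-terminal ERS, N-terminal PRS) by local alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .io_core import ProteinSequence, ValidationError, logger
from .msa import score_matrix

__all__ = [
    "DotMatrix",
    "LinkerRegion",
    "RepeatUnit",
    "DetectConfig",
    "compute_dot_matrix",
    "extract_linker",
    "call_repeat_boundaries",
    "detect_degenerate_repeats",
    "units_to_rows",
]

DEFAULT_DOMAIN_LENGTH = 50


@dataclass(frozen=True)
class DetectConfig:
    """Stringency settings for one detection pass."""

    window: int = 11
    matrix_name: str = "PAM250"
    min_score_fraction: float = 0.5
    domain_length: int = DEFAULT_DOMAIN_LENGTH
    min_run: int = 3  # minimum diagonal run of marks to seed a unit


@dataclass
class DotMatrix:
    """Marks of a windowed dot-plot comparison (0-based window centers)."""

    query_id: str
    reference_id: str
    window: int
    matrix_name: str
    min_score_fraction: float
    marks: set[tuple[int, int]]

    def to_rows(self) -> list[tuple[int, int]]:
        return sorted(self.marks)

    def render(self, query_len: int, ref_len: int) -> str:
        """Text-art rendering, query along rows."""
        grid = [["."] * ref_len for _ in range(query_len)]
        for i, j in self.marks:
            grid[i][j] = "#"
        return "\n".join("".join(row) for row in grid)


@dataclass(frozen=True)
class LinkerRegion:
    """The inter-synthetase linker slice of a protein (0-based half-open)."""

    protein_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError("linker coordinates must satisfy 0 <= start < end")
        if len(self.sequence) != self.end - self.start:
            raise ValidationError("linker sequence length must equal end - start")


@dataclass
class RepeatUnit:
    """One fixed-length repeat domain within a protein."""

    species: Optional[str]
    protein_id: str
    ordinal: int
    start: int
    end: int
    sequence: str
    degenerate: bool = False
    stringency_detected: str = "high"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValidationError("repeat unit coordinates do not match sequence")


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    fallback = index.get("X", 0)
    return np.fromiter((index.get(c, fallback) for c in seq), dtype=np.intp,
                       count=len(seq))


def compute_dot_matrix(
    query: ProteinSequence,
    reference: ProteinSequence,
    window: int = 11,
    matrix_name: str = "PAM250",
    min_score_fraction: float = 0.5,
) -> DotMatrix:
    """Windowed dot-plot comparison.

    A mark is placed at window-center pair (i, j) iff the ungapped window
    score is at least ``min_score_fraction`` times the maximum attainable
    window self-score — the query window's self-score, capped by the
    reference window's so that self-comparisons are exactly symmetric.
    """
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be an odd integer >= 3")
    if window > min(len(query), len(reference)):
        raise ValidationError("window exceeds a sequence length")
    if not (0 < min_score_fraction <= 1):
        raise ValidationError("min_score_fraction must lie in (0, 1]")
    mat, index = score_matrix(matrix_name)
    q = _encode(query.residues, index)
    r = _encode(reference.residues, index)
    half = window // 2
    S = mat[np.ix_(q, r)]
    n, m = len(q), len(r)
    # summed window scores at all full-window centers
    W = np.full((n, m), -np.inf)
    centers_i = np.arange(half, n - half)
    centers_j = np.arange(half, m - half)
    if len(centers_i) and len(centers_j):
        acc = np.zeros((len(centers_i), len(centers_j)))
        for k in range(-half, half + 1):
            acc += S[np.ix_(centers_i + k, centers_j + k)]
        W[np.ix_(centers_i, centers_j)] = acc
    # per-center window self-scores; the threshold is the query window's
    # maximum attainable self-score, capped by the reference window's so
    # that self-comparisons are exactly symmetric
    kernel = np.ones(window)

    def _self_win(codes: np.ndarray) -> np.ndarray:
        diag_self = mat[codes, codes].astype(float)
        win = np.convolve(diag_self, kernel, mode="valid")  # index = start
        out = np.full(len(codes), np.inf)
        out[half : len(codes) - half] = win
        return out

    tq = _self_win(q)
    tr = _self_win(r)
    thresholds = min_score_fraction * np.minimum(tq[:, None], tr[None, :])
    marks = set(zip(*np.nonzero(W >= thresholds)))
    return DotMatrix(
        query_id=query.id,
        reference_id=reference.id,
        window=window,
        matrix_name=matrix_name,
        min_score_fraction=min_score_fraction,
        marks={(int(i), int(j)) for i, j in marks},
    )


# ---------------------------------------------------------------------------
# Linker extraction
# ---------------------------------------------------------------------------


class AnchorNotFoundError(ValidationError):
    """A catalytic-domain anchor failed to align above the score threshold."""


def _local_align(protein: ProteinSequence, anchor: ProteinSequence):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(protein.residues.replace("*", "X"),
                        anchor.residues.replace("*", "X"))[0]
    blocks = aln.aligned[0]
    start = int(blocks[0][0])
    end = int(blocks[-1][1])
    return float(aln.score), start, end


def extract_linker(
    protein: ProteinSequence,
    ers_anchor: ProteinSequence,
    prs_anchor: ProteinSequence,
    min_anchor_fraction: float = 0.4,
) -> LinkerRegion:
    """Locate the linker strictly between the ERS and PRS anchor footprints.

    Each anchor must align locally with score at least
    ``min_anchor_fraction`` of its self-alignment score.
    """
    if len(ers_anchor) < 30 or len(prs_anchor) < 30:
        raise ValidationError("anchors must be at least 30 residues")
    mat, index = score_matrix("BLOSUM62")

    def self_score(seq: str) -> float:
        codes = _encode(seq, index)
        return float(mat[codes, codes].sum())

    score_e, _, end_e = _local_align(protein, ers_anchor)
    score_p, start_p, _ = _local_align(protein, prs_anchor)
    if score_e < min_anchor_fraction * self_score(ers_anchor.residues):
        raise AnchorNotFoundError(f"anchor not found: ERS (score {score_e:.1f})")
    if score_p < min_anchor_fraction * self_score(prs_anchor.residues):
        raise AnchorNotFoundError(f"anchor not found: PRS (score {score_p:.1f})")
    if end_e >= start_p:
        raise ValidationError(
            f"anchors overlap or are out of order (ERS ends {end_e}, PRS starts {start_p})"
        )
    return LinkerRegion(
        protein_id=protein.id,
        start=end_e,
        end=start_p,
        sequence=protein.residues[end_e:start_p],
    )


# ---------------------------------------------------------------------------
# Boundary calling
# ---------------------------------------------------------------------------


def _diagonal_runs(marks: set[tuple[int, int]], min_run: int):
    """Maximal runs of consecutive marks along each diagonal offset."""
    by_offset: dict[int, list[int]] = {}
    for i, j in marks:
        by_offset.setdefault(i - j, []).append(i)
    runs = []
    for offset, centers in by_offset.items():
        centers.sort()
        run_start = prev = centers[0]
        for c in centers[1:] + [None]:
            if c is not None and c == prev + 1:
                prev = c
                continue
            if prev - run_start + 1 >= min_run:
                runs.append((offset, run_start, prev))
            if c is not None:
                run_start = prev = c
    return runs


def _ungapped_score(linker_codes, ref_codes, s, mat) -> float:
    L = len(ref_codes)
    return float(mat[linker_codes[s : s + L], ref_codes].sum())


def call_repeat_boundaries(
    linker: LinkerRegion,
    reference_domains: Sequence[ProteinSequence],
    window: int = 11,
    matrix_name: str = "PAM250",
    min_score_fraction: float = 0.5,
    domain_length: int = DEFAULT_DOMAIN_LENGTH,
    min_run: int = 3,
    species: Optional[str] = None,
) -> list[RepeatUnit]:
    """Automatic fixed-length repeat-boundary calling.

    For every maximal diagonal run of dot-plot marks between the linker and
    each reference domain, a ``domain_length`` frame is anchored at the
    start maximizing the summed ungapped score against the reference; hits
    are merged across references, overlaps resolved in favor of the higher
    score (ties: earlier start), and ordinals assigned N→C.
    """
    refs = [r for r in reference_domains if len(r) == domain_length]
    if not refs:
        raise ValidationError(
            f"need at least one reference domain of length {domain_length}"
        )
    L = len(linker.sequence)
    if L == 0:
        return []
    if domain_length > L:
        logger.warning(
            "linker %s shorter than domain_length; no units callable",
            linker.protein_id,
        )
        return []
    if "*" in linker.sequence:
        raise ValidationError(
            f"linker of {linker.protein_id!r} contains a stop character"
        )
    mat, index = score_matrix(matrix_name)
    linker_codes = _encode(linker.sequence, index)
    linker_prot = ProteinSequence(linker.protein_id + "_linker", linker.sequence)

    candidates = []  # (start, score, ref_id)
    for ref in refs:
        if window > min(L, domain_length):
            continue
        dm = compute_dot_matrix(
            linker_prot, ref, window, matrix_name, min_score_fraction
        )
        ref_codes = _encode(ref.residues, index)
        ref_self = float(mat[ref_codes, ref_codes].sum())
        # a window of w leaves only L - w + 1 valid centers on the
        # reference; wide windows cannot support long runs
        effective_min_run = max(1, min(min_run, domain_length - window + 1))
        for offset, lo, hi in _diagonal_runs(dm.marks, effective_min_run):
            s_lo = max(0, offset - window)
            s_hi = min(L - domain_length, offset + window)
            if s_lo > s_hi:
                continue
            best_s, best_score = None, -np.inf
            for s in range(s_lo, s_hi + 1):
                sc = _ungapped_score(linker_codes, ref_codes, s, mat)
                if sc > best_score:
                    best_s, best_score = s, sc
            if best_score >= min_score_fraction * ref_self:
                candidates.append((best_s, best_score, ref.id))

    # dedupe identical starts (keep best score), then resolve overlaps
    by_start: dict[int, tuple[float, str]] = {}
    for s, sc, rid in candidates:
        if s not in by_start or sc > by_start[s][0]:
            by_start[s] = (sc, rid)
    ranked = sorted(
        ((s, sc) for s, (sc, _) in by_start.items()),
        key=lambda t: (-t[1], t[0]),
    )
    chosen: list[tuple[int, float]] = []
    for s, sc in ranked:
        if all(s + domain_length <= t or t + domain_length <= s for t, _ in chosen):
            chosen.append((s, sc))
    chosen.sort()
    units = []
    for ordinal, (s, sc) in enumerate(chosen, start=1):
        units.append(
            RepeatUnit(
                species=species,
                protein_id=linker.protein_id,
                ordinal=ordinal,
                start=linker.start + s,
                end=linker.start + s + domain_length,
                sequence=linker.sequence[s : s + domain_length],
                degenerate=False,
                stringency_detected="high",
                score=sc,
            )
        )
    return units


def detect_degenerate_repeats(
    linker: LinkerRegion,
    reference_domains: Sequence[ProteinSequence],
    high_cfg: DetectConfig = DetectConfig(),
    low_cfg: DetectConfig = DetectConfig(min_score_fraction=0.3),
    species: Optional[str] = None,
) -> list[RepeatUnit]:
    """Two-stringency detection with degenerate-repeat flagging.

    Units found at high stringency are canonical; units found only at the
    lower stringency are flagged ``degenerate`` (detected at low
    stringency, little homology with canonical domains). Degenerate units
    may overlap canonical ones without violating the non-overlap invariant.
    """
    if not (low_cfg.min_score_fraction < high_cfg.min_score_fraction):
        raise ValidationError(
            "low-stringency min_score_fraction must be below high-stringency"
        )
    high = call_repeat_boundaries(
        linker, reference_domains, high_cfg.window, high_cfg.matrix_name,
        high_cfg.min_score_fraction, high_cfg.domain_length, high_cfg.min_run,
        species,
    )
    low = call_repeat_boundaries(
        linker, reference_domains, low_cfg.window, low_cfg.matrix_name,
        low_cfg.min_score_fraction, low_cfg.domain_length, low_cfg.min_run,
        species,
    )
    dl = high_cfg.domain_length
    out = list(high)
    for unit in low:
        overlaps = any(
            unit.start < h.end and h.start < unit.end for h in high
        )
        if not overlaps:
            unit.degenerate = True
            unit.stringency_detected = "low"
            out.append(unit)
    out.sort(key=lambda u: u.start)
    for ordinal, unit in enumerate(out, start=1):
        unit.ordinal = ordinal
    return out


def units_to_rows(units: Sequence[RepeatUnit]) -> list[dict]:
    """Repeat table rows (TSV columns of the external interface)."""
    return [
        {
            "species": u.species or "",
            "protein_id": u.protein_id,
            "ordinal": u.ordinal,
            "start": u.start,
            "end": u.end,
            "length": u.end - u.start,
            "degenerate": u.degenerate,
            "stringency": u.stringency_detected,
            "sequence": u.sequence,
        }
        for u in units
    ]
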