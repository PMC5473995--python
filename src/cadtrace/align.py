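"""Pairwise alignment machinery and the sliding-window dot-plot method.

A query protein is cut into overlapping 120-residue windows (step 5); each
window is locally aligned against a reference protein; hits are scored,
assigned Karlin–Altschul E-values, thresholded, and chained into collinear
segments.  Offset jumps between consecutive chained hits larger than a
tolerance are reported as architecture gaps (insertions/deletions of whole
domain blocks between the two proteins).

Alignment scoring uses an affine gap model in which a gap of length L costs
``gap_open + gap_extend * L`` (open 10, extend 0.1 by default) under a
BLOSUM substitution matrix.  Unknown residues 'X' score 0 against
everything.  The dynamic programming itself is delegated to
``Bio.Align.PairwiseAligner``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinRecord

#: E-value cutoff the original genome-wide tblastn screen used; kept as a
#: named constant for provenance, not used by the dot-plot itself.
DISCOVERY_EVALUE_CUTOFF = 1e-4


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for all pairwise alignment operations.

    ``gap_open``/``gap_extend`` follow the cost convention above (a length-1
    gap costs 10.1 with the defaults).  ``lambda_ka`` and ``k_ka`` are the
    ungapped Karlin–Altschul constants used for E-values; only the ordering
    and thresholding of E matter downstream, so standard BLOSUM62 values are
    used rather than re-derived statistics.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.1
    lambda_ka: float = 0.267
    k_ka: float = 0.041

    def __post_init__(self) -> None:
        if not self.gap_open > self.gap_extend > 0:
            raise ValueError("require gap_open > gap_extend > 0")
        if self.lambda_ka <= 0 or self.k_ka <= 0:
            raise ValueError("Karlin–Altschul constants must be positive")


@lru_cache(maxsize=8)
def load_matrix(name: str) -> substitution_matrices.Array:
    """A BLOSUM-family matrix with the X row/column neutralized to 0."""
    m = substitution_matrices.load(name)
    m = m.copy()
    if "X" in m.alphabet:
        for ch in m.alphabet:
            m["X", ch] = 0.0
            m[ch, "X"] = 0.0
    return m


def blast_local_params() -> AlignmentParams:
    """Default scoring for window-vs-reference local searches.

    The clustal-style 10/0.1 gap costs of :class:`AlignmentParams` are so
    permissive in *local* mode that random sequences reach high scores (the
    linear, non-Karlin–Altschul regime); window searches therefore default
    to the blastp-style 11/1 affine costs, for which λ=0.267 / K=0.041 are
    the standard gapped BLOSUM62 constants and E-values behave.
    """
    return AlignmentParams(gap_open=11.0, gap_extend=1.0)


def _make_aligner(params: AlignmentParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = load_matrix(params.matrix)
    # PairwiseAligner charges open for the first gap position and extend for
    # each further one; shift open so a length-L gap costs open + extend*L.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


@dataclass
class PairwiseAlignment:
    """A pairwise alignment as two equal-length gapped strings."""

    a_gapped: str
    b_gapped: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a_gapped) != len(self.b_gapped):
            raise ValueError("gapped rows differ in length")


def global_align(a: str, b: str, params: AlignmentParams | None = None
                 ) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch/Gotoh) alignment with affine gaps."""
    params = params or AlignmentParams()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(params, "global")
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(a_gapped=str(aln[0]), b_gapped=str(aln[1]),
                             score=float(aln.score))


def percent_identity(alignment: PairwiseAlignment) -> float:
    """Percent identical residue pairs over aligned columns.

    Terminal-gap overhang columns (leading/trailing columns where either row
    is still unaligned) are excluded from the denominator, so two sequences
    of different length that match perfectly over their overlap score 100.
    """
    a, b = alignment.a_gapped, alignment.b_gapped
    n = len(a)
    start = max(_first_residue(a), _first_residue(b))
    end = min(_last_residue(a), _last_residue(b))
    ident = 0
    total = 0
    for i in range(start, end + 1):
        if a[i] == "-" and b[i] == "-":
            continue
        total += 1
        if a[i] == b[i] and a[i] != "-":
            ident += 1
    if total == 0:
        raise ValueError("alignment has no comparable columns")
    return 100.0 * ident / total


def _first_residue(gapped: str) -> int:
    for i, ch in enumerate(gapped):
        if ch != "-":
            return i
    return len(gapped)


def _last_residue(gapped: str) -> int:
    for i in range(len(gapped) - 1, -1, -1):
        if gapped[i] != "-":
            return i
    return -1


# ---------------------------------------------------------------------------
# Sliding windows

@dataclass(frozen=True)
class Window:
    """One sliding-window slice of a query protein (start is 1-based)."""

    index: int
    start: int
    sequence: str
    terminal: bool = False
    short: bool = False


def make_windows(sequence: str | ProteinRecord, width: int = 120,
                 step: int = 5) -> list[Window]:
    """Overlapping windows at starts 1, 1+step, ...

    If the last full-width window does not reach the sequence end, one extra
    window anchored to end exactly at L is appended so C-terminal residues
    are never unscanned.  A sequence shorter than ``width`` yields a single
    short window, flagged.
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    seq = sequence.sequence if isinstance(sequence, ProteinRecord) else sequence
    L = len(seq)
    if L < width:
        return [Window(index=0, start=1, sequence=seq, short=True)]
    windows = []
    n_full = (L - width) // step + 1
    for i in range(n_full):
        s = i * step  # 0-based
        windows.append(Window(index=i, start=s + 1, sequence=seq[s : s + width]))
    last_end = (n_full - 1) * step + width
    if last_end < L:
        s = L - width
        windows.append(
            Window(index=n_full, start=s + 1, sequence=seq[s:], terminal=True)
        )
    return windows


# ---------------------------------------------------------------------------
# Local alignment and E-values

@dataclass(frozen=True)
class LocalHit:
    """One local alignment hit (all coordinates 1-based inclusive)."""

    score: float
    q_start: int
    q_end: int
    ref_start: int
    ref_end: int


def local_align(window: str | Window, reference: str, params:
                AlignmentParams | None = None, min_score: float = 1.0,
                max_hits: int = 5) -> list[LocalHit]:
    """Smith–Waterman optimal hit plus non-overlapping suboptimal hits.

    Suboptimal hits are found by masking the reference interval of each hit
    with 'X' (score 0) and re-aligning, until the score drops below
    ``min_score`` or ``max_hits`` is reached.
    """
    params = params or AlignmentParams()
    qseq = window.sequence if isinstance(window, Window) else window
    if len(qseq) < 1:
        return []
    aligner = _make_aligner(params, "local")
    hits: list[LocalHit] = []
    ref = reference
    for _ in range(max_hits):
        try:
            aln = aligner.align(qseq, ref)[0]
        except (IndexError, ValueError):
            break
        if aln.score < min_score:
            break
        qblocks, rblocks = aln.aligned
        if len(qblocks) == 0:
            break
        q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
        r0, r1 = int(rblocks[0][0]), int(rblocks[-1][1])
        hits.append(
            LocalHit(score=float(aln.score), q_start=q0 + 1, q_end=q1,
                     ref_start=r0 + 1, ref_end=r1)
        )
        ref = ref[:r0] + "X" * (r1 - r0) + ref[r1:]
    return hits


def evalue(score: float, m: int, n: int,
           params: AlignmentParams | None = None) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λS)."""
    params = params or AlignmentParams()
    if score < 0:
        raise ValueError("score must be non-negative")
    return params.k_ka * m * n * math.exp(-params.lambda_ka * score)


def min_score_for_evalue(e: float, m: int, n: int,
                         params: AlignmentParams | None = None) -> float:
    """Smallest score whose E-value is at most ``e``."""
    params = params or AlignmentParams()
    return math.log(params.k_ka * m * n / e) / params.lambda_ka


# ---------------------------------------------------------------------------
# Dot plot and collinear chaining

@dataclass(frozen=True)
class DotHit:
    """One retained window-vs-reference hit of a dot plot.

    ``q_start``/``q_end`` are global query coordinates (window offset already
    applied); ``offset`` is the diagonal ``ref_start − q_start``.
    """

    window_index: int
    q_start: int
    q_end: int
    ref_start: int
    ref_end: int
    score: float
    evalue: float

    @property
    def offset(self) -> int:
        return self.ref_start - self.q_start


@dataclass
class ChainSegment:
    """A maximal run of chained collinear hits at stable diagonal offset."""

    hits: list[DotHit]

    @property
    def q_range(self) -> tuple[int, int]:
        return self.hits[0].q_start, self.hits[-1].q_end

    @property
    def ref_range(self) -> tuple[int, int]:
        return self.hits[0].ref_start, self.hits[-1].ref_end

    @property
    def mean_offset(self) -> float:
        return float(np.mean([h.offset for h in self.hits]))

    @property
    def score(self) -> float:
        return sum(h.score for h in self.hits)


@dataclass(frozen=True)
class ChainGap:
    """An offset jump between two consecutive collinear segments."""

    q_position: int
    offset_jump: int


#: −log10(E) bin edges used for the heat-map view (presentational only)
EVALUE_BINS = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass
class DotPlot:
    query_id: str
    reference_id: str
    query_length: int
    reference_length: int
    window_width: int
    step: int
    e_cutoff: float
    hits: list[DotHit]
    segments: list[ChainSegment] = field(default_factory=list)
    gaps: list[ChainGap] = field(default_factory=list)

    def matrix_view(self) -> np.ndarray:
        """window-index × reference-position grid of −log10(E) bins (0–6)."""
        n_windows = max((h.window_index for h in self.hits), default=-1) + 1
        grid = np.zeros((n_windows, self.reference_length), dtype=np.int8)
        for h in self.hits:
            b = int(np.searchsorted(EVALUE_BINS, -math.log10(max(h.evalue, 1e-300)),
                                    side="right"))
            grid[h.window_index, h.ref_start - 1 : h.ref_end] = np.maximum(
                grid[h.window_index, h.ref_start - 1 : h.ref_end], b
            )
        return grid

    def hits_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "window_index": h.window_index,
                    "q_start": h.q_start,
                    "q_end": h.q_end,
                    "ref_start": h.ref_start,
                    "ref_end": h.ref_end,
                    "score": h.score,
                    "evalue": h.evalue,
                }
                for h in self.hits
            ]
        )


def dotplot(query: ProteinRecord, reference: ProteinRecord,
            params: AlignmentParams | None = None, e_cutoff: float = 1e-3,
            width: int = 120, step: int = 5, max_hits_per_window: int = 3,
            gap_tolerance: int = 30) -> DotPlot:
    """Sliding-window dot plot of ``query`` against ``reference``.

    Deterministic for fixed inputs: windows are scanned in order and hits
    with E ≤ ``e_cutoff`` retained, then chained into collinear segments.
    Local scoring defaults to :func:`blast_local_params`.
    """
    params = params or blast_local_params()
    windows = make_windows(query.sequence, width=width, step=step)
    n = len(reference.sequence)
    hits: list[DotHit] = []
    for w in windows:
        m = len(w.sequence)
        floor = max(min_score_for_evalue(e_cutoff, m, n, params), 1.0)
        for lh in local_align(w.sequence, reference.sequence, params,
                              min_score=floor, max_hits=max_hits_per_window):
            e = evalue(lh.score, m, n, params)
            if e <= e_cutoff:
                hits.append(
                    DotHit(
                        window_index=w.index,
                        q_start=w.start + lh.q_start - 1,
                        q_end=w.start + lh.q_end - 1,
                        ref_start=lh.ref_start,
                        ref_end=lh.ref_end,
                        score=lh.score,
                        evalue=e,
                    )
                )
    segments, gaps = chain_collinear(hits, gap_tolerance=gap_tolerance)
    return DotPlot(
        query_id=query.id,
        reference_id=reference.id,
        query_length=len(query.sequence),
        reference_length=n,
        window_width=width,
        step=step,
        e_cutoff=e_cutoff,
        hits=hits,
        segments=segments,
        gaps=gaps,
    )


def chain_collinear(hits: list[DotHit], gap_tolerance: int = 30
                    ) -> tuple[list[ChainSegment], list[ChainGap]]:
    """Maximum-score collinear chain, split into constant-offset segments.

    The chain is the weighted longest-increasing-subsequence of hits that is
    strictly increasing in both query start and reference start, maximizing
    total hit score.  Consecutive chain members whose diagonal offset differs
    by more than ``gap_tolerance`` residues split the chain into segments and
    emit a gap record carrying the (signed) offset jump.  Output is invariant
    to the order of the input hits.
    """
    if not hits:
        return [], []
    ordered = sorted(hits, key=lambda h: (h.q_start, h.ref_start, h.ref_end))
    nh = len(ordered)
    q = np.array([h.q_start for h in ordered])
    r = np.array([h.ref_start for h in ordered])
    w = np.array([h.score for h in ordered])
    best = np.zeros(nh)
    prev = np.full(nh, -1, dtype=int)
    for i in range(nh):
        mask = (q[:i] < q[i]) & (r[:i] < r[i])
        if mask.any():
            cand = np.where(mask)[0]
            j = cand[np.argmax(best[cand])]
            best[i] = best[j] + w[i]
            prev[i] = j
        else:
            best[i] = w[i]
    end = int(np.argmax(best))
    chain: list[DotHit] = []
    while end != -1:
        chain.append(ordered[end])
        end = prev[end]
    chain.reverse()

    segments: list[ChainSegment] = []
    current = [chain[0]]
    for h in chain[1:]:
        if abs(h.offset - current[-1].offset) > gap_tolerance:
            segments.append(ChainSegment(hits=current))
            current = [h]
        else:
            current.append(h)
    segments.append(ChainSegment(hits=current))
    # gap magnitude from segment mean offsets: robust against single hits
    # whose local alignment spans the breakpoint with an internal gap
    gaps = [
        ChainGap(
            q_position=nxt.hits[0].q_start,
            offset_jump=round(nxt.mean_offset - prev.mean_offset),
        )
        for prev, nxt in zip(segments, segments[1:])
    ]
    return segments, gaps
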