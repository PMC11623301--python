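"""Single best alignment of a gene against a whole genome.

Two routes live here on purpose:

* :func:`dp_align_oracle` — a full Smith–Waterman local dynamic program,
  written from the recurrence, used as the exhaustive reference in tests.
  It is O(|a|·|b|) in time and memory and is only meant for small inputs.
* :func:`best_hit` — the production seed-and-extend search: exact k-mer
  seeds anchor candidate diagonals; each surviving candidate window is
  scored with Bio.Align.PairwiseAligner. The *ranking score* is the local
  alignment score of the window (comparable to the oracle). The reported
  alignment length and percent identity come from a "glocal" alignment
  (whole query, local subject), so that a diverged gene is measured over
  its full length instead of a trimmed conserved core — trimming would
  bias background identity upward and break the vertical-descent
  baseline the screen depends on.

Percent identity is matches divided by all alignment columns including
gap columns; N never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import Align

from .io_formats import GenomeSequence, reverse_complement

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class Scoring:
    """Linear scoring scheme: match > 0, mismatch < 0, gap < 0 per gap column."""

    match: int = 1
    mismatch: int = -1
    gap: int = -4

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap >= 0:
            raise ValueError("require match > 0, mismatch < 0, gap < 0")


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment summary.

    Spans are half-open on the input sequences; ``columns`` counts all
    alignment columns including gap columns.
    """

    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    columns: int
    matches: int
    gaps: int
    score: int

    @property
    def mismatches(self) -> int:
        return self.columns - self.matches - self.gaps


@dataclass(frozen=True)
class BestHit:
    """Top-scoring placement of one gene in one genome (one scatter point)."""

    gene_id: str
    subject_contig: str
    subject_span: tuple[int, int]
    align_len: int  # alignment columns, incl. gaps
    pct_identity: float
    score: int
    strand: str = "+"


def percent_identity(aln: Alignment) -> float:
    """100 * matches / columns; gap columns count as non-matches."""
    if aln.columns <= 0:
        raise ValueError("alignment has zero columns")
    return 100.0 * aln.matches / aln.columns


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_matrix_row(a_char: str, b: np.ndarray, scoring: Scoring) -> np.ndarray:
    # N never matches, not even N vs N
    if a_char == "N":
        return np.full(b.shape, scoring.mismatch, dtype=np.int64)
    eq = b == ord(a_char)
    out = np.where(eq, scoring.match, scoring.mismatch).astype(np.int64)
    out[b == ord("N")] = scoring.mismatch
    return out


def dp_align_oracle(a: str, b: str, scoring: Scoring = Scoring()) -> Alignment:
    """Exhaustive local alignment of a (query) vs b (subject) by full DP.

    Returns a maximal-scoring local alignment. Ties are broken by
    (smaller subject start, then smaller query start, then fewer
    columns). A best score of 0 is reported as an empty alignment.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    m, n = len(a), len(b)
    g = scoring.gap
    b_arr = _encode(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    jidx = np.arange(n, dtype=np.int64)
    for i in range(1, m + 1):
        sub = _match_matrix_row(a[i - 1], b_arr, scoring)
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + g)
        cand = np.maximum(cand, 0)
        # horizontal gap chains, H[i,j] = max(cand[j], H[i,j-1] + g), unroll to
        # a decayed prefix max: H[i,j] = g*j + max_{l<=j}(cand[l] - g*l)
        H[i, 1:] = np.maximum.accumulate(cand - g * jidx) + g * jidx
    best_score = int(H.max())
    if best_score <= 0:
        return Alignment((0, 0), (0, 0), 0, 0, 0, 0)
    ends = np.argwhere(H == best_score)
    candidates = []
    for i_end, j_end in ends:
        aln = _traceback(H, a, b_arr, int(i_end), int(j_end), scoring)
        candidates.append(aln)
    candidates.sort(key=lambda x: (x.subject_span[0], x.query_span[0], x.columns))
    return candidates[0]


def _traceback(
    H: np.ndarray, a: str, b_arr: np.ndarray, i: int, j: int, scoring: Scoring
) -> Alignment:
    g = scoring.gap
    matches = gaps = columns = 0
    i_end, j_end = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = _pair_score(a[i - 1], b_arr[j - 1], scoring)
        if H[i, j] == H[i - 1, j - 1] + sub:
            if sub == scoring.match:
                matches += 1
            columns += 1
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + g:
            gaps += 1
            columns += 1
            i -= 1
        elif H[i, j] == H[i, j - 1] + g:
            gaps += 1
            columns += 1
            j -= 1
        else:  # pragma: no cover - recurrence guarantees one branch holds
            raise AssertionError("traceback inconsistency")
    return Alignment(
        query_span=(i, i_end),
        subject_span=(j, j_end),
        columns=columns,
        matches=matches,
        gaps=gaps,
        score=int(H[i_end, j_end]),
    )


def _pair_score(a_char: str, b_byte: int, scoring: Scoring) -> int:
    if a_char == "N" or b_byte == ord("N"):
        return scoring.mismatch
    return scoring.match if ord(a_char) == b_byte else scoring.mismatch


# ---------------------------------------------------------------------------
# Production search: seed-and-extend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchParams:
    seed_len: int = 11
    scoring: Scoring = Scoring()
    min_score: int = 30
    band: int = 16  # half-width of diagonal drift tolerated in one window
    max_windows: int = 4  # candidate windows taken to full alignment per strand


class GenomeIndex:
    """Exact k-mer position index of one genome (forward strand only)."""

    def __init__(self, genome: GenomeSequence, k: int):
        if k < 4:
            raise ValueError("seed length must be >= 4")
        self.genome = genome
        self.k = k
        index: dict[str, list[int]] = {}
        seq = genome.residues
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append(pos)
        self._index = index

    def positions(self, kmer: str) -> list[int]:
        return self._index.get(kmer, [])


def _make_aligners(scoring: Scoring) -> tuple[Align.PairwiseAligner, Align.PairwiseAligner]:
    local = Align.PairwiseAligner()
    local.mode = "local"
    glocal = Align.PairwiseAligner()
    glocal.mode = "global"
    for al in (local, glocal):
        al.match_score = scoring.match
        al.mismatch_score = scoring.mismatch
        al.open_gap_score = scoring.gap
        al.extend_gap_score = scoring.gap
    # must come after the generic gap scores, which overwrite all gap classes:
    glocal.end_deletion_score = 0  # subject overhang beyond the query is free
    return local, glocal


def _diagonal_clusters(seeds: list[tuple[int, int]], band: int) -> list[tuple[int, int]]:
    """Group seed hits (q_pos, s_pos) by diagonal; return (diag, n_seeds) clusters.

    Diagonals within ``band`` of each other chain into one cluster; the
    cluster is represented by its most frequent diagonal (smallest on a
    tie), which anchors the extension window.
    """
    diags = sorted(s - q for q, s in seeds)
    clusters: list[tuple[int, int]] = []
    group: list[int] = [diags[0]]
    for d in diags[1:]:
        if d - group[-1] <= band:
            group.append(d)
        else:
            clusters.append((_mode(group), len(group)))
            group = [d]
    clusters.append((_mode(group), len(group)))
    return clusters


def _mode(values: list[int]) -> int:
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return min(counts, key=lambda v: (-counts[v], v))


def _ungapped_prescore(
    q_arr: np.ndarray, s_arr: np.ndarray, diag: int, scoring: Scoring
) -> int:
    """Best local ungapped segment score along one diagonal (Kadane via cumsum)."""
    m = len(q_arr)
    s_start = diag
    q_lo = max(0, -s_start)
    q_hi = min(m, len(s_arr) - s_start)
    if q_hi - q_lo <= 0:
        return 0
    qs = q_arr[q_lo:q_hi]
    ss = s_arr[s_start + q_lo : s_start + q_hi]
    x = np.where((qs == ss) & (qs != ord("N")), scoring.match, scoring.mismatch)
    c = np.concatenate(([0], np.cumsum(x)))
    return int(np.max(c[1:] - np.minimum.accumulate(c[:-1])))


def _glocal_stats(
    glocal: Align.PairwiseAligner, query: str, window: str
) -> tuple[int, int, int, tuple[int, int]]:
    """Align full query into window; return (columns, matches, gaps, subject span).

    Subject-overhang columns (query-row gaps at either end) are trimmed
    before counting — they are the free flanks, not alignment columns.
    """
    aln = glocal.align(window, query)[0]
    t_row = str(aln[0])
    q_row = str(aln[1])
    lo = 0
    while lo < len(q_row) and q_row[lo] == "-":
        lo += 1
    hi = len(q_row)
    while hi > lo and q_row[hi - 1] == "-":
        hi -= 1
    t_core, q_core = t_row[lo:hi], q_row[lo:hi]
    columns = len(q_core)
    matches = gaps = 0
    for tc, qc in zip(t_core, q_core):
        if tc == "-" or qc == "-":
            gaps += 1
        elif tc == qc and tc != "N":
            matches += 1
    t_ranges = aln.aligned[0]
    subject_span = (int(t_ranges[0][0]), int(t_ranges[-1][1]))
    return columns, matches, gaps, subject_span


def best_hit(
    gene_id: str,
    gene_seq: str,
    index: GenomeIndex,
    params: SearchParams = SearchParams(),
) -> Optional[BestHit]:
    """Seed-and-extend search of one gene against one genome; top hit or None.

    Both strands are searched (the reverse complement of the gene against
    the forward genome); coordinates are always reported on the subject's
    forward strand. Ties are broken by (higher score, '+' before '-',
    smaller subject start, smaller query diagonal).
    """
    k = params.seed_len
    if len(gene_seq) <= k:
        raise ValueError(f"gene {gene_id!r}: length must exceed seed length {k}")
    genome = index.genome
    s_arr = _encode(genome.residues)
    local, glocal = _make_aligners(params.scoring)
    pad = 2 * params.band + 8

    windows: list[tuple[int, int, str]] = []  # (prescore, diag, strand)
    for strand, seq in (("+", gene_seq), ("-", reverse_complement(gene_seq))):
        seeds = []
        for q_pos in range(len(seq) - k + 1):
            kmer = seq[q_pos : q_pos + k]
            if "N" in kmer:
                continue
            for s_pos in index.positions(kmer):
                seeds.append((q_pos, s_pos))
        if not seeds:
            continue
        q_arr = _encode(seq)
        for diag, _count in _diagonal_clusters(seeds, params.band):
            pre = _ungapped_prescore(q_arr, s_arr, diag, params.scoring)
            windows.append((pre, diag, strand))
    if not windows:
        return None
    windows.sort(key=lambda w: (-w[0], w[2] != "+", w[1]))

    best: Optional[tuple[float, int, str, tuple[int, int]]] = None
    for pre, diag, strand in windows[: params.max_windows]:
        # a window's gapped local score can exceed its ungapped prescore only
        # by chaining nearby segments across gap penalties; once a window is
        # in hand, ones with a small fraction of its score cannot win
        if best is not None and best[0] >= params.min_score and 3 * pre < best[0]:
            break
        seq = gene_seq if strand == "+" else reverse_complement(gene_seq)
        w_lo = max(0, diag - pad)
        w_hi = min(genome.length, diag + len(seq) + pad)
        if w_hi <= w_lo:
            continue
        score = local.score(genome.residues[w_lo:w_hi], seq)
        key = (score, w_lo, strand, (w_lo, w_hi))
        if best is None or (score, strand == "+", -w_lo) > (best[0], best[2] == "+", -best[1]):
            best = (score, w_lo, strand, (w_lo, w_hi))

    if best is None or best[0] < params.min_score:
        return None
    score, _w_lo, strand, (lo, hi) = best
    seq = gene_seq if strand == "+" else reverse_complement(gene_seq)
    window = genome.residues[lo:hi]
    columns, matches, gaps, (t_lo, t_hi) = _glocal_stats(glocal, seq, window)
    if columns == 0:
        return None
    return BestHit(
        gene_id=gene_id,
        subject_contig=genome.id,
        subject_span=(lo + t_lo, lo + t_hi),
        align_len=columns,
        pct_identity=100.0 * matches / columns,
        score=int(score),
        strand=strand,
    )
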