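"""All-vs-all protein local alignment and per-hit statistics.

Alignment is exact Smith-Waterman with affine gaps (Gotoh), computed by
Biopython's C pairwise aligner; identity, positives and coverage statistics
are derived from the optimal traceback.  Gap costs follow the BLAST
convention: a gap of length L costs ``gap_open + gap_extend * L``.

For large gene sets an optional exact-match k-mer prescreen restricts the
quadratic pair list to sequence pairs sharing at least ``min_kmer_matches``
5-mers; the prescreen is deterministic, and with the default of 0 every
pair above the reporting score floor is aligned and reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import Proteome, TabularHit

logger = logging.getLogger(__name__)

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_SCORE_FLOOR = 40.0
PRESCREEN_K = 5


@dataclass
class AlignmentHit:
    """Statistics of one optimal local alignment between two proteins."""

    query_id: str
    subject_id: str
    score: float
    pct_identity: float      # identical columns / all aligned columns, in %
    pct_positives: float     # positive-scoring columns / all aligned columns, in %
    q_cov: float             # aligned query span / query length
    s_cov: float             # aligned subject span / subject length
    aln_length: int          # aligned columns including gap columns

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= self.pct_positives <= 100.0 + 1e-9):
            raise ValueError(
                f"identity/positives out of order for {self.query_id}->{self.subject_id}: "
                f"{self.pct_identity} vs {self.pct_positives}"
            )

    def swapped(self) -> "AlignmentHit":
        """The same alignment viewed from the subject's side."""
        return AlignmentHit(
            query_id=self.subject_id,
            subject_id=self.query_id,
            score=self.score,
            pct_identity=self.pct_identity,
            pct_positives=self.pct_positives,
            q_cov=self.s_cov,
            s_cov=self.q_cov,
            aln_length=self.aln_length,
        )


def make_aligner(
    matrix_name: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Align.PairwiseAligner:
    if gap_open < gap_extend or gap_extend < 0:
        raise ValueError("require gap_open >= gap_extend >= 0")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # BLAST convention: gap of length L costs open + extend*L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _positive_pairs(matrix) -> Set[Tuple[str, str]]:
    """Residue pairs counted as 'positives': positive matrix score, plus
    identities (so identity <= positives holds even for X-X columns)."""
    alpha = matrix.alphabet
    pairs = {(x, y) for x in alpha for y in alpha if matrix[x, y] > 0}
    pairs.update((x, x) for x in alpha)
    return pairs


def _hit_from_alignment(query_id, subject_id, a, b, alignment, positive_pairs) -> AlignmentHit:
    qa, sa = alignment.aligned  # blocks of (start, end) on each sequence
    n_ident = 0
    n_pos = 0
    n_match_cols = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        for i in range(qe - qs):
            ca, cb = a[qs + i], b[ss + i]
            n_match_cols += 1
            if ca == cb:
                n_ident += 1
            if (ca, cb) in positive_pairs:
                n_pos += 1
    # gap columns between consecutive aligned blocks
    n_gap_cols = 0
    for k in range(1, len(qa)):
        n_gap_cols += (qa[k][0] - qa[k - 1][1]) + (sa[k][0] - sa[k - 1][1])
    aln_length = n_match_cols + n_gap_cols
    q_span = qa[-1][1] - qa[0][0]
    s_span = sa[-1][1] - sa[0][0]
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(alignment.score),
        pct_identity=100.0 * n_ident / aln_length,
        pct_positives=100.0 * n_pos / aln_length,
        q_cov=q_span / len(a),
        s_cov=s_span / len(b),
        aln_length=aln_length,
    )


def align_local(
    a: str,
    b: str,
    matrix_name: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    query_id: str = "query",
    subject_id: str = "subject",
    aligner: Optional[Align.PairwiseAligner] = None,
) -> Optional[AlignmentHit]:
    """Optimal Smith-Waterman local alignment of two proteins.

    Returns ``None`` when no positive-scoring local alignment exists
    (the Smith-Waterman score floor of 0).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    if aligner is None:
        aligner = make_aligner(matrix_name, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return None
    alignment = aligner.align(a, b)[0]
    return _hit_from_alignment(
        query_id, subject_id, a, b, alignment, _positive_pairs(aligner.substitution_matrix)
    )


def _kmer_set(seq: str, k: int = PRESCREEN_K) -> Set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _candidate_pairs(
    A: Proteome, B: Proteome, min_kmer_matches: int, self_mode: bool
) -> Iterable[Tuple[int, int]]:
    if min_kmer_matches <= 0:
        for i, j in itertools.product(range(A.n_genes), range(B.n_genes)):
            if self_mode and A.records[i].id == B.records[j].id:
                continue
            yield i, j
        return
    # inverted index: kmer -> subject indices
    index: Dict[str, List[int]] = {}
    for j, rec in enumerate(B.records):
        for kmer in _kmer_set(rec.seq):
            index.setdefault(kmer, []).append(j)
    for i, rec in enumerate(A.records):
        counts: Dict[int, int] = {}
        for kmer in _kmer_set(rec.seq):
            for j in index.get(kmer, ()):
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            if c >= min_kmer_matches:
                if self_mode and rec.id == B.records[j].id:
                    continue
                yield i, j


def all_vs_all(
    A: Proteome,
    B: Proteome,
    matrix_name: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    score_floor: float = DEFAULT_SCORE_FLOOR,
    min_kmer_matches: int = 0,
) -> List[AlignmentHit]:
    """Align every gene of A against every gene of B (exact DP, deterministic).

    Hits scoring below ``score_floor`` are not reported.  When A and B are
    the same proteome (self-mode), self-pairs are skipped so each gene's
    best hit is its closest paralog.
    """
    aligner = make_aligner(matrix_name, gap_open, gap_extend)
    positive_pairs = _positive_pairs(aligner.substitution_matrix)
    self_mode = A.genome_id == B.genome_id
    hits: List[AlignmentHit] = []
    n_aligned = 0
    for i, j in _candidate_pairs(A, B, min_kmer_matches, self_mode):
        ra, rb = A.records[i], B.records[j]
        score = aligner.score(ra.seq, rb.seq)
        n_aligned += 1
        if score < score_floor or score <= 0:
            continue
        alignment = aligner.align(ra.seq, rb.seq)[0]
        hits.append(_hit_from_alignment(ra.id, rb.id, ra.seq, rb.seq, alignment, positive_pairs))
    logger.info(
        "all_vs_all %s x %s: %d pairs aligned, %d hits >= floor %.0f",
        A.genome_id, B.genome_id, n_aligned, len(hits), score_floor,
    )
    return hits


# ---------------------------------------------------------------------------
# Interop with the 12-column tabular dialect


def hit_to_tabular(hit: AlignmentHit, q_len: int, s_len: int) -> TabularHit:
    """Lossy conversion to the 12-column dialect (coordinates approximate:
    the tabular carrier keeps the aligned spans, not the block structure)."""
    q_span = max(1, round(hit.q_cov * q_len))
    s_span = max(1, round(hit.s_cov * s_len))
    return TabularHit(
        query_id=hit.query_id,
        subject_id=hit.subject_id,
        pct_identity=round(hit.pct_identity, 2),
        aln_length=hit.aln_length,
        mismatches=0,
        gap_opens=0,
        q_start=1,
        q_end=q_span,
        s_start=1,
        s_end=s_span,
        evalue=0.0,
        bit_score=hit.score,
    )


def tabular_to_hit(t: TabularHit, q_len: int, s_len: int) -> AlignmentHit:
    """Interpret an externally supplied tabular hit as an AlignmentHit.

    Percent positives is not present in the 12-column dialect; it is
    conservatively set equal to percent identity.
    """
    return AlignmentHit(
        query_id=t.query_id,
        subject_id=t.subject_id,
        score=t.bit_score,
        pct_identity=t.pct_identity,
        pct_positives=t.pct_identity,
        q_cov=(t.q_end - t.q_start + 1) / q_len,
        s_cov=(t.s_end - t.s_start + 1) / s_len,
        aln_length=t.aln_length,
    )


EXTENDED_COLUMNS = (
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qcov", "scov", "ppos",
)


def write_hits_tsv(hits: Sequence[AlignmentHit], lengths: Dict[str, int], path, extended: bool = True) -> None:
    """Write hits in the tabular dialect; extended adds qcov/scov/ppos columns."""
    with open(path, "w") as fh:
        for h in hits:
            t = hit_to_tabular(h, lengths[h.query_id], lengths[h.subject_id])
            row = [
                t.query_id, t.subject_id, f"{t.pct_identity:.2f}", str(t.aln_length),
                str(t.mismatches), str(t.gap_opens), str(t.q_start), str(t.q_end),
                str(t.s_start), str(t.s_end), f"{t.evalue:.2g}", f"{t.bit_score:.1f}",
            ]
            if extended:
                row += [f"{h.q_cov:.4f}", f"{h.s_cov:.4f}", f"{h.pct_positives:.2f}"]
            fh.write("\t".join(row) + "\n")
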