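"""All-vs-all protein similarity with E-values, reciprocal best hits and
greedy non-redundant clustering.

Local alignments are exact Smith-Waterman (BLOSUM62, affine gaps; a gap of
length L costs ``gap_open + L * gap_extend``).  E-values follow the
Karlin-Altschul formula ``E = K * m * n * exp(-lambda * S)`` with the
standard gapped BLOSUM62-11-1 constants (lambda = 0.267, K = 0.041) as
configurable defaults; in database mode ``n`` is the total residue count of
the search panel, approximating database-style statistics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .synthetic import SeqEntry

__all__ = [
    "ScoringScheme",
    "SimilarityHit",
    "ClusterResult",
    "align_pair",
    "search_all_vs_all",
    "reciprocal_best_hits",
    "cluster_nonredundant",
    "as_entries",
]

logger = logging.getLogger(__name__)

_AA = set("ARNDCQEGHILKMFPSTWYVX")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring and E-value statistics.

    ``db_size`` (total residues of the search space) switches E-values into
    database mode; when None, pairwise mode uses the subject length.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    K: float = 0.041
    db_size: int | None = None

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)


@dataclass(frozen=True)
class SimilarityHit:
    """A pairwise local-alignment hit (the similarity network's edge currency)."""

    query: str
    subject: str
    raw_score: float
    identity: float
    aln_length: int
    evalue: float


@dataclass
class ClusterResult:
    representatives: list[SeqEntry]
    members: dict[str, list[str]]  # representative id -> member ids (incl. itself)


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    m = substitution_matrices.load(matrix)
    m = m.copy()
    if "X" in m.alphabet:   # ambiguous residues are scored neutrally
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence for {name}")
    seq = seq.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"sequence {name} contains invalid residues {sorted(bad)}")
    return seq


def as_entries(items) -> list[SeqEntry]:
    """Coerce SeqEntry / (id, seq) tuples / objects with id+seq attributes."""
    out = []
    for it in items:
        if isinstance(it, SeqEntry):
            out.append(it)
        elif isinstance(it, tuple):
            out.append(SeqEntry(id=it[0], seq=it[1]))
        else:
            seq = getattr(it, "aa_seq", None) or getattr(it, "seq")
            out.append(SeqEntry(id=it.id, seq=seq))
    return out


def raw_score(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Smith-Waterman score only (no traceback) -- fast path."""
    scheme = scheme or ScoringScheme()
    aligner = _aligner(scheme.matrix, scheme.gap_open, scheme.gap_extend)
    return float(aligner.score(_check_seq(a, "a"), _check_seq(b, "b")))


def align_pair(
    a: str,
    b: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> SimilarityHit:
    """Exact Smith-Waterman local alignment of two proteins.

    Identity is the fraction of identical aligned columns over the alignment
    length (aligned columns plus internal gaps).  The E-value uses m = |a|
    and n = scheme.db_size (database mode) or |b|.
    """
    scheme = scheme or ScoringScheme()
    a, b = _check_seq(a, query_id), _check_seq(b, subject_id)
    aligner = _aligner(scheme.matrix, scheme.gap_open, scheme.gap_extend)
    score = float(aligner.score(a, b))
    aln = next(iter(aligner.align(a, b)))
    blocks = aln.aligned
    identities = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(blocks[0], blocks[1]):
        seg_a, seg_b = a[a0:a1], b[b0:b1]
        identities += sum(x == y for x, y in zip(seg_a, seg_b))
        aligned_cols += a1 - a0
    if len(blocks[0]):
        span_a = blocks[0][-1][1] - blocks[0][0][0]
        span_b = blocks[1][-1][1] - blocks[1][0][0]
        aln_length = max(span_a, span_b)
    else:
        aln_length = 0
    identity = identities / aln_length if aln_length else 0.0
    n = scheme.db_size if scheme.db_size is not None else len(b)
    return SimilarityHit(
        query=query_id,
        subject=subject_id,
        raw_score=score,
        identity=identity,
        aln_length=aln_length,
        evalue=scheme.evalue(score, len(a), n),
    )


def search_all_vs_all(
    queries,
    panel,
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-5,
) -> list[SimilarityHit]:
    """Search every query against every panel entry, keeping hits with
    E-value <= ``evalue_max``; per-query hits are sorted by ascending
    E-value, then descending score, then subject id.  E-values are computed
    against the panel's total residue count (database mode) unless the
    scheme pins ``db_size``.
    """
    queries = as_entries(queries)
    panel = as_entries(panel)
    scheme = scheme or ScoringScheme()
    if not panel:
        warnings.warn("empty search panel: no hits")
        return []
    if scheme.db_size is None:
        scheme = replace(scheme, db_size=sum(len(p.seq) for p in panel))
    hits: list[SimilarityHit] = []
    for q in queries:
        q_hits = []
        for p in panel:
            # cheap score-only pass; traceback only for passing hits
            s = raw_score(q.seq, p.seq, scheme)
            if scheme.evalue(s, len(q.seq), scheme.db_size) > evalue_max:
                continue
            hit = align_pair(q.seq, p.seq, scheme, query_id=q.id, subject_id=p.id)
            if hit.evalue <= evalue_max:
                q_hits.append(hit)
        q_hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject))
        hits.extend(q_hits)
    return hits


def _unique_top(scores: np.ndarray, ids: list[str]) -> int | None:
    """Index of the strictly-best score, or None on an unresolved tie."""
    best = scores.max()
    tied = np.flatnonzero(scores == best)
    if len(tied) == 1:
        return int(tied[0])
    return None


def reciprocal_best_hits(
    set_A,
    set_B,
    scheme: ScoringScheme | None = None,
) -> list[tuple[str, str]]:
    """Pairs (a, b) such that b is a's unique top hit in B and a is b's
    unique top hit in A.  Since Smith-Waterman scores are symmetric, tops in
    both directions are taken from one pairwise score matrix; unresolved
    score ties are excluded and logged.  The result is a partial matching.
    """
    A, B = as_entries(set_A), as_entries(set_B)
    scheme = scheme or ScoringScheme()
    if not A or not B:
        return []
    S = np.empty((len(A), len(B)))
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            S[i, j] = raw_score(a.seq, b.seq, scheme)
    pairs = []
    for i, a in enumerate(A):
        j = _unique_top(S[i], [b.id for b in B])
        if j is None:
            logger.info("RBH: tie for top hit of %s; excluded", a.id)
            continue
        i_back = _unique_top(S[:, j], [x.id for x in A])
        if i_back is None:
            logger.info("RBH: tie for top hit of %s; excluded", B[j].id)
            continue
        if i_back == i:
            pairs.append((a.id, B[j].id))
    return pairs


def cluster_nonredundant(
    panel,
    identity_threshold: float = 0.9,
    scheme: ScoringScheme | None = None,
) -> ClusterResult:
    """Greedy longest-first non-redundant clustering.

    Sequences (longest first; ties by id) either join the first existing
    representative to which their aligned identity over the shorter sequence
    length reaches the threshold, or found a new cluster.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    panel = as_entries(panel)
    scheme = scheme or ScoringScheme()
    order = sorted(panel, key=lambda e: (-len(e.seq), e.id))
    reps: list[SeqEntry] = []
    members: dict[str, list[str]] = {}
    for entry in order:
        placed = False
        for rep in reps:
            hit = align_pair(entry.seq, rep.seq, scheme,
                             query_id=entry.id, subject_id=rep.id)
            ident_cols = hit.identity * hit.aln_length
            if ident_cols / min(len(entry.seq), len(rep.seq)) >= identity_threshold - 1e-12:
                members[rep.id].append(entry.id)
                placed = True
                break
        if not placed:
            reps.append(entry)
            members[entry.id] = [entry.id]
    return ClusterResult(representatives=reps, members=members)
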