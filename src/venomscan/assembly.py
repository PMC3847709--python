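"""Greedy overlap-consensus mini-assembly and read-to-contig mapping.

The assembler enforces the classic EST-style contig-building thresholds
(>= 40 bp overlap at >= 98% identity by default).  It is designed for
desk-scale cDNA libraries with substitution-dominated errors: candidate
overlaps are detected with a sampled k-mer index and verified exactly as
ungapped (Hamming) overlaps at a fixed diagonal, which is exact for
substitution-only reads.  Reads whose best overlap lies on the reverse
strand are reverse-complemented before joining, so contigs are built in a
single canonical orientation.

Consensus is a per-column majority vote; ties take the base contributed by
the earliest-joined read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import Read, revcomp

__all__ = [
    "AssemblyParams",
    "Contig",
    "MappingResult",
    "assemble",
    "map_reads_to_contigs",
]

logger = logging.getLogger(__name__)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_BIG = np.iinfo(np.int32).max


@dataclass(frozen=True)
class AssemblyParams:
    """Contig-building thresholds.

    ``min_overlap`` and ``min_identity`` gate every read join; reads shorter
    than ``min_read_len`` are never assembled (they are reported among the
    singletons with a logged count).
    """

    min_overlap: int = 40
    min_identity: float = 0.98
    min_read_len: int = 50

    def __post_init__(self):
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")

    @property
    def k(self) -> int:
        return max(4, min(16, self.min_overlap))

    @property
    def stride(self) -> int:
        return max(1, self.k - 4)


@dataclass
class Contig:
    """An assembled consensus with its member reads (the abundance currency)."""

    id: str
    consensus: str
    member_reads: list[str]

    @property
    def read_count(self) -> int:
        return len(self.member_reads)


@dataclass
class MappingResult:
    counts: dict[str, int]
    assignments: dict[str, str]
    unmapped: list[str]
    ambiguous: set[str] = field(default_factory=set)


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _codes(vals: np.ndarray, k: int) -> np.ndarray:
    """Dense k-mer integer codes; -1 where the window contains a non-ACGT."""
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    code = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        window = vals[i: n + i].astype(np.int64)
        bad |= window >= 4
        code = code * 4 + np.where(window >= 4, 0, window)
    code[bad] = -1
    return code


def _validate_reads(reads: list[Read]) -> None:
    for r in reads:
        if not set(r.seq.upper()) <= set("ACGTN"):
            raise ValueError(f"read {r.id} contains non-nucleotide characters")


class _ReadIndex:
    """Sampled k-mer index over both strands of every read."""

    def __init__(self, seqs: list[np.ndarray], rc_seqs: list[np.ndarray], k: int, stride: int):
        self.k, self.stride = k, stride
        self.table: dict[int, list[int]] = {}
        for ridx, (fwd, rc) in enumerate(zip(seqs, rc_seqs)):
            for strand, vals in ((0, fwd), (1, rc)):
                codes = _codes(vals, k)
                for pos in range(0, len(codes), stride):
                    c = codes[pos]
                    if c >= 0:
                        packed = ((ridx << 13) | pos) << 1 | strand
                        self.table.setdefault(int(c), []).append(packed)

    def query(self, codes: np.ndarray, qpos_offset: int):
        """Yield (ridx, strand, read_pos, cons_pos) for every sampled match."""
        for q, c in enumerate(codes):
            if c < 0:
                continue
            hits = self.table.get(int(c))
            if hits:
                for packed in hits:
                    strand = packed & 1
                    pos = (packed >> 1) & 0x1FFF
                    ridx = packed >> 14
                    yield ridx, strand, pos, q + qpos_offset


class _GrowingContig:
    """Mutable consensus with per-column base counts and first-contributor
    order for deterministic majority-vote tie-breaking."""

    def __init__(self, vals: np.ndarray):
        L = len(vals)
        self.counts = np.zeros((L, 4), dtype=np.int32)
        self.first = np.full((L, 4), _BIG, dtype=np.int32)
        self.cons = np.full(L, 4, dtype=np.uint8)
        self.left = 0            # columns prepended so far (seed coords + left = array index)
        self.n_joined = 0
        self.members: list[tuple[int, int, int]] = []  # (ridx, strand, seed_offset)

    def __len__(self):
        return len(self.cons)

    def _extend(self, left_by: int, right_by: int):
        if left_by > 0:
            self.counts = np.vstack([np.zeros((left_by, 4), np.int32), self.counts])
            self.first = np.vstack([np.full((left_by, 4), _BIG, np.int32), self.first])
            self.cons = np.concatenate([np.full(left_by, 4, np.uint8), self.cons])
            self.left += left_by
        if right_by > 0:
            self.counts = np.vstack([self.counts, np.zeros((right_by, 4), np.int32)])
            self.first = np.vstack([self.first, np.full((right_by, 4), _BIG, np.int32)])
            self.cons = np.concatenate([self.cons, np.full(right_by, 4, np.uint8)])

    def add(self, ridx: int, strand: int, seed_offset: int, vals: np.ndarray):
        start = seed_offset + self.left
        self._extend(-start if start < 0 else 0, max(0, start + len(vals) - len(self.cons)))
        start = max(0, start)
        cols = np.arange(start, start + len(vals))
        valid = vals < 4
        cols_v, vals_v = cols[valid], vals[valid].astype(np.int64)
        self.counts[cols_v, vals_v] += 1
        newly = self.first[cols_v, vals_v] == _BIG
        self.first[cols_v[newly], vals_v[newly]] = self.n_joined
        self._revote(cols_v)
        self.n_joined += 1
        self.members.append((ridx, strand, seed_offset))

    def _revote(self, cols: np.ndarray):
        c = self.counts[cols]
        maxc = c.max(axis=1, keepdims=True)
        score = self.first[cols] + np.where(c < maxc, np.int64(_BIG), 0)
        self.cons[cols] = np.argmin(score, axis=1).astype(np.uint8)

    def overlap_stats(self, seed_offset: int, vals: np.ndarray) -> tuple[int, int]:
        start = seed_offset + self.left
        a, b = max(0, start), min(len(self.cons), start + len(vals))
        if b <= a:
            return 0, 0
        seg_c = self.cons[a:b]
        seg_r = vals[a - start: b - start]
        matches = int(np.count_nonzero((seg_c == seg_r) & (seg_r < 4) & (seg_c < 4)))
        return b - a, matches

    def consensus_str(self) -> str:
        return _DECODE[self.cons].tobytes().decode()


def _passes(overlap: int, matches: int, params: AssemblyParams) -> bool:
    return overlap >= params.min_overlap and matches >= params.min_identity * overlap - 1e-9


def assemble(
    reads: list[Read], params: AssemblyParams | None = None
) -> tuple[list[Contig], list[str]]:
    """Greedy overlap-consensus assembly.

    Seeds each contig with the longest unassigned read, then repeatedly joins
    the unassigned read with the largest passing overlap to the growing
    consensus (ties: lexicographically smallest read id).  Reads that join no
    contig are returned as singletons; membership and the singleton set
    partition the input read ids.
    """
    params = params or AssemblyParams()
    if not reads:
        raise ValueError("no reads supplied")
    _validate_reads(reads)

    n = len(reads)
    seqs = [_encode(r.seq) for r in reads]
    rcs = [_encode(revcomp(r.seq.upper())) for r in reads]
    too_short = np.array([len(s) < params.min_read_len for s in seqs])
    if too_short.any():
        logger.info("assemble: %d reads shorter than %d nt left unassembled",
                    int(too_short.sum()), params.min_read_len)

    index = _ReadIndex(
        [s if not short else s[:0] for s, short in zip(seqs, too_short)],
        [s if not short else s[:0] for s, short in zip(rcs, too_short)],
        params.k, params.stride,
    )
    order = sorted(range(n), key=lambda i: (-len(seqs[i]), reads[i].id))
    assigned = np.zeros(n, dtype=bool)
    contigs: list[Contig] = []
    singletons: list[str] = []

    for seed in order:
        if assigned[seed] or too_short[seed]:
            continue
        assigned[seed] = True
        contig = _GrowingContig(seqs[seed])
        contig.add(seed, 0, 0, seqs[seed])
        # candidate pool: ridx -> {(strand, seed_offset): votes}
        pool: dict[int, dict[tuple[int, int], int]] = {}
        queried_hi = 0   # consensus columns (seed coords) queried so far: [queried_lo, queried_hi)
        queried_lo = 0

        def harvest(lo: int, hi: int):
            """Query index with consensus k-mers over seed-coord range [lo, hi)."""
            a, b = lo + contig.left, hi + contig.left
            a = max(0, a - params.k + 1)
            region = contig.cons[a:b]
            for ridx, strand, pos, q in index.query(_codes(region, params.k), a):
                if assigned[ridx]:
                    continue
                offset = (q - contig.left) - pos  # read start in seed coords
                votes = pool.setdefault(ridx, {})
                votes[(strand, offset)] = votes.get((strand, offset), 0) + 1

        harvest(0, len(seqs[seed]))
        queried_hi = len(seqs[seed])

        while True:
            accepted = []
            for ridx, votes in pool.items():
                if assigned[ridx]:
                    continue
                (strand, offset), _ = max(
                    votes.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1])
                )
                vals = rcs[ridx] if strand else seqs[ridx]
                overlap, matches = contig.overlap_stats(offset, vals)
                if _passes(overlap, matches, params):
                    accepted.append((overlap, reads[ridx].id, ridx, strand, offset))
            if not accepted:
                break
            accepted.sort(key=lambda t: (-t[0], t[1]))
            merged = 0
            for _, _, ridx, strand, offset in accepted:
                if assigned[ridx]:
                    continue
                vals = rcs[ridx] if strand else seqs[ridx]
                overlap, matches = contig.overlap_stats(offset, vals)
                if not _passes(overlap, matches, params):
                    continue  # consensus moved on; retry next round
                assigned[ridx] = True
                contig.add(ridx, strand, offset, vals)
                pool.pop(ridx, None)
                merged += 1
            if not merged:
                break
            lo_now = -contig.left
            hi_now = len(contig) - contig.left
            if lo_now < queried_lo:
                harvest(lo_now, queried_lo)
                queried_lo = lo_now
            if hi_now > queried_hi:
                harvest(queried_hi, hi_now)
                queried_hi = hi_now

        if contig.n_joined == 1:
            singletons.append(reads[seed].id)
        else:
            contigs.append(
                Contig(
                    id=f"contig{len(contigs) + 1:05d}",
                    consensus=contig.consensus_str(),
                    member_reads=[reads[m[0]].id for m in contig.members],
                )
            )
    singletons.extend(reads[i].id for i in range(n) if too_short[i])
    return contigs, singletons


def map_reads_to_contigs(
    reads: list[Read],
    contigs: list[Contig],
    params: AssemblyParams | None = None,
) -> MappingResult:
    """Assign each read to the contig with the best passing ungapped overlap
    (most matching bases, then longest overlap, then lexicographically
    smallest contig id; ties on the first two criteria are flagged
    ambiguous).  Counts are conserved: sum(counts) + |unmapped| = |reads|.
    """
    params = params or AssemblyParams()
    _validate_reads(reads)
    if not contigs:
        warnings.warn("no contigs supplied: all reads unmapped")
        return MappingResult({}, {}, [r.id for r in reads], set())

    k, stride = params.k, params.stride
    table: dict[int, list[tuple[int, int]]] = {}
    cvals = []
    for cidx, c in enumerate(contigs):
        vals = _encode(c.consensus)
        cvals.append(vals)
        for pos, code in enumerate(_codes(vals, k)):
            if code >= 0:
                table.setdefault(int(code), []).append((cidx, pos))

    counts = {c.id: 0 for c in contigs}
    assignments: dict[str, str] = {}
    unmapped: list[str] = []
    ambiguous: set[str] = set()

    for r in reads:
        fwd = _encode(r.seq)
        candidates: dict[tuple[int, int, int], int] = {}
        for strand, vals in ((0, fwd), (1, _encode(revcomp(r.seq.upper())))):
            codes = _codes(vals, k)
            positions = list(range(0, len(codes), stride)) or [0]
            for pos in positions:
                if pos >= len(codes) or codes[pos] < 0:
                    continue
                for cidx, cpos in table.get(int(codes[pos]), ()):
                    key = (cidx, strand, cpos - pos)
                    candidates[key] = candidates.get(key, 0) + 1
        best = None  # (-matches, -overlap, contig_id, strand, offset)
        tie = False
        seen_pairs = set()
        for (cidx, strand, offset), _ in sorted(
            candidates.items(), key=lambda kv: (-kv[1], kv[0])
        ):
            if (cidx, strand, offset) in seen_pairs:
                continue
            seen_pairs.add((cidx, strand, offset))
            vals = _encode(revcomp(r.seq.upper())) if strand else fwd
            overlap, matches = _overlap_vs(cvals[cidx], offset, vals)
            if not _passes(overlap, matches, params):
                continue
            key = (-matches, -overlap, contigs[cidx].id)
            if best is None or key[:2] < best[0][:2]:
                best = (key, cidx)
                tie = False
            elif key[:2] == best[0][:2] and key[2] != best[0][2]:
                tie = True
                if key[2] < best[0][2]:
                    best = (key, cidx)
        if best is None:
            unmapped.append(r.id)
        else:
            cid = contigs[best[1]].id
            counts[cid] += 1
            assignments[r.id] = cid
            if tie:
                ambiguous.add(r.id)
    return MappingResult(counts, assignments, unmapped, ambiguous)


def _overlap_vs(cons: np.ndarray, offset: int, vals: np.ndarray) -> tuple[int, int]:
    a, b = max(0, offset), min(len(cons), offset + len(vals))
    if b <= a:
        return 0, 0
    seg_c = cons[a:b]
    seg_r = vals[a - offset: b - offset]
    matches = int(np.count_nonzero((seg_c == seg_r) & (seg_r < 4) & (seg_c < 4)))
    return b - a, matches
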