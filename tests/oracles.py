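"""Independent reference implementations used to cross-check the package.

Each oracle is deliberately written as a naive, exhaustive computation that
shares no code path with the implementation it checks.
"""

import itertools

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from venomscan.synthetic import revcomp

_STOPS = {"TAA", "TAG", "TGA"}
_B62 = substitution_matrices.load("BLOSUM62")


def orf_enumeration_oracle(seq: str, min_len: int):
    """Brute-force six-frame ORF scan from every position."""
    out = set()
    n = len(seq)
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        for start in range(len(s) - 2):
            if s[start:start + 3] != "ATG":
                continue
            j = start
            while j + 3 <= len(s):
                codon = s[j:j + 3]
                if codon in _STOPS:
                    aa_len = (j - start) // 3
                    if aa_len >= min_len:
                        end = j + 3
                        if strand == 1:
                            frame, interval = start % 3 + 1, (start, end)
                        else:
                            frame, interval = -(start % 3 + 1), (n - end, n - start)
                        out.add((frame, interval, str(Seq(s[start:j]).translate())))
                    break
                j += 3
    return out


def sw_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Full-matrix Gotoh local alignment score (gap of length L costs
    gap_open + L * gap_extend)."""
    first = gap_open + gap_extend
    m, n = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            sub = H[i - 1][j - 1] + _B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class UnionFind:
    """Minimal disjoint-set structure for component cross-checks."""

    def __init__(self, nodes):
        self.parent = {n: n for n in nodes}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def partition(self):
        groups = {}
        for n in self.parent:
            groups.setdefault(self.find(n), set()).add(n)
        comps = sorted(
            (frozenset(g) for g in groups.values() if len(g) >= 2),
            key=lambda c: (-len(c), min(c)),
        )
        singles = sorted(n for g in groups.values() if len(g) == 1 for n in g)
        return comps, singles


def _aa(codon):
    out = str(Seq(codon).translate())
    return None if out == "*" else out


def ng86_site_oracle(a: str, b: str):
    """Per-codon enumeration of NG86 synonymous/nonsynonymous site counts,
    averaged over both sequences (stop mutations count nonsynonymous)."""
    def codon_s(codon):
        s = 0.0
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if _aa(alt) is not None and _aa(alt) == _aa(codon):
                    s += 1 / 3
        return s

    S = 0.0
    for i in range(0, len(a), 3):
        S += (codon_s(a[i:i + 3]) + codon_s(b[i:i + 3])) / 2
    return S, len(a) - S


SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in _STOPS
]
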