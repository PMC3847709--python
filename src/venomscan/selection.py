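"""Pairwise dN/dS (omega) screen over codon alignments.

Implements the Nei-Gojobori (1986) counting estimator with Jukes-Cantor
multiple-hit correction: synonymous and nonsynonymous *sites* are counted
from each codon's single-mutation neighbourhood (averaged over the two
sequences), *differences* are averaged with equal weights over all minimal
mutational pathways between differing codons, and the proportions are
corrected with d = -3/4 ln(1 - 4p/3).  An omega (dN/dS) above 1 over a
group of isoforms flags diversifying selection -- the inferential direction
of site-model analyses, at desk scale.

Mutations creating stop codons are counted as nonsynonymous sites (so site
counts conserve 3 per codon) but pathways passing through a stop codon are
excluded from difference averaging unless every pathway does.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "SelectionEstimate",
    "ng86_pairwise",
    "group_omega_screen",
    "simulate_codon_pair",
    "simulate_codon_alignment",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_NT = "ACGT"


def _aa(codon: str) -> str | None:
    """Amino acid for a codon, None for stops."""
    return _TABLE.forward_table.get(codon)


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous.
    Changes to stop codons count as nonsynonymous."""
    aa0 = _aa(codon)
    syn = 0
    for nt in _NT:
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1:]
        if _aa(alt) == aa0 and alt not in _STOPS:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3."""
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over minimal mutational pathways."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in _STOPS:
                through_stop = True
            if _aa(cur) == _aa(nxt) and not (cur in _STOPS or nxt in _STOPS):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    usable = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


@dataclass
class CodonAlignment:
    """Gap-aware aligned coding sequences of equal length (multiple of 3);
    gap runs must not break the reading frame."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length must be divisible by 3")

    def __len__(self):
        return len(self.seqs)


@dataclass
class SelectionEstimate:
    """Pairwise NG86 estimate; ``omega`` is None when dS is 0 or a
    Jukes-Cantor correction saturated."""

    pair: tuple[str, str]
    dN: float
    dS: float
    omega: float | None
    n_sites: float
    s_sites: float
    saturated: bool = False


def _strip_gaps(a: str, b: str) -> tuple[str, str]:
    out_a, out_b = [], []
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        out_a.append(ca)
        out_b.append(cb)
    return "".join(out_a), "".join(out_b)


def _jc(p: float) -> tuple[float, bool]:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("inf"), True
    return -0.75 * math.log(arg), False


def ng86_pairwise(a: str, b: str, pair: tuple[str, str] = ("a", "b")) -> SelectionEstimate:
    """Nei-Gojobori pairwise dN/dS with Jukes-Cantor correction.

    Inputs are equal-length in-frame codon sequences (gap columns, if
    present, are stripped codon-wise).  Internal stop codons are an input
    error.  The estimator is symmetric in its arguments.
    """
    a, b = a.upper().replace("U", "T"), b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("sequence length must be divisible by 3")
    a, b = _strip_gaps(a, b)
    codons_a = [a[i:i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i:i + 3] for i in range(0, len(b), 3)]
    for seq_name, codons in (("first", codons_a), ("second", codons_b)):
        for ci, c in enumerate(codons[:-1]):
            if c in _STOPS:
                raise ValueError(
                    f"internal stop codon at codon {ci} of the {seq_name} sequence"
                )
    # a terminal stop is allowed and ignored
    if codons_a and codons_a[-1] in _STOPS and codons_b[-1] in _STOPS:
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]
    elif codons_a and (codons_a[-1] in _STOPS or codons_b[-1] in _STOPS):
        raise ValueError("internal stop codon at the final position of one sequence")

    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, sat_s = _jc(pS)
    dN, sat_n = _jc(pN)
    saturated = sat_s or sat_n
    omega = None
    if not saturated and dS > 0:
        omega = dN / dS
    return SelectionEstimate(
        pair=pair,
        dN=dN if not sat_n else float("inf"),
        dS=dS if not sat_s else float("inf"),
        omega=omega,
        n_sites=N,
        s_sites=S,
        saturated=saturated,
    )


@dataclass
class GroupScreen:
    estimates: list[SelectionEstimate]
    mean_omega: float | None
    diversifying: bool


def group_omega_screen(alignment: CodonAlignment) -> GroupScreen:
    """All pairwise NG86 estimates over an isoform group.

    The group mean omega averages pairs with defined omega (dS > 0 and no
    saturated correction); the group is flagged diversifying when that mean
    exceeds 1.
    """
    if len(alignment) < 2:
        raise ValueError("a group screen needs at least 2 sequences")
    estimates = []
    for i, j in itertools.combinations(range(len(alignment)), 2):
        estimates.append(
            ng86_pairwise(
                alignment.seqs[i], alignment.seqs[j],
                pair=(alignment.ids[i], alignment.ids[j]),
            )
        )
    omegas = [e.omega for e in estimates if e.omega is not None]
    mean_omega = float(np.mean(omegas)) if omegas else None
    return GroupScreen(
        estimates=estimates,
        mean_omega=mean_omega,
        diversifying=mean_omega is not None and mean_omega > 1.0,
    )


# ---------------------------------------------------------------------------
# codon-evolution simulator (for parameter-recovery checks)
# ---------------------------------------------------------------------------

def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    codons = [c for c in _TABLE.forward_table]
    return "".join(rng.choice(sorted(codons), size=n_codons))


def _evolve(rng: np.random.Generator, seq: str, n_subs: int, omega: float) -> str:
    """Accept/reject single-nucleotide substitutions: synonymous proposals
    accepted with probability min(1, 1/omega), nonsynonymous with
    min(1, omega), so the realised nonsynonymous/synonymous rate ratio per
    site is omega.  Stop-creating proposals are always rejected."""
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_non = min(1.0, omega)
    chars = list(seq)
    accepted = 0
    while accepted < n_subs:
        pos = int(rng.integers(len(chars)))
        old = chars[pos]
        new = _NT[int(rng.integers(4))]
        if new == old:
            continue
        c0 = pos - pos % 3
        codon = "".join(chars[c0:c0 + 3])
        alt = codon[: pos - c0] + new + codon[pos - c0 + 1:]
        if alt in _STOPS:
            continue
        synonymous = _aa(codon) == _aa(alt)
        p = p_syn if synonymous else p_non
        if rng.random() < p:
            chars[pos] = new
            accepted += 1
    return "".join(chars)


def simulate_codon_pair(
    n_codons: int, omega: float, subs_per_seq: int, seed: int = 0
) -> tuple[str, str]:
    """Two coding sequences diverged from a random ancestor under a simple
    codon model with the given dN/dS."""
    rng = np.random.default_rng(seed)
    ancestor = _random_coding(rng, n_codons)
    a = _evolve(rng, ancestor, subs_per_seq, omega)
    b = _evolve(rng, ancestor, subs_per_seq, omega)
    return a, b


def simulate_codon_alignment(
    n_seqs: int, n_codons: int, omega: float, subs_per_seq: int, seed: int = 0
) -> CodonAlignment:
    """A star-topology isoform family evolved under the given dN/dS."""
    rng = np.random.default_rng(seed)
    ancestor = _random_coding(rng, n_codons)
    seqs = [_evolve(rng, ancestor, subs_per_seq, omega) for _ in range(n_seqs)]
    return CodonAlignment(ids=[f"iso{i + 1}" for i in range(n_seqs)], seqs=seqs)
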