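"""Six-frame ORF discovery, rule-based signal-peptide calls and cysteine profiling.

Open reading frames are enumerated in all six frames (standard genetic code)
from every ATG to the next in-frame stop codon.  Secreted proteins are
recognised with a deterministic heuristic modelled on the classical
von Heijne view of a signal peptide: a short positively charged n-region,
a hydrophobic h-region and small residues at the (-3, -1) positions flanking
the cleavage site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "ProteinRecord",
    "SignalCall",
    "SignalParams",
    "find_orfs",
    "predict_signal_peptide",
    "cysteine_profile",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SignalCall:
    """Outcome of the signal-peptide heuristic.

    ``cleavage_site`` is the 0-based index of the first mature residue.
    ``evaluable`` is False when the input was too short to assess, which is
    distinct from an evaluated-and-rejected call.
    """

    cleavage_site: int | None
    score: float
    accepted: bool
    evaluable: bool = True


@dataclass(frozen=True)
class SignalParams:
    """Tunable thresholds of the signal-peptide heuristic (all residue
    coordinates 0-based unless noted)."""

    cleavage_min: int = 15
    cleavage_max: int = 35
    n_region_len: int = 5          # leading residues searched for K/R
    min_basic: int = 1
    core_min_len: int = 6          # minimal hydrophobic-window length
    min_hydropathy: float = 1.6    # mean Kyte-Doolittle over the window
    small_residues: str = "AGSCT"  # allowed at positions c-3 and c-1


@dataclass
class ProteinRecord:
    """A translated ORF with its provenance on the source sequence.

    ``cds_interval`` is 0-based half-open on the *forward* strand of the
    source sequence and, for complete ORFs, includes the stop codon.
    """

    id: str
    source_id: str
    frame: int                      # +1,+2,+3,-1,-2,-3
    cds_interval: tuple[int, int]
    aa_seq: str
    has_start: bool = True
    has_stop: bool = True
    signal: SignalCall | None = None
    cys_positions: list[int] = field(default_factory=list)

    @property
    def truncated(self) -> bool:
        return not (self.has_start and self.has_stop)

    @property
    def mature_seq(self) -> str:
        if self.signal is not None and self.signal.accepted:
            return self.aa_seq[self.signal.cleavage_site:]
        return self.aa_seq


def _frame_orfs(frame_seq: str, min_len: int, include_partial: bool):
    """Yield (aa_start_codon_index, aa_len, has_start, has_stop) over one
    frame given as an in-frame nucleotide string."""
    n_codons = len(frame_seq) // 3
    codons = [frame_seq[3 * i: 3 * i + 3] for i in range(n_codons)]
    stop_idx = [i for i, c in enumerate(codons) if c in _STOPS]
    start_idx = [i for i, c in enumerate(codons) if c == "ATG"]
    stops = iter(stop_idx)
    for s in start_idx:
        nxt = next((t for t in stop_idx if t >= s), None)
        if nxt is not None:
            aa_len = nxt - s
            if aa_len >= min_len:
                yield s, aa_len, True, True
        elif include_partial:
            aa_len = n_codons - s
            if aa_len >= min_len:
                yield s, aa_len, True, False
    if include_partial and stop_idx:
        # open 5' end: frame start up to the first stop, no ATG required
        first = stop_idx[0]
        if first >= min_len and codons and codons[0] != "ATG":
            yield 0, first, False, True


def find_orfs(
    seq: str,
    min_len: int = 60,
    include_partial: bool = False,
    source_id: str = "",
) -> list[ProteinRecord]:
    """Enumerate ORFs of at least ``min_len`` amino acids in all six frames.

    Complete ORFs run from an ATG to the next in-frame stop (stop required);
    with ``include_partial`` ORFs running off either end of the sequence are
    also reported and flagged truncated.  Records are sorted by descending
    amino-acid length (ties: frame order +1,+2,+3,-1,-2,-3, then position).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = seq.upper()
    if len(seq) < 3:
        return []
    rc = str(Seq(seq).reverse_complement())
    found = []
    n = len(seq)
    for strand, s in ((1, seq), (-1, rc)):
        for off in range(3):
            frame_seq = s[off: off + 3 * ((len(s) - off) // 3)]
            for cs, aa_len, has_start, has_stop in _frame_orfs(
                frame_seq, min_len, include_partial
            ):
                nt_start = off + 3 * cs
                nt_end = nt_start + 3 * (aa_len + (1 if has_stop else 0))
                if strand == 1:
                    interval = (nt_start, nt_end)
                    frame = off + 1
                else:
                    interval = (n - nt_end, n - nt_start)
                    frame = -(off + 1)
                aa = str(Seq(frame_seq[nt_start - off: nt_start - off + 3 * aa_len]).translate())
                found.append((aa_len, frame, interval, aa, has_start, has_stop))
    frame_order = {f: i for i, f in enumerate((1, 2, 3, -1, -2, -3))}
    found.sort(key=lambda t: (-t[0], frame_order[t[1]], t[2][0]))
    records = []
    for i, (aa_len, frame, interval, aa, has_start, has_stop) in enumerate(found):
        rid = f"{source_id}|orf{i + 1}" if source_id else f"orf{i + 1}"
        records.append(
            ProteinRecord(
                id=rid,
                source_id=source_id,
                frame=frame,
                cds_interval=interval,
                aa_seq=aa,
                has_start=has_start,
                has_stop=has_stop,
            )
        )
    return records


def _max_window_mean(values: list[float], min_len: int) -> float:
    """Maximum mean over all contiguous windows of length >= min_len."""
    best = float("-inf")
    n = len(values)
    if n < min_len:
        return best
    prefix = list(itertools.accumulate(values, initial=0.0))
    for length in range(min_len, n + 1):
        for start in range(0, n - length + 1):
            mean = (prefix[start + length] - prefix[start]) / length
            if mean > best:
                best = mean
    return best


def predict_signal_peptide(aa_seq: str, params: SignalParams | None = None) -> SignalCall:
    """Deterministic rule-based signal-peptide call.

    A cleavage position ``c`` (0-based first mature residue) is accepted when
    the first ``n_region_len`` residues carry at least ``min_basic`` K/R, a
    hydrophobic window of >= ``core_min_len`` residues with mean
    Kyte-Doolittle hydropathy >= ``min_hydropathy`` lies within residues
    3..c-4 (1-based), and residues c-3 and c-1 are small.  The reported
    cleavage site maximises the window score (ties: smallest c); the score is
    the best window hydropathy in the candidate region.
    """
    p = params or SignalParams()
    aa_seq = aa_seq.upper()
    if len(aa_seq) < 25:
        return SignalCall(None, float("nan"), accepted=False, evaluable=False)
    hydro = [KYTE_DOOLITTLE.get(a, 0.0) for a in aa_seq]
    n_basic = sum(1 for a in aa_seq[: p.n_region_len] if a in "KR")
    c_hi = min(p.cleavage_max, len(aa_seq) - 1)
    overall = _max_window_mean(hydro[2: c_hi - 3], p.core_min_len)
    best_c, best_score = None, float("-inf")
    if n_basic >= p.min_basic:
        for c in range(p.cleavage_min, c_hi + 1):
            if aa_seq[c - 3] not in p.small_residues:
                continue
            if aa_seq[c - 1] not in p.small_residues:
                continue
            # 1-based residues 3..c-4  ->  0-based slice [2 : c-4]
            w = _max_window_mean(hydro[2: c - 4], p.core_min_len)
            if w < p.min_hydropathy:
                continue
            if w > best_score:
                best_score, best_c = w, c
    if best_c is None:
        return SignalCall(None, overall, accepted=False)
    return SignalCall(best_c, best_score, accepted=True)


def cysteine_profile(aa_seq: str, mature_start: int = 0) -> tuple[list[int], int]:
    """Positions (0-based within the mature region) and count of cysteines."""
    if not 0 <= mature_start < max(len(aa_seq), 1):
        raise ValueError("mature_start out of range")
    positions = [i for i, a in enumerate(aa_seq[mature_start:].upper()) if a == "C"]
    return positions, len(positions)
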