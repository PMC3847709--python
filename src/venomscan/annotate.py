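"""Toxin annotation workflow for assembled venom-gland transcripts.

The decision logic mirrors classic EST venom-gland screens:

1. *Known toxins*: a transcript's best panel hit (E <= 1e-5) must match a
   toxin-family keyword, and the call is only confirmed when the transcript
   and panel sequence are reciprocal best hits (a guard against the high
   false-positive rate of keyword searches, since most toxins arose by
   duplication of ordinary cellular genes).
2. *Stringency filters*: truncated ORFs, sequences with ambiguous residues
   and sequences without a signal peptide are excluded from the toxin
   repertory; named weakly-expressed families (sarafotoxins by default) are
   exempted, with a warning on the record.
3. *Novel candidates*: transcripts with no panel hit at all, a predicted
   signal peptide, a minimal mature cysteine count and a high abundance rank.
4. Everything else is a non-toxin.

Abundance is raw mapped-read counts (not length-normalized), ranked densely;
``cumulative_coverage`` inverts the cumulative curve (how many transcripts
cover a target fraction of reads).  ``parse_sarafotoxin_precursor`` excises
tandem mature peptides from polycistronic sarafotoxin precursors.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import AssemblyParams, Contig, assemble
from .orfs import ProteinRecord, SignalParams, cysteine_profile, find_orfs, predict_signal_peptide
from .similarity import ScoringScheme, SimilarityHit, as_entries, reciprocal_best_hits, search_all_vs_all
from .synthetic import Read, SeqEntry

__all__ = [
    "TOXIN_KEYWORDS",
    "AnnotationRecord",
    "AbundanceTable",
    "SarafotoxinPrecursor",
    "NovelParams",
    "select_toxin_candidates",
    "apply_stringency_filters",
    "detect_novel_candidates",
    "rank_abundance",
    "cumulative_coverage",
    "parse_sarafotoxin_precursor",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger(__name__)

#: case-insensitive substrings searched in panel description lines, mirroring
#: the classical list of venom protein families
TOXIN_KEYWORDS = (
    "three-finger",
    "three finger",
    "3ftx",
    "kunitz",
    "avit",
    "waprin",
    "crisp",
    "cysteine-rich secretory",
    "lectin",
    "pla2",
    "phospholipase",
    "svmp",
    "metalloprotease",
    "disintegrin",
    "kallikrein",
    "serine protease",
    "lipocalin",
    "sarafotoxin",
    "crotamine",
    "cystatin",
    "natriuretic",
    "nerve growth factor",
    "choline esterase",
    "calglandulin",
    "l-amino acid oxidase",
    "hyaluronidase",
    "defensin",
    "vespryn",
    "veficolin",
)


@dataclass
class AnnotationRecord:
    """Per-transcript verdict with its evidence trail."""

    transcript_id: str
    verdict: str                      # known_toxin | novel_candidate | non_toxin | excluded
    family: str | None = None
    evidence: dict = field(default_factory=dict)
    exclusion_reason: str | None = None   # truncated | ambiguous_positions | no_signal_peptide
    warnings: list[str] = field(default_factory=list)


@dataclass
class AbundanceTable:
    """Read counts, fractions and dense ranks per transcript."""

    df: pd.DataFrame     # columns: transcript_id, count, fraction, rank
    mode: str = "non_normalized"

    def rank(self, transcript_id: str) -> int:
        return int(self.df.set_index("transcript_id").loc[transcript_id, "rank"])

    def fraction(self, transcript_id: str) -> float:
        return float(self.df.set_index("transcript_id").loc[transcript_id, "fraction"])


@dataclass
class SarafotoxinPrecursor:
    precursor_id: str
    cassette_intervals: list[tuple[int, int]]   # 0-based half-open on the protein
    mature_peptides: list[str]


@dataclass(frozen=True)
class CassetteMotif:
    """How mature sarafotoxins are excised from their precursor: a dibasic
    boundary, a fixed-length endothelin-like core pattern (cysteine spacing),
    and an optional C-terminal extension tripeptide."""

    boundary: str = "KR"
    core_pattern: str = r"C[A-Z]C[A-Z]{18}"   # 21-residue endothelin-like core
    extension: str = "DEP"


@dataclass(frozen=True)
class NovelParams:
    min_cys: int = 2
    top_rank: int = 57
    require_signal: bool = True
    evalue_max: float = 1e-5


def select_toxin_candidates(
    proteins,
    panel,
    keywords=TOXIN_KEYWORDS,
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-5,
    hits: list[SimilarityHit] | None = None,
) -> list[AnnotationRecord]:
    """Keyword + reciprocal-best-hit selection of known toxins.

    A protein whose best panel hit (E <= ``evalue_max``) carries a toxin
    keyword in its description line becomes a candidate; the candidate is
    confirmed as ``known_toxin`` only when it also forms a reciprocal best
    hit with the panel, in which case the family is taken from the panel
    metadata.  All other proteins are provisionally ``non_toxin``.
    """
    if not keywords:
        raise ValueError("the toxin keyword list must not be empty")
    proteins = as_entries(proteins)
    panel = as_entries(panel)
    scheme = scheme or ScoringScheme()
    if hits is None:
        hits = search_all_vs_all(proteins, panel, scheme, evalue_max)
    panel_by_id = {p.id: p for p in panel}
    top_hit: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.query not in top_hit:   # hits are per-query sorted best-first
            top_hit[h.query] = h
    rbh = dict(reciprocal_best_hits(proteins, panel, scheme))
    lowered = [k.lower() for k in keywords]

    records = []
    for p in proteins:
        ev: dict = {"keyword_hit": False, "rbh_confirmed": False}
        h = top_hit.get(p.id)
        family = None
        verdict = "non_toxin"
        if h is not None:
            subject = panel_by_id[h.subject]
            ev["top_hit"] = h.subject
            ev["top_evalue"] = h.evalue
            desc = subject.description.lower()
            if any(k in desc for k in lowered):
                ev["keyword_hit"] = True
                partner = rbh.get(p.id)
                if partner is not None:
                    ev["rbh_confirmed"] = True
                    ev["rbh_partner"] = partner
                    family = panel_by_id[partner].family or subject.family
                    verdict = "known_toxin"
                else:
                    logger.info(
                        "keyword hit for %s not reciprocally confirmed; "
                        "treated as false-positive guard", p.id,
                    )
        records.append(
            AnnotationRecord(transcript_id=p.id, verdict=verdict,
                             family=family, evidence=ev)
        )
    return records


def apply_stringency_filters(
    records: list[AnnotationRecord],
    proteins: dict[str, ProteinRecord],
    relaxed_families: frozenset[str] = frozenset({"SRTX", "sarafotoxin"}),
) -> list[AnnotationRecord]:
    """Exclude (i) truncated ORFs, (ii) sequences with ambiguous residues and
    (iii) sequences lacking a signal peptide from the confirmed-toxin set.

    Families named in ``relaxed_families`` (weakly expressed families for
    which full-length transcripts may be unobtainable) are retained with a
    warning instead of excluded.
    """
    for rec in records:
        if rec.verdict != "known_toxin":
            continue
        prot = proteins.get(rec.transcript_id)
        if prot is None:
            continue
        reason = None
        if prot.truncated:
            reason = "truncated"
        elif "X" in prot.aa_seq:
            reason = "ambiguous_positions"
        else:
            sig = prot.signal or predict_signal_peptide(prot.aa_seq)
            if not sig.accepted:
                reason = "no_signal_peptide"
        if reason is None:
            continue
        if rec.family in relaxed_families:
            rec.warnings.append(f"retained despite {reason} (relaxed family)")
            rec.evidence["relaxed"] = True
        else:
            rec.verdict = "excluded"
            rec.exclusion_reason = reason
    return records


def detect_novel_candidates(
    records: list[AnnotationRecord],
    proteins: dict[str, ProteinRecord],
    abundance: AbundanceTable,
    params: NovelParams | None = None,
    hits: list[SimilarityHit] | None = None,
) -> list[AnnotationRecord]:
    """Flag putative new toxin classes among the unannotated transcripts.

    A transcript becomes a ``novel_candidate`` when it has no panel hit at
    E <= ``evalue_max``, carries a predicted signal peptide, has at least
    ``min_cys`` mature cysteines (skipped when ``min_cys`` is 0) and ranks
    within the ``top_rank`` most abundant transcripts.
    """
    if abundance is None:
        raise ValueError("an abundance table is required for the novel screen")
    params = params or NovelParams()
    hit_queries = {h.query for h in (hits or []) if h.evalue <= params.evalue_max}
    ranked = abundance.df.set_index("transcript_id")

    flagged = []
    for rec in records:
        if rec.verdict != "non_toxin":
            continue
        prot = proteins.get(rec.transcript_id)
        if prot is None:
            continue
        ev = rec.evidence
        ev["panel_hit"] = rec.transcript_id in hit_queries or ev.get("top_hit") is not None
        if ev["panel_hit"]:
            continue
        sig = prot.signal or predict_signal_peptide(prot.aa_seq)
        ev["signal_peptide"] = bool(sig.accepted)
        if params.require_signal and not sig.accepted:
            continue
        mature_start = sig.cleavage_site if sig.accepted else 0
        _, n_cys = cysteine_profile(prot.aa_seq, mature_start)
        ev["cys_count"] = n_cys
        if params.min_cys and n_cys < params.min_cys:
            continue
        if rec.transcript_id not in ranked.index:
            continue
        rank = int(ranked.loc[rec.transcript_id, "rank"])
        ev["abundance_rank"] = rank
        if rank > params.top_rank:
            continue
        rec.verdict = "novel_candidate"
        ev["mature_length"] = len(prot.aa_seq) - mature_start
        flagged.append(rec)
    return flagged


def rank_abundance(counts: dict[str, int], mode: str = "non_normalized") -> AbundanceTable:
    """Fractions and dense ranks from raw per-transcript read counts.

    Equal counts share a dense rank; display order is by descending count
    then transcript id.
    """
    if not counts or sum(counts.values()) == 0:
        raise ValueError("abundance ranking requires non-zero read counts")
    df = pd.DataFrame(
        {"transcript_id": list(counts), "count": list(counts.values())}
    ).sort_values(["count", "transcript_id"], ascending=[False, True], kind="mergesort")
    total = df["count"].sum()
    df["fraction"] = df["count"] / total
    df["rank"] = df["count"].rank(method="dense", ascending=False).astype(int)
    return AbundanceTable(df.reset_index(drop=True), mode=mode)


def cumulative_coverage(table: AbundanceTable, target_fraction: float) -> tuple[int, pd.DataFrame]:
    """Smallest k such that the k most abundant transcripts reach the target
    read fraction; also returns the full cumulative curve."""
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    df = table.df.copy()
    df["cumulative"] = df["fraction"].cumsum()
    k = int(np.searchsorted(df["cumulative"].to_numpy(), target_fraction - 1e-12) + 1)
    k = min(k, len(df))
    return k, df[["transcript_id", "fraction", "cumulative"]]


def parse_sarafotoxin_precursor(
    protein,
    motif: CassetteMotif | None = None,
) -> SarafotoxinPrecursor:
    """Excise tandem mature peptides from a polycistronic precursor.

    Each cassette is located at a dibasic boundary followed by the
    endothelin-like core pattern; when the core is immediately followed by
    the extension tripeptide, the long-form mature peptide includes it
    (21-residue core + "DEP" = 24 residues).
    """
    motif = motif or CassetteMotif()
    if isinstance(protein, ProteinRecord):
        pid, seq = protein.id, protein.aa_seq
    elif isinstance(protein, SeqEntry):
        pid, seq = protein.id, protein.seq
    else:
        pid, seq = protein
    pattern = re.compile(
        re.escape(motif.boundary)
        + "(" + motif.core_pattern + "(?:" + re.escape(motif.extension) + ")?)"
    )
    intervals, matures = [], []
    for m in pattern.finditer(seq.upper()):
        intervals.append((m.start(1), m.end(1)))
        matures.append(m.group(1))
    if not matures:
        warnings.warn(f"no sarafotoxin cassette found in {pid}")
    return SarafotoxinPrecursor(pid, intervals, matures)


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    contigs: list[Contig]
    singletons: list[str]
    proteins: dict[str, ProteinRecord]       # per-contig representative ORF
    records: list[AnnotationRecord]
    abundance: AbundanceTable
    hits: list[SimilarityHit]


def _representative_orf(contig: Contig, min_len: int) -> ProteinRecord | None:
    """Longest complete ORF of the contig (fallback: longest partial)."""
    orfs = find_orfs(contig.consensus, min_len=min_len,
                     include_partial=True, source_id=contig.id)
    complete = [o for o in orfs if not o.truncated]
    pool = complete or orfs
    return pool[0] if pool else None


def run_pipeline(
    reads: list[Read],
    panel,
    assembly_params: AssemblyParams | None = None,
    scheme: ScoringScheme | None = None,
    novel_params: NovelParams | None = None,
    min_orf_len: int = 60,
    keywords=TOXIN_KEYWORDS,
    relaxed_families: frozenset[str] = frozenset({"SRTX", "sarafotoxin"}),
    signal_params: SignalParams | None = None,
) -> PipelineResult:
    """Assemble reads, pick a representative ORF per contig, annotate.

    Every contig receives exactly one verdict; contigs without an ORF of at
    least ``min_orf_len`` residues are reported as non-toxins with an
    ``no_orf`` evidence flag.
    """
    contigs, singletons = assemble(reads, assembly_params)
    proteins: dict[str, ProteinRecord] = {}
    for c in contigs:
        orf = _representative_orf(c, min_orf_len)
        if orf is not None:
            orf.signal = predict_signal_peptide(orf.aa_seq, signal_params)
            mature_start = orf.signal.cleavage_site if orf.signal.accepted else 0
            orf.cys_positions = cysteine_profile(orf.aa_seq, mature_start)[0]
            proteins[c.id] = orf

    counts = {c.id: c.read_count for c in contigs}
    abundance = rank_abundance(counts)

    entries = [SeqEntry(id=cid, seq=p.aa_seq) for cid, p in proteins.items()]
    scheme = scheme or ScoringScheme()
    novel_params = novel_params or NovelParams()
    hits = search_all_vs_all(entries, panel, scheme, novel_params.evalue_max)
    records = select_toxin_candidates(entries, panel, keywords, scheme,
                                      novel_params.evalue_max, hits=hits)
    records = apply_stringency_filters(records, proteins, relaxed_families)
    detect_novel_candidates(records, proteins, abundance, novel_params, hits=hits)

    annotated = {r.transcript_id for r in records}
    for c in contigs:
        if c.id not in annotated:
            records.append(
                AnnotationRecord(transcript_id=c.id, verdict="non_toxin",
                                 evidence={"no_orf": True})
            )
    records.sort(key=lambda r: r.transcript_id)
    return PipelineResult(contigs, singletons, proteins, records, abundance, hits)


def annotation_report(result: PipelineResult) -> pd.DataFrame:
    """Flat TSV-ready report: one row per transcript."""
    ranked = result.abundance.df.set_index("transcript_id")
    rows = []
    for r in result.records:
        rank = ranked.loc[r.transcript_id, "rank"] if r.transcript_id in ranked.index else None
        frac = ranked.loc[r.transcript_id, "fraction"] if r.transcript_id in ranked.index else None
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "verdict": r.verdict,
                "family": r.family or "",
                "keyword_hit": bool(r.evidence.get("keyword_hit")),
                "rbh_confirmed": bool(r.evidence.get("rbh_confirmed")),
                "signal_peptide": bool(r.evidence.get("signal_peptide")),
                "exclusion_reason": r.exclusion_reason or "",
                "rank": rank,
                "fraction": frac,
            }
        )
    return pd.DataFrame(rows)
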