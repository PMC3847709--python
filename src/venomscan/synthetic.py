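"""Synthetic venom-gland transcriptome generator.

Builds a template library that mimics the statistical shape of a snake
venom-gland cDNA experiment: a handful of secreted toxin families planted on
top of a large housekeeping background, with a heavy-tailed abundance law in
which the 57 highest-weight transcripts carry more than half of the reads.

Planted families
----------------
* ``3FTx`` -- 13 three-finger toxin isoforms with the plesiotypic ten-cysteine
  mature scaffold, engineered into four similarity clusters plus one outlier.
* ``SRTX`` -- 2 polycistronic sarafotoxin precursors carrying tandem
  mature-peptide cassettes (21-residue endothelin-like core + ``DEP``
  C-terminal extension, i.e. 24-residue long-form sarafotoxins).
* ``lipocalin`` / ``CRISP`` -- additional secreted toxin families.
* ``novel_secreted`` -- 10 isoforms of an unannotated secreted protein with a
  173-residue mature region containing two conserved cysteines.
* ``housekeeping`` / ``TE_like`` -- non-secreted background transcripts.
* ``other`` -- one highly transcribed *non-secreted* orphan used as a
  negative control for the novel-toxin screen.

Every secreted template starts with a generated signal peptide that the
rule-based predictor in :mod:`venomscan.orfs` accepts (generator/detector
consistency is asserted at generation time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .orfs import predict_signal_peptide

__all__ = [
    "FAMILIES",
    "GeneratorConfig",
    "LibrarySpec",
    "Read",
    "TranscriptTemplate",
    "TruthTable",
    "SeqEntry",
    "SRTX_CORE",
    "generate_transcriptome",
    "simulate_reads",
    "build_reference_panel",
    "gini",
    "revcomp",
    "write_templates_fasta",
    "write_reads_fastq",
    "write_truth_tsv",
    "write_panel_fasta",
    "read_panel_fasta",
]

FAMILIES = (
    "3FTx",
    "SRTX",
    "lipocalin",
    "CRISP",
    "housekeeping",
    "novel_secreted",
    "TE_like",
    "other",
)

TOXIN_FAMILIES = ("3FTx", "SRTX", "lipocalin", "CRISP")

# 21-residue endothelin-like sarafotoxin core (cysteines at 0, 2, 10, 14)
# followed in long isoforms by the "DEP" C-terminal extension.
SRTX_CORE = "CSCKDMTDKECLYFCHQDVIW"
SRTX_EXTENSION = "DEP"

# mature-region residue usage: hydrophilic-biased (no cysteine; cysteines are
# placed explicitly) so that shuffled mature regions do not mimic the
# hydrophobic h-region of a signal peptide.
_MATURE_AA = np.array(list("ARNDQEGHILKMFPSTWYV"))
_MATURE_W = np.array(
    [7, 6, 5, 6, 5, 7, 8, 3, 2, 3, 7, 1, 2, 5, 9, 7, 1, 4, 2], dtype=float
)
_MATURE_W /= _MATURE_W.sum()

_HYDROPHOBIC = np.array(list("LIVF"))
_SPACER_AA = np.array(list("GSNQTA"))  # SRTX propeptide spacers: no K/R/C/D/E/P

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOP_CODONS = sorted(_TABLE.stop_codons)

# ten-cysteine scaffold of the plesiotypic three-finger toxin mature chain
_CYS_3FTX = (2, 8, 13, 20, 26, 38, 43, 47, 53, 59)
_3FTX_MATURE_LEN = 62

_NOVEL_MATURE_LEN = 173
_NOVEL_CYS = (39, 119)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptTemplate:
    """A transcript with known coding structure and abundance weight."""

    id: str
    family: str
    cds: str                 # ATG..stop, length divisible by 3
    utr5: str
    utr3: str
    protein: str             # translation of the CDS without the stop
    mature_start: int        # 0-based first mature residue (0 if no signal)
    has_signal: bool
    cys_count_mature: int
    abundance_weight: float = 0.0

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def mature_seq(self) -> str:
        return self.protein[self.mature_start:]


@dataclass
class TruthTable:
    """Ground-truth labels for every template: family, abundance fraction and
    the verdict the annotation pipeline is expected to reach."""

    df: pd.DataFrame  # columns: template_id, family, fraction, expected_verdict

    def fraction(self, template_id: str) -> float:
        return float(self.df.set_index("template_id").loc[template_id, "fraction"])

    def by_family(self, family: str) -> list[str]:
        return self.df.loc[self.df["family"] == family, "template_id"].tolist()

    def expected(self, template_id: str) -> str:
        return str(self.df.set_index("template_id").loc[template_id, "expected_verdict"])


@dataclass(frozen=True)
class SeqEntry:
    """A named (protein) sequence with optional family metadata -- the
    currency of the reference panel and of the similarity searches."""

    id: str
    seq: str
    description: str = ""
    family: str | None = None


@dataclass(frozen=True)
class GeneratorConfig:
    """Family counts and abundance-law settings of the synthetic library."""

    n_3ftx: int = 13
    n_srtx: int = 2
    n_lipocalin: int = 3
    n_crisp: int = 1
    n_novel: int = 10
    n_housekeeping: int = 200
    n_te_like: int = 5
    n_orphan: int = 1
    srtx_cassettes: int = 3
    top_n: int = 57
    top_share: float = 0.55      # calibration target for the top-57 share
    ftx_mut_rate: float = 0.10   # within-cluster mature divergence
    novel_mut_rate: float = 0.04

    def validate(self) -> None:
        for name in (
            "n_3ftx", "n_srtx", "n_lipocalin", "n_crisp", "n_novel",
            "n_housekeeping", "n_te_like", "n_orphan",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"family count {name} must be >= 0")
        if not 0 < self.top_share < 1:
            raise ValueError("top_share must be in (0, 1)")


@dataclass(frozen=True)
class LibrarySpec:
    """Read-sampling settings.

    Mean read length defaults to 344 nt for normalized and 315 nt for
    non-normalized libraries (454-era averages); normalized sampling flattens
    the abundance law to ``w**gamma``.
    """

    mode: str = "non_normalized"
    n_reads: int = 100_000
    read_length_mean: int | None = None
    read_length_sd: float = 50.0
    error_rate: float = 0.005
    seed: int = 0
    gamma: float = 0.25          # normalization flattening exponent
    rc_fraction: float = 0.5     # reads sampled from the reverse strand

    def __post_init__(self):
        if self.mode not in ("normalized", "non_normalized"):
            raise ValueError(f"unknown library mode {self.mode!r}")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")

    @property
    def mean_length(self) -> int:
        if self.read_length_mean is not None:
            return self.read_length_mean
        return 344 if self.mode == "normalized" else 315


@dataclass
class Read:
    """A simulated read with provenance back to its source template."""

    id: str
    seq: str
    template_id: str
    strand: str = "+"
    start: int = 0


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------

def _random_mature(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_MATURE_AA, size=length, p=_MATURE_W))


def _with_cysteines(seq: str, positions: tuple[int, ...]) -> str:
    chars = list(seq)
    for p in positions:
        chars[p] = "C"
    return "".join(chars)


def _make_signal(rng: np.random.Generator) -> str:
    """A 20-residue signal peptide the heuristic predictor accepts with
    cleavage after residue 19: M + K/R + 14-residue hydrophobic core + NAPA
    ((-3,-1) small-residue rule satisfied by the alanines)."""
    core = "".join(rng.choice(_HYDROPHOBIC, size=14))
    return "M" + str(rng.choice(list("KR"))) + core + "NAPA"


def _mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    frozen: frozenset[int] = frozenset(),
) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if i in frozen or chars[i] == "C":
            continue
        if rng.random() < rate:
            chars[i] = str(rng.choice(_MATURE_AA, p=_MATURE_W))
    return "".join(chars)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [str(rng.choice(_CODONS[aa])) for aa in protein]
    codons.append(str(rng.choice(_STOP_CODONS)))
    return "".join(codons)


def _random_utr(rng: np.random.Generator, length: int, forbid_atg: bool = True) -> str:
    while True:
        utr = "".join(rng.choice(np.array(list("ACGT")), size=length))
        if not (forbid_atg and "ATG" in utr):
            return utr


def _finish_template(
    rng: np.random.Generator,
    tid: str,
    family: str,
    protein: str,
    mature_start: int,
    has_signal: bool,
) -> TranscriptTemplate:
    cds = _back_translate(rng, protein)
    mature = protein[mature_start:]
    return TranscriptTemplate(
        id=tid,
        family=family,
        cds=cds,
        utr5=_random_utr(rng, 30),
        utr3=_random_utr(rng, 40, forbid_atg=False),
        protein=protein,
        mature_start=mature_start,
        has_signal=has_signal,
        cys_count_mature=mature.count("C"),
    )


def _ftx_cluster_sizes(n: int) -> list[int]:
    """Partition n three-finger isoforms into 4 clusters + 1 outlier (the
    planted group structure); degenerates gracefully for small n."""
    if n <= 0:
        return []
    if n < 6:
        return [n]
    body = n - 1  # one outlier
    base, extra = divmod(body, 4)
    return [base + (1 if i < extra else 0) for i in range(4)] + [1]


# ---------------------------------------------------------------------------
# template generation
# ---------------------------------------------------------------------------

def _build_templates(rng: np.random.Generator, cfg: GeneratorConfig) -> list[TranscriptTemplate]:
    templates: list[TranscriptTemplate] = []

    # three-finger toxins: clustered isoforms sharing the ten-cysteine scaffold
    clusters = _ftx_cluster_sizes(cfg.n_3ftx)
    iso = 0
    for ci, size in enumerate(clusters):
        signal = _make_signal(rng)
        ancestor = _with_cysteines(_random_mature(rng, _3FTX_MATURE_LEN), _CYS_3FTX)
        for _ in range(size):
            iso += 1
            mature = _with_cysteines(
                _mutate(rng, ancestor, cfg.ftx_mut_rate), _CYS_3FTX
            )
            templates.append(
                _finish_template(
                    rng, f"3FTX_{iso:02d}", "3FTx", signal + mature, len(signal), True
                )
            )

    # sarafotoxin precursors: signal + tandem (spacer-KR-core-DEP) cassettes
    for i in range(cfg.n_srtx):
        signal = _make_signal(rng)
        cassettes = []
        for _ in range(max(2, cfg.srtx_cassettes)):
            spacer = "".join(rng.choice(_SPACER_AA, size=8))
            cassettes.append(spacer + "KR" + SRTX_CORE + SRTX_EXTENSION)
        protein = signal + "".join(cassettes)
        templates.append(
            _finish_template(rng, f"SRTX_{i + 1:02d}", "SRTX", protein, len(signal), True)
        )

    # lipocalins
    if cfg.n_lipocalin:
        signal = _make_signal(rng)
        ancestor = _with_cysteines(_random_mature(rng, 150), (30, 60, 100, 140))
        for i in range(cfg.n_lipocalin):
            mature = _with_cysteines(_mutate(rng, ancestor, 0.12), (30, 60, 100, 140))
            templates.append(
                _finish_template(
                    rng, f"LIPO_{i + 1:02d}", "lipocalin", signal + mature, len(signal), True
                )
            )

    # CRISPs
    crisp_cys = tuple(range(10, 200, 12))[:16]
    for i in range(cfg.n_crisp):
        signal = _make_signal(rng)
        mature = _with_cysteines(_random_mature(rng, 200), crisp_cys)
        templates.append(
            _finish_template(
                rng, f"CRISP_{i + 1:02d}", "CRISP", signal + mature, len(signal), True
            )
        )

    # novel secreted protein: 173-aa mature, two conserved cysteines
    if cfg.n_novel:
        signal = _make_signal(rng)
        ancestor = _with_cysteines(_random_mature(rng, _NOVEL_MATURE_LEN), _NOVEL_CYS)
        for i in range(cfg.n_novel):
            mature = _with_cysteines(
                _mutate(rng, ancestor, cfg.novel_mut_rate), _NOVEL_CYS
            )
            templates.append(
                _finish_template(
                    rng, f"NOVEL_{i + 1:02d}", "novel_secreted",
                    signal + mature, len(signal), True,
                )
            )

    # non-secreted, highly transcribed orphan control (family "other")
    for i in range(cfg.n_orphan):
        protein = "M" + _with_cysteines(_random_mature(rng, 180), (20, 90, 150))
        templates.append(
            _finish_template(rng, f"ORPHAN_{i + 1:02d}", "other", protein, 0, False)
        )

    # transposable-element-like background
    for i in range(cfg.n_te_like):
        protein = "M" + _random_mature(rng, int(rng.integers(200, 400)))
        templates.append(
            _finish_template(rng, f"TE_{i + 1:02d}", "TE_like", protein, 0, False)
        )

    # housekeeping background
    for i in range(cfg.n_housekeeping):
        protein = "M" + _random_mature(rng, int(rng.integers(120, 450)))
        templates.append(
            _finish_template(rng, f"HK_{i + 1:03d}", "housekeeping", protein, 0, False)
        )

    return templates


def _fit_power_exponent(n_templates: int, top_n: int, top_share: float) -> float:
    """Smallest rank-frequency exponent whose top-``top_n`` weight share
    reaches ``top_share`` (bisection on the monotone share curve)."""
    ranks = np.arange(1, n_templates + 1, dtype=float)
    top_n = min(top_n, n_templates)

    def share(a: float) -> float:
        w = ranks ** -a
        return float(w[:top_n].sum() / w.sum())

    lo, hi = 0.0, 6.0
    if share(hi) < top_share:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if share(mid) >= top_share:
            hi = mid
        else:
            lo = mid
    return hi


def _rank_templates(
    rng: np.random.Generator, templates: list[TranscriptTemplate], cfg: GeneratorConfig
) -> list[TranscriptTemplate]:
    """Order templates by planned abundance rank: the orphan and the novel
    isoforms at the very top (the paper-shaped scenario in which the most
    abundant transcript is unannotated), lipocalins next, toxin isoforms
    within the high-abundance band, sarafotoxins weakly expressed."""
    by_family: dict[str, list[TranscriptTemplate]] = {}
    for t in templates:
        by_family.setdefault(t.family, []).append(t)
    for fam in by_family:
        order = rng.permutation(len(by_family[fam]))
        by_family[fam] = [by_family[fam][i] for i in order]

    novel = by_family.get("novel_secreted", [])
    orphan = by_family.get("other", [])
    lipo = by_family.get("lipocalin", [])
    ftx = by_family.get("3FTx", [])
    crisp = by_family.get("CRISP", [])
    te = by_family.get("TE_like", [])
    hk = by_family.get("housekeeping", [])
    srtx = by_family.get("SRTX", [])

    ordered: list[TranscriptTemplate] = []
    ordered += novel[:1]
    ordered += orphan[:1]
    ordered += lipo
    # interleave the remaining planted families into the high-abundance band
    band: list[TranscriptTemplate] = []
    pools = [novel[1:], ftx, crisp + te + orphan[1:]]
    while any(pools):
        for pool in pools:
            if pool:
                band.append(pool.pop(0))
    ordered += band
    # housekeeping fills the tail; sarafotoxins planted at low ranks
    tail = list(hk)
    for k, t in enumerate(srtx):
        tail.insert(min(len(tail), 60 + 20 * k), t)
    ordered += tail
    assert len(ordered) == len(templates)
    return ordered


def generate_transcriptome(
    config: GeneratorConfig | None = None, seed: int = 1
) -> tuple[list[TranscriptTemplate], TruthTable]:
    """Generate the template library and its ground-truth table.

    Deterministic for a fixed seed.  Abundance weights follow a discrete
    truncated power law over the planned rank order, with the exponent fitted
    so the expected share of the ``top_n`` highest-weight templates reaches
    ``top_share`` (default 0.55, comfortably above one-half).
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    templates = _build_templates(rng, cfg)
    if not templates:
        raise ValueError("configuration produced no templates")
    templates = _rank_templates(rng, templates, cfg)

    a = _fit_power_exponent(len(templates), cfg.top_n, cfg.top_share)
    weights = np.arange(1, len(templates) + 1, dtype=float) ** -a
    fractions = weights / weights.sum()
    for t, w, f in zip(templates, weights, fractions):
        t.abundance_weight = float(w)

    expected = {
        "3FTx": "known_toxin",
        "SRTX": "known_toxin",
        "lipocalin": "known_toxin",
        "CRISP": "known_toxin",
        "novel_secreted": "novel_candidate",
    }
    truth = TruthTable(
        pd.DataFrame(
            {
                "template_id": [t.id for t in templates],
                "family": [t.family for t in templates],
                "fraction": fractions,
                "expected_verdict": [
                    expected.get(t.family, "non_toxin") for t in templates
                ],
            }
        )
    )

    # generator/detector consistency: every planted secreted template must be
    # accepted by the package's own signal-peptide heuristic
    for t in templates:
        if t.has_signal:
            call = predict_signal_peptide(t.protein)
            if not (call.accepted and call.cleavage_site == t.mature_start):
                raise AssertionError(
                    f"generated signal peptide of {t.id} not recovered by the predictor"
                )
    return templates, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    templates: list[TranscriptTemplate],
    truth: TruthTable,
    spec: LibrarySpec,
) -> list[Read]:
    """Sample reads from templates proportionally to abundance weight
    (``non_normalized``) or to ``weight**gamma`` (``normalized``).

    Read start positions are uniform over the transcript; lengths are normal,
    truncated to [50, transcript length]; substitution errors are applied at
    ``spec.error_rate``; each read records its source template.
    """
    if spec.n_reads == 0:
        warnings.warn("n_reads=0: returning an empty library")
        return []
    if spec.n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(spec.seed)
    w = np.array([t.abundance_weight for t in templates], dtype=float)
    if spec.mode == "normalized":
        w = w ** spec.gamma
    probs = w / w.sum()
    counts = rng.multinomial(spec.n_reads, probs)

    bases = np.array(list("ACGT"))
    reads: list[Read] = []
    ridx = 0
    for t, n in zip(templates, counts):
        if n == 0:
            continue
        seq = t.sequence
        L = len(seq)
        lengths = rng.normal(spec.mean_length, spec.read_length_sd, size=n)
        lengths = np.clip(np.rint(lengths), 50, L).astype(int)
        starts = rng.integers(0, L - lengths + 1)
        rc = rng.random(n) < spec.rc_fraction
        n_err = rng.binomial(lengths, spec.error_rate)
        for i in range(n):
            ridx += 1
            rl, st = int(lengths[i]), int(starts[i])
            rseq = seq[st: st + rl]
            if n_err[i]:
                chars = list(rseq)
                for pos in rng.choice(rl, size=n_err[i], replace=False):
                    old = chars[pos]
                    choices = [b for b in "ACGT" if b != old]
                    chars[pos] = choices[int(rng.integers(3))]
                rseq = "".join(chars)
            strand = "-" if rc[i] else "+"
            if strand == "-":
                rseq = revcomp(rseq)
            reads.append(Read(f"r{ridx:06d}", rseq, t.id, strand, st))
    return reads


# ---------------------------------------------------------------------------
# reference panel (curated-toxin-database stand-in)
# ---------------------------------------------------------------------------

_FAMILY_KEYWORD = {
    "3FTx": "three-finger toxin (3FTx)",
    "SRTX": "sarafotoxin precursor",
    "lipocalin": "lipocalin venom protein",
    "CRISP": "cysteine-rich secretory protein (CRISP)",
}

_DECOY_FAMILIES = (
    ("kunitz", "kunitz-type protease inhibitor"),
    ("PLA2", "phospholipase A2 (PLA2)"),
    ("waprin", "waprin venom protein"),
    ("lectin", "C-type lectin"),
    ("SVMP", "snake venom metalloprotease (SVMP)"),
    ("kallikrein", "kallikrein serine protease"),
    ("AVIT", "AVIT venom protein"),
    ("crotamine", "crotamine myotoxin"),
    ("cystatin", "cystatin venom protein"),
    ("natriuretic", "natriuretic peptide"),
)


def build_reference_panel(
    templates: list[TranscriptTemplate],
    seed: int = 101,
    divergence: float = 0.18,
    n_decoys: int = 10,
) -> list[SeqEntry]:
    """Derive a curated-toxin reference panel from the planted toxin
    templates: one moderately diverged homolog per toxin isoform (cysteines
    conserved) plus decoy entries from unrelated toxin families.  Header
    descriptions carry the family keyword used by the annotation pipeline.
    """
    rng = np.random.default_rng(seed)
    panel: list[SeqEntry] = []
    for t in templates:
        if t.family not in TOXIN_FAMILIES:
            continue
        homolog = _mutate(rng, t.protein, divergence)
        pid = f"TOXDB_{t.id}"
        panel.append(
            SeqEntry(
                id=pid,
                seq=homolog,
                description=f"{_FAMILY_KEYWORD[t.family]}, snake venom homolog",
                family=t.family,
            )
        )
    for i in range(n_decoys):
        fam, phrase = _DECOY_FAMILIES[i % len(_DECOY_FAMILIES)]
        length = int(rng.integers(80, 250))
        panel.append(
            SeqEntry(
                id=f"TOXDB_DECOY_{i + 1:02d}",
                seq="M" + _random_mature(rng, length),
                description=f"{phrase}, venom protein",
                family=fam,
            )
        )
    return panel


# ---------------------------------------------------------------------------
# utilities and I/O
# ---------------------------------------------------------------------------

def gini(counts) -> float:
    """Gini coefficient of a non-negative count vector (0 = perfectly even)."""
    x = np.sort(np.asarray(counts, dtype=float))
    if x.sum() == 0:
        return 0.0
    n = len(x)
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def write_templates_fasta(templates: list[TranscriptTemplate], path) -> None:
    with open(path, "w") as fh:
        for t in templates:
            fh.write(
                f">{t.id} family={t.family} has_signal={int(t.has_signal)} "
                f"cys_mature={t.cys_count_mature} weight={t.abundance_weight:.6g}\n"
            )
            seq = t.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


def write_reads_fastq(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id} template={r.template_id} strand={r.strand}\n")
            fh.write(r.seq + "\n+\n" + "I" * len(r.seq) + "\n")


def write_truth_tsv(truth: TruthTable, path) -> None:
    truth.df.to_csv(path, sep="\t", index=False)


def write_panel_fasta(panel: list[SeqEntry], path) -> None:
    with open(path, "w") as fh:
        for e in panel:
            fh.write(f">{e.id} family={e.family} {e.description}\n{e.seq}\n")


def read_panel_fasta(path) -> list[SeqEntry]:
    """Parse a panel FASTA whose headers carry ``family=`` tags."""
    entries: list[SeqEntry] = []
    with open(path) as fh:
        name = desc = None
        chunks: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    entries.append(_panel_entry(name, desc, "".join(chunks)))
                header = line[1:].split(None, 1)
                name = header[0]
                desc = header[1] if len(header) > 1 else ""
                chunks = []
            else:
                chunks.append(line.strip())
        if name is not None:
            entries.append(_panel_entry(name, desc, "".join(chunks)))
    return entries


def _panel_entry(name: str, desc: str, seq: str) -> SeqEntry:
    family = None
    for token in desc.split():
        if token.startswith("family="):
            family = token[len("family="):]
    return SeqEntry(id=name, seq=seq, description=desc, family=family)
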