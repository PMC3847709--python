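"""Greedy overlap-consensus assembly and read mapping."""

import numpy as np
import pytest

from venomscan.assembly import AssemblyParams, Contig, assemble, map_reads_to_contigs
from venomscan.synthetic import LibrarySpec, Read, revcomp, simulate_reads


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_two_reads_with_50nt_overlap_make_one_contig():
    rng = np.random.default_rng(0)
    base = _random_dna(rng, 350)
    contigs, singles = assemble([Read("a", base[:200], "t"), Read("b", base[150:], "t")])
    assert len(contigs) == 1 and not singles
    assert len(contigs[0].consensus) == 350
    assert contigs[0].consensus == base
    assert contigs[0].read_count == 2


def test_single_read_is_a_singleton():
    rng = np.random.default_rng(1)
    contigs, singles = assemble([Read("solo", _random_dna(rng, 80), "t")])
    assert contigs == [] and singles == ["solo"]


def test_39nt_overlap_below_minimum_keeps_reads_apart():
    """The 40-bp overlap floor is a strict boundary."""
    rng = np.random.default_rng(2)
    base = _random_dna(rng, 361)
    contigs, singles = assemble(
        [Read("a", base[:200], "t"), Read("b", base[161:], "t")]
    )
    assert contigs == [] and sorted(singles) == ["a", "b"]
    # one more base of overlap and they join
    base = _random_dna(rng, 360)
    contigs, singles = assemble(
        [Read("a", base[:200], "t"), Read("b", base[160:], "t")]
    )
    assert len(contigs) == 1 and len(contigs[0].consensus) == 360


def test_reverse_strand_reads_are_canonicalised():
    rng = np.random.default_rng(3)
    base = _random_dna(rng, 350)
    contigs, singles = assemble(
        [Read("a", base[:200], "t"), Read("b", revcomp(base[150:]), "t")]
    )
    assert len(contigs) == 1 and len(contigs[0].consensus) == 350


def test_identity_threshold_gate():
    rng = np.random.default_rng(4)
    base = _random_dna(rng, 350)
    # 3 clustered mismatches in a 50-nt overlap: 94% identity < 98%
    tail = list(base[150:])
    for pos in (36, 37, 38):
        tail[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tail[pos]]
    contigs, singles = assemble([Read("a", base[:200], "t"), Read("b", "".join(tail), "t")])
    assert contigs == [] and len(singles) == 2
    contigs, _ = assemble(
        [Read("a", base[:200], "t"), Read("b", "".join(tail), "t")],
        AssemblyParams(min_identity=0.9),
    )
    assert len(contigs) == 1


def test_non_nucleotide_read_is_an_input_error():
    with pytest.raises(ValueError, match="badread"):
        assemble([Read("badread", "ACGTQACGT" * 10, "t")])


def test_partition_invariant(small_reads):
    """Contig membership and singletons partition the read ids."""
    contigs, singles = assemble(small_reads[:3000])
    ids = [m for c in contigs for m in c.member_reads] + list(singles)
    assert sorted(ids) == sorted(r.id for r in small_reads[:3000])
    assert all(c.read_count >= 2 for c in contigs)


def test_idempotence_on_members():
    """Reassembling a contig's member reads reproduces a single contig."""
    rng = np.random.default_rng(5)
    base = _random_dna(rng, 600)
    reads = [Read(f"r{i}", base[s:s + 220], "t") for i, s in enumerate(range(0, 400, 80))]
    contigs, _ = assemble(reads)
    assert len(contigs) == 1
    again, singles = assemble(reads)
    assert len(again) == 1 and not singles
    assert again[0].consensus == contigs[0].consensus


def test_error_free_tiling_reconstructs_template(default_library):
    """At >= 15x error-free coverage the consensus equals the template."""
    templates, _ = default_library
    t = templates[0]
    seq = t.sequence
    L = len(seq)
    reads = []
    i = 0
    for rep in range(6):                      # staggered tiling, ends included
        for s in range(0, L - 150, 37):
            reads.append(Read(f"r{i:04d}", seq[s:s + 160], t.id)); i += 1
        reads.append(Read(f"r{i:04d}", seq[L - 160:], t.id)); i += 1
    contigs, singles = assemble(reads)
    assert len(contigs) == 1 and not singles
    assert contigs[0].consensus in (seq, revcomp(seq))


def test_majority_vote_corrects_substitution_errors(default_library):
    templates, truth = default_library
    t = templates[0]
    reads = simulate_reads(
        [t], _single_truth(truth, t.id),
        LibrarySpec(n_reads=120, error_rate=0.01, seed=21),
    )
    contigs, _ = assemble(reads)
    best = max(contigs, key=lambda c: c.read_count)
    cons = best.consensus if best.consensus in t.sequence else revcomp(best.consensus)
    assert cons in t.sequence
    assert len(cons) >= 0.9 * len(t.sequence)


def _single_truth(truth, tid):
    import pandas as pd

    from venomscan.synthetic import TruthTable
    row = truth.df[truth.df.template_id == tid].copy()
    row["fraction"] = 1.0
    return TruthTable(row.reset_index(drop=True))


class TestMapping:
    def test_all_reads_map_to_their_template_contig(self, default_library):
        templates, truth = default_library
        t = templates[0]
        reads = simulate_reads(
            [t], _single_truth(truth, t.id),
            LibrarySpec(n_reads=200, error_rate=0.0, seed=8),
        )
        contig = Contig(id="c1", consensus=t.sequence, member_reads=[])
        res = map_reads_to_contigs(reads, [contig])
        assert res.counts["c1"] == 200 and not res.unmapped

    def test_tie_between_duplicate_contigs_is_deterministic_and_flagged(self):
        rng = np.random.default_rng(9)
        seq = _random_dna(rng, 300)
        contigs = [
            Contig(id="c_b", consensus=seq, member_reads=[]),
            Contig(id="c_a", consensus=seq, member_reads=[]),
        ]
        reads = [Read("r1", seq[50:200], "t")]
        res = map_reads_to_contigs(reads, contigs)
        assert res.assignments["r1"] == "c_a"      # lexicographically smaller
        assert "r1" in res.ambiguous

    def test_counts_are_conserved(self, small_reads, default_library):
        templates, _ = default_library
        contigs = [
            Contig(id=t.id, consensus=t.sequence, member_reads=[])
            for t in templates[:50]
        ]
        reads = small_reads[:2000]
        res = map_reads_to_contigs(reads, contigs)
        assert sum(res.counts.values()) + len(res.unmapped) == len(reads)

    def test_empty_contig_set_warns(self, small_reads):
        with pytest.warns(UserWarning):
            res = map_reads_to_contigs(small_reads[:10], [])
        assert len(res.unmapped) == 10


def test_invalid_params():
    with pytest.raises(ValueError):
        AssemblyParams(min_overlap=0)
    with pytest.raises(ValueError):
        AssemblyParams(min_identity=1.5)
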