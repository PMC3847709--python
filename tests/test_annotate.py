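"""Annotation workflow: toxin selection, filters, novel screen, abundance,
sarafotoxin parsing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from venomscan.annotate import (
    AnnotationRecord,
    NovelParams,
    apply_stringency_filters,
    cumulative_coverage,
    detect_novel_candidates,
    parse_sarafotoxin_precursor,
    rank_abundance,
    select_toxin_candidates,
)
from venomscan.orfs import ProteinRecord, predict_signal_peptide
from venomscan.synthetic import SRTX_CORE, SeqEntry


def _protein(pid, aa, has_start=True, has_stop=True):
    rec = ProteinRecord(id=pid, source_id=pid, frame=1,
                        cds_interval=(0, 3 * (len(aa) + 1)), aa_seq=aa,
                        has_start=has_start, has_stop=has_stop)
    rec.signal = predict_signal_peptide(aa)
    return rec


class TestSelectToxinCandidates:
    def test_planted_toxin_confirmed_with_family(self, default_library, panel):
        templates, _ = default_library
        ftx = next(t for t in templates if t.family == "3FTx")
        records = select_toxin_candidates([SeqEntry(ftx.id, ftx.protein)], panel)
        assert records[0].verdict == "known_toxin"
        assert records[0].family == "3FTx"
        assert records[0].evidence["keyword_hit"]
        assert records[0].evidence["rbh_confirmed"]

    def test_housekeeping_protein_stays_non_toxin(self, default_library, panel):
        templates, _ = default_library
        hk = next(t for t in templates if t.family == "housekeeping")
        records = select_toxin_candidates([SeqEntry(hk.id, hk.protein)], panel)
        assert records[0].verdict == "non_toxin"
        assert not records[0].evidence["keyword_hit"]

    def test_keyword_hit_without_reciprocity_is_not_confirmed(self, default_library, panel):
        """Two queries share the same closest panel entry; only the
        reciprocal one is confirmed -- the false-positive guard."""
        templates, _ = default_library
        ftx = next(t for t in templates if t.family == "3FTx")
        decoy_id = "nearcopy"
        mutated = list(ftx.protein)
        for i in np.random.default_rng(3).choice(len(mutated), size=6, replace=False):
            mutated[i] = "Q"
        queries = [SeqEntry(ftx.id, ftx.protein), SeqEntry(decoy_id, "".join(mutated))]
        records = {r.transcript_id: r for r in select_toxin_candidates(queries, panel)}
        assert records[ftx.id].verdict == "known_toxin"
        assert records[decoy_id].evidence["keyword_hit"]
        assert not records[decoy_id].evidence["rbh_confirmed"]
        assert records[decoy_id].verdict == "non_toxin"

    def test_empty_keyword_list_is_config_error(self, panel):
        with pytest.raises(ValueError):
            select_toxin_candidates([("q", "MKL" * 30)], panel, keywords=())


class TestStringencyFilters:
    def _toxin_record(self, pid, family="3FTx"):
        return AnnotationRecord(transcript_id=pid, verdict="known_toxin", family=family)

    def test_ambiguous_positions_excluded(self, default_library):
        templates, _ = default_library
        ftx = next(t for t in templates if t.family == "3FTx")
        aa = ftx.protein[:40] + "X" + ftx.protein[41:]
        rec = self._toxin_record("p1")
        apply_stringency_filters([rec], {"p1": _protein("p1", aa)})
        assert rec.verdict == "excluded"
        assert rec.exclusion_reason == "ambiguous_positions"

    def test_full_length_signal_positive_toxin_retained(self, default_library):
        templates, _ = default_library
        ftx = next(t for t in templates if t.family == "3FTx")
        rec = self._toxin_record("p1")
        apply_stringency_filters([rec], {"p1": _protein("p1", ftx.protein)})
        assert rec.verdict == "known_toxin"

    def test_truncated_orf_excluded(self, default_library):
        templates, _ = default_library
        ftx = next(t for t in templates if t.family == "3FTx")
        rec = self._toxin_record("p1")
        apply_stringency_filters(
            [rec], {"p1": _protein("p1", ftx.protein, has_stop=False)}
        )
        assert rec.verdict == "excluded" and rec.exclusion_reason == "truncated"

    def test_relaxed_family_retained_with_warning(self, default_library):
        """Weakly expressed sarafotoxins keep their call despite truncation."""
        templates, _ = default_library
        srtx = next(t for t in templates if t.family == "SRTX")
        rec = self._toxin_record("p1", family="SRTX")
        apply_stringency_filters(
            [rec], {"p1": _protein("p1", srtx.protein, has_stop=False)},
            relaxed_families=frozenset({"SRTX"}),
        )
        assert rec.verdict == "known_toxin"
        assert rec.warnings and "truncated" in rec.warnings[0]

    def test_no_signal_peptide_excluded(self):
        rec = self._toxin_record("p1")
        aa = "M" + "QDERTKNDSG" * 12
        apply_stringency_filters([rec], {"p1": _protein("p1", aa)})
        assert rec.verdict == "excluded"
        assert rec.exclusion_reason == "no_signal_peptide"


class TestDetectNovel:
    def _abundance(self, ids):
        return rank_abundance({i: 100 - 10 * k for k, i in enumerate(ids)})

    def test_planted_novel_secreted_is_flagged(self, default_library):
        templates, _ = default_library
        novel = next(t for t in templates if t.family == "novel_secreted")
        rec = AnnotationRecord(transcript_id="n1", verdict="non_toxin")
        proteins = {"n1": _protein("n1", novel.protein)}
        flagged = detect_novel_candidates(
            [rec], proteins, self._abundance(["n1"]), NovelParams(), hits=[]
        )
        assert flagged == [rec] and rec.verdict == "novel_candidate"
        assert rec.evidence["mature_length"] == 173
        assert rec.evidence["cys_count"] == 2

    def test_panel_matching_protein_not_novel(self, default_library, panel):
        from venomscan.similarity import search_all_vs_all

        templates, _ = default_library
        ftx = next(t for t in templates if t.family == "3FTx")
        hits = search_all_vs_all([SeqEntry("t1", ftx.protein)], panel)
        rec = AnnotationRecord(transcript_id="t1", verdict="non_toxin")
        detect_novel_candidates(
            [rec], {"t1": _protein("t1", ftx.protein)},
            self._abundance(["t1"]), hits=hits,
        )
        assert rec.verdict == "non_toxin"

    def test_signal_negative_orphan_rejected(self, default_library):
        """The generator's non-secreted orphan control sits at rank 2 but has
        no signal peptide, so it must not be called novel."""
        templates, _ = default_library
        orphan = next(t for t in templates if t.family == "other")
        rec = AnnotationRecord(transcript_id="o1", verdict="non_toxin")
        detect_novel_candidates(
            [rec], {"o1": _protein("o1", orphan.protein)},
            self._abundance(["top", "o1"]), hits=[],
        )
        assert rec.verdict == "non_toxin"
        assert rec.evidence["signal_peptide"] is False

    def test_rank_gate(self, default_library):
        templates, _ = default_library
        novel = next(t for t in templates if t.family == "novel_secreted")
        rec = AnnotationRecord(transcript_id="n1", verdict="non_toxin")
        detect_novel_candidates(
            [rec], {"n1": _protein("n1", novel.protein)},
            self._abundance(["n1"]), NovelParams(top_rank=0), hits=[],
        )
        assert rec.verdict == "non_toxin"

    def test_missing_abundance_table_is_an_error(self):
        with pytest.raises(ValueError):
            detect_novel_candidates([], {}, None)


class TestAbundance:
    def test_fractions_and_dense_ranks(self):
        table = rank_abundance({"a": 50, "b": 30, "c": 20})
        df = table.df.set_index("transcript_id")
        assert df.loc["a", "fraction"] == 0.5
        assert df.loc["b", "fraction"] == 0.3
        assert list(df["rank"]) == [1, 2, 3]

    def test_ties_share_dense_rank_in_id_order(self):
        df = rank_abundance({"b": 10, "a": 10, "c": 5}).df
        assert list(df["transcript_id"]) == ["a", "b", "c"]
        assert list(df["rank"]) == [1, 1, 2]

    @given(st.dictionaries(
        st.text(alphabet="abcdefgh", min_size=1, max_size=4),
        st.integers(min_value=0, max_value=1000), min_size=1, max_size=30,
    ))
    def test_fractions_sum_to_one(self, counts):
        if sum(counts.values()) == 0:
            counts[next(iter(counts))] = 1
        table = rank_abundance(counts)
        assert table.df["fraction"].sum() == pytest.approx(1.0)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            rank_abundance({"a": 0})


class TestCumulativeCoverage:
    def test_uniform_table(self):
        table = rank_abundance({f"t{i}": 10 for i in range(10)})
        k, _ = cumulative_coverage(table, 0.8)
        assert k == 8

    def test_skewed_table(self):
        k, _ = cumulative_coverage(rank_abundance({"a": 60, "b": 30, "c": 10}), 0.8)
        assert k == 2

    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=40),
           st.floats(min_value=0.05, max_value=1.0))
    def test_inverse_of_cumulative_curve(self, counts, target):
        table = rank_abundance({f"t{i:02d}": c for i, c in enumerate(counts)})
        k, curve = cumulative_coverage(table, target)
        fr = table.df["fraction"].to_numpy()
        assert fr[:k].sum() >= target - 1e-9
        if k > 1:
            assert fr[:k - 1].sum() < target

    def test_invalid_target(self):
        table = rank_abundance({"a": 1})
        with pytest.raises(ValueError):
            cumulative_coverage(table, 0.0)


class TestSarafotoxinParsing:
    def test_generator_precursor_yields_three_24mers(self, default_library):
        """Long-form sarafotoxins: 21-residue endothelin-like core + DEP."""
        templates, _ = default_library
        srtx = next(t for t in templates if t.family == "SRTX")
        parsed = parse_sarafotoxin_precursor((srtx.id, srtx.protein))
        assert len(parsed.mature_peptides) == 3
        assert all(len(m) == 24 for m in parsed.mature_peptides)
        assert all(m.endswith("DEP") for m in parsed.mature_peptides)
        for (start, end), pep in zip(parsed.cassette_intervals, parsed.mature_peptides):
            assert srtx.protein[start:end] == pep

    def test_short_cassette_without_extension_is_21mer(self):
        protein = "MGSSTQNA" + "KR" + SRTX_CORE + "GGSSNQ"
        parsed = parse_sarafotoxin_precursor(("short", protein))
        assert parsed.mature_peptides == [SRTX_CORE]
        assert len(parsed.mature_peptides[0]) == 21

    def test_no_cassette_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            parsed = parse_sarafotoxin_precursor(("none", "MKLVNQESTG" * 6))
        assert parsed.mature_peptides == []

    def test_mature_lengths_within_sarafotoxin_range(self, default_library):
        templates, _ = default_library
        for t in templates:
            if t.family == "SRTX":
                parsed = parse_sarafotoxin_precursor((t.id, t.protein))
                assert all(21 <= len(m) <= 25 for m in parsed.mature_peptides)
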