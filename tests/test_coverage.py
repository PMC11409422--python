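"""Coverage evaluation: matching semantics, per-taxon reports, comparisons."""

import numpy as np
import pytest

from primerdegen import (
    AnnotatedSequence,
    PrimerRecord,
    ReferenceDatabase,
    UnknownTaxonError,
    compare_coverage,
    coverage,
    expand,
    reverse_complement,
    sequence_matched,
)
from primerdegen.coverage import round_percent

from conftest import FWD_515, REV_806, REV_806_M1


def _seq(identifier, taxonomy, sense):
    return AnnotatedSequence(identifier, taxonomy, sense)


def _brute_force_matched(primer: PrimerRecord, seq: AnnotatedSequence) -> bool:
    """0-allowance oracle: some expansion of the primer is an exact
    substring of the oriented template."""
    template = (
        reverse_complement(seq.sequence)
        if primer.orientation == "reverse"
        else seq.sequence
    )
    return any(p in template for p in expand(primer.sequence))


class TestSequenceMatched:
    def test_degenerate_forward_site_matches(self):
        fwd = PrimerRecord("515F", "forward", FWD_515)
        seq = _seq("a", (), "TT" + "GTGCCAGCAGCCGCGGTAA" + "AA")
        assert sequence_matched(fwd, seq)
        assert _brute_force_matched(fwd, seq)

    def test_one_mismatch_site_unmatched_at_zero(self):
        rev = PrimerRecord("806R", "reverse", REV_806)
        sense = "CC" + reverse_complement("GGACTACCAGAGTATCTAAT") + "GG"
        seq = _seq("dhc", (), sense)
        assert not sequence_matched(rev, seq, max_mismatches=0)
        assert not _brute_force_matched(rev, seq)
        assert sequence_matched(rev, seq, max_mismatches=1)

    def test_improved_primer_matches_same_template(self):
        rev = PrimerRecord("806R-M1", "reverse", REV_806_M1)
        sense = "CC" + reverse_complement("GGACTACCAGAGTATCTAAT") + "GG"
        seq = _seq("dhc", (), sense)
        match = sequence_matched(rev, seq)
        assert match and _brute_force_matched(rev, seq)
        assert match.reverse_start == 2

    def test_pair_requires_ordered_sites(self):
        fwd = PrimerRecord("F", "forward", "ACGTACGTAC")
        rev = PrimerRecord("R", "reverse", "TTTTTCCCCC")
        amplicon = "ACGTACGTAC" + "G" * 30 + reverse_complement("TTTTTCCCCC")
        ok = _seq("ok", (), "AA" + amplicon + "AA")
        match = sequence_matched((fwd, rev), ok)
        assert match
        assert match.forward_start == 2
        assert match.reverse_start == 2 + 10 + 30
        # reverse site upstream of forward site: no positive-length amplicon
        swapped = _seq(
            "swapped", (), "AA" + reverse_complement("TTTTTCCCCC") + "G" * 30 + "ACGTACGTAC"
        )
        assert not sequence_matched((fwd, rev), swapped)

    def test_sequence_shorter_than_primer_is_unmatched(self):
        fwd = PrimerRecord("F", "forward", "ACGTACGTAC")
        assert not sequence_matched(fwd, _seq("tiny", (), "ACG"))

    def test_oracle_equivalence_on_random_sequences(self):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGT"))
        rev = PrimerRecord("806R", "reverse", REV_806)
        hits = 0
        for i in range(60):
            sense = "".join(rng.choice(bases, size=120))
            if i % 2:  # plant an expansion of the primer half the time
                expansions = sorted(expand(REV_806))
                chosen = expansions[rng.integers(len(expansions))]
                pos = int(rng.integers(0, 120 - 20))
                sense = (
                    sense[:pos]
                    + reverse_complement(chosen)
                    + sense[pos + 20 :]
                )
            seq = _seq(f"r{i}", (), sense)
            got = bool(sequence_matched(rev, seq))
            assert got == _brute_force_matched(rev, seq)
            hits += got
        assert hits >= 30  # the planted half must all match


class TestReferenceDatabase:
    def test_duplicate_identifiers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ReferenceDatabase([_seq("a", (), "ACGT"), _seq("a", (), "ACGT")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ReferenceDatabase([])

    def test_select_by_label_and_path(self):
        db = ReferenceDatabase(
            [
                _seq("a", ("Bacteria", "Chloroflexi", "Dehalococcoides"), "ACGT"),
                _seq("b", ("Bacteria", "Proteobacteria"), "ACGT"),
                _seq("c", ("Archaea",), "ACGT"),
            ]
        )
        assert [s.identifier for s in db.select("Dehalococcoides")] == ["a"]
        assert [s.identifier for s in db.select("Bacteria")] == ["a", "b"]
        assert [s.identifier for s in db.select("Bacteria;Chloroflexi")] == ["a"]
        assert len(db.select(None)) == 3

    def test_unknown_taxon_suggests_near_misses(self):
        db = ReferenceDatabase([_seq("a", ("Bacteria", "Dehalococcoides"), "ACGT")])
        with pytest.raises(UnknownTaxonError) as err:
            db.select("Dehalococoides")
        assert "Dehalococcoides" in str(err.value)


class TestCoverageReport:
    @pytest.fixture()
    def db_35_of_38(self):
        """38 taxon-T sequences, 35 with an exact forward site."""
        fwd_site = "GTGCCAGCAGCCGCGGTAA"
        broken = "GTGACAGCAGCCGCGGTAA"  # Y covers C/T only: A at pos 4 misses
        records = [
            _seq(
                f"t{i}",
                ("Bacteria", "T"),
                "CA" * 10 + (fwd_site if i < 35 else broken) + "TG" * 10,
            )
            for i in range(38)
        ]
        return ReferenceDatabase(records)

    def test_percentages_match_hand_count(self, db_35_of_38):
        fwd = PrimerRecord("515F", "forward", FWD_515)
        report = coverage(fwd, db_35_of_38, taxa=["T"])
        (row,) = report.rows
        assert (row.taxon, row.matched, row.total, row.percent) == ("T", 35, 38, 92.1)
        assert report.overall.percent == 92.1
        assert report.mode == "single_primer"

    def test_primer_matching_nothing(self, db_35_of_38):
        fwd = PrimerRecord("none", "forward", "TTTTTTTTTTTTTTTTTTT")
        report = coverage(fwd, db_35_of_38, taxa=["T"])
        assert report.rows[0].percent == 0.0
        assert report.overall.matched == 0

    def test_conservation_and_rank_grouping(self, dehalo_fixture):
        _, db, _ = dehalo_fixture
        fwd = PrimerRecord("515F", "forward", FWD_515)
        rev = PrimerRecord("806R", "reverse", REV_806)
        report = coverage((fwd, rev), db, rank="domain")
        assert report.mode == "primer_pair"
        assert sum(r.total for r in report.rows) == len(db)
        for row in report.rows:
            assert 0 <= row.matched <= row.total
            assert row.percent == round_percent(row.matched, row.total)

    def test_pair_coverage_at_most_single(self, dehalo_fixture):
        _, db, _ = dehalo_fixture
        fwd = PrimerRecord("515F", "forward", FWD_515)
        rev = PrimerRecord("806R", "reverse", REV_806)
        pair = coverage((fwd, rev), db).overall.matched
        assert pair <= coverage(fwd, db).overall.matched
        assert pair <= coverage(rev, db).overall.matched

    def test_report_round_trips_to_tsv(self, tmp_path, db_35_of_38):
        import pandas as pd

        fwd = PrimerRecord("515F", "forward", FWD_515)
        report = coverage(fwd, db_35_of_38, taxa=["T"])
        out = tmp_path / "report.tsv"
        report.to_tsv(out)
        frame = pd.read_csv(out, sep="\t")
        assert list(frame.columns) == ["taxon", "matched", "total", "percent"]
        assert frame.iloc[0]["percent"] == 92.1


class TestCompareCoverage:
    def test_identical_pairs_all_deltas_zero(self, dehalo_fixture, pair_515_806):
        _, db, _ = dehalo_fixture
        frame = compare_coverage(pair_515_806, pair_515_806, db, rank="domain")
        assert (frame["delta"] == 0).all()

    def test_improved_pair_never_decreases(self, dehalo_fixture, pair_515_806):
        _, db, _ = dehalo_fixture
        fwd, rev = pair_515_806
        improved = (fwd, rev.with_sequence(REV_806_M1))
        frame = compare_coverage(
            pair_515_806, improved, db, rank="domain", taxa=["Dehalococcoides"]
        )
        assert (frame["delta"] >= 0).all()
        target = frame.set_index("taxon").loc["Dehalococcoides"]
        assert target["delta"] > 0
        # sorted by delta descending
        assert list(frame["delta"]) == sorted(frame["delta"], reverse=True)


def test_round_percent_half_up():
    assert round_percent(35, 38) == 92.1
    assert round_percent(1, 16) == 6.3  # 6.25 rounds half-up
    assert round_percent(0, 5) == 0.0
    assert round_percent(5, 5) == 100.0
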