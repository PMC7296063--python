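"""Parsing HMMER domtblout, ordering/deduplicating hits, and file I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domainca import arch_io
from domainca.arch_io import (
    Architecture,
    Corpus,
    DomainHit,
    ParseError,
    hits_to_architecture,
    parse_domtblout,
    read_architectures,
    write_architectures,
    write_frequency_csv,
)


def domtblout_line(
    domain="RhoGEF",
    protein="sp|Q1",
    i_evalue=1e-50,
    env_from=10,
    env_to=109,
    acc=0.95,
):
    """One well-formed hmmscan --domtblout data line (23 columns)."""
    return (
        f"{domain} PF00001.1 100 {protein} - 500 {i_evalue:.1e} 250.0 0.1 "
        f"1 2 {i_evalue:.1e} {i_evalue:.1e} 240.0 0.1 1 100 "
        f"{env_from} {env_to} {env_from} {env_to} {acc:.2f} test hit"
    )


def hit(domain="A", protein="p1", start=1, end=100, e=1e-50, acc=0.9):
    return DomainHit(
        protein_id=protein,
        domain_name=domain,
        env_start=start,
        env_end=end,
        e_value=e,
        acc=acc,
    )


class TestParseDomtblout:
    def test_comments_only_yields_empty(self, tmp_path):
        path = tmp_path / "empty.domtblout"
        path.write_text("# comment\n# another\n")
        assert parse_domtblout(path, 1e-37) == []

    def test_evalue_filter_keeps_hits_at_or_below_threshold(self, tmp_path):
        path = tmp_path / "hits.domtblout"
        path.write_text(
            "\n".join(
                [
                    "# header",
                    domtblout_line(domain="A", i_evalue=1e-50),
                    domtblout_line(domain="B", i_evalue=1e-10, env_from=150, env_to=249),
                    domtblout_line(domain="C", i_evalue=1e-40, env_from=300, env_to=399),
                ]
            )
            + "\n"
        )
        hits = parse_domtblout(path, max_evalue=1e-37)
        assert [h.domain_name for h in hits] == ["A", "C"]
        assert all(h.e_value <= 1e-37 for h in hits)

    def test_default_threshold_matches_explicit_1e37(self, tmp_path):
        path = tmp_path / "hits.domtblout"
        path.write_text(
            domtblout_line(i_evalue=1e-38) + "\n" + domtblout_line(i_evalue=1e-36) + "\n"
        )
        assert parse_domtblout(path) == parse_domtblout(path, max_evalue=1e-37)
        assert len(parse_domtblout(path)) == 1

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "bad.domtblout"
        path.write_text("# ok\nA B C D\n")
        with pytest.raises(ParseError, match="line 2"):
            parse_domtblout(path, 1e-37)

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        bad = domtblout_line().split()
        bad[19] = "ten"
        path = tmp_path / "bad.domtblout"
        path.write_text(" ".join(bad) + "\n")
        with pytest.raises(ParseError, match="line 1"):
            parse_domtblout(path, 1e-37)

    def test_unreadable_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            parse_domtblout(tmp_path / "missing.domtblout", 1e-37)


class TestHitsToArchitecture:
    def test_orders_by_envelope_start(self):
        hits = [
            hit("A", start=10, end=50),
            hit("C", start=200, end=260),
            hit("B", start=90, end=150),
        ]
        assert hits_to_architecture(hits).domains == ("A", "B", "C")

    def test_full_overlap_keeps_higher_acc(self):
        hits = [hit("LOW", acc=0.80), hit("HIGH", acc=0.95)]
        assert hits_to_architecture(hits).domains == ("HIGH",)

    def test_acc_tie_broken_by_lower_evalue_then_file_order(self):
        by_evalue = [hit("WORSE", acc=0.9, e=1e-20), hit("BETTER", acc=0.9, e=1e-40)]
        assert hits_to_architecture(by_evalue).domains == ("BETTER",)
        by_order = [hit("FIRST", acc=0.9, e=1e-30), hit("SECOND", acc=0.9, e=1e-30)]
        assert hits_to_architecture(by_order).domains == ("FIRST",)

    def test_small_overlap_keeps_both_hits(self):
        # 20-residue overlap of 100-residue envelopes: below the 50% rule.
        hits = [hit("A", start=1, end=100), hit("B", start=81, end=180)]
        assert hits_to_architecture(hits).domains == ("A", "B")

    def test_single_hit_gives_singleton(self):
        assert hits_to_architecture([hit("A")]).domains == ("A",)

    def test_empty_hits_raise(self):
        with pytest.raises(ValueError, match="no domains"):
            hits_to_architecture([])

    def test_mixed_proteins_raise(self):
        with pytest.raises(ValueError, match="multiple proteins"):
            hits_to_architecture([hit("A", protein="p1"), hit("B", protein="p2")])


class TestArchitectureFiles:
    def test_read_basic(self, tmp_path):
        path = tmp_path / "arch.tsv"
        path.write_text("p1\tPH,RhoGEF\np2\tRhoGEF\n")
        corpus = read_architectures(path)
        assert len(corpus) == 2
        assert corpus.alphabet == {"PH", "RhoGEF"}
        assert corpus.g == 2

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "arch.tsv"
        path.write_text("\n\n")
        with pytest.raises(ParseError, match="empty corpus"):
            read_architectures(path)

    @pytest.mark.parametrize("line", ["p1 PH,RhoGEF", "p1\t", "\tPH"])
    def test_malformed_line_names_line_number(self, tmp_path, line):
        path = tmp_path / "arch.tsv"
        path.write_text("ok\tPH\n" + line + "\n")
        with pytest.raises(ParseError, match="line 2"):
            read_architectures(path)

    names = st.text(
        alphabet="ABCdef123_", min_size=1, max_size=6
    )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seqs=st.lists(
            st.lists(names, min_size=1, max_size=5), min_size=1, max_size=8
        )
    )
    def test_write_read_round_trip_is_identity(self, tmp_path_factory, seqs):
        corpus = Corpus(
            architectures=tuple(
                Architecture(protein_id=f"p{i}", domains=tuple(seq))
                for i, seq in enumerate(seqs)
            )
        )
        path = tmp_path_factory.mktemp("rt") / "arch.tsv"
        write_architectures(corpus, path)
        assert read_architectures(path) == corpus


class TestFrequencyCsv:
    def test_top_row_and_percent_format(self, tmp_path):
        path = tmp_path / "freq.csv"
        write_frequency_csv({"X": 3, "Y": 1}, path, top_num=1)
        lines = path.read_text().splitlines()
        assert lines == ["item,frequency,probability_percent", "X,3,75.0"]

    def test_truncation_never_pads(self, tmp_path):
        table = {f"item{i:02d}": i + 1 for i in range(10)}
        path = tmp_path / "freq.csv"
        write_frequency_csv(table, path, top_num=100)
        assert len(path.read_text().splitlines()) == 11  # header + 10 rows

    def test_ties_broken_lexicographically(self, tmp_path):
        path = tmp_path / "freq.csv"
        write_frequency_csv({"B": 2, "A": 2, "C": 5}, path, top_num=3)
        items = [line.split(",")[0] for line in path.read_text().splitlines()[1:]]
        assert items == ["C", "A", "B"]

    def test_top_num_below_one_raises(self, tmp_path):
        with pytest.raises(ValueError, match="top_num"):
            write_frequency_csv({"X": 1}, tmp_path / "freq.csv", top_num=0)


def test_filter_soundness_no_hit_above_threshold_reaches_architecture(tmp_path):
    path = tmp_path / "hits.domtblout"
    path.write_text(
        domtblout_line(domain="GOOD", i_evalue=1e-40)
        + "\n"
        + domtblout_line(domain="BAD", i_evalue=1e-5, env_from=200, env_to=299)
        + "\n"
    )
    corpus = arch_io.corpus_from_hits(parse_domtblout(path, 1e-37))
    assert corpus.architectures[0].domains == ("GOOD",)
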