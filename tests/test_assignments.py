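"""Assignment parsing and the bigram adjacency/gap rules."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from bigramnet.assignments import (
    AssignmentParseError,
    Bigram,
    DomainHit,
    ProteinArchitecture,
    all_bigrams,
    extract_bigrams,
    homo_pair_count,
    parse_assignments,
    peripheral_domains,
    write_assignments,
)
from bigramnet.graph import build_network


def arch(*hits, protein="p1", genome="g1"):
    return ProteinArchitecture(protein, genome, [DomainHit(d, ((s, e),)) for d, s, e in hits])


class TestParsing:
    def test_single_row(self):
        table = io.StringIO("g1\tp1\tD_A\t1-100\n")
        out = parse_assignments(table)
        (a,) = out["g1"]
        assert a.protein_id == "p1"
        assert a.hits[0].domain_id == "D_A"
        assert a.hits[0].segments == ((1, 100),)

    def test_discontinuous_region_is_one_hit_with_envelope(self):
        out = parse_assignments(io.StringIO("g1\tp1\tD_A\t1-100,150-200\n"))
        hit = out["g1"][0].hits[0]
        assert len(hit.segments) == 2
        assert (hit.start, hit.end) == (1, 200)

    def test_hits_sorted_by_envelope_start(self):
        table = io.StringIO("g1\tp1\tD_B\t120-200\ng1\tp1\tD_A\t5-100\n")
        hits = parse_assignments(table)["g1"][0].hits
        assert [h.start for h in hits] == [5, 120]

    def test_comments_and_blank_lines_skipped(self):
        table = io.StringIO("# header\n\ng1\tp1\tD_A\t1-100\n")
        assert len(parse_assignments(table)["g1"]) == 1

    @pytest.mark.parametrize(
        "row, fragment",
        [
            ("g1\tp1\tD_A\t100-1\n", "line 1"),          # end < start
            ("g1\tp1\tD_A\tten-20\n", "line 1"),          # non-numeric
            ("g1\tp1\tD_A\n", "line 1"),                  # missing column
            ("g1\tp1\tD_A\t1-2\ng1\tp2\tD_B\tx\n", "line 2"),
        ],
    )
    def test_malformed_rows_name_the_line(self, row, fragment):
        with pytest.raises(AssignmentParseError, match=fragment):
            parse_assignments(io.StringIO(row))

    def test_round_trip_through_file(self, tmp_path):
        archs = [
            arch(("D_A", 1, 100), ("D_B", 120, 200)),
            arch(("D_C", 3, 50), protein="p2"),
        ]
        path = tmp_path / "assign.tsv"
        write_assignments(archs, path)
        back = parse_assignments(path)["g1"]
        assert [[(h.domain_id, h.segments) for h in a.hits] for a in back] == [
            [(h.domain_id, h.segments) for h in a.hits] for a in archs
        ]


class TestBigramExtraction:
    @pytest.mark.parametrize(
        "hits, expected",
        [
            ([("A", 1, 100), ("B", 120, 200)], [("A", "B", 19)]),   # gap 19 < 30
            ([("A", 1, 100), ("B", 131, 200)], []),                 # gap 30: boundary
            ([("A", 1, 100), ("B", 130, 200)], [("A", "B", 29)]),   # gap 29: last linked
            ([("A", 1, 100), ("A", 110, 200)], []),                 # homo pair excluded
            ([("A", 1, 100), ("B", 90, 150)], [("A", "B", -11)]),   # overlap is adjacent
            ([("A", 1, 100)], []),                                  # single-domain
            ([], []),
        ],
    )
    def test_gap_rule(self, hits, expected):
        got = extract_bigrams(arch(*hits))
        assert [(b.upstream, b.downstream, b.gap) for b in got] == expected

    def test_only_consecutive_pairs_count(self):
        a = arch(("A", 1, 50), ("B", 60, 100), ("C", 110, 150))
        got = extract_bigrams(a)
        assert [(b.upstream, b.downstream) for b in got] == [("A", "B"), ("B", "C")]

    def test_nested_domain_forms_bigram(self):
        # envelope of B fully inside A: sorted consecutively, negative gap
        a = arch(("A", 1, 300), ("B", 50, 100))
        assert [(b.upstream, b.downstream) for b in extract_bigrams(a)] == [("A", "B")]

    def test_reversing_order_swaps_direction_same_edge(self):
        fwd = extract_bigrams(arch(("A", 1, 100), ("B", 120, 200)))[0]
        rev = extract_bigrams(arch(("B", 1, 100), ("A", 120, 200)))[0]
        assert (fwd.upstream, fwd.downstream) == (rev.downstream, rev.upstream)
        assert fwd.edge == rev.edge

    def test_homo_pair_diagnostic_counter(self):
        archs = [arch(("A", 1, 100), ("A", 110, 200), ("B", 220, 300))]
        assert homo_pair_count(archs) == {"A": 1}

    def test_bigram_invariant_rejects_self_pair(self):
        with pytest.raises(ValueError):
            Bigram("A", "A")


class TestPeripheralDomains:
    def test_single_domain_protein(self):
        assert peripheral_domains([arch(("A", 1, 100))]) == {"A"}

    def test_linked_and_lonely(self):
        archs = [arch(("A", 1, 100), ("B", 110, 200)), arch(("C", 1, 80), protein="p2")]
        assert peripheral_domains(archs) == {"C"}

    def test_distant_pair_both_peripheral(self):
        archs = [arch(("A", 1, 100), ("B", 140, 200))]  # gap 39 >= 30
        assert peripheral_domains(archs) == {"A", "B"}

    def test_peripheral_disjoint_from_network_vertices(self):
        archs = [
            arch(("A", 1, 100), ("B", 110, 200)),
            arch(("B", 1, 90), ("C", 95, 150), protein="p2"),
            arch(("D", 1, 100), protein="p3"),
        ]
        net = build_network(all_bigrams(archs))
        assert peripheral_domains(archs) & set(net.graph.nodes) == set()


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.sampled_from("ABCDE"), st.integers(0, 40)), min_size=1, max_size=6))
def test_every_domain_is_networked_or_peripheral(layout):
    """Partition property: each domain id ends up with degree >= 1 or peripheral."""
    hits, pos = [], 1
    for dom, gap in layout:
        hits.append((dom, pos, pos + 49))
        pos += 50 + gap
    a = arch(*hits)
    net = build_network(extract_bigrams(a), include_isolated=peripheral_domains([a]))
    assert set(net.graph.nodes) >= set(a.domain_ids)
    for dom in a.domain_ids:
        deg = net.graph.degree(dom)
        assert (deg >= 1) == (dom not in peripheral_domains([a]))
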