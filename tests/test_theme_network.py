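import math

import pytest

from trefoil_themes import theme_network as tn
from trefoil_themes.profile_hmm import ThemeHit


def _hit(profile="p1", master="mA", target="t1", group="11.1.1", rmsd=None):
    return ThemeHit(
        profile_id=profile,
        master_domain=master,
        target_domain=target,
        target_group=group,
        bit_score=20.0,
        evalue=1e-5,
        alignment=[(1, 5), (2, 6), (3, 7)],
        segment_rmsd=rmsd,
    )


CLASSIFICATION = {"mA": "6.1.1", "mB": "6.1.2"}


class TestBuildNetwork:
    def test_single_hit_single_edge(self):
        net = tn.build_network([_hit()], CLASSIFICATION)
        assert len(net.edges) == 1
        assert len(net.trefoil_nodes) == 1 and len(net.lineage_nodes) == 1

    def test_two_profiles_share_one_edge(self):
        hits = [_hit(profile="p1"), _hit(profile="p2", target="t2")]
        net = tn.build_network(hits, CLASSIFICATION)
        (edge,) = net.edges
        assert edge[2] == ["p1", "p2"]

    def test_empty_hits_empty_network(self):
        net = tn.build_network([], CLASSIFICATION)
        assert net.edges == [] and net.trefoil_nodes == []

    def test_unclassified_query_skipped(self):
        net = tn.build_network([_hit(master="unknown")], CLASSIFICATION)
        assert net.edges == []

    def test_edge_count_bounded_by_hits_and_monotone(self):
        hits = [
            _hit(profile="p1", group="11.1.1"),
            _hit(profile="p1", target="t2", group="5.1.1"),
            _hit(profile="p2", master="mB", group="11.1.1"),
        ]
        full = tn.build_network(hits, CLASSIFICATION)
        assert len(full.edges) <= len(hits)
        fewer = tn.build_network(hits[:1], CLASSIFICATION)
        assert len(fewer.edges) <= len(full.edges)


class TestCountUniqueThemes:
    def test_redundant_hits_collapse_to_one_theme(self):
        hits = [_hit(target=f"t{i}") for i in range(3)]
        table = tn.count_unique_themes(hits)
        assert table.loc[0, "n_unique_themes"] == 1

    def test_two_profiles_count_two(self):
        hits = [_hit(profile="p1"), _hit(profile="p2")]
        table = tn.count_unique_themes(hits)
        assert table.loc[0, "n_unique_themes"] == 2

    def test_empty_table(self):
        assert tn.count_unique_themes([]).empty

    def test_totals_never_exceed_distinct_profiles(self):
        hits = [
            _hit(profile=p, target=t, group=g)
            for p in ("p1", "p2")
            for t, g in (("t1", "11.1.1"), ("t2", "5.1.1"))
        ]
        table = tn.count_unique_themes(hits)
        assert (table["n_unique_themes"] <= 2).all()


class TestFgroupPairs:
    def test_duplicate_pairs_deduplicated(self):
        hits = [_hit(target="t1"), _hit(target="t1b")]
        table = tn.fgroup_pair_associations(hits, CLASSIFICATION)
        assert table.loc[0, "n_pairs"] == 1

    def test_two_targets_one_family_one_pair(self):
        hits = [_hit(target="t1", group="11.1.7"), _hit(target="t2", group="11.1.7")]
        table = tn.fgroup_pair_associations(hits, CLASSIFICATION)
        assert table.loc[0, "n_pairs"] == 1

    def test_two_query_families_two_pairs(self):
        hits = [_hit(master="mA"), _hit(master="mB")]
        table = tn.fgroup_pair_associations(hits, CLASSIFICATION)
        assert table.loc[0, "n_pairs"] == 2

    def test_missing_fgroup_goes_to_tgroup_bucket(self):
        hits = [_hit(group="11.1")]
        table = tn.fgroup_pair_associations(hits, CLASSIFICATION)
        assert "11.1.?" in str(table.loc[0, "pairs"])


class TestStrandAssociations:
    def test_identity_alignment_pairs_every_strand(self):
        ss = "CEEEECCEEEECC"
        hit = _hit()
        hit.alignment = [(i, i) for i in range(1, len(ss) + 1)]
        pairs = tn.strand_associations(hit, ss, ss)
        assert pairs == [(1, 1), (2, 2)]

    def test_alignment_outside_strands_is_empty(self):
        ss_q = "EEEECCCCCC"
        ss_t = "CCCCCCEEEE"
        hit = _hit()
        hit.alignment = [(5, 1), (6, 2), (7, 3)]
        assert tn.strand_associations(hit, ss_q, ss_t) == []

    def test_constructed_cross_association(self):
        # query strand 2 aligned onto target strand 5 over 4 residues
        ss_q = "CEEECC" + "EEEE" + "CC"
        ss_t = "CEEECEEECEEECEEEC" + "EEEE" + "C"
        hit = _hit()
        hit.alignment = [(7 + k, 18 + k) for k in range(4)]
        assert tn.strand_associations(hit, ss_q, ss_t) == [(2, 5)]

    def test_missing_ss_returns_empty(self):
        assert tn.strand_associations(_hit(), "", "EEE") == []


class TestMetamorphism:
    def test_basic_median_and_fraction(self):
        median, fraction, n, miss = tn.metamorphism_stats([1.0, 2.0, 3.0])
        assert median == 2.0 and fraction == pytest.approx(2 / 3)

    def test_all_at_paper_median_value(self):
        median, fraction, *_ = tn.metamorphism_stats([5.6] * 7)
        assert median == 5.6 and fraction == 0.0

    def test_boundary_is_strict(self):
        _, fraction, *_ = tn.metamorphism_stats([2.5])
        assert fraction == 0.0

    def test_missing_values_counted_separately(self):
        hits = [_hit(rmsd=1.0), _hit(rmsd=None), _hit(rmsd=float("nan"))]
        median, fraction, n, miss = tn.metamorphism_stats(hits)
        assert (median, n, miss) == (1.0, 1, 2)

    def test_no_defined_values_flagged(self):
        median, fraction, n, miss = tn.metamorphism_stats([None, None])
        assert math.isnan(median) and miss == 2
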