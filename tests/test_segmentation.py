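"""Label-to-interval mapping, chopping grammar, structure annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paedomains import parse_structure
from paedomains.clustering import ClusterAssignment, canonicalize_labels
from paedomains.errors import ChoppingParseError, ReconciliationError
from paedomains.segmentation import (
    Segmentation,
    annotate_structure,
    clusters_to_segmentation,
    parse_chopping_string,
    residue_csv,
    segmentation_table,
    to_chopping_string,
)

from conftest import make_pdb


def assignment_from(labels):
    labels = canonicalize_labels(labels)
    return ClusterAssignment(labels=labels, k=len(set(labels)), quality=0.0)


class TestClustersToSegmentation:
    def test_discontinuous_domain_from_runs(self):
        seg = clusters_to_segmentation(assignment_from([0, 0, 0, 1, 1, 0, 0]),
                                       min_size=1)
        assert to_chopping_string(seg) == "1-3_6-7,4-5"
        assert seg.domains[0].residue_count == 5
        assert len(seg.domains[0].segments) == 2

    def test_min_size_moves_small_cluster_to_unassigned(self):
        seg = clusters_to_segmentation(assignment_from([0, 0, 0, 0, 0, 1]),
                                       min_size=3)
        assert to_chopping_string(seg) == "1-5"
        assert seg.unassigned == {5}

    def test_every_residue_assigned_or_unassigned_exactly_once(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            labels = rng.integers(0, 5, size=n).tolist()
            seg = clusters_to_segmentation(assignment_from(labels), min_size=3)
            covered = set()
            total = 0
            for d in seg.domains:
                res = d.residues()
                assert not (covered & res), "residue in two domains"
                covered |= res
                total += d.residue_count
            assert total + len(seg.unassigned) == n

    def test_filter_monotonicity(self):
        rng = np.random.default_rng(22)
        labels = rng.integers(0, 6, size=80).tolist()
        counts = [clusters_to_segmentation(assignment_from(labels),
                                           min_size=m).n_domains
                  for m in (1, 3, 6, 12, 30)]
        assert counts == sorted(counts, reverse=True)

    def test_exclude_goes_straight_to_unassigned(self):
        seg = clusters_to_segmentation(assignment_from([0] * 10), min_size=2,
                                       exclude=frozenset({4, 5}))
        assert seg.unassigned >= {4, 5}
        assert to_chopping_string(seg) == "1-4_7-10"


class TestChoppingGrammar:
    @pytest.mark.parametrize("text, n_domains, n_segments_first", [
        ("1-3_6-7,4-5", 2, 2),
        ("10-20", 1, 1),
        ("1-100", 1, 1),
    ])
    def test_parse_examples(self, text, n_domains, n_segments_first):
        seg = parse_chopping_string(text)
        assert seg.n_domains == n_domains
        assert len(seg.domains[0].segments) == n_segments_first

    def test_empty_string_is_empty_segmentation(self):
        assert parse_chopping_string("").n_domains == 0
        assert to_chopping_string(Segmentation(())) == ""

    @pytest.mark.parametrize("bad", ["20-10", "a-b", "5-", "1-3_,4-5", "1--3"])
    def test_malformed_tokens_rejected(self, bad):
        with pytest.raises(ChoppingParseError):
            parse_chopping_string(bad)

    def test_error_names_offending_token(self):
        with pytest.raises(ChoppingParseError, match="20-10"):
            parse_chopping_string("1-5,20-10")

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=60))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_identity(self, labels):
        """parse(to_string(seg)) reproduces seg for any label vector."""
        seg = clusters_to_segmentation(assignment_from(labels), min_size=1)
        text = to_chopping_string(seg)
        again = parse_chopping_string(text)
        assert to_chopping_string(again) == text
        assert [d.residues() for d in again.domains] == \
               [d.residues() for d in seg.domains]

    def test_insertion_code_round_trip(self):
        text = "52-60A"
        seg = parse_chopping_string(text)
        assert seg.domains[0].segments[0].end_icode == "A"
        assert to_chopping_string(seg) == text


class TestAnnotateStructure:
    def test_domain_indices_in_b_factor(self):
        pdb = make_pdb({"A": [(i, "", 50.0) for i in range(1, 11)]})
        seg = clusters_to_segmentation(assignment_from([0] * 5 + [1] * 5),
                                       min_size=1)
        out = annotate_structure(pdb.encode(), seg)
        table = parse_structure(out, format="pdb")
        assert [e.plddt for e in table] == [1.0] * 5 + [2.0] * 5

    def test_all_unassigned_gets_minus_one(self):
        pdb = make_pdb({"A": [(i, "", 50.0) for i in range(1, 6)]})
        seg = Segmentation((), frozenset(range(5)))
        out = annotate_structure(pdb.encode(), seg)
        table = parse_structure(out, format="pdb")
        assert [e.plddt for e in table] == [-1.0] * 5

    def test_labels_recoverable_after_round_trip(self):
        rng = np.random.default_rng(23)
        labels = canonicalize_labels(np.sort(rng.integers(0, 3, size=20)).tolist())
        pdb = make_pdb({"A": [(i, "", 50.0) for i in range(1, 21)]})
        seg = clusters_to_segmentation(assignment_from(labels), min_size=1)
        table = parse_structure(annotate_structure(pdb.encode(), seg), format="pdb")
        recovered = [int(e.plddt) for e in table]
        # each domain's residues share one recovered index; domains distinct
        assert canonicalize_labels(recovered) == canonicalize_labels(labels)

    def test_residue_count_mismatch(self):
        pdb = make_pdb({"A": [(i, "", 50.0) for i in range(1, 6)]})
        seg = clusters_to_segmentation(assignment_from([0] * 7), min_size=1)
        with pytest.raises(ReconciliationError):
            annotate_structure(pdb.encode(), seg)


def test_tabular_writers_have_expected_shape():
    seg = clusters_to_segmentation(assignment_from([0, 0, 0, 1, 1, 0, 0]),
                                   min_size=1)
    tsv = segmentation_table(seg).splitlines()
    assert tsv[0].split("\t") == ["domain_index", "n_segments", "chopping", "n_residues"]
    assert tsv[1].split("\t") == ["1", "2", "1-3_6-7", "5"]

    from paedomains.pae_io import default_residue_table
    csv_text = residue_csv(seg, default_residue_table(7)).splitlines()
    assert len(csv_text) == 8
    assert csv_text[1].split(",")[-1] == "1"
    assert csv_text[4].split(",")[-1] == "2"
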