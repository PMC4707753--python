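"""Tree/trait I/O, fossil handling and pseudo-outgroup grafting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabletrees import (
    AGE_EPS,
    TimeTree,
    TraitTable,
    graft_outgroup,
    prune_fossil_tips,
    prune_to_tips,
    read_traits,
    read_tree,
    write_traits,
    write_tree,
)


def _tree_from(tmp_path, text, fmt="newick"):
    p = tmp_path / ("t.nwk" if fmt == "newick" else "t.nex")
    p.write_text(text)
    return read_tree(p, fmt)


def _tip_dist(tree):
    """Root-to-tip path lengths by label."""
    return {l: tree.root_age - a for l, a in tree.tip_ages.items()}


class TestReadTree:
    def test_ultrametric_ages(self, tmp_path):
        t = _tree_from(tmp_path, "((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert t.root_age == pytest.approx(2.0)
        assert all(a == pytest.approx(0.0) for a in t.tip_ages.values())
        assert t.fossil_tip_labels() == []

    def test_fossil_tip_from_path_lengths(self, tmp_path):
        t = _tree_from(tmp_path, "((A:1,B:0.5):1,C:2);")
        assert t.tip_ages["B"] == pytest.approx(0.5)
        assert t.fossil_tip_labels() == ["B"]
        assert sorted(t.extant_tip_labels()) == ["A", "C"]

    def test_pendant_zero_edge_retained_internal_collapsed(self, tmp_path):
        # pendant near-zero edge survives; near-zero internal edge collapses
        t = _tree_from(tmp_path, "((A:1,B:1e-12):1,C:2);")
        assert "B" in t.tip_labels()
        assert t.tip_ages["B"] == pytest.approx(1.0, abs=1e-6)
        t2 = _tree_from(tmp_path, "((A:1,B:1):1e-12,C:1);")
        # internal edge collapsed -> root polytomy with 3 children
        assert len(t2.children[t2.root]) == 3
        assert t2.n_nodes == 4

    def test_missing_branch_length_error(self, tmp_path):
        with pytest.raises(ValueError, match="branch length"):
            _tree_from(tmp_path, "((A:1,B),C:2);")

    def test_duplicate_tip_labels_error(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            _tree_from(tmp_path, "((A:1,A:1):1,C:2);")

    def test_explicitly_unrooted_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unroot"):
            _tree_from(tmp_path, "[&U] (A:1,B:1,C:2);")

    @pytest.mark.parametrize("fmt", ["newick", "nexus"])
    def test_round_trip(self, tmp_path, fmt):
        src = _tree_from(tmp_path, "(((A:1.25,B:0.5):0.75,C:2):1.5,(D:1,E:3.1):0.4);")
        out = tmp_path / f"rt.{fmt}"
        write_tree(src, out, fmt)
        back = read_tree(out, fmt)
        assert sorted(back.tip_labels()) == sorted(src.tip_labels())
        assert back.root_age == pytest.approx(src.root_age, abs=1e-9)
        d0, d1 = _tip_dist(src), _tip_dist(back)
        for l in d0:
            assert d1[l] == pytest.approx(d0[l], abs=1e-9)
        assert back.clade_index().keys() == src.clade_index().keys()


class TestTraits:
    def test_read_traits_log10(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("species\tmass_kg\nAfrotheria_anc\t0.1\nLoxodonta\t5000\n")
        t = read_traits(p)
        assert t.working_values["Afrotheria_anc"] == pytest.approx(-1.0)
        assert TraitTable.back_transform(-1.0) == pytest.approx(0.1)

    def test_headerless_csv(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("A,0.5\nB,2\n")
        assert read_traits(p).records == {"A": 0.5, "B": 2.0}

    @pytest.mark.parametrize("bad,msg", [
        ("A\t-5\n", "non-positive"),
        ("A\t0\n", "non-positive"),
        ("A\tx\n", "non-numeric"),
        ("A\t1\nA\t2\n", "duplicate"),
    ])
    def test_errors_with_row_numbers(self, tmp_path, bad, msg):
        p = tmp_path / "m.tsv"
        p.write_text("species\tmass_kg\n" + bad)
        with pytest.raises(ValueError, match=msg):
            read_traits(p)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6,
                              allow_nan=False, allow_infinity=False),
                    min_size=1, max_size=8, unique=True))
    @settings(max_examples=40, deadline=None)
    def test_log10_working_scale_round_trip(self, masses):
        tab = TraitTable({f"s{i}": m for i, m in enumerate(masses)})
        for k, v in tab.records.items():
            assert tab.working_values[k] == pytest.approx(math.log10(v))
            assert TraitTable.back_transform(tab.working_values[k]) == pytest.approx(v, rel=1e-12)

    def test_binding_requires_full_coverage(self, two_tip_star):
        with pytest.raises(KeyError, match="B"):
            TraitTable({"A": 1.0}).bind(two_tip_star)


class TestPruneFossils:
    def test_conserves_extant_distances(self, tmp_path):
        t = _tree_from(tmp_path, "(((A:1,F1:0.2):1,B:2):1,(C:1.5,F2:0.5):1.5);")
        assert sorted(t.fossil_tip_labels()) == ["F1", "F2"]
        p = prune_fossil_tips(t)
        assert sorted(p.tip_labels()) == ["A", "B", "C"]
        d0, d1 = _tip_dist(t), _tip_dist(p)
        for l in "ABC":
            assert d1[l] == pytest.approx(d0[l], abs=1e-9)
        assert p.root_age == pytest.approx(t.root_age)
        # extant subtree stays ultrametric
        assert max(abs(a) for a in p.tip_ages.values()) <= AGE_EPS

    def test_no_fossils_identity(self, tmp_path):
        t = _tree_from(tmp_path, "((A:1,B:1):1,C:2);")
        p = prune_fossil_tips(t)
        assert p.clade_index().keys() == t.clade_index().keys()
        assert _tip_dist(p) == pytest.approx(_tip_dist(t))

    def test_too_few_tips_error(self, tmp_path):
        t = _tree_from(tmp_path, "((A:1,B:0.5):1,C:2);")
        with pytest.raises(ValueError, match="< 3"):
            prune_fossil_tips(t)

    def test_prune_to_subset(self, tmp_path):
        t = _tree_from(tmp_path, "(((A:1,B:1):1,C:2):1,D:3);")
        p = prune_to_tips(t, ["A", "C"])
        assert sorted(p.tip_labels()) == ["A", "C"]
        assert _tip_dist(p)["A"] == pytest.approx(_tip_dist(t)["A"])


class TestGraftOutgroup:
    def test_geometry_and_distances(self, tmp_path):
        t = _tree_from(tmp_path, "((A:1,B:1):1,C:2);")
        traits = TraitTable({"A": 1.0, "B": 2.0, "C": 0.5})
        g, gt = graft_outgroup(t, traits, outgroup_mass=0.1)
        assert g.n_tips == t.n_tips + 1
        assert g.root_age == pytest.approx(t.root_age + 4.99)
        assert gt.records["pseudo_outgroup"] == pytest.approx(0.1)
        # pendant fossil tip of duration 0.01 hanging off the new root
        assert g.tip_ages["pseudo_outgroup"] == pytest.approx(g.root_age - 0.01)
        # original pairwise tip distances unchanged
        d0, d1 = _tip_dist(t), _tip_dist(g)
        for l in "ABC":
            assert d1[l] - 4.99 == pytest.approx(d0[l], abs=1e-9)

    def test_sep_is_stem_reading(self, tmp_path):
        t = _tree_from(tmp_path, "((A:1,B:1):1,C:2);")
        traits = TraitTable({"A": 1.0, "B": 2.0, "C": 0.5})
        g, _ = graft_outgroup(t, traits, 1.0, sep_is_stem=True)
        assert g.root_age == pytest.approx(t.root_age + 5.0)

    def test_graft_then_prune_is_inverse(self, tmp_path):
        t = _tree_from(tmp_path, "((A:1,B:1):1,C:2);")
        traits = TraitTable({"A": 1.0, "B": 2.0, "C": 0.5})
        g, _ = graft_outgroup(t, traits, 5.0)
        back = prune_to_tips(g, t.tip_labels(), keep_root=False)
        assert _tip_dist(back) == pytest.approx(_tip_dist(t), abs=1e-9)
        assert {c for c in back.clade_index() if len(c) > 1} >= \
               {c for c in t.clade_index() if len(c) > 1}

    def test_invalid_mass_and_geometry(self, tmp_path):
        t = _tree_from(tmp_path, "((A:1,B:1):1,C:2);")
        traits = TraitTable({"A": 1.0, "B": 2.0, "C": 0.5})
        with pytest.raises(ValueError, match="positive"):
            graft_outgroup(t, traits, 0.0)
        with pytest.raises(ValueError, match="separation"):
            graft_outgroup(t, traits, 1.0, sep_total=0.005, pendant=0.01)
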