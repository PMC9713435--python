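"""Backbone loading/validation, hierarchical assignment, imputation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from msycnv.haplotree import (
    BackboneTree,
    InconsistentGenotypeError,
    MarkerDef,
    TreeConfigError,
    UnassignableError,
    assign_haplotype,
    assign_table,
    default_backbone,
    ht_frequencies,
    impute_profile,
    next_markers,
)

PUBLISHED_HTS = {
    "Ad", "Am", "Ao", "Ta", "Tb", "Tb-1", "Tb-d", "Tb-o", "Tu", "Hs",
    "DW1", "DW3", "DW4", "Y", "I", "M", "N", "O", "Pa", "Pb",
}


def full_genotype(tree, node):
    """Complete marker vector consistent with a placement at ``node``."""
    on_path = tree.path_markers(node)
    return {
        m.name: m.derived if m.name in on_path else m.ancestral
        for m in tree.markers
    }


class TestBackboneConfig:
    def test_bundled_fixture_is_valid(self, tree):
        assert len(tree.markers) == 30
        assert sum(m.kind == "indel" for m in tree.markers) == 1
        assert PUBLISHED_HTS <= set(tree.nodes)
        assert tree.gate_marker == "rAX"

    def test_marker_on_two_edges_rejected(self, tree):
        cfg = tree.to_dict()
        cfg["markers"].append(dict(cfg["markers"][0]))  # duplicate rAX
        with pytest.raises(TreeConfigError, match="more than one edge"):
            BackboneTree.from_dict(cfg)

    def test_cycle_rejected(self):
        with pytest.raises(TreeConfigError):
            BackboneTree(
                root="R",
                parent={"a": "b", "b": "a"},
                markers=[MarkerDef("m1", "a", "A", "G"),
                         MarkerDef("m2", "b", "A", "G")],
            )

    def test_orphan_parent_rejected(self):
        with pytest.raises(TreeConfigError, match="unknown parent"):
            BackboneTree(root="R", parent={"a": "ghost"},
                         markers=[MarkerDef("m1", "a", "A", "G")])

    def test_bare_edge_rejected(self, tree):
        cfg = tree.to_dict()
        cfg["markers"] = [m for m in cfg["markers"] if m["name"] != "p-Hs"]
        with pytest.raises(TreeConfigError, match="without markers"):
            BackboneTree.from_dict(cfg)

    def test_identical_alleles_rejected(self):
        with pytest.raises(TreeConfigError):
            MarkerDef("m", "a", "A", "a")

    def test_yaml_round_trip(self, tree, tmp_path):
        path = tmp_path / "tree.yaml"
        tree.to_yaml(path)
        back = BackboneTree.from_yaml(path)
        assert back.to_dict() == tree.to_dict()

    def test_random_tree_round_trips(self, tmp_path, rng):
        """Randomly grown marker trees survive save/load unchanged."""
        for rep in range(10):
            nodes = ["Root"]
            parent = {}
            markers = []
            for i in range(int(rng.integers(2, 15))):
                label = f"n{i}"
                parent[label] = nodes[int(rng.integers(len(nodes)))]
                markers.append(MarkerDef(f"m{i}", label, "A", "G"))
                nodes.append(label)
            t = BackboneTree("Root", parent, markers)
            path = tmp_path / f"t{rep}.yaml"
            t.to_yaml(path)
            assert BackboneTree.from_yaml(path).to_dict() == t.to_dict()


class TestAssignment:
    def test_full_derived_path_reaches_leaf(self, tree):
        a = assign_haplotype(full_genotype(tree, "Tb-d"), tree)
        assert a.node == "Tb-d" and a.resolved

    def test_partial_genotype_stops_at_internal_node(self, tree):
        g = {"rAX": "T", "rAY": "C", "p-DW4u": "G"}  # ancestral at DW4's child
        a = assign_haplotype(g, tree)
        assert a.node == "DW4" and not a.resolved

    def test_all_ancestral_is_outgroup_at_root(self, tree):
        a = assign_haplotype(full_genotype(tree, tree.root), tree)
        assert a.node == tree.root and not a.resolved
        assert set(a.imputed_profile) <= set("ACGT") or "del" in a.imputed_profile

    def test_missing_gate_marker_unassignable(self, tree):
        with pytest.raises(UnassignableError):
            assign_haplotype({"rA": "G"}, tree)

    def test_derived_sibling_edges_inconsistent(self, tree):
        g = full_genotype(tree, "T")
        g["rW"] = "T"  # derived on the sibling A edge too
        with pytest.raises(InconsistentGenotypeError):
            assign_haplotype(g, tree)

    def test_unknown_allele_rejected(self, tree):
        g = full_genotype(tree, tree.root)
        g["rAX"] = "G"  # neither ancestral (T) nor derived (C)
        with pytest.raises(InconsistentGenotypeError):
            assign_haplotype(g, tree)

    def test_allele_matching_is_case_insensitive(self, tree):
        g = {k: v.lower() for k, v in full_genotype(tree, "Hs").items()}
        assert assign_haplotype(g, tree).node == "Hs"

    def test_sequential_equals_full_for_every_node(self, tree):
        """Typing only the markers the protocol requests at each step gives
        the same placement as the complete 30-marker vector, for all nodes."""
        for node in tree.nodes:
            complete = full_genotype(tree, node)
            seen = {}
            if tree.gate_marker:
                seen[tree.gate_marker] = complete[tree.gate_marker]
            cur = tree.root
            while True:
                for name in next_markers(tree, cur):
                    seen[name] = complete[name]
                nxt = [
                    c for c in tree.children[cur]
                    if any(seen.get(m.name) == m.derived
                           for m in tree.edge_markers[c])
                ]
                if not nxt:
                    break
                cur = nxt[0]
            sequential = assign_haplotype(seen, tree)
            full = assign_haplotype(complete, tree)
            assert (sequential.node, sequential.resolved) == (full.node, full.resolved)
            assert sequential.imputed_profile == full.imputed_profile


class TestNextMarkers:
    def test_crown_substructure_markers(self, tree):
        assert next_markers(tree, "Crown") == ["rA", "rW", "fYR"]

    def test_leaf_has_none(self, tree):
        assert next_markers(tree, "Tb-d") == []

    def test_root_includes_crown_gate(self, tree):
        assert "rAX" in next_markers(tree, tree.root)

    def test_unknown_node_rejected(self, tree):
        with pytest.raises(KeyError):
            next_markers(tree, "Atlantis")


class TestImputation:
    def test_outgroup_profile_is_all_ancestral(self, tree):
        prof = impute_profile(tree.root, tree)
        assert prof == "".join(m.ancestral for m in tree.markers)

    def test_derived_exactly_on_path(self, tree):
        prof = impute_profile("Tb-d", tree)
        on_path = tree.path_markers("Tb-d")
        expected = "".join(
            m.derived if m.name in on_path else m.ancestral for m in tree.markers
        )
        assert prof == expected

    def test_observed_contradiction_raises(self, tree):
        g = {"p-Hs": "T"}  # derived deep in the H clade
        with pytest.raises(InconsistentGenotypeError):
            impute_profile("Tb-d", tree, observed=g)

    def test_idempotent_through_assignment(self, tree):
        for node in ("Tb-d", "DW4", "Pa", tree.root):
            a = assign_haplotype(full_genotype(tree, node), tree)
            again = assign_haplotype(
                dict(zip((m.name for m in tree.markers), _split(tree, a.imputed_profile))),
                tree,
            )
            assert again.imputed_profile == a.imputed_profile

    def test_distinct_leaves_have_distinct_profiles(self, tree):
        profs = {leaf: impute_profile(leaf, tree) for leaf in tree.leaves()}
        for a, b in itertools.combinations(profs, 2):
            assert profs[a] != profs[b]


def _split(tree, profile):
    """Invert the concatenation: one allele token per marker, in order."""
    out = []
    i = 0
    for m in tree.markers:
        width = len(m.ancestral) if profile[i:].startswith(m.ancestral) else len(m.derived)
        out.append(profile[i:i + width])
        i += width
    return out


class TestFrequencies:
    def test_counts_and_zero_nodes_retained(self, tree):
        freqs = ht_frequencies(["Tb-d", "Tb-d", "Ad"], tree)
        table = freqs.set_index("node")["count"]
        assert table["Tb-d"] == 2 and table["Ad"] == 1
        assert table["DW2"] == 0
        assert len(freqs) == len(tree.nodes)

    def test_single_sample(self, tree):
        freqs = ht_frequencies(["Hs"], tree)
        assert freqs["count"].sum() == 1

    def test_unknown_label_rejected(self, tree):
        with pytest.raises(KeyError):
            ht_frequencies(["Narnia"], tree)


class TestAssignTable:
    def test_long_format_round_trip(self, tree):
        rows = [
            {"sample_id": "k1", "marker": m.name, "allele": m.ancestral}
            for m in tree.markers
        ]
        rows += [
            {"sample_id": "h1", "marker": name, "allele": allele}
            for name, allele in full_genotype(tree, "Hs").items()
        ]
        out = assign_table(pd.DataFrame(rows), tree).set_index("sample_id")
        assert out.loc["k1", "ht"] == tree.root and not out.loc["k1", "resolved"]
        assert out.loc["h1", "ht"] == "Hs" and out.loc["h1", "hg"] == "Crown"
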