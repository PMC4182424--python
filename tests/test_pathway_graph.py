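import io
import xml.etree.ElementTree as ET

import networkx as nx
import numpy as np
import pytest

from tcgsea import (
    FoldChangeTable,
    all_shortest_paths,
    compound_graph,
    merge_graphs,
    overlay_direction,
    parse_kgml,
    prune_isolated,
    read_compound_graph,
    render,
    write_compound_graph,
)
from tcgsea.pathway_graph import Reaction, ParsedPathway, graphs_equal
from tcgsea.synthetic_data import default_toy_pathways, make_toy_kgml


TOY_KGML = """<?xml version="1.0"?>
<pathway name="path:toy99999" org="ko" number="99999" title="Toy">
  <entry id="1" name="cpd:C00001" type="compound"><graphics name="A" type="circle"/></entry>
  <entry id="2" name="cpd:C00002" type="compound"><graphics name="B" type="circle"/></entry>
  <entry id="3" name="cpd:C00003" type="compound"><graphics name="C" type="circle"/></entry>
  <entry id="4" name="ko:K00001 ko:K00002" type="ortholog" reaction="rn:R00001"/>
  <entry id="5" name="ko:K00003" type="ortholog" reaction="rn:R00002"/>
  <reaction id="1" name="rn:R00001" type="irreversible">
    <substrate id="1" name="cpd:C00001"/><product id="2" name="cpd:C00002"/>
  </reaction>
  <reaction id="2" name="rn:R00002" type="irreversible">
    <substrate id="2" name="cpd:C00002"/><product id="3" name="cpd:C00003"/>
  </reaction>
</pathway>
"""


def exhaustive_min_paths(g, source, target, undirected=False):
    """Test-local oracle: enumerate every simple path by recursion and
    keep the minimum-length ones.  Independent of networkx search."""
    adj = {}
    for u, v in g.edges():
        adj.setdefault(u, set()).add(v)
        if undirected:
            adj.setdefault(v, set()).add(u)
    if source == target:
        return [[source]]
    found = []

    def walk(node, path):
        for nxt in adj.get(node, ()):  # noqa: B023
            if nxt in path:
                continue
            if nxt == target:
                found.append(path + [nxt])
            else:
                walk(nxt, path + [nxt])

    walk(source, [source])
    if not found:
        return []
    best = min(len(p) for p in found)
    return sorted(p for p in found if len(p) == best)


class TestParseKgml:
    def test_direct_transcription(self):
        parsed = parse_kgml(io.StringIO(TOY_KGML))
        assert parsed.pathway_id == "toy99999"
        assert set(parsed.compounds) == {"C00001", "C00002", "C00003"}
        assert parsed.compounds["C00001"] == "A"
        assert len(parsed.reactions) == 2
        g = compound_graph(parsed)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert g["C00001"]["C00002"]["R00001"]["orthologs"] == {"K00001", "K00002"}

    def test_reversible_reaction_gives_both_directions(self):
        xml = TOY_KGML.replace(
            'name="rn:R00001" type="irreversible"', 'name="rn:R00001" type="reversible"'
        )
        g = compound_graph(parse_kgml(io.StringIO(xml)))
        assert g.has_edge("C00001", "C00002", key="R00001")
        assert g.has_edge("C00002", "C00001", key="R00001")
        assert g.number_of_edges() == 3

    def test_fixture_counts_match_generator_manifest(self, toy_kgml):
        kgml_dir, manifest = toy_kgml
        for pid, expected in manifest["pathways"].items():
            parsed = parse_kgml(kgml_dir / f"{pid}.xml")
            assert len(parsed.compounds) == expected["compounds"]
            assert len(parsed.reactions) == expected["reactions"]
            g = compound_graph(parsed)
            assert g.number_of_edges() == expected["directed_edges"]

    def test_malformed_xml_raises_with_position(self):
        with pytest.raises(ET.ParseError):
            parse_kgml(io.StringIO("<pathway><entry></pathway>"))

    def test_reaction_with_undeclared_compound_skipped(self, caplog):
        xml = TOY_KGML.replace("cpd:C00003", "cpd:C09999").replace(
            '<entry id="3" name="cpd:C09999" type="compound">'
            '<graphics name="C" type="circle"/></entry>',
            "",
        )
        with caplog.at_level("WARNING"):
            parsed = parse_kgml(io.StringIO(xml))
        assert len(parsed.reactions) == 1
        assert "C09999" in caplog.text


class TestRestructure:
    def test_edge_multiset_matches_expansion_oracle(self, rng):
        compounds = {f"C{i:05d}": f"cpd{i}" for i in range(8)}
        ids = list(compounds)
        reactions = []
        for r in range(10):
            subs = list(rng.choice(ids, size=rng.integers(1, 3), replace=False))
            prods = list(rng.choice(ids, size=rng.integers(1, 3), replace=False))
            reactions.append(
                Reaction(f"R{r:05d}", subs, prods, bool(rng.integers(0, 2)),
                         {f"K{r:05d}"})
            )
        parsed = ParsedPathway("toyrand", "rand", compounds, reactions)
        g = compound_graph(parsed)
        expected = set()
        for rxn in reactions:
            for s in rxn.substrates:
                for p in rxn.products:
                    expected.add((s, p, rxn.reaction_id))
                    if rxn.reversible:
                        expected.add((p, s, rxn.reaction_id))
        assert set(g.edges(keys=True)) == expected


class TestMergePrune:
    def test_shared_compound_unions_memberships(self):
        a = compound_graph(ParsedPathway(
            "p1", "p1", {"C00022": "Pyruvate", "C00001": "A"},
            [Reaction("R1", ["C00001"], ["C00022"], False, {"K1"})]))
        b = compound_graph(ParsedPathway(
            "p2", "p2", {"C00022": "Pyruvate", "C00002": "B"},
            [Reaction("R2", ["C00022"], ["C00002"], False, {"K2"})]))
        m = merge_graphs([a, b])
        assert m.nodes["C00022"]["pathways"] == {"p1", "p2"}
        assert m.number_of_nodes() == 3

    def test_disjoint_graphs_sum_node_counts(self):
        a = compound_graph(ParsedPathway("p1", "p1", {"C1": "x", "C2": "y"},
                                         [Reaction("R1", ["C1"], ["C2"], False)]))
        b = compound_graph(ParsedPathway("p2", "p2", {"C3": "z", "C4": "w"},
                                         [Reaction("R2", ["C3"], ["C4"], False)]))
        assert merge_graphs([a, b]).number_of_nodes() == 4

    def test_shared_reaction_merges_ortholog_sets(self, toy_kgml):
        kgml_dir, _ = toy_kgml
        graphs = [
            compound_graph(parse_kgml(kgml_dir / f"{p}.xml"))
            for p in ("toy00561", "toy00020")
        ]
        merged = merge_graphs(graphs)
        # R00209 appears in both pathways with different KO labels
        assert merged["C00022"]["C00024"]["R00209"]["orthologs"] == {"K00161", "K00163"}

    def test_membership_tallies_match_manifest(self, toy_kgml):
        kgml_dir, manifest = toy_kgml
        graphs = [
            compound_graph(parse_kgml(kgml_dir / f"{p}.xml"))
            for p in manifest["pathways"]
        ]
        merged = merge_graphs(graphs)
        tally = {}
        for _, data in merged.nodes(data=True):
            k = len(data["pathways"])
            tally[str(k)] = tally.get(str(k), 0) + 1
        assert tally == manifest["merged"]["membership_counts"]
        assert merged.number_of_nodes() == manifest["merged"]["nodes"]
        assert merged.number_of_edges() == manifest["merged"]["edges"]

    def test_prune_removes_only_isolated(self, toy_kgml):
        kgml_dir, manifest = toy_kgml
        graphs = [
            compound_graph(parse_kgml(kgml_dir / f"{p}.xml"))
            for p in manifest["pathways"]
        ]
        merged = merge_graphs(graphs)
        pruned = prune_isolated(merged)
        assert pruned.number_of_nodes() == manifest["pruned"]["nodes"]
        assert pruned.number_of_edges() == manifest["pruned"]["edges"]
        # surviving node set equals a degree>0 oracle on the input
        assert set(pruned.nodes) == {n for n in merged if merged.degree(n) > 0}
        # fixpoint on connected graphs
        assert graphs_equal(prune_isolated(pruned), pruned)

    def test_merge_is_commutative_and_associative(self, rng):
        parts = []
        for i in range(3):
            cs = {f"C{i}{j}": "x" for j in range(3)}
            cs["C00"] = "shared"
            parts.append(compound_graph(ParsedPathway(
                f"p{i}", f"p{i}", cs,
                [Reaction(f"R{i}", [f"C{i}0"], ["C00"], False, {f"K{i}"})])))
        a, b, c = parts
        assert graphs_equal(merge_graphs([a, b]), merge_graphs([b, a]))
        assert graphs_equal(
            merge_graphs([merge_graphs([a, b]), c]),
            merge_graphs([a, merge_graphs([b, c])]),
        )

    def test_restructure_merge_prune_idempotent(self, toy_kgml):
        kgml_dir, manifest = toy_kgml
        graphs = [
            compound_graph(parse_kgml(kgml_dir / f"{p}.xml"))
            for p in manifest["pathways"]
        ]
        once = prune_isolated(merge_graphs(graphs))
        again = prune_isolated(merge_graphs([once]))
        assert graphs_equal(once, again)


class TestShortestPaths:
    def test_source_equals_target(self, toy_kgml):
        kgml_dir, _ = toy_kgml
        g = compound_graph(parse_kgml(kgml_dir / "toy00010.xml"))
        assert all_shortest_paths(g, "C00031", "C00031") == [["C00031"]]

    def test_no_path_is_empty_not_error(self):
        g = compound_graph(ParsedPathway(
            "p", "p", {"C1": "a", "C2": "b"},
            [Reaction("R1", ["C1"], ["C2"], False)]))
        assert all_shortest_paths(g, "C2", "C1") == []
        with pytest.raises(KeyError):
            all_shortest_paths(g, "C1", "C9")

    def test_designed_two_route_diamond(self, toy_kgml):
        kgml_dir, manifest = toy_kgml
        graphs = [
            compound_graph(parse_kgml(kgml_dir / f"{p}.xml"))
            for p in manifest["pathways"]
        ]
        g = prune_isolated(merge_graphs(graphs))
        paths = all_shortest_paths(g, "C00031", "C00422")
        assert paths == manifest["shortest_paths"]["C00031->C00422"]
        assert len(paths) == 2
        assert {len(p) for p in paths} == {9}

    def test_random_graphs_match_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 13))
            g = nx.MultiDiGraph()
            g.add_nodes_from(range(n))
            for u in range(n):
                for v in range(n):
                    if u != v and rng.random() < 0.25:
                        g.add_edge(u, v, key=f"R{u}_{v}")
            s, t = rng.choice(n, size=2, replace=False)
            assert all_shortest_paths(g, int(s), int(t)) == exhaustive_min_paths(
                g, int(s), int(t)
            )

    def test_undirected_option_ignores_direction(self):
        g = compound_graph(ParsedPathway(
            "p", "p", {"C1": "a", "C2": "b"},
            [Reaction("R1", ["C1"], ["C2"], False)]))
        assert all_shortest_paths(g, "C2", "C1", undirected=True) == [["C2", "C1"]]


class TestOverlay:
    def make_fc(self, kid_values, time_points=(0.0, 24.0)):
        kids = list(kid_values)
        lfc = np.array([kid_values[k] for k in kids], dtype=float)
        return FoldChangeTable(kids, lfc, time_points)

    def graph_one_edge(self, orthologs):
        return compound_graph(ParsedPathway(
            "p", "p", {"C1": "a", "C2": "b"},
            [Reaction("R1", ["C1"], ["C2"], False, set(orthologs))]))

    def test_single_ortholog_up(self):
        g = self.graph_one_edge({"K00001"})
        fc = self.make_fc({"K00001": [0.0, 1.3]})
        assert overlay_direction(g, fc, 24.0) == {("C1", "C2", "R1"): "up"}

    def test_absent_orthologs_unknown(self):
        g = self.graph_one_edge({"K00009"})
        fc = self.make_fc({"K00001": [0.5, 1.0]})
        assert overlay_direction(g, fc, 0.0) == {("C1", "C2", "R1"): "unknown"}

    def test_zero_mean_maps_to_unknown(self):
        g = self.graph_one_edge({"K00001", "K00002"})
        fc = self.make_fc({"K00001": [1.0, 1.0], "K00002": [-1.0, 2.0]})
        assert overlay_direction(g, fc, 0.0) == {("C1", "C2", "R1"): "unknown"}

    def test_unknown_time_point_rejected(self):
        g = self.graph_one_edge({"K00001"})
        fc = self.make_fc({"K00001": [0.5, 1.0]})
        with pytest.raises(ValueError):
            overlay_direction(g, fc, 12.0)

    def test_random_assignment_matches_loop_oracle(self, rng, toy_kgml):
        kgml_dir, manifest = toy_kgml
        graphs = [
            compound_graph(parse_kgml(kgml_dir / f"{p}.xml"))
            for p in manifest["pathways"]
        ]
        g = prune_isolated(merge_graphs(graphs))
        kos = sorted({k for *_, d in g.edges(keys=True, data=True)
                      for k in d["orthologs"]})
        present = [k for k in kos if rng.random() < 0.7]
        fc = FoldChangeTable(present, rng.normal(size=(len(present), 4)),
                             [0.0, 24.0, 48.0, 60.0])
        signs = overlay_direction(g, fc, 48.0)
        for u, v, k, data in g.edges(keys=True, data=True):
            vals = []
            for ko in data["orthologs"]:
                if ko in present:
                    vals.append(fc.lfc[present.index(ko), 2])
            if not vals:
                expected = "unknown"
            else:
                m = sum(vals) / len(vals)
                expected = "up" if m > 0 else "down" if m < 0 else "unknown"
            assert signs[(u, v, k)] == expected


class TestExportRender:
    def test_graphml_round_trip_identity(self, toy_kgml, tmp_path):
        kgml_dir, manifest = toy_kgml
        graphs = [
            compound_graph(parse_kgml(kgml_dir / f"{p}.xml"))
            for p in manifest["pathways"]
        ]
        g = prune_isolated(merge_graphs(graphs))
        path = tmp_path / "merged.graphml"
        write_compound_graph(g, path)
        assert graphs_equal(read_compound_graph(path), g)

    def test_render_exports_highlight_attribute_counts(self, toy_kgml, tmp_path):
        kgml_dir, manifest = toy_kgml
        graphs = [
            compound_graph(parse_kgml(kgml_dir / f"{p}.xml"))
            for p in manifest["pathways"]
        ]
        g = prune_isolated(merge_graphs(graphs))
        paths = manifest["shortest_paths"]["C00031->C00422"]
        img = tmp_path / "graph.png"
        gml = tmp_path / "graph.graphml"
        render(g, img, graphml_path=gml, highlight_paths=paths, layout_seed=1)
        assert img.exists()
        back = read_compound_graph(gml)
        highlighted = {n for n, d in back.nodes(data=True) if d.get("highlight")}
        assert highlighted == {n for p in paths for n in p}

    def test_render_without_overlay_runs(self, tmp_path):
        g = compound_graph(ParsedPathway(
            "p", "p", {"C1": "a", "C2": "b"},
            [Reaction("R1", ["C1"], ["C2"], False, {"K1"})]))
        render(g, tmp_path / "g.svg", graphml_path=tmp_path / "g.graphml")
        assert (tmp_path / "g.svg").exists()
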