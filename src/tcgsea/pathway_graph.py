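"""KEGG pathway maps as compound graphs.

KGML encodes a pathway gene-centrically: entries are orthologs (or
compounds), and ``reaction`` elements tie substrate and product
compounds to the ortholog entries that catalyse them.  For metabolic
reasoning the useful inversion is a *compound graph*: nodes are KEGG
compounds, and each directed edge is one (reaction, substrate, product)
triple carrying the set of KEGG Orthology IDs of its catalysing genes.
Reversible reactions contribute both directions.  Graphs from several
pathways merge by compound ID (pathway memberships unioned, duplicate
edges collapsed with ortholog sets merged), isolated compounds are
pruned, and the merged graph supports all-shortest-path queries between
compounds (e.g. glucose to triacylglycerol) plus per-time fold-change
direction overlays on the edges.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from tcgsea.expression_prep import FoldChangeTable

logger = logging.getLogger(__name__)

UP, DOWN, UNKNOWN = "up", "down", "unknown"

_SIGN_COLORS = {UP: "#2ca02c", DOWN: "#d62728", UNKNOWN: "#b0b0b0"}


@dataclass
class Reaction:
    reaction_id: str
    substrates: list
    products: list
    reversible: bool
    orthologs: set = field(default_factory=set)


@dataclass
class ParsedPathway:
    pathway_id: str
    title: str
    compounds: dict  # compound_id -> display name
    reactions: list  # list[Reaction]


def _strip_prefix(token: str) -> str:
    return token.split(":", 1)[1] if ":" in token else token


def parse_kgml(source) -> ParsedPathway:
    """Parse one KGML file into compounds and ortholog-labelled reactions.

    Reactions that reference a compound not declared as an ``entry`` of
    type ``compound`` are skipped with a warning; malformed XML raises
    ``xml.etree.ElementTree.ParseError`` (which carries the position).
    """
    tree = ET.parse(source)
    root = tree.getroot()
    pathway_id = _strip_prefix(root.get("name", ""))
    title = root.get("title", pathway_id)

    compounds: dict[str, str] = {}
    reaction_orthologs: dict[str, set] = {}
    for entry in root.findall("entry"):
        etype = entry.get("type")
        names = [_strip_prefix(n) for n in entry.get("name", "").split()]
        if etype == "compound":
            graphics = entry.find("graphics")
            label = graphics.get("name") if graphics is not None else None
            for cid in names:
                compounds.setdefault(cid, label or cid)
        elif etype in ("ortholog", "gene"):
            kos = {n for n in names if n.startswith("K")}
            for rid in entry.get("reaction", "").split():
                reaction_orthologs.setdefault(_strip_prefix(rid), set()).update(kos)

    reactions: list[Reaction] = []
    for rxn in root.findall("reaction"):
        rid = _strip_prefix(rxn.get("name", ""))
        subs = [_strip_prefix(s.get("name", "")) for s in rxn.findall("substrate")]
        prods = [_strip_prefix(p.get("name", "")) for p in rxn.findall("product")]
        missing = [c for c in subs + prods if c not in compounds]
        if missing:
            logger.warning(
                "%s: reaction %s references undeclared compound(s) %s; skipped",
                pathway_id, rid, ",".join(missing),
            )
            continue
        reactions.append(
            Reaction(
                reaction_id=rid,
                substrates=subs,
                products=prods,
                reversible=rxn.get("type") == "reversible",
                orthologs=set(reaction_orthologs.get(rid, set())),
            )
        )
    return ParsedPathway(pathway_id, title, compounds, reactions)


# ---------------------------------------------------------------------------
# graph construction


def compound_graph(parsed: ParsedPathway) -> nx.MultiDiGraph:
    """Invert a parsed pathway into a compound graph.

    One directed edge per (reaction, substrate, product) pair, keyed by
    reaction ID; reversible reactions also contribute the reverse arc.
    Compounds that appear in no reaction are kept (pruning is separate).
    """
    g = nx.MultiDiGraph(pathway_id=parsed.pathway_id)
    for cid, name in parsed.compounds.items():
        g.add_node(cid, name=name, pathways={parsed.pathway_id})
    for rxn in parsed.reactions:
        pairs = [(s, p) for s in rxn.substrates for p in rxn.products]
        if rxn.reversible:
            pairs += [(p, s) for s, p in pairs]
        for u, v in pairs:
            _add_edge(g, u, v, rxn.reaction_id, rxn.orthologs, rxn.reversible,
                      {parsed.pathway_id})
    return g


def _add_edge(g, u, v, rid, orthologs, reversible, pathways) -> None:
    if g.has_edge(u, v, key=rid):
        data = g[u][v][rid]
        data["orthologs"] = set(data["orthologs"]) | set(orthologs)
        data["reversible"] = bool(data["reversible"] or reversible)
        data["pathways"] = set(data["pathways"]) | set(pathways)
    else:
        g.add_edge(
            u, v, key=rid,
            reaction_id=rid,
            orthologs=set(orthologs),
            reversible=reversible,
            pathways=set(pathways),
        )


def merge_graphs(graphs) -> nx.MultiDiGraph:
    """Union compound graphs: nodes unified by compound ID with pathway
    memberships unioned; identical (reaction, substrate, product) edges
    collapsed with their ortholog sets merged."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("need at least one graph to merge")
    merged = nx.MultiDiGraph()
    for g in graphs:
        for cid, data in g.nodes(data=True):
            if merged.has_node(cid):
                merged.nodes[cid]["pathways"] = (
                    set(merged.nodes[cid]["pathways"]) | set(data.get("pathways", set()))
                )
            else:
                merged.add_node(
                    cid,
                    name=data.get("name", cid),
                    pathways=set(data.get("pathways", set())),
                )
        for u, v, k, data in g.edges(keys=True, data=True):
            _add_edge(merged, u, v, k, data["orthologs"], data["reversible"],
                      data["pathways"])
    return merged


def prune_isolated(g: nx.MultiDiGraph) -> nx.MultiDiGraph:
    """Drop compounds that take part in no reaction (degree 0)."""
    keep = [n for n in g.nodes if g.degree(n) > 0]
    return g.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# queries


def all_shortest_paths(g, source: str, target: str, undirected: bool = False):
    """All distinct minimum-hop compound paths from source to target.

    Returns a lexicographically sorted list of node-ID lists; an empty
    list if the target is unreachable.  ``source == target`` yields the
    single zero-length path ``[source]``.
    """
    for node in (source, target):
        if node not in g:
            raise KeyError(f"compound {node!r} is not in the graph")
    if source == target:
        return [[source]]
    h = g.to_undirected(as_view=True) if undirected else g
    try:
        paths = {tuple(p) for p in nx.all_shortest_paths(h, source, target)}
    except nx.NetworkXNoPath:
        return []
    return sorted(list(p) for p in paths)


def path_node_count(path) -> int:
    """Length convention: compounds on the path, endpoints included."""
    return len(path)


def overlay_direction(g, fc: FoldChangeTable, t: float) -> dict:
    """Sign of each edge's mean ortholog fold change at time ``t``.

    Strictly positive mean -> ``up``, strictly negative -> ``down``,
    exactly zero or no ortholog with data -> ``unknown``.  Keys are
    ``(substrate, product, reaction_id)`` triples.
    """
    times = list(fc.time_points)
    if t not in times:
        raise ValueError(f"time point {t!r} not in fold-change table {times}")
    col = times.index(t)
    lookup = {k: fc.lfc[i, col] for i, k in enumerate(fc.kids)}
    signs = {}
    for u, v, k, data in g.edges(keys=True, data=True):
        vals = [lookup[ko] for ko in data["orthologs"] if ko in lookup]
        if not vals:
            signs[(u, v, k)] = UNKNOWN
        else:
            mean = float(np.mean(vals))
            signs[(u, v, k)] = UP if mean > 0 else DOWN if mean < 0 else UNKNOWN
    return signs


def annotate_overlay(g, fc: FoldChangeTable, times=None) -> None:
    """Store per-time direction signs as edge attributes ``sign_<T>h``."""
    for t in (fc.time_points if times is None else times):
        signs = overlay_direction(g, fc, t)
        for (u, v, k), s in signs.items():
            g[u][v][k][f"sign_{t:g}h"] = s


# ---------------------------------------------------------------------------
# GraphML round trip

_SET_NODE_ATTRS = ("pathways",)
_SET_EDGE_ATTRS = ("pathways", "orthologs")


def write_compound_graph(g, path) -> None:
    """GraphML export; set-valued attributes are serialised as sorted
    space-joined strings so the file stays schema-plain."""
    out = nx.MultiDiGraph()
    for n, data in g.nodes(data=True):
        flat = dict(data)
        for attr in _SET_NODE_ATTRS:
            if attr in flat:
                flat[attr] = " ".join(sorted(flat[attr]))
        out.add_node(n, **flat)
    for u, v, k, data in g.edges(keys=True, data=True):
        flat = dict(data)
        for attr in _SET_EDGE_ATTRS:
            if attr in flat:
                flat[attr] = " ".join(sorted(flat[attr]))
        out.add_edge(u, v, key=k, **flat)
    nx.write_graphml(out, path)


def read_compound_graph(path) -> nx.MultiDiGraph:
    raw = nx.read_graphml(path, force_multigraph=True)
    g = nx.MultiDiGraph(**raw.graph)
    for n, data in raw.nodes(data=True):
        parsed = dict(data)
        for attr in _SET_NODE_ATTRS:
            if attr in parsed:
                parsed[attr] = set(str(parsed[attr]).split())
        g.add_node(n, **parsed)
    for u, v, k, data in raw.edges(keys=True, data=True):
        parsed = dict(data)
        for attr in _SET_EDGE_ATTRS:
            if attr in parsed:
                parsed[attr] = set(str(parsed[attr]).split()) if parsed[attr] else set()
        parsed.pop("reversible", None)
        g.add_edge(u, v, key=k,
                   reversible=bool(data.get("reversible", False)), **parsed)
    return g


def graphs_equal(a, b) -> bool:
    """Attribute-level equality of two compound graphs."""
    if set(a.nodes) != set(b.nodes):
        return False
    for n in a.nodes:
        if dict(a.nodes[n]) != dict(b.nodes[n]):
            return False
    ea = {(u, v, k): data for u, v, k, data in a.edges(keys=True, data=True)}
    eb = {(u, v, k): data for u, v, k, data in b.edges(keys=True, data=True)}
    if ea.keys() != eb.keys():
        return False
    return all(ea[k] == eb[k] for k in ea)


# ---------------------------------------------------------------------------
# rendering


def render(
    g,
    out_image,
    graphml_path=None,
    overlay: dict | None = None,
    highlight_paths=None,
    layout_seed: int = 0,
):
    """Draw the compound graph and export a machine-readable copy.

    Edges are coloured by the overlay sign (green up, red down, gray
    unknown or no overlay); nodes on ``highlight_paths`` are emphasised
    and carry a ``highlight`` attribute in the exported GraphML.  The
    layout is deterministic for a fixed ``layout_seed``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = g.copy()
    highlighted = {n for p in (highlight_paths or []) for n in p}
    for n in g.nodes:
        g.nodes[n]["highlight"] = n in highlighted
    if graphml_path is not None:
        write_compound_graph(g, graphml_path)

    pos = nx.spring_layout(g, seed=layout_seed)
    fig, ax = plt.subplots(figsize=(9, 9))
    edge_colors = []
    for u, v, k in g.edges(keys=True):
        sign = (overlay or {}).get((u, v, k), UNKNOWN)
        edge_colors.append(_SIGN_COLORS[sign])
    node_colors = [
        "#ff7f0e" if g.nodes[n]["highlight"] else "#1f77b4" for n in g.nodes
    ]
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=160, node_color=node_colors)
    nx.draw_networkx_edges(g, pos, ax=ax, edge_color=edge_colors, arrows=True,
                           arrowsize=8, connectionstyle="arc3,rad=0.08")
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=6)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(out_image, dpi=150)
    plt.close(fig)
    return g
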