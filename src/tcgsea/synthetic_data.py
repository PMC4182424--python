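"""Synthetic inputs with the statistical shape the analysis assumes.

Two generators cover the two halves of the pipeline.

``simulate_rpkm`` emulates a replicate-free two-condition RNA-Seq time
course: heavy-tailed (log-normal) control RPKM; treatment equal to
control times ``2**lfc``; a fraction of all-zero sequences (to exercise
the zero filter); a fraction of K IDs carried by several sequences (to
exercise the per-ortholog averaging).  Background genes draw one
time-constant log2 fold change per gene, ``lfc ~ Normal(0, sd)`` — in
unreplicated data the dominant source of apparent fold change is a
gene-level effect, and the resampling test's calibration rests on the
strong cross-time dependence this produces (see docs/methods.md).
Genes of a planted set additionally follow a mean trajectory delta(t),
giving known ground truth for power studies.

``make_toy_kgml`` emits small schema-valid KGML files together with a
manifest of ground-truth entity counts and all shortest paths between
designated compounds, the latter computed here by exhaustive simple-
path enumeration so downstream graph code can be checked against an
independent answer.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tcgsea.enrichment import GeneSet
from tcgsea.expression_prep import RpkmTable
from tcgsea.pathway_graph import Reaction

DEFAULT_TIME_POINTS = (0.0, 24.0, 48.0, 60.0)


# ---------------------------------------------------------------------------
# trajectories


def constant_trajectory(delta: float):
    """Same shift at every time point."""
    return lambda t: delta


def linear_trajectory(slope: float):
    """Shift growing linearly with time: delta(t) = slope * t (t in hours)."""
    return lambda t: slope * t


def late_onset_trajectory(delta: float, onset: float = 48.0):
    """No shift until ``onset`` hours, then a constant shift — the
    time-lag pattern that makes whole-course tests lose power."""
    return lambda t: delta if t >= onset else 0.0


@dataclass(frozen=True)
class PlantedSet:
    """A gene set given a known mean fold-change trajectory."""

    set_id: str
    size: int
    trajectory: object  # callable t -> delta, or per-time sequence

    def deltas(self, time_points) -> np.ndarray:
        if callable(self.trajectory):
            return np.array([float(self.trajectory(t)) for t in time_points])
        arr = np.asarray(self.trajectory, dtype=float)
        if arr.shape != (len(time_points),):
            raise ValueError(
                f"planted set {self.set_id!r}: trajectory length {arr.size} "
                f"!= {len(time_points)} time points"
            )
        return arr


@dataclass
class SimulationConfig:
    """Study-shaped defaults: four time points (0/24/48/60 h), log-normal
    RPKM around ~50, background fold-change SD 0.5 log2 units, 5% all-zero
    sequences, 10% of K IDs represented by two sequences."""

    n_genes: int = 1000
    time_points: tuple = DEFAULT_TIME_POINTS
    background_lfc_sd: float = 0.5
    planted_sets: tuple = ()
    rpkm_scale: float = 50.0
    rpkm_sigma: float = 1.5
    zero_fraction: float = 0.05
    duplicate_kid_fraction: float = 0.1
    time_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_sets = tuple(self.planted_sets)
        planted_total = sum(p.size for p in self.planted_sets)
        if self.n_genes < planted_total:
            raise ValueError(
                f"n_genes={self.n_genes} cannot hold {planted_total} planted genes"
            )
        if not self.background_lfc_sd > 0:
            raise ValueError("background_lfc_sd must be positive")
        for name in ("zero_fraction", "duplicate_kid_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if len(self.time_points) < 1 or np.any(np.diff(self.time_points) <= 0):
            raise ValueError("time_points must be non-empty and strictly increasing")


def simulate_rpkm(config: SimulationConfig):
    """Generate an ``RpkmTable`` plus a ground-truth manifest.

    The manifest records every gene's true log2 fold-change vector and
    planted-set membership, which sequences were zeroed, and which K IDs
    were given a duplicate sequence.  Identical config (including seed)
    gives byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    tp = np.asarray(config.time_points, dtype=float)
    n, T = config.n_genes, len(tp)
    kids = np.array([f"K{i + 1:05d}" for i in range(n)], dtype=object)

    membership = np.full(n, "", dtype=object)
    perm = rng.permutation(n)
    cursor = 0
    memberships: dict[str, list] = {}
    for ps in config.planted_sets:
        sel = perm[cursor:cursor + ps.size]
        cursor += ps.size
        membership[sel] = ps.set_id
        memberships[ps.set_id] = sorted(kids[sel].tolist())

    gene_effect = rng.normal(0.0, config.background_lfc_sd, size=n)
    lfc = np.repeat(gene_effect[:, None], T, axis=1)
    for ps in config.planted_sets:
        rows = membership == ps.set_id
        lfc[rows] += ps.deltas(tp)[None, :]
    if config.time_jitter_sd > 0:
        lfc += rng.normal(0.0, config.time_jitter_sd, size=(n, T))

    def draw_control(size):
        return rng.lognormal(np.log(config.rpkm_scale), config.rpkm_sigma, size=size)

    seq_ids = [f"seq{i + 1:05d}" for i in range(n)]
    seq_kids = list(kids)
    control = draw_control((n, T))
    treatment = control * np.exp2(lfc)

    # duplicate sequences for a fraction of K IDs (same true lfc,
    # independent expression level)
    n_dup = int(round(config.duplicate_kid_fraction * n))
    dup_rows = rng.choice(n, size=n_dup, replace=False) if n_dup else np.empty(0, int)
    dup_control = draw_control((n_dup, T))
    dup_treatment = dup_control * np.exp2(lfc[dup_rows])
    for j, i in enumerate(dup_rows):
        seq_ids.append(f"seq{i + 1:05d}b")
        seq_kids.append(kids[i])
    control = np.vstack([control, dup_control])
    treatment = np.vstack([treatment, dup_treatment])

    n_seq = len(seq_ids)
    n_zero = int(round(config.zero_fraction * n_seq))
    zero_rows = (
        rng.choice(n_seq, size=n_zero, replace=False) if n_zero else np.empty(0, int)
    )
    control[zero_rows] = 0.0
    treatment[zero_rows] = 0.0

    table = RpkmTable(
        np.array(seq_ids, dtype=object),
        np.array(seq_kids, dtype=object),
        control,
        treatment,
        tp,
    )
    truth = {
        "kids": kids.tolist(),
        "true_lfc": lfc.tolist(),
        "time_points": tp.tolist(),
        "memberships": memberships,
        "zeroed_sequences": sorted(np.array(seq_ids, dtype=object)[zero_rows].tolist()),
        "duplicated_kids": sorted(kids[dup_rows].tolist()),
        "seed": config.seed,
    }
    return table, truth


def make_gene_sets(
    truth: dict,
    n_background: int = 0,
    set_size: int = 20,
    seed: int = 0,
    background_prefix: str = "bg",
) -> list:
    """Gene sets for a simulated table: the planted sets (from the truth
    manifest) followed by ``n_background`` random sets of ``set_size``
    K IDs drawn without replacement from all simulated genes."""
    sets = [
        GeneSet(set_id, f"planted set {set_id}", tuple(members))
        for set_id, members in truth["memberships"].items()
    ]
    rng = np.random.default_rng(seed)
    kids = np.asarray(truth["kids"], dtype=object)
    for i in range(n_background):
        members = rng.choice(kids, size=set_size, replace=False)
        sets.append(
            GeneSet(
                f"{background_prefix}{i + 1:04d}",
                f"random background set {i + 1}",
                tuple(sorted(members.tolist())),
            )
        )
    return sets


# ---------------------------------------------------------------------------
# toy KGML


@dataclass
class ToyPathway:
    pathway_id: str
    title: str
    compounds: dict  # compound_id -> name
    reactions: list = field(default_factory=list)  # list[Reaction]


def default_toy_pathways() -> list:
    """A three-pathway miniature of central carbon + glycerolipid
    metabolism, designed so that glucose (C00031) to triacylglycerol
    (C00422) has exactly two equally short routes (glycerone vs
    glycerol-3-phosphate branch), compounds are shared across 1, 2 or 3
    pathways, and one declared compound takes part in no reaction."""
    glycolysis = ToyPathway(
        "toy00010",
        "Glycolysis (toy)",
        {
            "C00031": "D-Glucose",
            "C00002": "ATP",
            "C00008": "ADP",
            "C00668": "alpha-D-Glucose 6-phosphate",
            "C05345": "beta-D-Fructose 6-phosphate",
            "C00354": "D-Fructose 1,6-bisphosphate",
            "C00111": "Glycerone phosphate",
            "C00118": "D-Glyceraldehyde 3-phosphate",
            "C00022": "Pyruvate",
        },
        [
            Reaction("R01786", ["C00031", "C00002"], ["C00668", "C00008"], False,
                     {"K00844", "K12407"}),
            Reaction("R02740", ["C00668"], ["C05345"], True, {"K01810"}),
            Reaction("R04779", ["C05345"], ["C00354"], False, {"K00850"}),
            Reaction("R01068", ["C00354"], ["C00111"], True, {"K01623"}),
            Reaction("R01070", ["C00354"], ["C00118"], True, {"K01623"}),
            Reaction("R01015", ["C00111"], ["C00118"], True, {"K01803"}),
            Reaction("R00200", ["C00118"], ["C00022"], False, {"K00873"}),
        ],
    )
    glycerolipid = ToyPathway(
        "toy00561",
        "Glycerolipid metabolism (toy)",
        {
            "C00111": "Glycerone phosphate",
            "C00184": "Glycerone",
            "C00093": "sn-Glycerol 3-phosphate",
            "C00116": "Glycerol",
            "C00416": "Phosphatidate",
            "C00641": "1,2-Diacyl-sn-glycerol",
            "C00422": "Triacylglycerol",
            "C00022": "Pyruvate",
            "C00024": "Acetyl-CoA",
        },
        [
            Reaction("R09001", ["C00111"], ["C00184"], False, {"K00863"}),
            Reaction("R00842", ["C00111"], ["C00093"], True, {"K00057"}),
            Reaction("R09002", ["C00184"], ["C00416"], False, {"K00631"}),
            Reaction("R00851", ["C00093"], ["C00416"], False, {"K00629"}),
            Reaction("R09003", ["C00184"], ["C00116"], False, {"K00005"}),
            Reaction("R00847", ["C00116"], ["C00093"], False, {"K00864"}),
            Reaction("R02239", ["C00416"], ["C00641"], False, {"K01080"}),
            Reaction("R02250", ["C00641"], ["C00422"], False, {"K00635"}),
            Reaction("R00209", ["C00022"], ["C00024"], False, {"K00161"}),
        ],
    )
    tca = ToyPathway(
        "toy00020",
        "Pyruvate and TCA entry (toy)",
        {
            "C00022": "Pyruvate",
            "C00036": "Oxaloacetate",
            "C00149": "(S)-Malate",
            "C00008": "ADP",
            "C00002": "ATP",
            "C00024": "Acetyl-CoA",
            "C00080": "H+",  # declared but never reacts: exercises pruning
        },
        [
            Reaction("R00341", ["C00022"], ["C00036"], False, {"K01958"}),
            Reaction("R00342", ["C00036"], ["C00149"], True, {"K00025"}),
            Reaction("R00086", ["C00008"], ["C00002"], False, {"K02132"}),
            Reaction("R00209", ["C00022"], ["C00024"], False, {"K00163"}),
        ],
    )
    return [glycolysis, glycerolipid, tca]


def _directed_pairs(rxn: Reaction):
    pairs = [(s, p) for s in rxn.substrates for p in rxn.products]
    if rxn.reversible:
        pairs += [(p, s) for s, p in pairs]
    return pairs


def _enumerate_shortest(edges, source, target):
    """All minimum-hop simple paths by exhaustive DFS over the directed
    (substrate, product) pair set — independent of any graph library."""
    adjacency: dict[str, set] = {}
    for u, v in edges:
        adjacency.setdefault(u, set()).add(v)
    if source == target:
        return [[source]]
    best: list = []
    best_len = [float("inf")]

    def walk(node, path):
        if len(path) > best_len[0]:
            return
        for nxt in sorted(adjacency.get(node, ())):
            if nxt in path:
                continue
            if nxt == target:
                full = path + [nxt]
                if len(full) < best_len[0]:
                    best_len[0] = len(full)
                    best.clear()
                if len(full) == best_len[0]:
                    best.append(full)
            else:
                walk(nxt, path + [nxt])

    walk(source, [source])
    return sorted(best)


def _pathway_to_kgml(pw: ToyPathway) -> ET.ElementTree:
    root = ET.Element(
        "pathway",
        name=f"path:{pw.pathway_id}",
        org="ko",
        number=pw.pathway_id[-5:],
        title=pw.title,
    )
    eid = 0
    for cid, name in pw.compounds.items():
        eid += 1
        entry = ET.SubElement(
            root, "entry", id=str(eid), name=f"cpd:{cid}", type="compound"
        )
        ET.SubElement(entry, "graphics", name=name, type="circle")
    for rxn in pw.reactions:
        if rxn.orthologs:
            eid += 1
            ET.SubElement(
                root, "entry", id=str(eid),
                name=" ".join(f"ko:{k}" for k in sorted(rxn.orthologs)),
                type="ortholog", reaction=f"rn:{rxn.reaction_id}",
            )
    for i, rxn in enumerate(pw.reactions, 1):
        el = ET.SubElement(
            root, "reaction", id=str(i), name=f"rn:{rxn.reaction_id}",
            type="reversible" if rxn.reversible else "irreversible",
        )
        for s in rxn.substrates:
            ET.SubElement(el, "substrate", id="0", name=f"cpd:{s}")
        for p in rxn.products:
            ET.SubElement(el, "product", id="0", name=f"cpd:{p}")
    return ET.ElementTree(root)


def make_toy_kgml(
    pathways=None,
    out_dir=None,
    path_queries=(("C00031", "C00422"),),
):
    """Write KGML files for toy pathways and return a ground-truth manifest.

    The manifest holds per-pathway and merged entity counts, pathway-
    membership tallies, pruned counts, and — for each query pair — all
    shortest paths obtained by exhaustive enumeration at generation time.
    If ``out_dir`` is given, KGML files and ``manifest.json`` are written
    there.
    """
    pathways = list(default_toy_pathways() if pathways is None else pathways)
    for pw in pathways:
        for rxn in pw.reactions:
            undef = [c for c in rxn.substrates + rxn.products
                     if c not in pw.compounds]
            if undef:
                raise ValueError(
                    f"{pw.pathway_id}: reaction {rxn.reaction_id} references "
                    f"undefined compound(s) {','.join(undef)}"
                )

    per_pathway = {}
    merged_edges: set = set()
    membership: dict[str, set] = {}
    for pw in pathways:
        edges = {
            (u, v, rxn.reaction_id)
            for rxn in pw.reactions
            for u, v in _directed_pairs(rxn)
        }
        per_pathway[pw.pathway_id] = {
            "compounds": len(pw.compounds),
            "reactions": len(pw.reactions),
            "directed_edges": len(edges),
        }
        merged_edges |= edges
        for cid in pw.compounds:
            membership.setdefault(cid, set()).add(pw.pathway_id)

    counts: dict[int, int] = {}
    for cid, pws in membership.items():
        counts[len(pws)] = counts.get(len(pws), 0) + 1
    connected = {u for u, _, _ in merged_edges} | {v for _, v, _ in merged_edges}
    pair_set = {(u, v) for u, v, _ in merged_edges}
    manifest = {
        "pathways": per_pathway,
        "merged": {
            "nodes": len(membership),
            "edges": len(merged_edges),
            "membership_counts": {str(k): v for k, v in sorted(counts.items())},
        },
        "pruned": {
            "nodes": len(connected),
            "edges": len(merged_edges),
        },
        "shortest_paths": {
            f"{s}->{t}": _enumerate_shortest(pair_set, s, t)
            for s, t in path_queries
        },
    }

    files = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pw in pathways:
            path = out_dir / f"{pw.pathway_id}.xml"
            tree = _pathway_to_kgml(pw)
            ET.indent(tree)
            tree.write(path, xml_declaration=True, encoding="unicode")
            files.append(path)
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    manifest["files"] = [str(f) for f in files]
    return manifest
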