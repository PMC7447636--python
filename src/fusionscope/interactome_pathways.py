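"""Maximal foreseeable interactor sets and pathway-hierarchy mapping.

The *maximal foreseeable interactor set* of a fusion is the union of the
experimentally validated physical interactors of both wild-type partners,
minus the partners themselves — an upper bound on the fusion protein's
plausible interaction effects. Pathway terms live in a rooted DAG
(parent -> child edges, unit weight); each term's depth is its shortest
distance to any root, computed with Dijkstra's algorithm (which reduces to
BFS at unit weight — the equivalence is tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io_formats import InteractionEdge, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Interactor sets
# ---------------------------------------------------------------------------


def supported_adjacency(edges: list[InteractionEdge]) -> dict[str, set[str]]:
    """Adjacency over edges that are physical AND experimentally supported."""
    adj: dict[str, set[str]] = {}
    n_dropped = 0
    for e in edges:
        if not e.is_supported:
            n_dropped += 1
            continue
        adj.setdefault(e.protein_a, set()).add(e.protein_b)
        adj.setdefault(e.protein_b, set()).add(e.protein_a)
    if n_dropped:
        logger.info("supported_adjacency: discarded %d non-physical/non-experimental edge(s)", n_dropped)
    return adj


def build_interactor_set(gene5: str, gene3: str, adjacency: dict[str, set[str]]) -> set[str]:
    """Union of both partners' supported neighbors, excluding the partners.

    A partner absent from the network contributes nothing (not an error).
    """
    out = set(adjacency.get(gene5, ())) | set(adjacency.get(gene3, ()))
    out.discard(gene5)
    out.discard(gene3)
    return out


def interactor_sets(fusions: pd.DataFrame, edges: list[InteractionEdge]) -> dict[int, set[str]]:
    """Per-fusion interactor sets, keyed by the fusion table index."""
    adj = supported_adjacency(edges)
    return {
        idx: build_interactor_set(row["gene5"], row["gene3"], adj)
        for idx, row in fusions.iterrows()
    }


# ---------------------------------------------------------------------------
# Pathway DAG
# ---------------------------------------------------------------------------


@dataclass
class PathwayDAG:
    """Rooted pathway hierarchy with gene annotations at all levels."""

    graph: nx.DiGraph  # parent -> child
    annotations: pd.DataFrame  # gene_id, pathway_id

    @classmethod
    def from_tables(cls, edges: pd.DataFrame, annotations: pd.DataFrame) -> "PathwayDAG":
        g = nx.DiGraph()
        for r in edges.itertuples(index=False):
            g.add_edge(r.parent, r.child)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("pathway hierarchy contains a cycle")
        return cls(graph=g, annotations=annotations)

    @property
    def roots(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    def lowest_level_terms(self) -> set[str]:
        """Leaf terms (no children) — the lowest level of the hierarchy."""
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def genes_of(self, pathway: str) -> set[str]:
        a = self.annotations
        return set(a.loc[a["pathway_id"] == pathway, "gene_id"])


def root_distances(dag: PathwayDAG, max_depth: int | None = None) -> dict[str, int]:
    """Shortest unit-weight distance from every term to its nearest root.

    Implemented with multi-source Dijkstra from the roots (weight 1 on every
    edge; a term's minimum link count up to a root equals the root's shortest
    path down to it). Unreachable nodes are flagged and omitted, surfacing a
    broken hierarchy rather than hiding it.
    """
    dist = nx.multi_source_dijkstra_path_length(dag.graph, set(dag.roots))
    if max_depth is not None:
        dist = {n: d for n, d in dist.items() if d <= max_depth}
    missing = set(dag.graph.nodes) - set(dist) if max_depth is None else set()
    if missing:
        logger.warning("root_distances: %d node(s) cannot reach a root: %s",
                       len(missing), sorted(missing)[:5])
    return dict(dist)


# ---------------------------------------------------------------------------
# Pathway loads
# ---------------------------------------------------------------------------


def pathway_loads(
    sets: dict[int, set[str]],
    dag: PathwayDAG,
    fusion_projects: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-pathway interactor burden.

    Two variants are emitted side by side: ``n_interacting_fusions`` (count
    of fusions with at least one interactor annotated to the pathway) and
    ``summed_load`` (for each protein in the pathway, the number of fusions
    whose interactor set contains it, summed over proteins). When fusion
    projects are supplied, ``normalized`` rescales the summed load to [0, 1]
    within each project (1 = the project's most-interacting pathway).
    """
    gene_pathways: dict[str, set[str]] = {}
    for r in dag.annotations.itertuples(index=False):
        gene_pathways.setdefault(r.gene_id, set()).add(r.pathway_id)

    pathways = sorted(set(dag.annotations["pathway_id"]))
    rows = []
    for pw in pathways:
        genes = dag.genes_of(pw)
        n_fus = sum(1 for s in sets.values() if s & genes)
        load = sum(sum(1 for s in sets.values() if g in s) for g in genes)
        rows.append({"pathway_id": pw, "n_interacting_fusions": n_fus, "summed_load": load})
    df = pd.DataFrame(rows, columns=["pathway_id", "n_interacting_fusions", "summed_load"])

    if fusion_projects is not None:
        proj_rows = []
        for project in sorted(fusion_projects.dropna().unique()):
            idxs = [i for i in sets if i in fusion_projects.index and fusion_projects.get(i) == project]
            sub = {i: sets[i] for i in idxs}
            for pw in pathways:
                genes = dag.genes_of(pw)
                load = sum(sum(1 for s in sub.values() if g in s) for g in genes)
                n_fus = sum(1 for s in sub.values() if s & genes)
                proj_rows.append(
                    {"project": project, "pathway_id": pw,
                     "n_interacting_fusions": n_fus, "summed_load": load}
                )
        proj = pd.DataFrame(
            proj_rows, columns=["project", "pathway_id", "n_interacting_fusions", "summed_load"]
        )
        if len(proj):
            maxima = proj.groupby("project")["summed_load"].transform("max")
            proj["normalized"] = (proj["summed_load"] / maxima.where(maxima > 0)).fillna(0.0)
        df = df.merge(
            proj.pivot(index="pathway_id", columns="project", values="normalized").add_prefix("norm_"),
            left_on="pathway_id",
            right_index=True,
            how="left",
        )
    return df


def census_enrichment(
    sets: dict[int, set[str]],
    census: set[str],
    top_k: tuple[int, ...] = (100, 10),
    categories: pd.Series | None = None,
) -> dict:
    """Fraction of unique interactors found in a cancer gene census.

    Reported overall, restricted to the top-k most-interacting fusions
    (ranked by interactor-set size), and per fusion category when given.
    An empty interactor universe yields None rather than 0.
    """
    def _prop(subset: dict[int, set[str]]) -> float | None:
        universe = set().union(*subset.values()) if subset else set()
        if not universe:
            return None
        return len(universe & census) / len(universe)

    out: dict = {"overall": _prop(sets)}
    ranked = sorted(sets, key=lambda i: (-len(sets[i]), i))
    for k in top_k:
        out[f"top_{k}"] = _prop({i: sets[i] for i in ranked[:k]})
    if categories is not None:
        out["by_category"] = {
            cat: _prop({i: sets[i] for i in sets if categories.get(i) == cat})
            for cat in sorted(categories.dropna().unique())
        }
    return out
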