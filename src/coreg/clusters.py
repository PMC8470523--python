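"""From significant eVariants to candidate regions, the H4 graph and cliques.

Variants regulating two or more eGenes are merged into candidate regions
when consecutive variants lie less than 2 Mbp apart; within each region all
gene pairs are colocalized; pairs with H4 >= 0.8 form an undirected graph
whose maximal cliques (size >= 2) are the regulatory clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

H4_CUT = 0.8
MERGE_BP = 2_000_000
NODE_CAP = 100


@dataclass
class CandidateRegion:
    region_id: str
    chrom: str
    start: int  # 0-based half-open span over member variant positions
    end: int
    member_variants: set = field(default_factory=set)
    member_genes: set = field(default_factory=set)


@dataclass
class RegulatoryCluster:
    tissue: str | int
    region_id: str
    gene_ids: frozenset
    edges: list = field(default_factory=list)  # (gene_a, gene_b, h4)

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    @property
    def min_h4(self) -> float:
        return min(h for _, _, h in self.edges) if self.edges else float("nan")

    @property
    def mean_h4(self) -> float:
        return sum(h for _, _, h in self.edges) / len(self.edges) if self.edges else float("nan")


def find_candidate_regions(
    evariants: pd.DataFrame, variants: pd.DataFrame, merge_bp: int = MERGE_BP
) -> list[CandidateRegion]:
    """Merge multi-eGene variants into candidate co-regulation regions.

    ``evariants`` holds significant (gene_id, variant_id) calls; ``variants``
    supplies coordinates.  Only variants regulating >= 2 distinct eGenes
    qualify; consecutive qualifying variants on one chromosome merge while
    the gap is strictly below ``merge_bp`` (a gap of exactly 2 Mbp starts a
    new region).
    """
    if evariants.empty:
        return []
    gene_sets = evariants.groupby("variant_id")["gene_id"].agg(set)
    gene_sets = gene_sets[gene_sets.map(len) >= 2]
    if gene_sets.empty:
        return []
    coords = variants.set_index("id").loc[list(gene_sets.index), ["chrom", "pos"]]
    table = pd.DataFrame(
        {"variant_id": gene_sets.index, "chrom": coords["chrom"].to_numpy(),
         "pos": coords["pos"].to_numpy(), "genes": gene_sets.to_numpy()}
    ).sort_values(["chrom", "pos"], kind="stable")
    regions: list[CandidateRegion] = []
    current: CandidateRegion | None = None
    last_pos = None
    for row in table.itertuples(index=False):
        pos0 = row.pos - 1
        if current is None or row.chrom != current.chrom or pos0 - last_pos >= merge_bp:
            current = CandidateRegion(
                region_id=f"region_{len(regions)}",
                chrom=row.chrom, start=pos0, end=pos0 + 1,
            )
            regions.append(current)
        current.member_variants.add(row.variant_id)
        current.member_genes.update(row.genes)
        current.end = pos0 + 1
        last_pos = pos0
    return regions


def build_graph(records, h4_cut: float = H4_CUT) -> nx.Graph:
    """Undirected co-regulation graph: edge iff H4 >= h4_cut (untested pairs absent)."""
    g = nx.Graph()
    for rec in records:
        if rec.no_overlap:
            continue
        if rec.pp4 >= h4_cut:
            g.add_edge(rec.gene_a, rec.gene_b, h4=rec.pp4)
    return g


def enumerate_cliques(graph: nx.Graph, node_cap: int = NODE_CAP) -> list[tuple]:
    """Maximal cliques of size >= 2, each sorted, in lexicographic order.

    Bron-Kerbosch with pivoting via networkx; a node cap guards against
    pathological regions (real candidate regions hold a handful of genes).
    """
    if graph.number_of_nodes() > node_cap:
        raise ValueError(
            f"co-regulation graph has {graph.number_of_nodes()} nodes "
            f"(cap {node_cap}); split the region or raise the cap"
        )
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) >= 2]
    return sorted(cliques)


def clusters_from_records(
    records, tissue: str | int, region_id: str = "", h4_cut: float = H4_CUT
) -> list[RegulatoryCluster]:
    """Cliques plus a re-audit that every within-clique pair has H4 >= h4_cut."""
    graph = build_graph(records, h4_cut)
    h4 = {frozenset({r.gene_a, r.gene_b}): r.pp4 for r in records if not r.no_overlap}
    out = []
    for clique in enumerate_cliques(graph):
        edges = []
        for a, b in combinations(clique, 2):
            val = h4.get(frozenset({a, b}))
            if val is None or val < h4_cut:
                raise AssertionError(
                    f"clique {clique} contains pair ({a}, {b}) with H4 "
                    f"{val} below {h4_cut}: graph/record mismatch"
                )
            edges.append((a, b, val))
        out.append(
            RegulatoryCluster(tissue=tissue, region_id=region_id, gene_ids=frozenset(clique), edges=edges)
        )
    return out


@dataclass
class ClusterCatalog:
    """Per-tissue clusters, the deduplicated gene-set catalog, and sharing counts."""

    per_tissue: dict = field(default_factory=dict)  # tissue -> list[RegulatoryCluster]

    @property
    def tissues(self) -> list:
        return list(self.per_tissue)

    def unique_gene_sets(self, tissues=None) -> set[frozenset]:
        """Distinct gene sets; optionally restricted to a tissue subset."""
        keep = self.per_tissue if tissues is None else {t: self.per_tissue[t] for t in tissues}
        return {c.gene_ids for cl in keep.values() for c in cl}

    def shared_count(self, tissue_a, tissue_b) -> int:
        """Clusters of tissue_a shared with tissue_b by subset-or-equal matching.

        A cluster in one tissue that appears with additional genes in the
        other still counts; each tissue_a cluster contributes at most once.
        """
        sets_b = [c.gene_ids for c in self.per_tissue.get(tissue_b, [])]
        n = 0
        for ca in self.per_tissue.get(tissue_a, []):
            if any(ca.gene_ids <= cb or cb <= ca.gene_ids for cb in sets_b):
                n += 1
        return n

    def sharing_matrix(self) -> pd.DataFrame:
        t = self.tissues
        return pd.DataFrame(
            [[self.shared_count(a, b) for b in t] for a in t], index=t, columns=t
        )

    def size_histograms(self) -> pd.DataFrame:
        rows = []
        for t, clusters in self.per_tissue.items():
            counts: dict[int, int] = {}
            for c in clusters:
                counts[c.size] = counts.get(c.size, 0) + 1
            for size, count in sorted(counts.items()):
                rows.append({"tissue": t, "size": size, "n_clusters": count})
        return pd.DataFrame(rows, columns=["tissue", "size", "n_clusters"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, clusters in self.per_tissue.items():
            for c in clusters:
                rows.append(
                    {
                        "tissue": t,
                        "region_id": c.region_id,
                        "size": c.size,
                        "genes": ",".join(sorted(c.gene_ids)),
                        "min_h4": c.min_h4,
                        "mean_h4": c.mean_h4,
                    }
                )
        return pd.DataFrame(
            rows, columns=["tissue", "region_id", "size", "genes", "min_h4", "mean_h4"]
        )


def dedupe_and_compare(per_tissue: dict) -> ClusterCatalog:
    """Assemble the cross-tissue catalog from per-tissue cluster lists."""
    return ClusterCatalog(per_tissue=dict(per_tissue))
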