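"""Construction of the directed motif-motif interaction network.

Nodes are motifs with a significant combined activity change (|z| above a
threshold, 2.0 by default). A directed edge A -> B is drawn when a regulator
gene known to bind motif B is a predicted target of motif A: the gene's
best-promoter combined probability product exceeds the edge threshold
(defaults 0.35 for human, 0.15 for mouse). Edges are keyed by the regulator
gene, so a gene bound by several motifs yields one annotated edge per
(source, target) pair; self-loops (a motif targeting its own regulator) are
retained. Nodes left without any retained interaction are pruned to a
fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

DEFAULT_Z_THRESHOLD = 2.0
EDGE_THRESHOLDS = {"human": 0.35, "mouse": 0.15}


@dataclass
class MotifNetwork:
    graph: nx.MultiDiGraph
    z_threshold: float
    edge_threshold: float
    species: str | None = None

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, gene, data["probability_product"])
            for u, v, gene, data in sorted(self.graph.edges(keys=True, data=True))
        ]
        return pd.DataFrame(
            rows, columns=["motif_a", "motif_b", "regulator_gene", "probability_product"]
        )

    def node_table(self) -> pd.DataFrame:
        rows = [(m, self.graph.nodes[m]["z"]) for m in sorted(self.graph.nodes)]
        return pd.DataFrame(rows, columns=["motif", "z"])


def build_network(
    zscores: pd.DataFrame,
    p_comb: pd.DataFrame,
    reg_map: pd.DataFrame,
    promoter_gene_map: pd.Series,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    edge_threshold: float = 0.35,
    species: str | None = None,
) -> MotifNetwork:
    """Apply the node and edge rules and prune isolated motifs.

    Parameters
    ----------
    zscores
        Per-motif table with a ``z`` column (index = motif).
    p_comb
        Motifs x promoters combined target probabilities.
    reg_map
        (motif, regulator_gene) pairs: which genes encode regulators binding
        each motif.
    promoter_gene_map
        Promoter -> gene assignment used to lift promoter posteriors to
        gene level (best promoter per gene).
    """
    if zscores.empty:
        raise ValueError("no z-scores supplied")
    if z_threshold <= 0 or edge_threshold <= 0:
        raise ValueError("thresholds must be positive")
    z = zscores["z"] if "z" in getattr(zscores, "columns", []) else zscores

    g = nx.MultiDiGraph()
    candidates = z.index[z.abs() > z_threshold]
    for motif in candidates:
        g.add_node(motif, z=float(z[motif]))

    # promoters of each regulator gene, restricted to the scored universe
    genes = promoter_gene_map.reindex(p_comb.columns).dropna()
    promoters_of = genes.groupby(genes.values).groups

    for source in candidates:
        if source not in p_comb.index:
            continue
        row = p_comb.loc[source]
        for _, rec in reg_map.iterrows():
            target_motif, gene = rec["motif"], rec["regulator_gene"]
            if target_motif not in g:
                continue
            proms = promoters_of.get(gene)
            if proms is None:
                continue
            best = row[list(proms)].max()
            if pd.notna(best) and best > edge_threshold:
                g.add_edge(source, target_motif, key=gene, probability_product=float(best))

    net = MotifNetwork(
        graph=g, z_threshold=z_threshold, edge_threshold=edge_threshold, species=species
    )
    return prune_isolated(net)


def prune_isolated(network: MotifNetwork) -> MotifNetwork:
    """Drop motifs without any retained interaction until none remain.

    Idempotent; self-loops count as interactions.
    """
    g = network.graph
    while True:
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        if not isolated:
            break
        g.remove_nodes_from(isolated)
    return network
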