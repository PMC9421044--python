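"""Genotype network and activity-quintile summaries of a fitness landscape.

Nodes are genotypes, edges join genotypes one substitution apart (Hamming
distance 1 on the full sequence). Neighbor search is indexed — each
genotype's sequence hashed, candidate neighbors generated by toggling one
position — so building the graph is O(n * 3L) rather than O(n^2).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import ALPHABET, Genotype
from .reads import ActivityTable


def build_genotype_network(table: ActivityTable) -> nx.Graph:
    """Graph over the table's genotypes with edges at Hamming distance 1.

    Node keys are genotype strings; node attributes carry ``fraction_cleaved``
    and ``order``. Quintile attributes can be added with
    :func:`annotate_quintiles`.
    """
    if len(table) == 0:
        raise ValueError("activity table is empty")
    ref = table.reference
    graph = nx.Graph()
    seq_to_label: dict[str, str] = {}
    for _, row in table.data.iterrows():
        g = Genotype.from_string(row["genotype"])
        seq = g.sequence(ref)
        seq_to_label[seq] = row["genotype"]
        graph.add_node(
            row["genotype"],
            fraction_cleaved=float(row["fraction_cleaved"]),
            order=int(row["order"]),
        )
    for seq, label in seq_to_label.items():
        chars = list(seq)
        for i, base in enumerate(chars):
            for alt in ALPHABET:
                if alt == base:
                    continue
                chars[i] = alt
                neighbor = seq_to_label.get("".join(chars))
                if neighbor is not None and neighbor != label:
                    graph.add_edge(label, neighbor)
            chars[i] = base
    return graph


def quintile_bins(
    table: ActivityTable,
    method: str = "value",
    value_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[dict[str, int], dict[int, int]]:
    """Assign each genotype an activity quintile 1..5 and count per bin.

    method="value" (default): five equal-width bins over ``value_range``,
    right-closed, so bin k covers ((k-1)/5 * span, k/5 * span] with bin 1
    also including the lower edge. method="count": rank-based quintiles
    (equal occupancy up to ties).
    """
    df = table.data.dropna(subset=["fraction_cleaved"])
    if len(df) == 0:
        raise ValueError("no rows with defined activity")
    if len(df) < 5:
        raise ValueError("need at least 5 rows with defined activity")
    acts = df["fraction_cleaved"].to_numpy(float)
    if method == "value":
        lo, hi = value_range
        if not hi > lo:
            raise ValueError("value_range must be increasing")
        frac = (acts - lo) / (hi - lo)
        idx = np.ceil(frac * 5).astype(int)
        idx[frac <= 0] = 1
        idx = np.clip(idx, 1, 5)
    elif method == "count":
        ranks = pd.Series(acts).rank(method="first")
        idx = np.ceil(ranks / len(acts) * 5).astype(int)
        idx = np.clip(idx, 1, 5)
    else:
        raise ValueError(f"unknown quintile method {method!r}")
    assignment = dict(zip(df["genotype"], (int(i) for i in idx)))
    counts = {k: int((idx == k).sum()) for k in range(1, 6)}
    return assignment, counts


def annotate_quintiles(graph: nx.Graph, assignment: dict[str, int]) -> None:
    for node, q in assignment.items():
        if node in graph:
            graph.nodes[node]["quintile"] = q


def export_network(graph: nx.Graph, edge_tsv: str | Path, node_tsv: str | Path) -> None:
    """Edge list and node attribute tables (GraphML-compatible attributes)."""
    pd.DataFrame(sorted(graph.edges()), columns=["genotype_a", "genotype_b"]).to_csv(
        edge_tsv, sep="\t", index=False
    )
    rows = [
        {"genotype": n, **graph.nodes[n]} for n in sorted(graph.nodes())
    ]
    pd.DataFrame(rows).to_csv(node_tsv, sep="\t", index=False, na_rep="NA")


def export_bin_summary(counts: dict[int, int], path: str | Path, method: str = "value") -> None:
    Path(path).write_text(
        json.dumps({"method": method, "bins": {str(k): v for k, v in counts.items()}}, indent=2)
    )
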