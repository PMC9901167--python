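"""Binarized similarity edges and the heterogeneous bioactivity network.

Nodes are proteins and compounds; edges are protein-protein similarity
(same cluster), compound-compound similarity (Tanimoto >= threshold,
inclusive), or bioactivity (a measured compound-protein pair).  The network
drives the fully-dissimilar train/test split: records in different connected
components share no similarity, directly or transitively.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

from dtibench.compounds import tanimoto_matrix
from dtibench.errors import ConsistencyError
from dtibench.io import BioactivityTable, ClusterMap, FeatureTable

PP_SIM = "PP_SIM"
CC_SIM = "CC_SIM"
BIOACTIVITY = "BIOACTIVITY"

PROTEIN = "protein"
COMPOUND = "compound"


def compound_similarity_edges(
    fingerprints: FeatureTable | Mapping[str, np.ndarray],
    threshold: float = 0.5,
) -> List[Tuple[str, str]]:
    """All unordered compound pairs with Tanimoto >= threshold (inclusive).

    Exact all-pairs; the vectorized popcount path gives the same edge set as
    the pairwise definition.
    """
    vectors = fingerprints.vectors if isinstance(fingerprints, FeatureTable) else dict(fingerprints)
    ids = list(vectors)
    if not ids:
        warnings.warn("empty fingerprint table: no similarity edges", stacklevel=2)
        return []
    mat = np.stack([np.asarray(vectors[i]) for i in ids])
    sim = tanimoto_matrix(mat)
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if sim[i, j] >= threshold:
                edges.append((ids[i], ids[j]))
    return edges


def protein_similarity_edges(cluster_map: ClusterMap) -> List[Tuple[str, str]]:
    """Clique edges among same-cluster proteins (binary similarity relation)."""
    edges = []
    for members in cluster_map.clusters().values():
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.append((members[i], members[j]))
    return edges


def similarity_matrix_edges(
    matrix, row_ids: List[str], col_ids: List[str], threshold: float
) -> List[Tuple[str, str]]:
    """Edges (i, j) for precomputed similarity values >= threshold (e.g. a
    percent-identity matrix from an external aligner)."""
    matrix = np.asarray(matrix, dtype=float)
    edges = []
    for i, rid in enumerate(row_ids):
        for j, cid in enumerate(col_ids):
            if rid != cid and matrix[i, j] >= threshold:
                pair = tuple(sorted((rid, cid)))
                if pair not in edges:
                    edges.append(pair)
    return sorted(set(edges))


def build_hetero_graph(
    table: BioactivityTable,
    cc_edges: Optional[List[Tuple[str, str]]] = None,
    pp_edges: Optional[List[Tuple[str, str]]] = None,
) -> nx.Graph:
    """Merge similarity edges and bioactivity records into one typed graph.

    Node attribute ``kind`` is protein/compound; edge attribute ``kind`` is
    PP_SIM/CC_SIM/BIOACTIVITY; each bioactivity edge carries the record_ids
    it represents (one after upstream pair aggregation).
    """
    g = nx.Graph()
    for cid in table.compound_index:
        g.add_node(("c", cid), kind=COMPOUND, entity_id=cid)
    for pid in table.protein_index:
        g.add_node(("p", pid), kind=PROTEIN, entity_id=pid)
    for rec in table:
        u, v = ("c", rec.compound_id), ("p", rec.protein_id)
        if g.has_edge(u, v):
            g[u][v]["record_ids"].append(rec.record_id)
        else:
            g.add_edge(u, v, kind=BIOACTIVITY, record_ids=[rec.record_id])
    for a, b in cc_edges or []:
        for cid in (a, b):
            if ("c", cid) not in g:
                raise ConsistencyError(f"CC_SIM edge endpoint {cid!r} not in the table")
        if a != b:
            g.add_edge(("c", a), ("c", b), kind=CC_SIM)
    for a, b in pp_edges or []:
        for pid in (a, b):
            if ("p", pid) not in g:
                raise ConsistencyError(f"PP_SIM edge endpoint {pid!r} not in the table")
        if a != b:
            g.add_edge(("p", a), ("p", b), kind=PP_SIM)
    _check_typing(g)
    return g


def _check_typing(g: nx.Graph) -> None:
    for u, v, data in g.edges(data=True):
        ku, kv = g.nodes[u]["kind"], g.nodes[v]["kind"]
        kind = data["kind"]
        ok = (
            (kind == PP_SIM and ku == kv == PROTEIN)
            or (kind == CC_SIM and ku == kv == COMPOUND)
            or (kind == BIOACTIVITY and {ku, kv} == {PROTEIN, COMPOUND})
        )
        if not ok:
            raise ConsistencyError(f"edge {(u, v)} of kind {kind} joins {ku} and {kv}")


def graph_manifest(g: nx.Graph) -> Dict[str, int]:
    """Node/edge counts by kind, for run manifests."""
    out = {
        "n_nodes": g.number_of_nodes(),
        "n_compounds": sum(1 for _, d in g.nodes(data=True) if d["kind"] == COMPOUND),
        "n_proteins": sum(1 for _, d in g.nodes(data=True) if d["kind"] == PROTEIN),
        "n_edges": g.number_of_edges(),
    }
    for kind in (PP_SIM, CC_SIM, BIOACTIVITY):
        out[f"n_{kind.lower()}"] = sum(
            1 for _, _, d in g.edges(data=True) if d["kind"] == kind
        )
    return out
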