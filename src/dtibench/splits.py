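"""Train/test splitting strategies with controlled similarity leakage.

Three strategies, in increasing difficulty:

* random        — records assigned uniformly; similar compounds and proteins
                  may appear on both sides (the over-optimistic baseline).
* dissimilar-compound — connected components of the binarized
                  compound-similarity graph are assigned whole, so no
                  train/test compound pair has Tanimoto >= the threshold.
* fully-dissimilar — components of the heterogeneous protein/compound
                  similarity + bioactivity network are assigned whole; a
                  giant component is broken up by Louvain community
                  detection, discarding cross-community bioactivity edges
                  and, for cross-community compound-similarity edges, the
                  less-connected compound node.  No similar compound pair
                  and no same-cluster protein pair crosses folds.

Records discarded by the fully-dissimilar strategy can be propagated to the
other splits (``harmonize_splits``) so all three share an identical record
universe.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from dtibench.errors import ConsistencyError, InfeasibleSplitError, InputError
from dtibench.graph import BIOACTIVITY, CC_SIM, COMPOUND, PP_SIM, PROTEIN
from dtibench.io import BioactivityTable


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test/discarded partition of a table's record ids."""

    train: FrozenSet[int]
    test: FrozenSet[int]
    discarded: FrozenSet[int]
    params: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if (self.train & self.test) or (self.train & self.discarded) or (
            self.test & self.discarded
        ):
            raise ConsistencyError("train/test/discarded folds overlap")

    @property
    def all_records(self) -> FrozenSet[int]:
        return self.train | self.test | self.discarded

    def achieved_test_fraction(self) -> float:
        kept = len(self.train) + len(self.test)
        return len(self.test) / kept if kept else 0.0


# ---------------------------------------------------------------------------
# component-to-fold assignment
# ---------------------------------------------------------------------------

def _achievable_sums(sizes: Sequence[int]) -> int:
    """Bitmask of subset sums: bit s set iff some subset of sizes sums to s."""
    mask = 1
    for s in sizes:
        mask |= mask << s
    return mask


def _assign_components(
    sizes: Sequence[int], target: int, seed: int
) -> Optional[Set[int]]:
    """Choose component indices for the test fold so the test record count is
    as close as possible to ``target`` while leaving train nonempty.

    Returns None when every achievable nonempty assignment leaves train
    empty (single component).  Deterministic given seed: the component visit
    order is a seeded shuffle refined largest-first, and the subset with the
    closest achievable sum is reconstructed along that order.
    """
    total = sum(sizes)
    k = len(sizes)
    if k < 2 or total == 0:
        return None
    rng = _random.Random(seed)
    order = list(range(k))
    rng.shuffle(order)
    order.sort(key=lambda i: -sizes[i])  # stable: shuffle breaks size ties

    ordered_sizes = [sizes[i] for i in order]
    # suffix achievable-sum masks for reconstruction
    suffix = [1] * (k + 1)
    for i in range(k - 1, -1, -1):
        suffix[i] = suffix[i + 1] | (suffix[i + 1] << ordered_sizes[i])
    full = suffix[0]
    # candidate test sums: achievable, nonempty test and nonempty train
    best_sum = None
    for s in range(1, total):
        if (full >> s) & 1:
            if best_sum is None or abs(s - target) < abs(best_sum - target) or (
                abs(s - target) == abs(best_sum - target) and s < best_sum
            ):
                best_sum = s
    if best_sum is None:
        return None
    chosen: Set[int] = set()
    s = best_sum
    for pos in range(k):
        size = ordered_sizes[pos]
        if size <= s and ((suffix[pos + 1] >> (s - size)) & 1):
            chosen.add(order[pos])
            s -= size
        # else skip: remaining sum must be achievable without this component
    assert s == 0
    return chosen


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------

def split_random(table: BioactivityTable, test_fraction: float, seed: int) -> SplitResult:
    """Seeded uniform record-level split; nothing is discarded."""
    n = len(table)
    if n < 2:
        raise InputError("need at least 2 records to split")
    if not 0.0 < test_fraction < 1.0:
        raise InputError(f"test_fraction must be in (0,1), got {test_fraction}")
    n_test = int(round(test_fraction * n))
    n_test = max(1, min(n - 1, n_test))  # both folds nonempty
    rng = np.random.default_rng(seed)
    ids = rng.permutation(n)
    return SplitResult(
        train=frozenset(int(i) for i in ids[n_test:]),
        test=frozenset(int(i) for i in ids[:n_test]),
        discarded=frozenset(),
        params={"strategy": "random", "test_fraction": test_fraction, "seed": seed},
    )


def _compound_components(
    compound_ids: Iterable[str], cc_edges: Iterable[Tuple[str, str]]
) -> List[List[str]]:
    g = nx.Graph()
    g.add_nodes_from(compound_ids)
    g.add_edges_from(cc_edges)
    return [sorted(comp) for comp in nx.connected_components(g)]


def split_dissimilar_compound(
    table: BioactivityTable,
    cc_edges: Sequence[Tuple[str, str]],
    test_fraction: float,
    seed: int,
) -> SplitResult:
    """Assign whole compound-similarity components to folds.

    No compound-similarity edge crosses folds, so every train/test compound
    pair is below the similarity threshold the edges were built at; proteins
    may appear on both sides.
    """
    if not 0.0 < test_fraction < 1.0:
        raise InputError(f"test_fraction must be in (0,1), got {test_fraction}")
    components = _compound_components(table.compound_index, cc_edges)
    comp_records = [
        sorted(rid for cid in comp for rid in table.compound_index[cid])
        for comp in components
    ]
    sizes = [len(r) for r in comp_records]
    n = len(table)
    target = int(round(test_fraction * n))
    chosen = _assign_components(sizes, max(1, target), seed)
    if chosen is None:
        raise InfeasibleSplitError(
            "a single compound-similarity component covers all records; "
            "no dissimilar-compound split exists"
        )
    test = frozenset(rid for i in chosen for rid in comp_records[i])
    train = frozenset(range(n)) - test
    return SplitResult(
        train=train,
        test=test,
        discarded=frozenset(),
        params={
            "strategy": "dissimilar-compound",
            "test_fraction": test_fraction,
            "seed": seed,
        },
    )


# -- fully dissimilar --------------------------------------------------------

def _contract_protein_clusters(g: nx.Graph) -> nx.Graph:
    """Collapse every PP_SIM-connected protein set into one super-node so
    community detection can never separate same-cluster proteins."""
    pp = nx.Graph()
    pp.add_nodes_from(n for n, d in g.nodes(data=True) if d["kind"] == PROTEIN)
    pp.add_edges_from(
        (u, v) for u, v, d in g.edges(data=True) if d["kind"] == PP_SIM
    )
    super_of: Dict = {}
    for comp in nx.connected_components(pp):
        key = ("P", min(n[1] for n in comp))
        for node in comp:
            super_of[node] = key

    h = nx.Graph()
    for node, data in g.nodes(data=True):
        if data["kind"] == COMPOUND:
            h.add_node(node, kind=COMPOUND)
        else:
            h.add_node(super_of[node], kind=PROTEIN)
    for u, v, data in g.edges(data=True):
        if data["kind"] == PP_SIM:
            continue  # internal to a super-node
        uu = super_of.get(u, u)
        vv = super_of.get(v, v)
        if data["kind"] == BIOACTIVITY:
            if h.has_edge(uu, vv):
                h[uu][vv].setdefault("record_ids", []).extend(data["record_ids"])
            else:
                h.add_edge(uu, vv, kind=BIOACTIVITY, record_ids=list(data["record_ids"]))
        else:  # CC_SIM
            if not h.has_edge(uu, vv):
                h.add_edge(uu, vv, kind=CC_SIM)
    return h


def _component_records(h: nx.Graph) -> List[Tuple[List, List[int]]]:
    """(sorted nodes, record ids) per connected component of the work graph."""
    out = []
    for comp in nx.connected_components(h):
        records: List[int] = []
        sub = h.subgraph(comp)
        for _, _, d in sub.edges(data=True):
            if d["kind"] == BIOACTIVITY:
                records.extend(d["record_ids"])
        out.append((sorted(comp), sorted(records)))
    return out


def _compound_record_count(h: nx.Graph, node) -> int:
    return sum(
        len(d["record_ids"])
        for _, _, d in h.edges(node, data=True)
        if d["kind"] == BIOACTIVITY
    )


def split_fully_dissimilar(
    g: nx.Graph,
    test_fraction: float = 0.15,
    louvain_resolution: float = 1.0,
    seed: int = 0,
    tolerance: float = 0.05,
    max_rounds: int = 10,
) -> SplitResult:
    """Network-based split: whole components of the heterogeneous graph go to
    one fold, after iterative Louvain pruning of the giant component.

    Each round: detect communities in the largest component (by records),
    discard bioactivity edges crossing communities, and for crossing
    compound-similarity edges remove the endpoint compound with fewer
    bioactivity records (ties broken lexicographically), discarding its
    records.  Rounds repeat until some component assignment reaches the
    target test fraction within ``tolerance`` (of the retained records), up
    to ``max_rounds``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise InputError(f"test_fraction must be in (0,1), got {test_fraction}")
    h = _contract_protein_clusters(g)
    all_records: Set[int] = set()
    for _, _, d in g.edges(data=True):
        if d["kind"] == BIOACTIVITY:
            all_records.update(d["record_ids"])
    discarded: Set[int] = set()
    achieved_log: List[float] = []

    for round_no in range(max_rounds + 1):
        comps = _component_records(h)
        sizes = [len(r) for _, r in comps]
        remaining = sum(sizes)
        if remaining == 0:
            raise InfeasibleSplitError(
                "all bioactivity records were discarded during pruning",
                achievable_fractions=achieved_log,
            )
        target = max(1, int(round(test_fraction * remaining)))
        chosen = _assign_components(sizes, target, seed)
        if chosen is not None:
            test_count = sum(sizes[i] for i in chosen)
            achieved = test_count / remaining
            achieved_log.append(achieved)
            if abs(achieved - test_fraction) <= tolerance:
                test = frozenset(r for i in chosen for r in comps[i][1])
                train = frozenset(
                    r for i, (_, recs) in enumerate(comps) if i not in chosen for r in recs
                )
                return SplitResult(
                    train=train,
                    test=test,
                    discarded=frozenset(discarded),
                    params={
                        "strategy": "fully-dissimilar",
                        "test_fraction": test_fraction,
                        "louvain_resolution": louvain_resolution,
                        "seed": seed,
                        "tolerance": tolerance,
                        "rounds_used": round_no,
                        "achieved_test_fraction": achieved,
                    },
                )
        if round_no == max_rounds:
            break
        # prune the largest component (by record count) with Louvain
        largest_idx = max(range(len(comps)), key=lambda i: sizes[i])
        largest_nodes = comps[largest_idx][0]
        sub = h.subgraph(largest_nodes)
        if sub.number_of_edges() == 0:
            break
        communities = nx.community.louvain_communities(
            sub, resolution=louvain_resolution, seed=seed + round_no
        )
        comm_of = {}
        for ci, comm in enumerate(communities):
            for node in comm:
                comm_of[node] = ci
        if len(communities) < 2:
            break  # Louvain cannot subdivide further
        crossing_bio = []
        crossing_cc = []
        for u, v, d in sub.edges(data=True):
            if comm_of[u] != comm_of[v]:
                if d["kind"] == BIOACTIVITY:
                    crossing_bio.append((u, v))
                else:
                    crossing_cc.append(tuple(sorted((u, v))))
        for u, v in crossing_bio:
            discarded.update(h[u][v]["record_ids"])
            h.remove_edge(u, v)
        removed_nodes: Set = set()
        for u, v in sorted(crossing_cc):
            if u in removed_nodes or v in removed_nodes:
                continue
            cu = _compound_record_count(h, u)
            cv = _compound_record_count(h, v)
            # remove the endpoint with fewer records; ties -> smaller id
            victim = u if (cu, u[1]) <= (cv, v[1]) else v
            for _, nbr, d in list(h.edges(victim, data=True)):
                if d["kind"] == BIOACTIVITY:
                    discarded.update(d["record_ids"])
            h.remove_node(victim)
            removed_nodes.add(victim)

    raise InfeasibleSplitError(
        f"target test fraction {test_fraction} +/- {tolerance} unreachable after "
        f"{max_rounds} pruning rounds; achievable fractions: "
        f"{[round(a, 4) for a in achieved_log]}",
        achievable_fractions=achieved_log,
    )


def harmonize_splits(
    reference: SplitResult, others: Sequence[SplitResult]
) -> List[SplitResult]:
    """Propagate the reference split's discarded records into other splits so
    all strategies share an identical record universe."""
    out = []
    for split in others:
        if split.all_records != reference.all_records:
            raise ConsistencyError("splits cover different record universes")
        moved = reference.discarded
        out.append(
            SplitResult(
                train=split.train - moved,
                test=split.test - moved,
                discarded=split.discarded | moved,
                params={**split.params, "harmonized_against": reference.params.get("strategy")},
            )
        )
    return out
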