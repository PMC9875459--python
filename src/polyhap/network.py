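"""Haplotype evolutionary network: an epsilon=0 minimum-spanning network.

Distances between haplotypes are mutational steps on the MSA: differing
gap-free columns plus one step per InDel event carried by exactly one of the
pair.  Components are joined Kruskal-style in increasing distance; when two
components first meet at distance d, every inter-component pair at distance
d becomes an edge (tie retention), which approximates the statistical-
parsimony (TCS) layout for closely related haplotypes.  Multi-step edges can
be expanded through unlabeled inferred intermediates so that every drawn
edge represents a single mutation.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import Alignment
from .variation import IndelEvent

__all__ = [
    "pairwise_steps",
    "step_matrix",
    "build_msn",
    "insert_inferred_nodes",
    "central_haplotype",
    "single_linkage_groups",
]


def pairwise_steps(
    hap_a: str,
    hap_b: str,
    aln: Alignment,
    events: list[IndelEvent] | None = None,
) -> int:
    """Mutational steps between two MSA rows.

    Substitution steps: columns where both rows have bases and they differ.
    InDel steps: events (maximal gap runs vs the reference) carried by one of
    the pair but not the other — a 277 bp insertion is one step, not 277.
    """
    ra, rb = aln.row(hap_a), aln.row(hap_b)
    steps = sum(
        1 for x, y in zip(ra, rb) if x != "-" and y != "-" and x != y
    )
    for ev in events or []:
        in_a = hap_a in ev.carriers
        in_b = hap_b in ev.carriers
        if in_a != in_b:
            steps += 1
    return steps


def step_matrix(
    aln: Alignment,
    ids: list[str] | None = None,
    events: list[IndelEvent] | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise mutational steps."""
    ids = ids if ids is not None else list(aln.ids)
    d = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            s = pairwise_steps(a, b, aln, events)
            d.loc[a, b] = d.loc[b, a] = s
    return d


def build_msn(
    dist: pd.DataFrame,
    frequencies: dict[str, int] | None = None,
) -> nx.Graph:
    """Minimum-spanning network (epsilon=0) from a complete distance matrix.

    Distances are processed in increasing order; at each distance level all
    pairs joining distinct components (as of the start of the level) become
    edges, so ties are retained.  Deterministic: levels ascend, pairs break
    ties lexicographically.  Node attributes: ``kind='haplotype'`` and
    ``frequency`` (carrying-accession count, default 1); edge attribute
    ``steps``.  The graph carries ``backbone_weight``: the total steps of a
    minimum spanning tree.
    """
    ids = list(dist.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 haplotypes")
    arr = dist.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError("distances must be finite")
    G = nx.Graph()
    for h in ids:
        G.add_node(h, kind="haplotype", frequency=(frequencies or {}).get(h, 1))
    pairs = sorted(
        ((int(dist.loc[a, b]), a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]),
        key=lambda t: (t[0], t[1], t[2]),
    )
    comp = {h: h for h in ids}

    def find(x: str) -> str:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    backbone = 0
    k = 0
    while k < len(pairs):
        d = pairs[k][0]
        level = []
        while k < len(pairs) and pairs[k][0] == d:
            level.append(pairs[k])
            k += 1
        snapshot = {h: find(h) for h in ids}
        added = [(a, b) for _, a, b in level if snapshot[a] != snapshot[b]]
        for a, b in added:
            G.add_edge(a, b, steps=d)
            if find(a) != find(b):
                comp[find(a)] = find(b)
                backbone += d
    G.graph["backbone_weight"] = backbone
    return G


def insert_inferred_nodes(G: nx.Graph) -> nx.Graph:
    """Expand every k-step edge (k > 1) into a path through k-1 unlabeled
    inferred nodes, so every edge in the result is a single mutational step."""
    H = G.copy()
    counter = 0
    for u, v, data in sorted(G.edges(data=True)):
        k = data.get("steps", 1)
        if k <= 1:
            continue
        H.remove_edge(u, v)
        prev = u
        for _ in range(k - 1):
            counter += 1
            mid = f"inferred{counter}"
            H.add_node(mid, kind="inferred", frequency=0)
            H.add_edge(prev, mid, steps=1)
            prev = mid
        H.add_edge(prev, v, steps=1)
    return H


def single_linkage_groups(dist: pd.DataFrame, threshold: int) -> dict[str, int]:
    """Non-canonical convenience grouping: connected components of the graph
    whose edges are pairs at distance <= threshold (single linkage).

    Published network groupings of this kind are typically drawn by eye from
    the network layout; this cut is provided as plumbing for users who want
    a reproducible partition, not as a reconstruction of any visual one.
    Groups are numbered 1, 2, ... by smallest member id.
    """
    G = nx.Graph()
    ids = list(dist.index)
    G.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if dist.loc[a, b] <= threshold:
                G.add_edge(a, b)
    comps = sorted(nx.connected_components(G), key=lambda c: sorted(c)[0])
    return {n: k for k, comp in enumerate(comps, start=1) for n in comp}


def central_haplotype(G: nx.Graph) -> str:
    """The labeled node minimizing eccentricity (in mutational steps).

    Ties break toward higher frequency, then lexicographically smaller id.
    The most central haplotype of a star-like cluster is the natural
    candidate for the primitive (ancestral) haplotype.
    """
    labeled = [n for n, d in G.nodes(data=True) if d.get("kind") != "inferred"]
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="steps"))
    best = None
    for n in labeled:
        ecc = max(lengths[n][m] for m in labeled)
        key = (ecc, -G.nodes[n].get("frequency", 1), n)
        if best is None or key < best[0]:
            best = (key, n)
    assert best is not None
    return best[1]
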