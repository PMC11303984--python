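"""Chloroplast haplotype calling and median-joining networks.

The chloroplast genome is effectively a single non-recombining locus, so
relationships among its haplotypes are naturally drawn as a network rather
than a bifurcating tree.  This module reduces an alignment of chloroplast
coding regions to reliably scored segregating positions, calls haplotypes
(tolerating partial, low-coverage ancient assemblies), and builds a
median-joining network: minimum-spanning connections augmented with inferred
median ("consensus of triplet") vectors wherever they shorten the network.
Haplogroups are assigned from user-supplied seed haplotypes, and a simple
molecular-clock conversion turns substitution counts into divergence times.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING_STATE = "N"
UNASSIGNED = "UNASSIGNED"
UNRESOLVED = "UNRESOLVED"

#: safety cap on tie-generated candidate medians per iteration
MAX_CANDIDATE_MEDIANS = 1000


# ---------------------------------------------------------------------------
# scored sites and haplotype calling
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeAlignment:
    """Samples × scored-position state matrix.

    ``scored_positions`` are 1-based alignment coordinates.  States are
    A/C/G/T or ``N`` for gap/ambiguity.  ``labels`` maps sample to a
    haplotype label (or UNASSIGNED) after :func:`call_haplotypes`;
    ``haplotypes`` maps label to its complete state vector.
    """

    samples: list
    scored_positions: list
    states: np.ndarray  # (n_samples, n_scored) of U1
    labels: dict = field(default_factory=dict)
    haplotypes: dict = field(default_factory=dict)

    @property
    def n_scored(self) -> int:
        return len(self.scored_positions)

    def vector(self, sample: str) -> tuple:
        return tuple(self.states[self.samples.index(sample)])


def read_fasta_alignment(path) -> dict:
    """FASTA alignment as {sequence id: sequence string}."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def read_bed_mask(path) -> list:
    """BED intervals (0-based half-open) as [(start, end), ...].

    Only the coordinate columns are used; the alignment is a single
    reference frame, so the chromosome column is ignored.
    """
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append((int(parts[1]), int(parts[2])))
    return intervals


def apply_exclusion_mask(seqs: dict, intervals) -> dict:
    """Replace masked columns with ``N`` in every sequence.

    Used for regions that must not contribute scored sites, e.g. a
    chloroplast segment with a diverged mitochondrial paralog whose reads
    contaminate assemblies.
    """
    masked = {}
    for sid, seq in seqs.items():
        chars = list(seq)
        for start, end in intervals:
            for i in range(max(start, 0), min(end, len(chars))):
                chars[i] = MISSING_STATE
        masked[sid] = "".join(chars)
    return masked


def extract_scored_sites(seqs: dict, exclusion_intervals=None) -> HaplotypeAlignment:
    """Reduce an alignment to reliably polymorphic columns.

    A column is scored when, among non-missing states (gaps and IUPAC
    ambiguities are missing), at least two states occur and the minor state
    is present in >= 2 sequences.  Columns varying only by gap-vs-base are
    monomorphic among valid states and excluded.
    """
    if exclusion_intervals:
        seqs = apply_exclusion_mask(seqs, exclusion_intervals)
    samples = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("alignment sequences have unequal lengths")
    arr = np.array([list(str(seqs[s]).upper()) for s in samples], dtype="U1")
    arr[~np.isin(arr, list("ACGT"))] = MISSING_STATE

    scored = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        states, counts = np.unique(col[col != MISSING_STATE],
                                   return_counts=True)
        if len(states) >= 2 and np.sort(counts)[-2] >= 2:
            scored.append(j)
    if not scored:
        log.warning("no scorable polymorphic columns in alignment")
    return HaplotypeAlignment(
        samples=samples,
        scored_positions=[j + 1 for j in scored],
        states=arr[:, scored] if scored else np.empty((len(samples), 0), "U1"),
    )


def call_haplotypes(haln: HaplotypeAlignment,
                    max_missing: float = 0.5) -> HaplotypeAlignment:
    """Assign haplotype labels from scored state vectors.

    Complete vectors define haplotypes (identical vectors share a label;
    labels H1, H2, ... in order of decreasing multiplicity).  A vector with
    missing entries is assigned iff it is compatible at every non-missing
    position with exactly one haplotype; compatibility with several — or a
    missing fraction above ``max_missing`` — leaves it UNASSIGNED.
    """
    vectors = {s: tuple(haln.states[i]) for i, s in enumerate(haln.samples)}
    complete = {s: v for s, v in vectors.items()
                if MISSING_STATE not in v}
    counts: dict[tuple, int] = {}
    order: dict[tuple, int] = {}
    for i, v in enumerate(complete.values()):
        counts[v] = counts.get(v, 0) + 1
        order.setdefault(v, i)
    ranked = sorted(counts, key=lambda v: (-counts[v], order[v]))
    haplotypes = {f"H{i + 1}": v for i, v in enumerate(ranked)}
    by_vector = {v: lbl for lbl, v in haplotypes.items()}

    labels = {}
    n = haln.n_scored
    for s, v in vectors.items():
        if s in complete:
            labels[s] = by_vector[v]
            continue
        miss = sum(1 for st in v if st == MISSING_STATE)
        if n == 0 or miss / n > max_missing:
            labels[s] = UNASSIGNED
            continue
        compatible = [lbl for lbl, hv in haplotypes.items()
                      if all(a == MISSING_STATE or a == b
                             for a, b in zip(v, hv))]
        labels[s] = compatible[0] if len(compatible) == 1 else UNASSIGNED
    return HaplotypeAlignment(
        samples=haln.samples,
        scored_positions=haln.scored_positions,
        states=haln.states,
        labels=labels,
        haplotypes=haplotypes,
    )


# ---------------------------------------------------------------------------
# median-joining network
# ---------------------------------------------------------------------------


def hamming(u, v) -> int:
    return sum(1 for a, b in zip(u, v) if a != b)


@dataclass
class MJNetwork:
    """Median-joining network over haplotype state vectors.

    ``graph`` holds one node per distinct vector with attributes ``label``
    (haplotype label or ``median<i>``), ``kind`` (observed / median) and
    ``multiplicity``.  Edges carry ``weight`` = substitution count.
    ``length`` is the spanning-tree length of the final node set — the
    quantity the median vectors are added to minimise.  Reticulation edges
    (equally short alternatives retained by the epsilon-relaxed spanning
    network) make the summed edge weight exceed ``length``.
    """

    graph: nx.Graph
    length: int
    epsilon: int

    def edge_list(self) -> pd.DataFrame:
        rows = [{"from": self.graph.nodes[u]["label"],
                 "to": self.graph.nodes[v]["label"],
                 "weight": d["weight"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["from", "to", "weight"])

    def node_table(self) -> pd.DataFrame:
        rows = [{"label": d["label"], "kind": d["kind"],
                 "multiplicity": d["multiplicity"],
                 "vector": "".join(n)}
                for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(rows, columns=["label", "kind", "multiplicity",
                                           "vector"])

    def to_gml(self, path) -> None:
        g = nx.relabel_nodes(self.graph,
                             {n: d["label"]
                              for n, d in self.graph.nodes(data=True)})
        nx.write_gml(g, str(path))


def _spanning_network(nodes: list, epsilon: int) -> list:
    """Epsilon-relaxed minimum spanning network edges.

    A pair at distance w is linked iff its endpoints are not already
    connected using only pairs at distance <= w - epsilon - 1.  At
    epsilon = 0 this is the union of all minimum spanning trees.
    """
    dists = {}
    for u, v in itertools.combinations(nodes, 2):
        dists[(u, v)] = hamming(u, v)
    edges = []
    for (u, v), w in dists.items():
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(p for p, d in dists.items() if d <= w - epsilon - 1)
        if not nx.has_path(g, u, v):
            edges.append((u, v, w))
    return edges


def _tree_length(nodes: list) -> int:
    """Minimum spanning tree weight of the complete Hamming graph."""
    if len(nodes) < 2:
        return 0
    g = nx.Graph()
    for u, v in itertools.combinations(nodes, 2):
        g.add_edge(u, v, weight=hamming(u, v))
    return int(sum(d["weight"]
                   for _, _, d in nx.minimum_spanning_edges(g, data=True)))


def _median_candidates(u, v, w) -> list:
    """Per-position majority vectors of a triplet.

    A position where all three states differ is a tie; every tied state is
    expanded, bounded by ``MAX_CANDIDATE_MEDIANS``.
    """
    per_pos = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            per_pos.append((a,))
        elif b == c:
            per_pos.append((b,))
        else:
            per_pos.append(tuple(dict.fromkeys((a, b, c))))
    out = []
    for combo in itertools.product(*per_pos):
        out.append(tuple(combo))
        if len(out) >= MAX_CANDIDATE_MEDIANS:
            break
    return out


def mj_network(haplotypes: dict, epsilon: int = 0,
               multiplicities: dict | None = None) -> MJNetwork:
    """Build a median-joining network from complete haplotype vectors.

    ``haplotypes`` maps label -> state vector (sequence of single
    characters); vectors must be complete (no missing states) and distinct.
    The algorithm alternates between building the epsilon-relaxed minimum
    spanning network, proposing median vectors for connected triplets, and
    keeping any median that shortens the spanning-tree length; obsolete
    medians are pruned before the final network is assembled.
    """
    vectors = {lbl: tuple(v) for lbl, v in haplotypes.items()}
    for lbl, v in vectors.items():
        if MISSING_STATE in v:
            raise ValueError(f"haplotype {lbl} has missing states; resolve "
                             "or exclude before network construction")
    if len(set(vectors.values())) < 2:
        raise ValueError("need >= 2 distinct haplotypes")
    if len(set(vectors.values())) < len(vectors):
        raise ValueError("haplotype vectors must be distinct per label")
    observed = {v: lbl for lbl, v in vectors.items()}
    nodes = list(observed)
    observed_length = _tree_length(nodes)

    # greedy median additions: accept the single best improving median,
    # re-derive the spanning network, repeat until no median helps
    while True:
        current = _tree_length(nodes)
        edges = _spanning_network(nodes, epsilon)
        adj: dict[tuple, set] = {n: set() for n in nodes}
        for u, v, _ in edges:
            adj[u].add(v)
            adj[v].add(u)
        candidates: set = set()
        for center in nodes:
            for u, w in itertools.combinations(sorted(adj[center]), 2):
                for m in _median_candidates(u, center, w):
                    if m not in nodes:
                        candidates.add(m)
        best, best_len = None, current
        for c in sorted(candidates):
            trial = _tree_length(nodes + [c])
            if trial < best_len:
                best, best_len = c, trial
        if best is None:
            break
        nodes.append(best)

    # prune medians whose removal does not lengthen the tree
    changed = True
    while changed:
        changed = False
        for n in list(nodes):
            if n in observed:
                continue
            rest = [x for x in nodes if x != n]
            if _tree_length(rest) <= _tree_length(nodes):
                nodes = rest
                changed = True

    length = _tree_length(nodes)
    assert length <= observed_length

    graph = nx.Graph()
    median_i = 0
    for n in nodes:
        if n in observed:
            lbl = observed[n]
            mult = (multiplicities or {}).get(lbl, 1)
            graph.add_node(n, label=lbl, kind="observed", multiplicity=mult)
        else:
            median_i += 1
            graph.add_node(n, label=f"median{median_i}", kind="median",
                           multiplicity=0)
    for u, v, w in _spanning_network(nodes, epsilon):
        graph.add_edge(u, v, weight=w)
    return MJNetwork(graph=graph, length=length, epsilon=epsilon)


# ---------------------------------------------------------------------------
# haplogroups and dating
# ---------------------------------------------------------------------------


def assign_haplogroups(net: MJNetwork, seeds: dict) -> dict:
    """Label every observed haplotype with its nearest seed's haplogroup.

    ``seeds`` maps haplogroup label -> haplotype label or state vector;
    distance is the shortest weighted path in the network.  Exact ties and
    unreachable nodes resolve to UNRESOLVED (with a warning for the
    latter).
    """
    by_label = {d["label"]: n for n, d in net.graph.nodes(data=True)}
    seed_nodes = {}
    for group, ref in seeds.items():
        node = by_label.get(ref) if isinstance(ref, str) and ref in by_label \
            else tuple(ref)
        if node not in net.graph:
            raise KeyError(f"seed {group!r} ({ref!r}) is not a network node")
        seed_nodes[group] = node

    dist_from_seed = {
        group: nx.single_source_dijkstra_path_length(net.graph, node,
                                                     weight="weight")
        for group, node in seed_nodes.items()
    }
    assignment = {}
    for node, data in net.graph.nodes(data=True):
        if data["kind"] != "observed":
            continue
        dists = {g: d[node] for g, d in dist_from_seed.items() if node in d}
        if not dists:
            log.warning("haplotype %s unreachable from every seed",
                        data["label"])
            assignment[data["label"]] = UNRESOLVED
            continue
        best = min(dists.values())
        winners = [g for g, d in dists.items() if d == best]
        assignment[data["label"]] = winners[0] if len(winners) == 1 \
            else UNRESOLVED
    return assignment


def divergence_time(d: float, L: float, mu: float) -> float:
    """Molecular-clock divergence time in years.

    ``T = (d / L) / (2 mu)`` for ``d`` substitutions over ``L`` compared
    sites and per-site per-year rate ``mu`` (the factor 2 counts both
    diverging lineages).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if mu <= 0:
        raise ValueError("mu must be positive")
    return (d / L) / (2.0 * mu)
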