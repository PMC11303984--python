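import itertools

import networkx as nx
import numpy as np
import pytest

from privar.haplonet import (
    UNASSIGNED,
    UNRESOLVED,
    MJNetwork,
    apply_exclusion_mask,
    assign_haplogroups,
    call_haplotypes,
    divergence_time,
    extract_scored_sites,
    mj_network,
)


# ---------------------------------------------------------------------------
# exact Steiner-tree oracle (Dreyfus–Wagner on the binary hypercube)
# ---------------------------------------------------------------------------


def steiner_optimum(terminals):
    """Minimum weight of a Steiner tree connecting binary terminals, with
    any hypercube vertex usable as an auxiliary node."""
    k = len(terminals[0])
    vertices = list(itertools.product("01", repeat=k))
    index = {v: i for i, v in enumerate(vertices)}
    nV = len(vertices)
    dist = np.array([[sum(a != b for a, b in zip(u, v)) for v in vertices]
                     for u in vertices])
    t = len(terminals)
    full = (1 << t) - 1
    INF = 10 ** 9
    S = np.full((1 << t, nV), INF)
    for i, term in enumerate(terminals):
        S[1 << i] = dist[index[term]]
    for mask in range(1, full + 1):
        if mask & (mask - 1) == 0:
            continue
        best = np.full(nV, INF)
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if sub < other:  # each split once
                cand = S[sub] + S[other]
                best = np.minimum(best, cand)
            sub = (sub - 1) & mask
        # relax through any vertex
        S[mask] = np.min(best[None, :] + dist, axis=1)
        S[mask] = np.minimum(S[mask], best)
    root = index[terminals[0]]
    return int(S[full][root])


PLANTED_CASES = [
    ["000", "110", "101"],                       # classic median case
    ["0000", "1000", "0100", "0010", "0001"],    # observed-centre star
    ["00", "11"],                                # single edge
    ["000000", "111000", "000111", "111111"],    # two 3-bit jumps
    ["0000", "1100", "0011"],                    # median halves two legs
    ["00000", "11000", "10100", "01100", "00011", "00111"],  # two clusters
]


def as_vectors(strings):
    return {f"h{i}": tuple(s) for i, s in enumerate(strings)}


# ---------------------------------------------------------------------------
# scored sites
# ---------------------------------------------------------------------------


class TestExtractScoredSites:
    def test_minor_count_two_required(self):
        seqs = {
            "a": "AAG", "b": "AAG", "c": "AGG", "d": "AGG", "e": "CAG",
        }
        # col 0: minor C count 1 -> excluded; col 1: A3/G2 -> scored;
        # col 2: monomorphic
        haln = extract_scored_sites(seqs)
        assert haln.scored_positions == [2]

    def test_gap_only_variation_excluded(self):
        seqs = {"a": "A-A", "b": "AAA", "c": "A-A", "d": "AAA"}
        assert extract_scored_sites(seqs).n_scored == 0

    def test_ambiguities_are_missing(self):
        seqs = {"a": "AR", "b": "AG", "c": "AG", "d": "AA", "e": "AA"}
        haln = extract_scored_sites(seqs)
        assert haln.scored_positions == [2]
        assert haln.states[0, 0] == "N"

    def test_exclusion_mask_removes_columns(self):
        seqs = {"a": "GGAA", "b": "GGAA", "c": "CCAA", "d": "CCAA"}
        assert extract_scored_sites(seqs).scored_positions == [1, 2]
        masked = extract_scored_sites(seqs, exclusion_intervals=[(0, 1)])
        assert masked.scored_positions == [2]
        assert apply_exclusion_mask(seqs, [(0, 2)])["a"] == "NNAA"


class TestCallHaplotypes:
    def build(self, rows):
        seqs = {f"s{i}": r for i, r in enumerate(rows)}
        return call_haplotypes(extract_scored_sites(seqs), max_missing=0.5)

    def test_identical_vectors_share_label(self):
        called = self.build(["AAG", "AAG", "GAG", "GAG"])
        assert called.labels["s0"] == called.labels["s1"] == "H1"
        assert len(called.haplotypes) == 2

    def test_partial_compatible_with_one_assigned(self):
        called = self.build(["AG", "AG", "CT", "CT", "A-"])
        # scored cols both; partial vector (A, N) only matches AG
        assert called.labels["s4"] == called.labels["s0"]

    def test_partial_compatible_with_two_unassigned(self):
        called = self.build(["AG", "AG", "AT", "AT", "A-"])
        assert called.labels["s4"] == UNASSIGNED

    def test_too_much_missing_unassigned(self):
        seqs = {"a": "AGC", "b": "AGC", "c": "CTA", "d": "CTA",
                "e": "A--"}
        called = call_haplotypes(extract_scored_sites(seqs), max_missing=0.5)
        assert called.labels["e"] == UNASSIGNED

    def test_complete_vector_is_exact_lookup(self):
        called = self.build(["AG", "AG", "CT", "CT", "CT"])
        assert called.labels["s2"] == "H1"  # CT has higher multiplicity
        assert called.haplotypes[called.labels["s2"]] == ("C", "T")


class TestMJNetwork:
    def test_two_haplotypes_single_edge(self):
        net = mj_network(as_vectors(["0000", "0110"]))
        assert net.graph.number_of_edges() == 1
        assert net.length == 2
        (u, v, d), = net.graph.edges(data=True)
        assert d["weight"] == 2

    def test_median_vector_shortens_triangle(self):
        net = mj_network(as_vectors(["000", "110", "101"]))
        vectors = set(net.graph.nodes)
        assert tuple("100") in vectors
        assert net.length == 3
        weights = sorted(d["weight"] for _, _, d in
                         net.graph.edges(data=True))
        assert weights == [1, 1, 1]

    def test_observed_star_needs_no_medians(self):
        net = mj_network(as_vectors(["0000", "1000", "0100", "0010",
                                     "0001"]))
        kinds = {d["kind"] for _, d in net.graph.nodes(data=True)}
        assert kinds == {"observed"}
        assert net.length == 4

    @pytest.mark.parametrize("case", PLANTED_CASES,
                             ids=["median-triangle", "star", "edge",
                                  "two-jumps", "two-legs", "two-clusters"])
    def test_length_matches_exact_steiner_optimum(self, case):
        net = mj_network(as_vectors(case))
        assert net.length == steiner_optimum([tuple(s) for s in case])

    @pytest.mark.parametrize("case", PLANTED_CASES,
                             ids=["median-triangle", "star", "edge",
                                  "two-jumps", "two-legs", "two-clusters"])
    def test_connected_and_observed_nodes_survive(self, case):
        net = mj_network(as_vectors(case))
        assert nx.is_connected(net.graph)
        observed = {n for n, d in net.graph.nodes(data=True)
                    if d["kind"] == "observed"}
        assert observed == {tuple(s) for s in case}
        # medians may only shorten the network relative to observed-only MST
        g = nx.Graph()
        for u, v in itertools.combinations(case, 2):
            g.add_edge(u, v, weight=sum(a != b for a, b in zip(u, v)))
        mst_observed = sum(d["weight"] for _, _, d in
                           nx.minimum_spanning_edges(g, data=True))
        assert net.length <= mst_observed

    def test_incomplete_vectors_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            mj_network({"a": tuple("AN"), "b": tuple("AG")})

    def test_multistate_median_tie_handled(self):
        # all three states differ at one position: tie generates candidates
        net = mj_network(as_vectors_acgt(["AAT", "CCT", "GGT"]))
        assert nx.is_connected(net.graph)


def as_vectors_acgt(strings):
    return {f"h{i}": tuple(s) for i, s in enumerate(strings)}


class TestHaplogroups:
    def test_nearest_seed_wins(self):
        # a chain: A-center ... node one step away, B-center 15 steps off
        hapA = "0" * 16
        near = "1" + "0" * 15
        hapB = "0" + "1" * 15
        net = mj_network(as_vectors([hapA, near, hapB]))
        groups = assign_haplogroups(net, {"A": "h0", "B": "h2"})
        assert groups["h1"] == "A"

    def test_seed_keeps_its_own_label(self):
        net = mj_network(as_vectors(["00", "01", "11"]))
        groups = assign_haplogroups(net, {"A": "h0", "B": "h2"})
        assert groups["h0"] == "A" and groups["h2"] == "B"

    def test_equidistant_node_unresolved(self):
        net = mj_network(as_vectors(["00", "01", "11"]))
        groups = assign_haplogroups(net, {"A": "h0", "B": "h2"})
        assert groups["h1"] == UNRESOLVED

    def test_unknown_seed_errors(self):
        net = mj_network(as_vectors(["00", "11"]))
        with pytest.raises(KeyError):
            assign_haplogroups(net, {"A": "nope"})


class TestDivergenceTime:
    def test_zero_distance(self):
        assert divergence_time(0, 100, 1e-9) == 0.0

    def test_direct_formula(self):
        # d/L = 2e-4 at mu = 1e-9 /site/year: T = 2e-4 / 2e-9 = 100,000 y
        assert divergence_time(2, 10_000, 1e-9) == pytest.approx(100_000.0)

    def test_inverse_in_mu(self):
        t1 = divergence_time(3, 1000, 1e-9)
        t2 = divergence_time(3, 1000, 2e-9)
        assert t1 == pytest.approx(2 * t2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            divergence_time(1, 0, 1e-9)
        with pytest.raises(ValueError):
            divergence_time(1, 100, 0)
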