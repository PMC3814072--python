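"""State calling, replica collapsing, and network construction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mwnet.io import ExpressionMatrix
from mwnet.network import (
    NEUTRAL,
    OVER,
    SILENCED,
    StateMatrix,
    build_mwnet,
    call_states,
    collapse_replicas,
    edge_weight_vector,
    read_network,
    write_network,
)

from conftest import brute_force_network, network_as_dict, random_state_matrix


def make_states(rows, genes=None, epsilon=0.0):
    rows = np.atleast_2d(rows)
    genes = genes or [f"g{j}" for j in range(rows.shape[1])]
    df = pd.DataFrame(rows, index=[f"s{i}" for i in range(rows.shape[0])], columns=genes)
    return StateMatrix(df, epsilon=epsilon)


class TestCallStates:
    @pytest.mark.parametrize(
        "value, epsilon, expected",
        [
            (0.5, 0.0, OVER),
            (0.0, 0.0, NEUTRAL),  # strict inequality: no call at the threshold
            (-0.2, 0.3, NEUTRAL),
            (-0.4, 0.3, SILENCED),
            (0.3, 0.3, NEUTRAL),
            (np.nan, 0.0, NEUTRAL),
        ],
    )
    def test_threshold_rule(self, value, epsilon, expected):
        gem = ExpressionMatrix(
            pd.DataFrame([[value, 1.0]], index=["s1"], columns=["gA", "gB"])
        )
        states = call_states(gem, epsilon, require_normalized=False)
        assert states.data.loc["s1", "gA"] == expected

    def test_negative_epsilon_rejected(self):
        gem = ExpressionMatrix(pd.DataFrame([[1.0]], index=["s1"], columns=["gA"]))
        with pytest.raises(ValueError, match="non-negative"):
            call_states(gem, -0.1, require_normalized=False)

    def test_unnormalized_matrix_requires_opt_out(self):
        gem = ExpressionMatrix(pd.DataFrame([[1.0]], index=["s1"], columns=["gA"]))
        with pytest.raises(ValueError, match="not normalized"):
            call_states(gem, 0.0)


class TestCollapseReplicas:
    def test_exhaustive_replica_pair_combinations(self):
        """All 9 state combinations of two replicas, under the default rule.

        At least one non-neutral replica makes the gene expressed; agreeing
        signs win; conflicting signs collapse to neutral.
        """
        combos = list(itertools.product([OVER, NEUTRAL, SILENCED], repeat=2))
        row = [s for combo in combos for s in combo]
        genes = [f"c{i}_{r}" for i in range(9) for r in "ab"]
        states = make_states([row], genes=genes)
        rmap = {f"c{i}_{r}": f"gene{i}" for i in range(9) for r in "ab"}
        out = collapse_replicas(states, rmap)
        for i, (a, b) in enumerate(combos):
            nonneutral = [s for s in (a, b) if s != NEUTRAL]
            if not nonneutral:
                expected = NEUTRAL
            elif len(set(nonneutral)) == 1:
                expected = nonneutral[0]
            else:
                expected = NEUTRAL  # conflicting replicas are unreliable
            assert out.data.loc["s0", f"gene{i}"] == expected

    def test_any_replica_examples(self):
        states = make_states([[OVER, NEUTRAL], [NEUTRAL, NEUTRAL]], genes=["a1", "a2"])
        out = collapse_replicas(states, {"a1": "A", "a2": "A"})
        assert out.data["A"].tolist() == [OVER, NEUTRAL]

    def test_max_magnitude_policy_uses_expression(self):
        gem = ExpressionMatrix(
            pd.DataFrame([[2.0, -3.0]], index=["s0"], columns=["a1", "a2"]),
            allow_duplicate_genes=True,
        )
        states = call_states(gem, 0.0, require_normalized=False)
        out = collapse_replicas(
            states, {"a1": "A", "a2": "A"}, policy="max_magnitude", gem=gem
        )
        assert out.data.loc["s0", "A"] == SILENCED

    def test_max_magnitude_requires_gem(self):
        states = make_states([[OVER, SILENCED]], genes=["a1", "a2"])
        with pytest.raises(ValueError, match="requires the expression matrix"):
            collapse_replicas(states, {"a1": "A", "a2": "A"}, policy="max_magnitude")

    def test_unmapped_spot_listed(self):
        states = make_states([[OVER, OVER]], genes=["a1", "a2"])
        with pytest.raises(KeyError, match="a2"):
            collapse_replicas(states, {"a1": "A"})


class TestBuildMWNet:
    def test_worked_example_weight_vector(self):
        # g1: O,O,S,O and g2: O,S,S,Neutral over four samples
        states = make_states(
            [[OVER, OVER], [OVER, SILENCED], [SILENCED, SILENCED], [OVER, NEUTRAL]],
            genes=["g1", "g2"],
        )
        net = build_mwnet(states)
        w = edge_weight_vector(net, "g1", "g2")
        np.testing.assert_array_equal(w, [1, 1, 0, 1])
        assert w.sum() == 3

    def test_all_neutral_gene_absent(self):
        states = make_states([[OVER, NEUTRAL], [SILENCED, NEUTRAL]], genes=["g1", "g2"])
        net = build_mwnet(states)
        assert set(net.nodes) == {"g1"}

    def test_never_coexpressed_pair_has_no_edge(self):
        states = make_states([[OVER, NEUTRAL], [NEUTRAL, SILENCED]], genes=["g1", "g2"])
        net = build_mwnet(states)
        assert net.number_of_edges() == 0
        assert set(net.nodes) == {"g1", "g2"}

    def test_query_order_swaps_os_so(self):
        states = make_states([[OVER, SILENCED]], genes=["g1", "g2"])
        net = build_mwnet(states)
        np.testing.assert_array_equal(edge_weight_vector(net, "g1", "g2"), [0, 1, 0, 0])
        np.testing.assert_array_equal(edge_weight_vector(net, "g2", "g1"), [0, 0, 1, 0])

    def test_weight_sums_match_coexpression_counts(self, rng):
        states = random_state_matrix(rng, n_max=8, m_max=10)
        net = build_mwnet(states)
        vals = states.data
        for a, b in net.edges:
            w = edge_weight_vector(net, a, b)
            both = int(((vals[a] != 0) & (vals[b] != 0)).sum())
            assert w.sum() == both
            assert 1 <= w.sum() <= states.n_samples

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            states = random_state_matrix(rng)
            nodes, edges = brute_force_network(states)
            got_nodes, got_edges = network_as_dict(build_mwnet(states))
            assert got_nodes == nodes
            assert got_edges == edges

    def test_raising_epsilon_is_monotone(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(6, 10)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"g{j}" for j in range(10)],
        )
        gem = ExpressionMatrix(df)
        prev = None
        for eps in [0.0, 0.3, 0.8, 1.5]:
            net = build_mwnet(call_states(gem, eps, require_normalized=False))
            nodes, edges = network_as_dict(net)
            if prev is not None:
                pnodes, pedges = prev
                assert nodes <= pnodes
                assert set(edges) <= set(pedges)
                for e, w in edges.items():
                    assert all(x <= y for x, y in zip(w, pedges[e]))
            prev = (nodes, edges)


class TestNetworkIO:
    @pytest.mark.parametrize("fmt", ["edge_tsv", "graphml"])
    def test_roundtrip_exact(self, rng, tmp_path, fmt):
        states = random_state_matrix(rng, n_max=6, m_max=10)
        net = build_mwnet(states)
        path = tmp_path / ("net.graphml" if fmt == "graphml" else "net.tsv")
        write_network(net, path, format=fmt)
        back = read_network(path, format=fmt)
        assert network_as_dict(back) == network_as_dict(net)
        assert back.graph["n_samples"] == net.graph["n_samples"]

    def test_empty_network_writes_header_only(self, tmp_path):
        states = make_states([[NEUTRAL, NEUTRAL]], genes=["g1", "g2"])
        net = build_mwnet(states)
        path = tmp_path / "net.tsv"
        write_network(net, path)
        lines = path.read_text().splitlines()
        assert lines == ["gene_a\tgene_b\twOO\twOS\twSO\twSS"]
        back = read_network(path)
        assert back.number_of_nodes() == 0

    def test_unknown_format_rejected(self, tmp_path):
        net = build_mwnet(make_states([[OVER, OVER]], genes=["g1", "g2"]))
        with pytest.raises(ValueError, match="unknown network format"):
            write_network(net, tmp_path / "x", format="gexf")

    def test_canonical_file_independent_of_column_order(self, tmp_path):
        a = make_states([[OVER, SILENCED]], genes=["g1", "g2"])
        b = make_states([[SILENCED, OVER]], genes=["g2", "g1"])
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_network(build_mwnet(a), pa)
        write_network(build_mwnet(b), pb)
        assert pa.read_text() == pb.read_text()
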