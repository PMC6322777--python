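"""Finn cycling, trophic levels and Lindeman-spine transfer efficiencies."""

import numpy as np
import pytest

from stoichnet import (
    Element,
    NodeKind,
    SyntheticWebConfig,
    finn_cycling_index,
    synthesize_multinetwork,
    transfer_efficiencies,
    trophic_levels,
)

from conftest import make_network

P, C, D = NodeKind.PRODUCER, NodeKind.CONSUMER, NodeKind.DETRITUS


def oracle_fci(net):
    """Straight-from-formula cycling oracle: explicit matrix inversion."""
    T_i = np.maximum(net.T.sum(axis=0) + net.z, net.T.sum(axis=1) + net.e + net.r)
    n = net.n
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if T_i[j] > 0:
                G[i, j] = net.T[i, j] / T_i[j]
    N = np.linalg.inv(np.eye(n) - G)
    cycled = sum(T_i[i] * (N[i, i] - 1.0) / N[i, i] for i in range(n))
    return cycled / (net.T.sum() + net.z.sum())


def oracle_tl(net):
    """Node-by-node linear-system oracle for effective trophic levels."""
    n = net.n
    A = np.eye(n)
    b = np.ones(n)
    for j in range(n):
        if net.nodes[j].kind is not NodeKind.CONSUMER:
            continue
        intake = net.T[:, j].sum() + net.z[j]
        for i in range(n):
            A[j, i] -= net.T[i, j] / intake
        b[j] = 1.0 + net.z[j] / intake
    return np.linalg.solve(A, b)


class TestFinnCycling:
    def test_acyclic_network_has_zero_cycling(self):
        net = make_network(kinds=[P, C, C],
                           T=[[0, 6, 4], [0, 0, 2], [0, 0, 0]],
                           z=[10, 0, 0], r=[0, 4, 6])
        rep = finn_cycling_index(net)
        assert rep.fci == 0.0
        np.testing.assert_allclose(rep.N_diag, 1.0)

    def test_two_node_loop_matches_hand_inversion(self):
        # z1=10, T12=15, T21=5, e2=10: balanced loop; hand-invert the 2x2
        net = make_network(T=[[0, 15], [5, 0]], z=[10, 0], e=[0, 10])
        rep = finn_cycling_index(net)
        T_i = np.array([15.0, 15.0])
        G = np.array([[0, 15 / 15], [5 / 15, 0]])
        N = np.linalg.inv(np.eye(2) - G)
        expected = sum(T_i[i] * (N[i, i] - 1) / N[i, i] for i in range(2)) / 30.0
        assert rep.fci == pytest.approx(expected, rel=1e-12)
        assert 0.0 < rep.fci < 1.0

    def test_integral_diagonal_at_least_one(self, web_multi):
        multi, _ = web_multi
        for el in multi.elements:
            rep = finn_cycling_index(multi[el])
            assert np.all(rep.N_diag >= 1.0 - 1e-12)
            assert 0.0 <= rep.fci < 1.0

    def test_matches_formula_oracle_on_random_webs(self):
        for seed in range(20):
            multi, _ = synthesize_multinetwork(
                SyntheticWebConfig(seed=seed + 300, n_consumers=8)
            )
            net = multi[Element.CARBON]
            assert finn_cycling_index(net).fci == pytest.approx(
                oracle_fci(net), abs=1e-9
            )


class TestTrophicLevels:
    def test_simple_chain(self):
        net = make_network(kinds=[P, C, C],
                           T=[[0, 10, 0], [0, 0, 2], [0, 0, 0]],
                           z=[10, 0, 0], r=[0, 8, 2])
        np.testing.assert_allclose(trophic_levels(net), [1.0, 2.0, 3.0])

    def test_mixed_detritus_and_herbivore_diet(self):
        # 50% on TL1 detritus + 50% on TL2 herbivore -> TL 2.5
        net = make_network(
            kinds=[P, C, D, C],
            T=[[0, 10, 2, 0], [0, 0, 3, 5], [0, 0, 0, 5], [0, 0, 0, 0]],
            z=[12, 0, 0, 0], e=[0, 0, 0, 0], r=[0, 2, 0, 10],
        )
        tl = trophic_levels(net)
        assert tl[2] == pytest.approx(1.0)   # detritus pinned to 1
        assert tl[3] == pytest.approx(2.5)

    def test_import_diet_enters_at_level_one(self):
        net = make_network(kinds=[C], T=[[0.0]], z=[10.0], r=[10.0])
        assert trophic_levels(net)[0] == pytest.approx(2.0)

    def test_omnivorous_web_matches_linear_system_oracle(self):
        for seed in range(10):
            multi, _ = synthesize_multinetwork(
                SyntheticWebConfig(seed=seed + 500, n_consumers=9)
            )
            net = multi[Element.CARBON]
            np.testing.assert_allclose(trophic_levels(net), oracle_tl(net),
                                       atol=1e-9)

    def test_consumer_with_zero_consumption_is_an_error(self):
        net = make_network(kinds=[P, C], T=[[0, 0], [0, 0]], z=[1, 0],
                           e=[1, 0], B=[1, 1])
        with pytest.raises(ValueError, match="zero consumption"):
            trophic_levels(net)


class TestTransferEfficiencies:
    def test_chain_efficiencies_are_flow_ratios(self):
        # z1=100, T12=20, T23=2, rest respired: TE_I=0.20, TE_II=0.10
        net = make_network(kinds=[P, C, C],
                           T=[[0, 20, 0], [0, 0, 2], [0, 0, 0]],
                           z=[100, 0, 0], e=[80, 0, 0], r=[0, 18, 2])
        decomp = transfer_efficiencies(net)
        np.testing.assert_allclose(decomp.TE, [0.20, 0.10])
        assert not decomp.degenerate

    def test_producer_only_network_has_no_efficiencies(self):
        net = make_network(kinds=[P], T=[[0.0]], z=[10.0], e=[10.0])
        assert transfer_efficiencies(net).TE.size == 0

    def test_apportionment_shares_sum_to_one(self, web_multi):
        multi, _ = web_multi
        comp = transfer_efficiencies(multi[Element.CARBON]).composition
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_brute_force_path_enumeration(self):
        # acyclic omnivorous web: enumerate every diet path explicitly
        multi, truths = synthesize_multinetwork(
            SyntheticWebConfig(seed=42, n_consumers=4, detritivory=False)
        )
        assert truths.acyclic
        net = multi[Element.CARBON]
        n = net.n
        intake = net.T.sum(axis=0) + net.z
        consumer = [nd.kind is NodeKind.CONSUMER for nd in net.nodes]

        def shares(j, memo={}):
            if j in memo:
                return memo[j]
            if not consumer[j]:
                memo[j] = {1: 1.0}
                return memo[j]
            out = {}
            if net.z[j] > 0:
                out[2] = net.z[j] / intake[j]
            for i in range(n):
                if net.T[i, j] > 0:
                    for lev, frac in shares(i).items():
                        out[lev + 1] = out.get(lev + 1, 0.0) + \
                            frac * net.T[i, j] / intake[j]
            memo[j] = out
            return out

        decomp = transfer_efficiencies(net)
        m_max = decomp.composition.shape[1]
        for j in range(n):
            s = shares(j)
            for m in range(1, m_max + 1):
                assert decomp.composition[j, m - 1] == pytest.approx(
                    s.get(m, 0.0), abs=1e-12
                )
        # and the efficiencies from the explicit direct sums
        for m in range(1, m_max):
            level_in = sum(intake[j] * shares(j).get(m, 0.0) for j in range(n))
            passed = sum(
                net.T[i, j] * shares(i).get(m, 0.0)
                for i in range(n) for j in range(n)
                if consumer[j] and net.nodes[j].living
            )
            if level_in > 0:
                assert decomp.TE[m - 1] == pytest.approx(passed / level_in,
                                                         rel=1e-12)
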