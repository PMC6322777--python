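"""Biomass-inclusive ascendency, its gradients, and Liebig limitation."""

import numpy as np
import pandas as pd
import pytest

from stoichnet import (
    BalancerConfig,
    Element,
    MultiNetwork,
    NodeKind,
    SyntheticWebConfig,
    biomass_ascendency,
    classify_limitation,
    flow_sensitivities,
    liebig_classical,
    node_sensitivities,
    synthesize_multinetwork,
)
from stoichnet.ascendency import (
    numeric_flow_sensitivity,
    numeric_node_sensitivity,
)

from conftest import make_network

CNP = [Element.CARBON, Element.NITROGEN, Element.PHOSPHORUS]


def single_element_multi(net):
    return MultiNetwork(networks={Element.CARBON: net})


class TestAscendency:
    def test_mass_action_configuration_scores_zero(self):
        # flows T_ij = T.. B_i B_j / B.^2 with no boundary flows are exactly
        # the a-priori expectation: zero information gain
        rng = np.random.default_rng(0)
        B = rng.uniform(0.5, 5.0, 6)
        t_tot = 123.0
        T = t_tot * np.outer(B, B) / B.sum() ** 2
        net = make_network(T=T, B=B, z=np.zeros(6), e=np.zeros(6))
        res = biomass_ascendency(single_element_multi(net))
        assert abs(res.a_b) <= 1e-9 * t_tot

    def test_concentrating_flow_on_small_biomass_raises_a_b(self):
        # same T.., flows focused on the smallest-biomass pair beat mass action
        B = np.array([10.0, 1.0, 0.1])
        t_tot = 30.0
        T_ma = t_tot * np.outer(B, B) / B.sum() ** 2
        focused = np.zeros((3, 3))
        focused[1, 2] = t_tot  # small-biomass product pair
        a_ma = biomass_ascendency(
            single_element_multi(make_network(T=T_ma, B=B))
        ).a_b
        a_focus = biomass_ascendency(
            single_element_multi(make_network(T=focused, B=B))
        ).a_b
        assert a_focus > a_ma

    def test_per_element_contributions_sum_to_total(self, small_multi):
        multi, _ = small_multi
        res = biomass_ascendency(multi)
        assert res.a_b == pytest.approx(sum(res.per_element.values()), rel=1e-12)
        assert res.i_b == pytest.approx(res.a_b / res.total_flow)

    def test_single_element_form_matches_manual_formula(self):
        net = make_network(T=[[0, 8], [2, 0]], B=[2.0, 3.0], z=[6, 0], e=[0, 6])
        res = biomass_ascendency(single_element_multi(net))
        t_tot, b_tot = 10.0, 5.0
        manual = sum(
            t * np.log2(t * b_tot**2 / (t_tot * bi * bj))
            for t, bi, bj in [(8.0, 2.0, 3.0), (2.0, 3.0, 2.0)]
        )
        assert res.a_b == pytest.approx(manual, rel=1e-12)

    def test_flow_through_zero_biomass_node_names_the_pair(self):
        net = make_network(T=[[0, 5], [0, 0]], B=[1.0, 0.0], z=[5, 0], e=[0, 5])
        with pytest.raises(ValueError, match="1 -> 2"):
            biomass_ascendency(single_element_multi(net))


class TestGradients:
    def test_node_sensitivity_is_exact_gradient(self, small_multi):
        multi, _ = small_multi
        sens = node_sensitivities(multi, include_boundary=False)
        for el in multi.elements:
            net = multi[el]
            for p in range(net.n):
                analytic = sens.loc[net.nodes[p].id, el.symbol]
                if not np.isfinite(analytic) or net.B[p] <= 0:
                    continue
                numeric = numeric_node_sensitivity(multi, p, el)
                assert abs(analytic - numeric) <= 1e-6 * max(
                    abs(analytic), abs(numeric)
                )

    def test_flow_sensitivity_is_exact_gradient(self, small_multi):
        multi, _ = small_multi
        table = flow_sensitivities(multi)
        by_symbol = {el.symbol: el for el in multi.elements}
        for row in table.itertuples(index=False):
            el = by_symbol[row.element]
            net = multi[el]
            i, j = net.index_of(row.source), net.index_of(row.recipient)
            numeric = numeric_flow_sensitivity(multi, el, i, j)
            assert abs(row.sensitivity - numeric) <= 1e-6 * max(
                abs(row.sensitivity), abs(numeric)
            )

    def test_sensitivity_vanishes_at_system_turnover_rate(self):
        # solve B_p so the node's element turnover equals the system's
        net = make_network(T=[[0, 8], [2, 0]], B=[2.0, 3.0], z=[6, 0], e=[0, 6])
        multi = single_element_multi(net)
        p = 1
        c = 0.5 * (net.T[:, p].sum() + net.z[p] + net.T[p, :].sum()
                   + net.e[p] + net.r[p])
        b_other = net.B.sum() - net.B[p]
        t_dots = multi.total_flow()
        net.B[p] = c * b_other / (t_dots - c)
        sens = node_sensitivities(multi, include_boundary=True)
        assert sens.iloc[p]["C"] == pytest.approx(0.0, abs=1e-12)

    def test_flow_at_mass_action_expectation_scores_zero(self):
        rng = np.random.default_rng(1)
        B = rng.uniform(1, 4, 4)
        t_tot = 40.0
        T = t_tot * np.outer(B, B) / B.sum() ** 2
        table = flow_sensitivities(
            single_element_multi(make_network(T=T, B=B))
        )
        np.testing.assert_allclose(table["sensitivity"], 0.0, atol=1e-12)


class TestLimitation:
    def test_turnover_gradient_separates_guilds(self, web_multi):
        # fast-turnover microbes deplete faster than the system (negative
        # sensitivity); slow large organisms are positive and mutually similar
        multi, truths = web_multi
        sens = node_sensitivities(multi)
        microbial = [i for i, g in truths.guilds.items() if g == "microbial"]
        fish = [i for i, g in truths.guilds.items() if g == "fish"]
        assert sens.loc[microbial, "C"].mean() < 0
        assert (sens.loc[fish] > 0).all().all()
        spread = sens.loc[fish].std() / sens.loc[fish].mean()
        assert (spread < 0.5).all()

    def test_nutrient_pools_are_excluded(self, web_multi):
        multi, _ = web_multi
        report = classify_limitation(multi)
        pool_ids = [nd.id for nd in multi.nodes
                    if nd.kind is NodeKind.NUTRIENT_POOL]
        assert pool_ids
        assert not set(pool_ids) & set(report.limitation.index)

    def test_constructed_deficiency_is_recovered(self):
        # node receiving C, N in its biomass proportions but P at half rate
        nets = {}
        for el, supply in zip(CNP, [10.0, 10.0, 5.0]):
            nets[el] = make_network(
                element=el, kinds=[NodeKind.PRODUCER, NodeKind.CONSUMER],
                T=[[0, supply], [0, 0]], z=[supply, 0], e=[0, supply],
                B=[1.0, 1.0],
            )
        report = classify_limitation(MultiNetwork(networks=nets))
        assert report.limitation.loc[2, "limiting_element"] == "P"
        assert not report.limitation.loc[2, "co_limited"]

    def test_equal_relative_supply_is_full_co_limitation(self):
        nets = {}
        for el in CNP:
            nets[el] = make_network(
                element=el, kinds=[NodeKind.PRODUCER, NodeKind.CONSUMER],
                T=[[0, 7.0], [0, 0]], z=[7.0, 0], e=[0, 7.0], B=[1.0, 1.0],
            )
        table = liebig_classical(MultiNetwork(networks=nets))
        assert bool(table.loc[2, "co_limited"])
        assert table.loc[2, "co_limiting_set"] == "CNP"
        assert table.loc[2, "limiting_element"] == "C"  # deterministic label

    def test_liebig_routes_agree_on_balanced_webs(self):
        cfg_bal = BalancerConfig(tolerance=1e-6)
        for seed in range(25):
            multi, _ = synthesize_multinetwork(
                SyntheticWebConfig(seed=seed + 700, n_consumers=10), cfg_bal
            )
            a = classify_limitation(multi).limitation["limiting_element"]
            b = liebig_classical(multi)["limiting_element"]
            pd.testing.assert_series_equal(a, b)

    def test_routes_can_diverge_on_unbalanced_networks(self):
        # supply-only ranks N scarcest; the in+out average ranks P scarcest
        supplies = {Element.CARBON: 10.0, Element.NITROGEN: 1.0,
                    Element.PHOSPHORUS: 5.0}
        drains = {Element.CARBON: 10.0, Element.NITROGEN: 19.0,
                  Element.PHOSPHORUS: 5.0}
        nets = {
            el: make_network(
                element=el, kinds=[NodeKind.PRODUCER, NodeKind.CONSUMER],
                T=[[0, supplies[el]], [0, 0]], z=[supplies[el], 0],
                e=[0, drains[el]], B=[1.0, 1.0],
            )
            for el in CNP
        }
        multi = MultiNetwork(networks=nets)
        classical = liebig_classical(multi).loc[2, "limiting_element"]
        sens_based = classify_limitation(multi).limitation.loc[2,
                                                               "limiting_element"]
        assert classical == "N"
        assert sens_based == "P"

    def test_classification_is_scale_invariant(self, small_multi):
        multi, _ = small_multi
        base = classify_limitation(multi).limitation["limiting_element"]
        scaled = MultiNetwork(networks={
            el: make_network(
                element=el, kinds=[nd.kind for nd in multi.nodes],
                T=multi[el].T * 250.0, z=multi[el].z * 250.0,
                e=multi[el].e * 250.0, r=multi[el].r * 250.0, B=multi[el].B,
            )
            for el in multi.elements
        })
        # re-attach the true node specs (ratios, names)
        for el in scaled.elements:
            scaled[el].nodes = list(multi.nodes)
        after = classify_limitation(scaled).limitation["limiting_element"]
        pd.testing.assert_series_equal(base, after)

    def test_summary_percentages_cover_classified_nodes(self, web_multi):
        multi, _ = web_multi
        report = classify_limitation(multi)
        assert sum(report.summary.values()) == pytest.approx(100.0)


class TestFlowRanking:
    def test_ranked_with_identities_and_zero_flows_skipped(self, small_multi):
        multi, _ = small_multi
        table = flow_sensitivities(multi)
        assert (table["flow"] > 0).all()
        assert table["sensitivity"].is_monotonic_decreasing
        assert {"source_name", "recipient_name", "rank"} <= set(table.columns)

    def test_limiting_flows_are_phosphorus_on_p_scarce_webs(self, web_multi):
        # the study-like configuration: P flows deplete their sources fastest
        multi, _ = web_multi
        table = flow_sensitivities(multi)
        assert table.iloc[0]["element"] == "P"
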