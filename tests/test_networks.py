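"""Trait-level network reconstruction and export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lidm.data import NetworkSpec
from lidm.networks import (
    build_network,
    export_network,
    predicted_tie_weight,
    read_edge_list,
)
from lidm.parameters import LidmParameters
from lidm.model import predict_response
from .conftest import make_sim


def _spec_params(n=4, L=2, I=2, seed=0, model=1):
    spec = NetworkSpec.balanced(n, L, I)
    rng = np.random.default_rng(seed)
    T = L * I
    p = LidmParameters(
        beta0=rng.normal(), beta_S=rng.normal(size=T),
        beta_R=np.abs(rng.normal(size=T)) + 0.1,
        sigma=np.ones(T), theta=rng.normal(size=(n, L)), rho_theta=0.25,
        beta_D=-rng.uniform(0.05, 0.3, T) if model == 2 else None)
    return spec, p


class TestPredictedTieWeight:
    def test_single_item_subscale_equals_prediction(self):
        spec, p = _spec_params(I=1)
        w = predicted_tie_weight(p, 1, spec, 0, 1, subscale=2)
        assert w == pytest.approx(predict_response(1, p, spec, 1, 0, 1))

    def test_null_effects_give_count_times_grand_mean(self):
        spec, p = _spec_params(I=3)
        p.beta_S[:] = 0.0
        p.beta_R[:] = 1e-12
        w = predicted_tie_weight(p, 1, spec, 0, 2, subscale=1)
        assert w == pytest.approx(3 * p.beta0, abs=1e-9)

    def test_worked_arithmetic_on_reported_estimates(self):
        # 15-member trust fit, Model 1 EAPs: first-subscale items
        # (1.24, 0.14), (0.64, 0.22), (0.93, 0.08); members 1 and 2 score
        # 0.09 and 0.52 on that dimension; beta0 = 3.70.
        spec = NetworkSpec.balanced(15, 2, 3)
        theta = np.zeros((15, 2))
        theta[0, 0], theta[1, 0] = 0.09, 0.52
        p = LidmParameters(
            beta0=3.70, beta_S=[1.24, 0.64, 0.93, 0, 0, 0],
            beta_R=[0.14, 0.22, 0.08, 1e-9, 1e-9, 1e-9],
            sigma=np.ones(6), theta=theta, rho_theta=0.41)
        per_item = [3.70 + bs * 0.09 + br * 0.52
                    for bs, br in [(1.24, 0.14), (0.64, 0.22), (0.93, 0.08)]]
        w = predicted_tie_weight(p, 1, spec, 0, 1, subscale=1)
        assert w == pytest.approx(sum(per_item))

    def test_unknown_subscale(self):
        spec, p = _spec_params()
        with pytest.raises(KeyError):
            predicted_tie_weight(p, 1, spec, 0, 1, subscale=9)

    def test_distance_monotonicity_under_model2(self):
        """Holding both members' scores on the measured dimension fixed,
        moving them apart on the other dimension (pure distance increase)
        never increases a tie weight when distance effects are negative."""
        spec, p = _spec_params(model=2)
        weights = []
        for gap in np.linspace(0.0, 3.0, 7):
            p.theta[1, 1] = p.theta[0, 1] + gap
            weights.append(predicted_tie_weight(p, 2, spec, 0, 1, subscale=1))
        assert np.all(np.diff(weights) <= 1e-12)


class TestBuildNetwork:
    def test_complete_digraph_edge_count(self):
        spec, p = _spec_params(n=5)
        net, _ = build_network(p, 1, spec, subscale=1)
        frame = net.edge_frame()
        assert len(frame) == 5 * 4
        assert np.all(np.diag(net.weights) == 0)

    def test_symmetric_traits_give_symmetric_weights(self):
        spec, p = _spec_params(n=4)
        p.theta[:] = 0.7  # every member identical
        net, _ = build_network(p, 1, spec, subscale=2)
        np.testing.assert_allclose(net.weights, net.weights.T)

    def test_raw_score_companion_from_observed_table(self, trust_table):
        spec, p = _spec_params(n=4, I=3)
        net, raw = build_network(p, 1, trust_table.spec, subscale=1,
                                 data=trust_table)
        assert raw[0, 1] == 9    # 3+4+2
        assert raw[1, 0] == 12   # 5+3+4

    def test_predicted_correlates_with_raw_scores(self):
        """On moderately noisy simulated data the truth-derived trait
        network must rank-correlate positively with raw summed scores."""
        for seed in (1, 2, 3):
            cfg, truth, table = make_sim(n=10, model=1, seed=seed)
            net, raw = build_network(truth, 1, table.spec, subscale=1,
                                     data=table)
            off = ~np.eye(10, dtype=bool)
            rho = stats.spearmanr(net.weights[off], raw[off]).statistic
            assert rho > 0


class TestExport:
    def test_edge_list_round_trip_exact(self, tmp_path):
        spec, p = _spec_params(n=4)
        net, _ = build_network(p, 1, spec, subscale=1)
        path = export_network(net, tmp_path / "net.csv", fmt="csv")
        back = read_edge_list(path)
        pd.testing.assert_frame_equal(back, net.edge_frame(),
                                      check_dtype=False)

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx
        spec, p = _spec_params(n=4)
        net, _ = build_network(p, 1, spec, subscale=2)
        path = export_network(net, tmp_path / "net.graphml", fmt="graphml")
        g = nx.read_graphml(path)
        # graphml stringifies node ids; weights preserved exactly
        for row in net.edge_frame().itertuples(index=False):
            assert g[str(row.source)][str(row.target)]["weight"] == \
                pytest.approx(row.weight)

    def test_graphml_is_well_formed_xml(self, tmp_path):
        from lxml import etree
        spec, p = _spec_params(n=3)
        net, _ = build_network(p, 1, spec, subscale=1)
        path = export_network(net, tmp_path / "n.graphml", fmt="graphml")
        root = etree.parse(str(path)).getroot()
        assert root.tag.endswith("graphml")

    def test_multivariate_export_edge_count(self, tmp_path):
        spec, p = _spec_params(n=5)
        frames = []
        for sub in (1, 2):
            net, _ = build_network(p, 1, spec, subscale=sub)
            frames.append(net.edge_frame())
        both = pd.concat(frames)
        assert len(both) == 2 * 5 * 4

    def test_bit_stable_export(self, tmp_path):
        spec, p = _spec_params(n=4)
        net, _ = build_network(p, 1, spec, subscale=1)
        p1 = export_network(net, tmp_path / "a.csv", fmt="csv")
        p2 = export_network(net, tmp_path / "b.csv", fmt="csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_unsupported_format(self, tmp_path):
        spec, p = _spec_params(n=3)
        net, _ = build_network(p, 1, spec, subscale=1)
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "n.bin", fmt="bin")
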