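import numpy as np
import pytest

from eicon.core_spectra import EpochedSignals
from eicon.evaluation import (
    FCMap,
    classify_tp_fp,
    full_fc_map,
    label_permuted_map,
    mc_harness,
    percentile_graphs,
    roc_auc,
    tally_scores,
)
from eicon.fc_measures import measure_curve
from eicon.core_spectra import center_epochs, epoch_fft
from eicon.io import SensorScenario
from eicon.mixing_forward import SensorROIs


def _map(weights, measure="coh", band=(18.0, 22.0)):
    return FCMap(weights=np.asarray(weights, dtype=float), measure=measure, band=band)


class TestFullFCMap:
    def test_two_sensors_single_edge(self, rng):
        x = EpochedSignals(rng.normal(size=(6, 2, 64)), 250.0)
        fc = full_fc_map(x, "coh", band=(10.0, 30.0))
        assert fc.weights.shape == (2, 2)
        assert fc.weights[0, 1] == fc.weights[1, 0] > 0
        assert fc.weights[0, 0] == 0.0

    def test_duplicated_sensor_has_unit_coherence(self, rng):
        a = rng.normal(size=(6, 1, 64))
        x = EpochedSignals(np.concatenate([a, a, rng.normal(size=a.shape)], axis=1),
                           250.0)
        fc = full_fc_map(x, "coh", band=(5.0, 50.0))
        assert fc.weights[0, 1] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("measure", ["coh", "icoh1", "wpli", "eic2"])
    def test_matches_per_pair_curves(self, rng, measure):
        x = EpochedSignals(rng.normal(size=(5, 4, 64)), 250.0)
        band = (8.0, 40.0)
        fc = full_fc_map(x, measure, band=band)
        spec = epoch_fft(center_epochs(x))
        sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
        for i in range(4):
            for j in range(i + 1, 4):
                curve = measure_curve(spec, measure, i, j).values
                assert fc.weights[i, j] == pytest.approx(
                    np.abs(curve[sel]).max(), abs=1e-12
                )

    def test_empty_band_rejected(self, rng):
        x = EpochedSignals(rng.normal(size=(2, 2, 64)), 250.0)
        with pytest.raises(ValueError, match="band"):
            full_fc_map(x, "coh", band=(10.2, 10.4))


class TestPercentileGraphs:
    def test_endpoints_all_and_none(self):
        w = np.zeros((4, 4))
        w[np.triu_indices(4, 1)] = [1, 2, 3, 4, 5, 6]
        w = w + w.T
        graphs = percentile_graphs(_map(w), 3)
        assert len(graphs) == 4
        assert len(graphs[0]) == 6  # complete graph
        assert len(graphs[-1]) == 0  # empty by definition

    def test_equal_weight_ties_kept(self):
        w = np.zeros((4, 4))
        w[np.triu_indices(4, 1)] = 1.0
        w = w + w.T
        graphs = percentile_graphs(_map(w), 2)
        # all weights equal: every threshold below the top keeps all edges
        assert len(graphs[0]) == len(graphs[1]) == 6
        assert len(graphs[2]) == 0

    def test_matches_sort_based_oracle(self, rng):
        n = 8
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.random(len(iu[0]))
        w[iu] = vals
        w = w + w.T
        m_steps = 10
        graphs = percentile_graphs(_map(w), m_steps)
        for m in range(m_steps):
            thr = np.percentile(vals, 100.0 * m / m_steps)
            assert len(graphs[m]) == int((vals >= thr).sum())

    def test_m_below_one_rejected(self):
        with pytest.raises(ValueError):
            percentile_graphs(_map(np.zeros((3, 3))), 0)


class TestClassification:
    ROIS = SensorROIs(sensors=((0, 1, 2), (3, 4, 5)), k=3)

    def test_exhaustive_toy_counts(self):
        edges = np.array([(i, j) for i in range(6) for j in range(i + 1, 6)])
        tp, fp = classify_tp_fp(edges, self.ROIS)
        assert tp == 9  # 3 x 3 cross-region pairs
        assert fp == 6  # 3 within each region
        assert tp + fp == len(edges)

    def test_within_region_edge_is_fp(self):
        assert classify_tp_fp(np.array([[0, 1]]), self.ROIS) == (0, 1)

    def test_cross_region_edge_is_tp(self):
        assert classify_tp_fp(np.array([[0, 3]]), self.ROIS) == (1, 0)

    def test_edge_touching_unassigned_sensor_is_fp(self):
        assert classify_tp_fp(np.array([[0, 7]]), self.ROIS) == (0, 1)


class TestROC:
    def _geometry(self):
        return SensorROIs(sensors=((0, 1), (2, 3)), k=2)

    def test_perfect_separation_gives_auc_one(self):
        w = np.zeros((6, 6))
        # every cross-region pair outweighs every other pair
        for i in (0, 1):
            for j in (2, 3):
                w[i, j] = w[j, i] = 1.0
        w[4, 5] = w[5, 4] = 0.1
        w[0, 1] = w[1, 0] = 0.2
        roc = roc_auc(_map(w), self._geometry(), 50)
        assert roc.auc == pytest.approx(1.0)

    def test_random_weights_give_chance_auc(self, rng):
        aucs = []
        rois = self._geometry()
        n = 10
        iu = np.triu_indices(n, 1)
        for _ in range(100):
            w = np.zeros((n, n))
            w[iu] = rng.permutation(len(iu[0])) + 1.0
            w = w + w.T
            aucs.append(roc_auc(_map(w), rois, 50).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_rates_monotone_and_anchored(self, rng):
        n = 8
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        w[iu] = rng.random(len(iu[0]))
        w = w + w.T
        roc = roc_auc(_map(w), self._geometry(), 100)
        assert roc.tpr[0] == roc.fpr[0] == 1.0
        assert np.all(np.diff(roc.tpr) <= 1e-12)
        assert np.all(np.diff(roc.fpr) <= 1e-12)
        assert 0.0 <= roc.auc <= 1.0
        np.testing.assert_array_equal(roc.tp + roc.fp,
                                      [len(g) for g in percentile_graphs(_map(w), 100)])

    def test_auc_invariant_under_monotone_transform(self, rng):
        n = 8
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        w[iu] = rng.random(len(iu[0]))
        w = w + w.T
        rois = self._geometry()
        a = roc_auc(_map(w), rois, 40)
        b = roc_auc(_map(np.expm1(3 * w)), rois, 40)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        np.testing.assert_array_equal(a.tp, b.tp)

    def test_degenerate_geometry_rejected(self):
        w = np.ones((3, 3)) - np.eye(3)
        rois = SensorROIs(sensors=((0, 1, 2),), k=3)  # single region: no TP
        with pytest.raises(ValueError, match="degenerate"):
            roc_auc(_map(w), rois, 10)

    def test_label_permutation_preserves_weights(self, rng):
        n = 6
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        w[iu] = rng.random(len(iu[0]))
        w = w + w.T
        perm = label_permuted_map(_map(w), rng)
        assert sorted(perm.weights[iu]) == pytest.approx(sorted(w[iu]))


class TestMCHarness:
    def test_small_scenario_runs_and_orders_pairs(self):
        scen = SensorScenario(
            name="tiny", model="mvar", n_rois=3, alpha=0.5, beta=0.9,
            n_trials=20, n_sensors=24, n_background=30, layout_seed=5,
        )
        comp = mc_harness([scen], ["icoh1", "eic2"], n_realizations=3,
                          kns_range=(2, 3), seed=0)
        a = comp.auc[("tiny", "icoh1")]
        b = comp.auc[("tiny", "eic2")]
        assert a.shape == b.shape == (3,)
        assert np.all((a > 0) & (a < 1))
        key = ("tiny", "icoh1", "eic2")
        assert 0.0 <= comp.pairwise[key]["p"] <= 1.0
        assert comp.bonferroni_n == 1

    def test_requires_scenarios_and_replicates(self):
        with pytest.raises(ValueError):
            mc_harness([], ["coh"], 5)
        scen = SensorScenario(name="x", n_sensors=12, n_background=5, n_trials=4)
        with pytest.raises(ValueError):
            mc_harness([scen], ["coh"], 1)


class TestScoring:
    def test_hand_built_tournament(self):
        # a beats b twice, draws c once; b beats c once
        outcomes = [
            ("a", "b", "a"),
            ("a", "b", "a"),
            ("a", "c", None),
            ("b", "c", "b"),
        ]
        rec = tally_scores(outcomes)
        assert rec["a"] == {"W": 2, "L": 0, "D": 1,
                            "league_points": 7, "chess_points": 2.5}
        assert rec["b"]["W"] == 1 and rec["b"]["L"] == 2
        assert rec["c"] == {"W": 0, "L": 1, "D": 1,
                            "league_points": 1, "chess_points": 0.5}

    def test_unknown_winner_rejected(self):
        with pytest.raises(ValueError):
            tally_scores([("a", "b", "z")])
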