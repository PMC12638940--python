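"""Centralities, hyperparameter search, and the validation battery."""

from __future__ import annotations

from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from biomarknet.features import Dataset
from biomarknet.learn import (DegenerateLabelsError, LearnError, ModelSpec,
                              SchemaError, ablation_by_feature_group,
                              cross_network_validate, default_feature_groups,
                              halving_random_search, make_estimator,
                              node_centralities, predict_probabilities,
                              train_model, validate)
from biomarknet.motifs import SignedNetwork

from .conftest import network_from_edges, random_signed_edges


def toy_dataset(n=60, n_features=5, seed=0, informative=True,
                network="n1") -> Dataset:
    """Labelled dataset where feature f0 equals the label (separable)."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(float)
    X = rng.normal(size=(n, n_features))
    if informative:
        X[:, 0] = y
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    table.insert(0, "neighbour_id", [f"N{i}" for i in range(n)])
    table.insert(1, "target_id", ["T"] * n)
    table.insert(2, "network", [network] * n)
    table["label"] = y
    return Dataset(table, [f"f{i}" for i in range(n_features)])


FAST_RF = ModelSpec("random_forest", {"n_estimators": 30, "max_depth": 4},
                    random_state=0)
FAST_GBT = ModelSpec("gradient_boosted_trees",
                     {"n_estimators": 30, "max_depth": 3}, random_state=0)


class TestCentralities:
    def test_path_centre(self):
        net = network_from_edges([("A", "B", 1), ("B", "C", 1)])
        cents = node_centralities(net)
        assert cents["B"][0] > cents["A"][0] == cents["C"][0] == 0.0

    def test_star_centre_maximal(self):
        edges = [("HUB", f"L{i}", 1) for i in range(5)]
        cents = node_centralities(network_from_edges(edges))
        hub_b = cents["HUB"][0]
        assert all(hub_b >= cents[f"L{i}"][0] for i in range(5))

    def test_isolated_node_zero(self):
        net = SignedNetwork(edges=[], nodes=["A", "B", "LONE"])
        cents = node_centralities(net)
        assert cents["LONE"] == (0.0, 0.0)

    def test_betweenness_matches_path_enumeration(self):
        """Brute-force all-pairs shortest-path recount on a 20-node graph."""
        rng = np.random.default_rng(5)
        edges = random_signed_edges(rng, 20, 0.15, 0.3)
        net = network_from_edges(edges)
        cents = node_centralities(net)
        g = net.to_networkx()
        n = g.number_of_nodes()
        raw = dict.fromkeys(g.nodes, 0.0)
        for s in g.nodes:
            for t in g.nodes:
                if s == t or not nx.has_path(g, s, t):
                    continue
                paths = list(nx.all_shortest_paths(g, s, t))
                for path in paths:
                    for v in path[1:-1]:
                        raw[v] += 1.0 / len(paths)
        scale = 1.0 / ((n - 1) * (n - 2))
        for v in g.nodes:
            assert cents[v][0] == pytest.approx(raw[v] * scale)


class TestHalvingSearch:
    def test_budget_one_returns_the_candidate(self):
        ds = toy_dataset()
        spec, est, trace = halving_random_search(ds, "random_forest",
                                                 budget=1, seed=3)
        assert len({t["round"] for t in trace}) == 1
        assert est.predict(ds.X).shape == (len(ds.table),)

    def test_deterministic_per_seed(self):
        ds = toy_dataset()
        a, _, _ = halving_random_search(ds, "gradient_boosted_trees",
                                        budget=4, seed=11)
        b, _, _ = halving_random_search(ds, "gradient_boosted_trees",
                                        budget=4, seed=11)
        assert a.hyperparameters == b.hyperparameters

    def test_winner_at_least_median(self):
        """The winner's full-data CV accuracy >= median of all sampled
        candidates evaluated exhaustively on the full data."""
        from biomarknet.learn import (DEFAULT_GRID, _cv_accuracy,
                                      _sample_candidates)
        ds = toy_dataset(n=80, seed=4)
        spec, _, _ = halving_random_search(ds, "random_forest", budget=6,
                                           seed=7)
        rng = np.random.default_rng(7)
        sampled = _sample_candidates(DEFAULT_GRID["random_forest"], 6, rng)
        assert spec.hyperparameters in sampled
        X, y = ds.X, ds.y.astype(int)
        scores = {
            repr(sorted(c.items())): _cv_accuracy(
                make_estimator(ModelSpec("random_forest", c, 7)), X, y, 7)
            for c in sampled}
        winner_score = scores[repr(sorted(spec.hyperparameters.items()))]
        assert winner_score >= np.median(list(scores.values())) - 1e-9

    def test_single_class_rejected(self):
        ds = toy_dataset()
        ds.table["label"] = 1.0
        with pytest.raises(DegenerateLabelsError):
            halving_random_search(ds, "random_forest", budget=2, seed=0)


class TestValidate:
    def test_separable_loocv(self):
        ds = toy_dataset(n=40)
        report = validate(ds, FAST_RF, scheme="loocv")
        assert report.metrics["accuracy"] >= 0.95
        assert len(report.probabilities) == 40

    def test_permuted_labels_chance_auc(self):
        ds = toy_dataset(n=200, informative=False, seed=5)
        report = validate(ds, FAST_RF, scheme="loocv")
        assert 0.35 <= report.metrics["roc_auc"] <= 0.65

    def test_f1_harmonic_mean_identity(self):
        ds = toy_dataset(n=60)
        report = validate(ds, FAST_GBT, scheme="split_70_30", seed=2)
        m = report.metrics
        if m["precision"] + m["recall"] > 0:
            assert m["f1"] == pytest.approx(
                2 * m["precision"] * m["recall"]
                / (m["precision"] + m["recall"]))

    def test_repeated_kfold_reports_per_repeat(self):
        ds = toy_dataset(n=50)
        report = validate(ds, FAST_RF, scheme="repeated_kfold", n_repeats=3)
        assert len(report.per_fold) == 3
        assert 0 <= report.metrics["accuracy"] <= 1

    def test_loocv_order_invariant(self):
        ds = toy_dataset(n=30, seed=9)
        shuffled_table = ds.table.sample(frac=1.0, random_state=1)
        ds2 = Dataset(shuffled_table.reset_index(drop=True),
                      list(ds.feature_names))
        r1 = validate(ds, FAST_RF, scheme="loocv")
        r2 = validate(ds2, FAST_RF, scheme="loocv")
        key1 = dict(zip(ds.table["neighbour_id"], r1.probabilities))
        key2 = dict(zip(ds2.table["neighbour_id"], r2.probabilities))
        assert key1 == pytest.approx(key2)

    def test_too_small_dataset(self):
        ds = toy_dataset(n=6)
        with pytest.raises(LearnError):
            validate(ds, FAST_RF, scheme="loocv")


class TestAblation:
    def test_full_group_equals_plain_validate(self):
        ds = toy_dataset(n=40)
        full = validate(ds, FAST_RF, scheme="loocv")
        abl = ablation_by_feature_group(ds, {"all": ds.feature_names},
                                        FAST_RF)
        assert abl["all"].metrics == full.metrics

    def test_constant_column_uninformative(self):
        # held-out probabilities of a constant feature are all equal, so
        # ROC AUC is exactly chance on the 70:30 split
        ds = toy_dataset(n=100, seed=2)
        ds.table["f4"] = 1.0
        abl = ablation_by_feature_group(ds, {"const": ["f4"]}, FAST_RF,
                                        scheme="split_70_30")
        assert abl["const"].metrics["roc_auc"] == pytest.approx(0.5)

    def test_planted_group_wins(self):
        """Only the 'topological' group carries signal."""
        ds = toy_dataset(n=100, seed=3)   # f0 equals the label
        abl = ablation_by_feature_group(
            ds, {"signal": ["f0"], "noise": ["f1", "f2"]}, FAST_RF)
        assert abl["signal"].metrics["accuracy"] > \
            abl["noise"].metrics["accuracy"]

    def test_empty_group_rejected(self):
        ds = toy_dataset()
        with pytest.raises(LearnError):
            ablation_by_feature_group(ds, {"empty": []}, FAST_RF)

    def test_default_groups_cover_schema(self):
        names = ["n_triangles", "sign_nt", "neighbour_disprot_content",
                 "neighbour_betweenness", "target_modality_antibody",
                 "in_net_x"]
        groups = default_feature_groups(names)
        assert set(groups["biological"]) \
            | set(groups["topological"]) == set(names)
        assert not set(groups["biological"]) & set(groups["topological"])
        assert groups["motif_counts"] == ["n_triangles"]


class TestCrossNetwork:
    def test_identity_matches_resubstitution(self):
        ds = toy_dataset(n=40)
        cross = cross_network_validate(ds, ds, FAST_RF)
        resub = validate(ds, FAST_RF, scheme="resubstitution")
        assert cross.metrics == resub.metrics

    def test_shared_signal_transfers(self):
        a = toy_dataset(n=80, seed=1, network="a")
        b = toy_dataset(n=80, seed=2, network="b")
        report = cross_network_validate(a, b, FAST_GBT)
        assert report.metrics["roc_auc"] > 0.8

    def test_disjoint_signal_near_chance(self):
        a = toy_dataset(n=120, seed=1, network="a")
        b = toy_dataset(n=120, seed=2, network="b", informative=False)
        report = cross_network_validate(a, b, FAST_RF)
        assert 0.3 <= report.metrics["roc_auc"] <= 0.7

    def test_schema_mismatch(self):
        a = toy_dataset(n=30)
        b = toy_dataset(n=30, n_features=3)
        with pytest.raises(SchemaError):
            cross_network_validate(a, b, FAST_RF)


class TestPredict:
    def test_matrix_shape_and_range(self):
        ds = toy_dataset(n=30)
        models = [(FAST_RF, train_model(ds, FAST_RF)),
                  (FAST_GBT, train_model(ds, FAST_GBT))]
        probs = predict_probabilities(ds, models)
        assert probs.shape == (30, 2)
        assert ((probs.values >= 0) & (probs.values <= 1)).all()
        assert list(probs.columns) == [FAST_RF.name, FAST_GBT.name]

    def test_duplicated_row_identical_probability(self):
        ds = toy_dataset(n=30)
        est = train_model(ds, FAST_RF)
        X = ds.X
        p1 = est.predict_proba(X[[0]])[0, 1]
        p2 = est.predict_proba(np.vstack([X[0], X[0]]))[:, 1]
        assert p1 == p2[0] == p2[1]

    def test_feature_importance_recovers_planted_signal(self):
        """Label = indicator on one column: that column ranks first."""
        ds = toy_dataset(n=150, seed=6)
        est = train_model(ds, FAST_RF)
        assert int(np.argmax(est.feature_importances_)) == 0


def test_modelspec_scope_space():
    """2 algorithms x 4 training scopes x 4 annotation scopes = 32 models."""
    from biomarknet.learn import ALGORITHMS, ANNOTATION_SCOPES
    scopes = ["netA", "netB", "netC", "combined"]
    specs = [ModelSpec(a, training_scope=t, annotation_scope=s)
             for a in ALGORITHMS for t in scopes for s in ANNOTATION_SCOPES]
    assert len(specs) == 32
    assert len({s.name for s in specs}) == 32
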