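"""Hierarchical gate tree: structure, threshold derivation, application."""

import numpy as np
import pandas as pd
import pytest

import lungspectra as ls
from lungspectra.gating import (
    GateNode,
    GateTree,
    GateTreeClassifier,
    build_lung_gate_tree,
    derive_thresholds,
    evaluate_recovery,
    marker_frame,
)
from lungspectra.simulate import LEVELS
from lungspectra.unmix import unmix_ols


@pytest.fixture(scope="module")
def tree():
    return build_lung_gate_tree()


class TestTreeStructure:
    def test_resolves_17_terminal_target_populations(self, tree):
        assert len(tree.target_populations) == 17
        assert len(set(tree.target_populations)) == 17

    def test_references_18_lineage_antibodies(self, tree):
        markers = tree.referenced_markers(
            exclude=("Viability", "CD206", "CX3CR1", "CD44", "CD62L")
        )
        assert len(markers) == 18

    def test_treg_path_descends_the_lymphoid_branch(self, tree):
        path = tree.path_to("Treg")
        assert path == [
            "All events",
            "Non-debris",
            "Singlets",
            "Live",
            "CD45+",
            "Lymphoid",
            "T cells",
            "T helper",
            "Treg",
        ]

    def test_duplicate_terminal_population_is_rejected(self):
        nodes = {
            "root": GateNode("root", None),
            "a": GateNode("a", "root", population="X"),
            "b": GateNode("b", "root", population="X"),
        }
        with pytest.raises(ValueError, match="unique"):
            GateTree(nodes=nodes, threshold_specs={})

    def test_multiple_roots_are_rejected(self):
        nodes = {"a": GateNode("a", None), "b": GateNode("b", None)}
        with pytest.raises(ValueError, match="root"):
            GateTree(nodes=nodes, threshold_specs={})


class TestDeriveThresholds:
    def test_thresholds_separate_the_level_means(self, fitted_classifier):
        thr = fitted_classifier.thresholds_
        for ref, spec in fitted_classifier.tree_.threshold_specs.items():
            if spec["kind"] in ("pos", "lowpos"):
                assert LEVELS["neg"] < thr[ref] < LEVELS["hi"]
        assert LEVELS["neg"] < thr["CD3:pos"] < LEVELS["pos"]
        assert LEVELS["low"] < thr["CD127:lowpos"] < LEVELS["pos"]

    def test_rederivation_is_deterministic(self, tree, default_frame, default_sample):
        a, _ = derive_thresholds(tree, default_frame, default_sample.truth_labels)
        b, _ = derive_thresholds(tree, default_frame, default_sample.truth_labels)
        assert a == b

    def test_overlapping_references_are_flagged(self, tree, default_frame, default_sample):
        degenerate = default_frame.copy()
        degenerate["CD3"] = 1.0  # identical neg and pos distributions
        _, problems = derive_thresholds(tree, degenerate, default_sample.truth_labels)
        assert any("CD3" in p for p in problems)

    def test_missing_channel_is_reported(self, tree, default_frame, default_sample):
        _, problems = derive_thresholds(
            tree, default_frame.drop(columns=["CD19"]), default_sample.truth_labels
        )
        assert any("CD19" in p for p in problems)


def _frame_for(levels: dict, n=1, scatter=(100.0, 60.0)) -> pd.DataFrame:
    """Marker frame for constructed events at exact expression-level means."""
    tree = build_lung_gate_tree()
    channels = tree.referenced_markers()
    data = {ch: np.full(n, LEVELS[levels.get(ch, "neg")]) for ch in channels}
    data["FSC-A"] = np.full(n, scatter[0])
    data["SSC-A"] = np.full(n, scatter[1])
    data["FSC-H"] = 0.95 * data["FSC-A"]
    frame = pd.DataFrame(data)
    frame["FSC_ratio"] = frame["FSC-H"] / frame["FSC-A"]
    return frame


class TestApplyGates:
    def test_constructed_neutrophil_is_labeled_neutrophil(self, fitted_classifier):
        X = _frame_for({"CD45": "pos", "Ly6G": "hi", "CD11b": "pos"})
        assert fitted_classifier.predict(X)[0] == "Neutrophil"

    def test_constructed_treg_is_labeled_treg(self, fitted_classifier):
        X = _frame_for(
            {"CD45": "pos", "CD3": "pos", "CD4": "pos", "CD25": "pos", "CD127": "low"}
        )
        assert fitted_classifier.predict(X)[0] == "Treg"

    def test_cd4_conventional_t_cell_stops_at_t_helper(self, fitted_classifier):
        X = _frame_for({"CD45": "pos", "CD3": "pos", "CD4": "pos", "CD127": "pos"})
        assert fitted_classifier.predict(X)[0] == "T helper"

    def test_every_truth_population_is_the_plurality_of_its_class(
        self, fitted_classifier, default_frame, default_sample
    ):
        labels = fitted_classifier.predict(default_frame)
        truth = default_sample.truth_labels
        for pop in fitted_classifier.tree_.target_populations:
            mask = truth == pop
            counts = pd.Series(labels[mask]).value_counts()
            assert counts.idxmax() == pop

    def test_frequency_table_conserves_event_counts(
        self, fitted_classifier, default_frame
    ):
        gated = fitted_classifier.gate(default_frame)
        counts = gated.node_counts
        tree = fitted_classifier.tree_
        for name in tree.nodes:
            kids = tree.children(name)
            if kids:
                total = sum(counts.get(k.name, 0) for k in kids)
                total += counts.get(f"{name}/unassigned", 0)
                assert total == counts.get(name, 0)

    def test_sibling_frequencies_sum_to_at_most_100(self, fitted_classifier, default_frame):
        gated = fitted_classifier.gate(default_frame)
        ft = gated.frequency_table
        for parent, group in ft.groupby("parent"):
            if parent:
                assert group["frequency_of_parent_pct"].sum() <= 100.0 + 1e-9

    def test_application_is_idempotent(self, fitted_classifier, default_frame):
        a = fitted_classifier.predict(default_frame)
        b = fitted_classifier.predict(default_frame)
        np.testing.assert_array_equal(a, b)

    def test_invariant_under_monotone_channel_transform(
        self, fitted_classifier, default_frame
    ):
        before = fitted_classifier.predict(default_frame)
        import copy

        clf = copy.deepcopy(fitted_classifier)
        transformed = default_frame.copy()

        # strictly monotone transform applied jointly to a channel and its threshold
        def mono(x):
            return 2 * x + np.arcsinh(x)

        transformed["CD19"] = mono(default_frame["CD19"])
        clf.thresholds_ = dict(clf.thresholds_)
        clf.thresholds_["CD19:pos"] = float(mono(clf.thresholds_["CD19:pos"]))
        after = clf.predict(transformed)
        np.testing.assert_array_equal(before, after)

    def test_unresolved_threshold_fails_before_processing(self, fitted_classifier, default_frame):
        import copy

        clf = copy.deepcopy(fitted_classifier)
        clf.thresholds_ = {
            k: v for k, v in clf.thresholds_.items() if k != "CD3:pos"
        }
        with pytest.raises(ValueError, match="unresolved"):
            clf.predict(default_frame)

    def test_noise_free_recovery_is_exact(self, panel, profiles, endmembers):
        zero = ls.NoiseModel(0.0, 0.0, 0.0)
        sample = ls.simulate_sample(
            profiles, np.full(17, 1 / 17), panel, endmembers, zero, 5_000, seed=13,
            carrier="beads",
        )
        from lungspectra.unmix import build_mixing_matrix

        m = build_mixing_matrix([endmembers[n] for n in sample.truth_names])
        X = marker_frame(unmix_ols(sample, m), sample.scatter, panel)
        clf = GateTreeClassifier().fit(X, sample.truth_labels)
        report = evaluate_recovery(sample.truth_labels, clf.predict(X))
        assert report.accuracy == 1.0


class TestSubstates:
    def test_naive_t_cells_get_the_naive_substate(self, fitted_classifier):
        X = _frame_for(
            {"CD45": "pos", "CD3": "pos", "CD4": "pos", "CD127": "pos",
             "CD62L": "pos", "CD44": "low"}
        )
        gated = fitted_classifier.gate(X)
        assert gated.labels[0] == "T helper"
        assert gated.substates[0] == "T_N"

    def test_mature_nk_substate(self, fitted_classifier):
        X = _frame_for(
            {"CD45": "pos", "CD335": "pos", "CD11b": "low", "KLRG1": "pos",
             "CD122": "pos"}
        )
        gated = fitted_classifier.gate(X)
        assert gated.labels[0] == "NK"
        assert gated.substates[0] == "mature NK"


class TestEvaluateRecovery:
    def test_perfect_prediction_has_accuracy_one(self):
        labels = np.array(["A", "B", "A"], dtype=object)
        assert evaluate_recovery(labels, labels).accuracy == 1.0

    def test_shuffled_labels_match_frequency_baseline(self):
        rng = np.random.default_rng(0)
        truth = rng.choice(["A", "B", "C", "D"], p=[0.4, 0.3, 0.2, 0.1], size=20_000)
        shuffled = rng.permutation(truth)
        baseline = sum(p**2 for p in (0.4, 0.3, 0.2, 0.1))
        acc = evaluate_recovery(truth, shuffled).accuracy
        assert acc == pytest.approx(baseline, abs=0.02)

    def test_disjoint_label_sets_warn(self):
        with pytest.warns(UserWarning, match="disjoint"):
            report = evaluate_recovery(np.array(["A"] * 20), np.array(["B"] * 20))
        assert report.accuracy == 0.0

    def test_dead_events_are_excluded_from_scoring(self):
        truth = np.array(["A", "Dead", "A", "Dead"], dtype=object)
        pred = np.array(["A", "X", "A", "Y"], dtype=object)
        assert evaluate_recovery(truth, pred).accuracy == 1.0
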