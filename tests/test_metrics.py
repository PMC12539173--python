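import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codahd import (
    adjusted_rand_index,
    baseline_delta,
    branch_overlap_rates,
    clustering_report,
    entropy_accuracy,
    entropy_purity,
    marker_auc,
    marker_panel_report,
    match_branches,
    normalized_mutual_information,
    pseudotime_pos,
    pseudotime_scc,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_ari(pred, truth):
    """Pair-counting ARI from the 2x2 pair-agreement table."""
    n = len(pred)
    n11 = n10 = n01 = n00 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_p = pred[i] == pred[j]
        same_t = truth[i] == truth[j]
        if same_p and same_t:
            n11 += 1
        elif same_p:
            n10 += 1
        elif same_t:
            n01 += 1
        else:
            n00 += 1
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return 1.0 if den == 0 else num / den


def brute_force_nmi(pred, truth):
    pred, truth = np.asarray(pred), np.asarray(truth)
    n = len(pred)
    mi = 0.0
    for a in np.unique(pred):
        for b in np.unique(truth):
            pab = np.mean((pred == a) & (truth == b))
            if pab > 0:
                mi += pab * np.log(pab / (np.mean(pred == a) * np.mean(truth == b)))
    ent = lambda x: -sum(
        np.mean(x == v) * np.log(np.mean(x == v)) for v in np.unique(x)
    )
    return 2 * mi / (ent(pred) + ent(truth))


def brute_force_entropy_accuracy(pred, truth):
    pred, truth = np.asarray(pred), np.asarray(truth)
    clusters = np.unique(pred)
    total = 0.0
    for c in clusters:
        members = truth[pred == c]
        for g in np.unique(members):
            p = np.mean(members == g)
            total -= p * np.log(p)
    return total / len(clusters)


# ---------------------------------------------------------------------------
# entropy metrics
# ---------------------------------------------------------------------------

class TestEntropyMetrics:
    def test_pure_clusters_zero(self):
        labels = ["a", "a", "b", "b", "c"]
        assert entropy_accuracy(labels, labels) == 0.0
        assert entropy_purity(labels, labels) == 0.0

    def test_half_half_log2(self):
        # 2 clusters, each half group A half group B
        pred = [0, 0, 1, 1]
        truth = ["A", "B", "A", "B"]
        assert entropy_accuracy(pred, truth) == pytest.approx(np.log(2))

    def test_one_cluster_two_groups_h_pur(self):
        # every true group sits in a single predicted cluster -> H_pur = 0
        pred = [0, 0, 0, 0]
        truth = ["A", "A", "B", "B"]
        assert entropy_purity(pred, truth) == pytest.approx(0.0)
        assert entropy_accuracy(pred, truth) == pytest.approx(np.log(2))

    def test_bounds_random_partitions(self):
        # the log(M)/log(N) bounds hold in the evaluation protocol where
        # the number of predicted clusters equals the number of true
        # groups; the universal bound is the log of the *other* side's
        # group count (a cluster's mixing entropy is capped by it)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(4, 30)
            m = rng.integers(2, 6)
            pred = rng.integers(0, m, n)
            truth = rng.integers(0, m, n)
            ha = entropy_accuracy(pred, truth)
            hp = entropy_purity(pred, truth)
            n_pred = len(np.unique(pred))
            n_true = len(np.unique(truth))
            if n_true <= n_pred:
                assert 0 <= ha <= np.log(n_pred) + 1e-12
            if n_pred <= n_true:
                assert 0 <= hp <= np.log(n_true) + 1e-12

    def test_universal_bounds_unequal_cluster_counts(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 30)
            pred = rng.integers(0, rng.integers(2, 6), n)
            truth = rng.integers(0, rng.integers(2, 6), n)
            assert 0 <= entropy_accuracy(pred, truth) <= np.log(
                len(np.unique(truth))
            ) + 1e-12
            assert 0 <= entropy_purity(pred, truth) <= np.log(
                len(np.unique(pred))
            ) + 1e-12

    def test_role_swap_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pred = rng.integers(0, 4, 30)
            truth = rng.integers(0, 3, 30)
            assert entropy_purity(pred, truth) == pytest.approx(
                entropy_accuracy(truth, pred)
            )

    def test_against_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            pred = rng.integers(0, 4, 25)
            truth = rng.integers(0, 3, 25)
            assert entropy_accuracy(pred, truth) == pytest.approx(
                brute_force_entropy_accuracy(pred, truth), abs=1e-12
            )

    def test_cell_set_mismatch(self):
        with pytest.raises(ValueError):
            entropy_accuracy([0, 1], [0, 1, 2])

    def test_label_renaming_invariance(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(0, 3, 40)
        truth = rng.integers(0, 4, 40)
        renamed = np.array(["xyz"[v] for v in pred])
        for fn in (entropy_accuracy, entropy_purity, adjusted_rand_index,
                   normalized_mutual_information):
            assert fn(pred, truth) == pytest.approx(fn(renamed, truth))


# ---------------------------------------------------------------------------
# ARI / NMI
# ---------------------------------------------------------------------------

class TestARI:
    def test_identical_partitions(self):
        labels = [0, 0, 1, 1, 2]
        assert adjusted_rand_index(labels, labels) == pytest.approx(1.0)

    def test_four_cell_example(self):
        pred = ["A", "A", "B", "B"]
        truth = [1, 2, 1, 2]
        assert adjusted_rand_index(pred, truth) == pytest.approx(
            brute_force_ari(pred, truth)
        )

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(4, 20)
            pred = rng.integers(0, 3, n)
            truth = rng.integers(0, 3, n)
            assert adjusted_rand_index(pred, truth) == pytest.approx(
                brute_force_ari(pred, truth), abs=1e-10
            )

    def test_sklearn_agreement(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(5)
        for _ in range(100):
            pred = rng.integers(0, 4, 50)
            truth = rng.integers(0, 5, 50)
            assert adjusted_rand_index(pred, truth) == pytest.approx(
                adjusted_rand_score(truth, pred), abs=1e-10
            )

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(6)
        vals = [
            adjusted_rand_index(rng.integers(0, 3, 60), rng.integers(0, 3, 60))
            for _ in range(1000)
        ]
        assert abs(np.mean(vals)) < 0.02


class TestNMI:
    def test_identical_partitions(self):
        assert normalized_mutual_information([0, 1, 1, 2], [0, 1, 1, 2]) == pytest.approx(1.0)

    def test_four_cell_brute_force(self):
        pred = [0, 0, 1, 1]
        truth = ["A", "B", "A", "A"]
        assert normalized_mutual_information(pred, truth) == pytest.approx(
            brute_force_nmi(pred, truth), abs=1e-12
        )

    def test_sklearn_agreement(self):
        from sklearn.metrics import normalized_mutual_info_score

        rng = np.random.default_rng(7)
        for _ in range(100):
            pred = rng.integers(0, 4, 50)
            truth = rng.integers(0, 5, 50)
            assert normalized_mutual_information(pred, truth) == pytest.approx(
                normalized_mutual_info_score(truth, pred, average_method="arithmetic"),
                abs=1e-10,
            )

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(8)
        pred = rng.integers(0, 2, 5000)
        truth = rng.integers(0, 2, 5000)
        assert normalized_mutual_information(pred, truth) < 0.01

    def test_both_single_cluster(self):
        assert normalized_mutual_information([0, 0, 0], [1, 1, 1]) == 1.0


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

class TestSCC:
    def test_perfect_order(self):
        t = np.arange(10.0)
        assert pseudotime_scc(t, t) == pytest.approx(1.0)

    def test_reversed(self):
        t = np.arange(10.0)
        assert pseudotime_scc(t[::-1], t) == pytest.approx(-1.0)

    def test_tied_ranks_brute_force(self):
        pt = np.array([1.0, 1.0, 2.0, 3.0])
        tt = np.array([0.0, 1.0, 1.0, 2.0])

        def midranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            i = 0
            xs = x[order]
            while i < len(x):
                j = i
                while j < len(x) and xs[j] == xs[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        ra, rb = midranks(pt), midranks(tt)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert pseudotime_scc(pt, tt) == pytest.approx(expected, abs=1e-12)

    def test_constant_pseudotime_rejected(self):
        with pytest.raises(ValueError):
            pseudotime_scc([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            pseudotime_scc([1.0, 2.0], [0.0, 1.0])


class TestPOS:
    def test_perfect_order(self):
        tt = np.repeat([0, 1, 2], 4).astype(float)
        pt = np.arange(12.0)
        assert pseudotime_pos(pt, tt) == pytest.approx(1.0)

    def test_reversed(self):
        tt = np.repeat([0, 1, 2], 4).astype(float)
        pt = np.arange(12.0)[::-1]
        assert pseudotime_pos(pt, tt) == pytest.approx(-1.0)

    def test_all_tied_zero(self):
        tt = np.array([0.0, 0.0, 1.0, 1.0])
        pt = np.ones(4)
        assert pseudotime_pos(pt, tt) == pytest.approx(0.0)

    def test_hand_counted(self):
        tt = np.array([0.0, 0.0, 1.0])
        pt = np.array([2.0, 0.0, 1.0])
        # comparable pairs: (0,2): pred 2>1 vs true 0<1 -> -1
        #                   (1,2): pred 0<1 vs true 0<1 -> +1
        assert pseudotime_pos(pt, tt) == pytest.approx(0.0)

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError):
            pseudotime_pos([1.0, 2.0], [0.0, 0.0])


class TestBranchMatching:
    def test_perfect_prediction(self):
        truth = ["X", "X", "Y", "Y", "Y"]
        bm = match_branches(truth, truth)
        assert bm.mapping == {"X": "X", "Y": "Y"}
        assert all(v == 1.0 for v in bm.true_overlap_rate.values())
        assert bm.trajectory_false_rate == 0.0
        assert bm.incorrect_cell_type_proportion == 0.0

    def test_three_type_lineage_overlap_rates(self):
        # A differentiates to B and C, even sizes; lineage branches share
        # the A cells. A predicted branch of exactly A+B overlaps the
        # A-to-B branch 100% and the A-to-C branch 50%.
        n = 30
        types = np.repeat(["A", "B", "C"], n)
        true_branches = {
            "A->B": np.isin(types, ["A", "B"]),
            "A->C": np.isin(types, ["A", "C"]),
        }
        pred = {"branch1": np.isin(types, ["A", "B"])}
        rates = branch_overlap_rates(pred, true_branches)
        assert rates["branch1"]["A->B"] == pytest.approx(1.0)
        assert rates["branch1"]["A->C"] == pytest.approx(0.5)
        bm = match_branches(pred, true_branches)
        assert bm.mapping == {"branch1": "A->B"}
        assert bm.true_overlap_rate["branch1"] == pytest.approx(1.0)

    def test_twelve_cell_hand_enumeration(self):
        truth = np.array(["T1"] * 6 + ["T2"] * 6)
        pred = np.array(
            ["p1"] * 4 + ["p2"] * 2 + ["p2"] * 5 + ["p1"] * 1
        )
        bm = match_branches(pred, truth)
        # p1: 4 T1 + 1 T2 -> T1; p2: 2 T1 + 5 T2 -> T2
        assert bm.mapping == {"p1": "T1", "p2": "T2"}
        assert bm.true_overlap_rate["p1"] == pytest.approx(4 / 6)
        assert bm.true_overlap_rate["p2"] == pytest.approx(5 / 6)
        # false rate: T1 cells in p2 = 2/6; T2 cells in p1 = 1/6
        assert bm.trajectory_false_rate == pytest.approx((2 / 6 + 1 / 6) / 2)
        # incorrect: p1 has 1/5 non-T1, p2 has 2/7 non-T2
        assert bm.incorrect_cell_type_proportion == pytest.approx(
            (1 / 5 + 2 / 7) / 2
        )

    def test_rates_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            pred = rng.integers(0, 3, 40)
            truth = rng.integers(0, 3, 40)
            bm = match_branches(pred, truth)
            assert 0 <= bm.trajectory_false_rate <= 1
            assert 0 <= bm.incorrect_cell_type_proportion <= 1
            assert all(0 <= v <= 1 for v in bm.true_overlap_rate.values())

    def test_empty_branch_rejected(self):
        with pytest.raises(ValueError):
            match_branches({"p": np.zeros(5, dtype=bool)}, np.zeros(5, dtype=int))


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------

class TestMarkerAUC:
    def test_perfect_separation(self):
        assert marker_auc([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0

    def test_all_tied(self):
        assert marker_auc([2, 2, 2, 2], [1, 0, 1, 0]) == 0.5

    def test_pair_enumeration(self):
        values = np.array([3.0, 1.0, 2.0, 0.0])
        positive = np.array([True, False, True, False])
        wins = ties = 0
        for i in np.where(positive)[0]:
            for j in np.where(~positive)[0]:
                if values[i] > values[j]:
                    wins += 1
                elif values[i] == values[j]:
                    ties += 1
        expected = (wins + 0.5 * ties) / (positive.sum() * (~positive).sum())
        assert marker_auc(values, positive) == pytest.approx(expected)

    def test_sklearn_agreement(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(10)
        for _ in range(50):
            v = rng.normal(size=30).round(1)  # rounding forces ties
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            assert marker_auc(v, y.astype(bool)) == pytest.approx(
                roc_auc_score(y, v), abs=1e-12
            )

    def test_complement_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            v = rng.normal(size=25)
            y = np.zeros(25, dtype=bool)
            y[rng.choice(25, size=rng.integers(1, 24), replace=False)] = True
            assert marker_auc(v, y) + marker_auc(v, ~y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            marker_auc([1.0, 2.0], [True, True])


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=40),
    st.data(),
)
def test_marker_auc_complement_property(values, data):
    n = len(values)
    k = data.draw(st.integers(min_value=1, max_value=n - 1))
    pos = np.zeros(n, dtype=bool)
    pos[:k] = True
    assert marker_auc(values, pos) + marker_auc(values, ~pos) == pytest.approx(1.0)


class TestMarkerPanelReport:
    def test_fraction_above_cutoff(self):
        table = {"g1": 0.95, "g2": 0.7, "g3": 0.5}
        report = marker_panel_report(table, cutoffs=(0.6,))
        assert report["frac_above"]["0.6"] == pytest.approx(2 / 3)

    def test_cutoff_one_needs_perfection(self):
        report = marker_panel_report({"g1": 0.99, "g2": 0.8}, cutoffs=(1.0,))
        assert report["frac_above"]["1.0"] == 0.0

    def test_non_marker_control(self):
        report = marker_panel_report(
            {"g1": 0.9}, cutoffs=(0.6,), nondeg_auc_table={"n1": 0.7, "n2": 0.5}
        )
        assert report["false_positive_frac"]["0.6"] == pytest.approx(0.5)

    def test_no_control_fields_without_table(self):
        report = marker_panel_report({"g1": 0.9})
        assert "false_positive_frac" not in report

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            marker_panel_report({})


class TestBaselineDelta:
    def test_sign_conventions(self):
        method = {"ARI": 0.8, "NMI": 0.7, "H_acc": 0.2, "H_pur": 0.1}
        base = {"ARI": 0.5, "NMI": 0.6, "H_acc": 0.5, "H_pur": 0.3}
        delta = baseline_delta(method, base)
        # positive always means the method improved on the baseline
        assert delta == pytest.approx(
            {"ARI": 0.3, "NMI": 0.1, "H_acc": 0.3, "H_pur": 0.2}
        )

    def test_report_shape(self):
        labels = [0, 0, 1, 1]
        r = clustering_report(labels, labels)
        assert set(r) == {"H_acc", "H_pur", "ARI", "NMI"}
        assert r["ARI"] == pytest.approx(1.0)
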