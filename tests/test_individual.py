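"""Individual-assignment metrics: sensitivity, specificity, CCC, kappa,
top-k concordance and its chance correction."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vametrics import (
    CauseList,
    ConfusionTable,
    DataError,
    DeathRecord,
    UndefinedMetricError,
    ValidationDataset,
    build_confusion,
    chance_corrected_concordance,
    cohen_kappa,
    expected_confusion,
    overall_ccc,
    partial_chance_concordance,
    pccc,
    sensitivity,
    specificity,
    top_k_concordance,
)
from vametrics.simulate import expected_confusion
from vametrics.core import CSMFVector

from conftest import make_dataset, random_dataset


@pytest.fixture
def method1_equal_conf(method1):
    comp = CSMFVector(method1.causes, [1 / 3] * 3)
    return expected_confusion(method1, comp)


class TestSensitivity:
    def test_method1_diagonal(self, method1_equal_conf):
        assert sensitivity(method1_equal_conf, "A") == pytest.approx(0.70)
        assert sensitivity(method1_equal_conf, "B") == pytest.approx(0.60)
        assert sensitivity(method1_equal_conf, "C") == pytest.approx(0.35)

    def test_perfect_table(self, causes_abc):
        conf = ConfusionTable(causes_abc, np.eye(3) * 5)
        assert all(sensitivity(conf, c) == 1.0 for c in causes_abc)

    def test_row_arithmetic(self, causes_abc):
        counts = [[35, 40, 25], [0, 1, 0], [0, 0, 1]]
        assert sensitivity(ConfusionTable(causes_abc, counts), "A") == 0.35

    def test_zero_row_is_undefined_not_zero(self, causes_abc):
        counts = [[0, 0, 0], [0, 5, 0], [0, 0, 5]]
        assert math.isnan(sensitivity(ConfusionTable(causes_abc, counts), "A"))


class TestSpecificity:
    def test_perfect(self):
        conf = ConfusionTable(CauseList(("A", "B")), [[5, 0], [0, 5]])
        assert specificity(conf, "A") == 1.0

    def test_all_off_cause_deaths_assigned_to_cause(self):
        conf = ConfusionTable(CauseList(("A", "B")), [[5, 0], [5, 0]])
        assert specificity(conf, "A") == 0.0

    def test_method1_equal_composition(self, method1_equal_conf):
        # off-cause deaths of A: rows B and C; false positives
        # (0.04 + 0.065)/3 out of 2/3 off-cause mass
        assert specificity(method1_equal_conf, "A") == pytest.approx(0.9475)


class TestCCC:
    def test_method1_values(self, method1_equal_conf):
        assert chance_corrected_concordance(method1_equal_conf, "A") == pytest.approx(0.55)
        assert chance_corrected_concordance(method1_equal_conf, "B") == pytest.approx(0.40)
        assert chance_corrected_concordance(method1_equal_conf, "C") == pytest.approx(0.025)

    def test_method2_cause_a(self, method2):
        conf = expected_confusion(method2, CSMFVector(method2.causes, [1 / 3] * 3))
        assert chance_corrected_concordance(conf, "A") == pytest.approx(0.70)

    @pytest.mark.parametrize("n", [2, 3, 5, 10])
    def test_zero_at_chance_level(self, n):
        causes = CauseList(tuple(f"c{i}" for i in range(n)))
        counts = np.full((n, n), 1.0 / n**2)  # sensitivity exactly 1/n
        conf = ConfusionTable(causes, counts)
        assert chance_corrected_concordance(conf, "c0") == pytest.approx(0.0, abs=1e-12)

    def test_negative_below_chance_bounded(self, causes_abc):
        counts = [[0, 5, 5], [1, 5, 0], [1, 0, 5]]  # sensitivity 0 for A
        ccc = chance_corrected_concordance(ConfusionTable(causes_abc, counts), "A")
        assert ccc == pytest.approx(-0.5)  # -1/(N-1)


class TestOverallCCC:
    def test_method1_equal_weights(self, method1_equal_conf):
        assert overall_ccc(method1_equal_conf) == pytest.approx((0.55 + 0.40 + 0.025) / 3)

    def test_perfect_assignment_any_scheme(self, causes_abc):
        conf = ConfusionTable(causes_abc, np.eye(3) * 7)
        for scheme in ("equal", "test-set", (0.2, 0.5, 0.3)):
            assert overall_ccc(conf, weights=scheme) == pytest.approx(1.0)

    def test_degenerate_weights_pick_one_cause(self, method1_equal_conf):
        assert overall_ccc(method1_equal_conf, weights=(1, 0, 0)) == pytest.approx(0.55)

    def test_bad_weight_vector_rejected(self, method1_equal_conf):
        with pytest.raises(DataError, match="sum"):
            overall_ccc(method1_equal_conf, weights=(0.5, 0.4, 0.2))

    def test_lies_between_cause_extremes(self, method1_equal_conf):
        val = overall_ccc(method1_equal_conf)
        assert 0.025 <= val <= 0.55

    def test_undefined_cause_excluded_with_renormalization(self, causes_abc):
        counts = [[0, 0, 0], [1, 8, 1], [1, 1, 8]]  # no true A deaths
        conf = ConfusionTable(causes_abc, counts)
        expected = (chance_corrected_concordance(conf, "B")
                    + chance_corrected_concordance(conf, "C")) / 2
        assert overall_ccc(conf) == pytest.approx(expected)
        with pytest.raises(UndefinedMetricError):
            overall_ccc(conf, exclude_undefined=False)


class TestCohenKappa:
    def test_perfect_agreement(self, causes_abc):
        assert cohen_kappa(ConfusionTable(causes_abc, np.eye(3) * 4)) == pytest.approx(1.0)

    def test_independence(self):
        conf = ConfusionTable(CauseList(("A", "B")), [[25, 25], [25, 25]])
        assert cohen_kappa(conf) == pytest.approx(0.0)

    def test_hand_computed(self):
        # P_obs = 35/50 = 0.7, P_exp = (30*25 + 20*25)/2500 = 0.5
        conf = ConfusionTable(CauseList(("A", "B")), [[20, 5], [10, 15]])
        assert cohen_kappa(conf) == pytest.approx(0.4)

    def test_all_mass_one_cell_undefined(self):
        conf = ConfusionTable(CauseList(("A", "B")), [[10, 0], [0, 0]])
        assert math.isnan(cohen_kappa(conf))


class TestTopK:
    @pytest.fixture
    def six_cause_death(self):
        causes = CauseList(
            ("tuberculosis", "pneumonia", "lung cancer", "AIDS",
             "heart failure", "other infectious")
        )
        rec = DeathRecord(
            "d1",
            "pneumonia",
            (("tuberculosis", 0.5), ("pneumonia", 0.2), ("lung cancer", 0.1),
             ("AIDS", 0.1), ("heart failure", 0.05), ("other infectious", 0.05)),
        )
        return ValidationDataset(causes, (rec,))

    def test_ranked_worked_example(self, six_cause_death):
        assert top_k_concordance(six_cause_death, 1) == 0.0
        assert top_k_concordance(six_cause_death, 2) == 1.0

    def test_k_equal_n_exhaustive(self, six_cause_death):
        assert top_k_concordance(six_cause_death, 6) == 1.0

    def test_counting_over_ranks(self, causes_abc):
        def rec(i, true, order):
            probs = dict(zip(order, (0.5, 0.3, 0.2)))
            return DeathRecord(str(i), true, tuple(probs.items()))

        ds = ValidationDataset(
            causes_abc,
            (
                rec(0, "A", ("A", "B", "C")),   # rank 1
                rec(1, "B", ("A", "B", "C")),   # rank 2
                rec(2, "C", ("A", "C", "B")),   # rank 2
                rec(3, "C", ("A", "B", "C")),   # rank 3
            ),
        )
        assert top_k_concordance(ds, 1) == 0.25
        assert top_k_concordance(ds, 2) == 0.75
        assert top_k_concordance(ds, 3) == 1.0

    def test_k_out_of_range(self, causes_abc):
        ds = make_dataset(causes_abc, [("A", "A")])
        with pytest.raises(DataError):
            top_k_concordance(ds, 0)
        with pytest.raises(DataError):
            top_k_concordance(ds, 4)

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_monotone_in_k(self, seed):
        rng = np.random.default_rng(seed)
        n_causes = int(rng.integers(2, 6))
        labels = tuple(chr(65 + i) for i in range(n_causes))
        causes = CauseList(labels)
        records = []
        for i in range(int(rng.integers(1, 30))):
            probs = rng.dirichlet(np.ones(n_causes))
            records.append(
                DeathRecord(str(i), labels[rng.integers(n_causes)],
                            tuple(zip(labels, probs / probs.sum())))
            )
        ds = ValidationDataset(causes, tuple(records))
        vals = [top_k_concordance(ds, k) for k in range(1, n_causes + 1)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestPartialChanceConcordance:
    def test_one_of_five(self):
        assert partial_chance_concordance(1, 5) == pytest.approx(0.20)

    @pytest.mark.parametrize("n", [2, 3, 6])
    def test_exhaustive_k_is_certain(self, n):
        assert partial_chance_concordance(n, n) == 1.0

    def test_matches_random_ranking_enumeration(self):
        # independent oracle: enumerate all rankings of N causes; the
        # chance of the true cause appearing in the top k is k/N
        for n in (3, 4):
            for k in range(1, n + 1):
                hits = 0
                perms = list(itertools.permutations(range(n)))
                for perm in perms:
                    hits += 0 in perm[:k]  # true cause = 0 wlog
                assert partial_chance_concordance(k, n) == pytest.approx(hits / len(perms))

    def test_strictly_increasing_in_k(self):
        vals = [partial_chance_concordance(k, 6) for k in range(1, 7)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_replacement_convention(self):
        assert partial_chance_concordance(1, 5, "replacement") == pytest.approx(0.2)
        assert partial_chance_concordance(5, 5, "replacement") < 1.0

    def test_k_out_of_range(self):
        with pytest.raises(DataError):
            partial_chance_concordance(4, 3)


class TestPCCC:
    def _ranked_dataset(self, causes, hits, total):
        """total deaths; `hits` have their true cause ranked first."""
        labels = causes.labels
        records = []
        for i in range(total):
            true = labels[0]
            if i < hits:
                order = labels
            else:
                order = (labels[1], labels[2], labels[0])
            probs = (0.6, 0.3, 0.1)
            records.append(DeathRecord(str(i), true, tuple(zip(order, probs))))
        return ValidationDataset(causes, tuple(records))

    def test_chance_level_scores_zero(self, causes_abc):
        # C(1) = 1/3 exactly: one hit in three deaths
        ds = self._ranked_dataset(causes_abc, hits=1, total=3)
        assert pccc(ds, 1) == pytest.approx(0.0)

    def test_perfect_scores_one(self, causes_abc):
        ds = self._ranked_dataset(causes_abc, hits=10, total=10)
        assert pccc(ds, 1) == pytest.approx(1.0)

    def test_reduces_to_single_cause_ccc(self, causes_abc):
        # C(1) = 0.70 with N=3 must give the CCC value 0.55
        ds = self._ranked_dataset(causes_abc, hits=7, total=10)
        assert pccc(ds, 1) == pytest.approx(0.55)

    def test_k_equal_n_undefined(self, causes_abc):
        ds = self._ranked_dataset(causes_abc, hits=1, total=3)
        with pytest.raises(UndefinedMetricError):
            pccc(ds, 3)
        with pytest.raises(DataError):
            pccc(ds, 4)


def test_brute_force_oracle_equivalence(rng):
    """Confusion-table metrics equal explicit per-record loops."""
    for _ in range(200):
        ds = random_dataset(rng)
        conf = build_confusion(ds)
        labels = ds.causes.labels
        n = len(labels)
        total = len(ds.records)
        for cause in labels:
            truly = [r for r in ds.records if r.true_cause == cause]
            others = [r for r in ds.records if r.true_cause != cause]
            if truly:
                sens = sum(r.top_cause == cause for r in truly) / len(truly)
                assert sensitivity(conf, cause) == sens
                assert chance_corrected_concordance(conf, cause) == pytest.approx(
                    (sens - 1 / n) / (1 - 1 / n)
                )
            else:
                assert math.isnan(sensitivity(conf, cause))
            if others:
                spec = sum(r.top_cause != cause for r in others) / len(others)
                assert specificity(conf, cause) == spec
        p_obs = sum(r.top_cause == r.true_cause for r in ds.records) / total
        p_exp = sum(
            (sum(r.true_cause == c for r in ds.records) / total)
            * (sum(r.top_cause == c for r in ds.records) / total)
            for c in labels
        )
        if 1 - p_exp > 1e-12:
            assert cohen_kappa(conf) == pytest.approx((p_obs - p_exp) / (1 - p_exp))
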