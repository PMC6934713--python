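"""Stratified CV, confusion metrics, and the two differential experiments."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from swaylearn import (
    ConfusionCounts,
    FeatureMatrix,
    ForestParams,
    balance_groups,
    metrics,
    project_xy,
    run_cv,
    stratified_folds,
)
from swaylearn.errors import ConfigurationError
from swaylearn.evaluation import average_metrics
from swaylearn.synthetic import sample_cohort, simulate_recording


class TestMetrics:
    # Printed fold confusion counts (TP, FP, TN, FN) and the metric values
    # they must reproduce, rounded to the reported precision.
    FOLDS = [
        ((8, 2, 3, 0), (0.80, 1.00, 0.60, 0.69, 0.89)),
        ((8, 3, 2, 0), (0.73, 1.00, 0.40, 0.54, 0.84)),
        ((8, 3, 2, 0), (0.73, 1.00, 0.40, 0.54, 0.84)),
        ((8, 2, 2, 0), (0.80, 1.00, 0.50, 0.63, 0.89)),
        ((7, 3, 1, 0), (0.70, 1.00, 0.25, 0.42, 0.82)),
    ]

    @pytest.mark.parametrize("counts,expected", FOLDS)
    def test_reported_fold_metrics_from_confusion_counts(self, counts, expected):
        m = metrics(ConfusionCounts(*counts))
        got = (m.precision, m.recall, m.specificity, m.mcc, m.f1)
        assert tuple(round(v, 2) for v in got) == expected

    def test_average_row_reproduced(self):
        avg = average_metrics([metrics(ConfusionCounts(*c)) for c, _ in self.FOLDS])
        got = (avg.precision, avg.recall, avg.specificity, avg.mcc, avg.f1)
        assert tuple(round(v, 2) for v in got) == (0.75, 1.00, 0.43, 0.56, 0.86)

    def test_perfect_classification(self):
        m = metrics(ConfusionCounts(tp=8, fp=0, tn=5, fn=0))
        assert tuple(m.as_dict().values()) == pytest.approx((1.0,) * 5)

    def test_zero_over_zero_convention(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.precision == 0.0 and m.recall == 0.0 and m.mcc == 0.0 and m.f1 == 0.0

    def test_mcc_against_brute_force_and_symmetry(self, rng):
        """Formula agrees with an independent recomputation on random tables
        and is invariant under the positive/negative relabelling swap."""
        for _ in range(25):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if (tp + fn) == 0 or (tn + fp) == 0:
                continue
            m = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            denom_zero = 0 in (tp + fp, tn + fn)
            if not denom_zero:
                assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))
            swapped = metrics(ConfusionCounts(int(tn), int(fn), int(tp), int(fp)))
            assert m.mcc == pytest.approx(swapped.mcc)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestStratifiedFolds:
    @staticmethod
    def _labels(n_asd, n_td):
        labels = {f"a{i}": "ASD" for i in range(n_asd)}
        labels.update({f"t{i}": "TD" for i in range(n_td)})
        return labels

    def test_study_shaped_cohort_margins(self):
        labels = self._labels(39, 23)
        assignment = stratified_folds(labels, k=5, seed=0)
        for fold in range(5):
            pids = [p for p, f in assignment.items() if f == fold]
            n_asd = sum(labels[p] == "ASD" for p in pids)
            n_td = len(pids) - n_asd
            assert n_asd in (7, 8)
            assert n_td in (4, 5)

    def test_degenerate_single_fold(self):
        assignment = stratified_folds(self._labels(3, 3), k=1)
        assert set(assignment.values()) == {0}

    def test_k_exceeding_class_size_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_folds(self._labels(10, 3), k=4)

    def test_seed_contract(self):
        labels = self._labels(12, 8)
        a = stratified_folds(labels, k=4, seed=1)
        b = stratified_folds(labels, k=4, seed=2)
        assert a != b
        assert stratified_folds(labels, k=4, seed=1) == a


class TestDifferentialExperiments:
    def test_project_xy_drops_joint_z_only(self, tiny_sim_config):
        profile = sample_cohort(tiny_sim_config)[0]
        rec = simulate_recording(profile, 1, 2, tiny_sim_config)
        (out,) = project_xy([rec])
        assert out.data.shape[1] == 42
        assert "board:x" in out.channel_names and "board:y" in out.channel_names
        assert not any(c.endswith(":z") for c in out.channel_names)

    def test_xy_projection_gives_84_features(self, tiny_sim_config):
        from swaylearn import featurize_recording

        profile = sample_cohort(tiny_sim_config)[0]
        rec = simulate_recording(profile, 1, 2, tiny_sim_config)
        (out,) = project_xy([rec])
        assert featurize_recording(out).vectors.shape[1] == 84

    def _stub_features(self, n_asd, n_td):
        fms, labels = [], {}
        for g, n in (("ASD", n_asd), ("TD", n_td)):
            for i in range(n):
                pid = f"{g.lower()}{i}"
                labels[pid] = g
                fms.append(FeatureMatrix(pid, 2, 1, np.zeros((1, 4)), ["f"] * 4))
        return fms, labels

    def test_balance_groups_subsamples_larger_group(self):
        fms, labels = self._stub_features(39, 23)
        kept, kept_labels = balance_groups(fms, labels, 23, seed=0)
        counts = {g: sum(v == g for v in kept_labels.values()) for g in ("ASD", "TD")}
        assert counts == {"ASD": 23, "TD": 23}
        assert len(kept) == 46

    def test_balance_full_size_is_identity(self):
        fms, labels = self._stub_features(5, 5)
        kept, kept_labels = balance_groups(fms, labels, 5, seed=0)
        assert kept_labels == labels

    def test_balance_seed_contract(self):
        fms, labels = self._stub_features(30, 10)
        _, l1 = balance_groups(fms, labels, 10, seed=1)
        _, l2 = balance_groups(fms, labels, 10, seed=2)
        assert set(l1) != set(l2)

    def test_balance_too_large_rejected(self):
        fms, labels = self._stub_features(5, 3)
        with pytest.raises(ConfigurationError):
            balance_groups(fms, labels, 4, seed=0)


class TestRunCV:
    def test_fold_bookkeeping_and_determinism(self, tiny_features):
        result = run_cv(tiny_features.features, tiny_features.labels, k=3, seed=4,
                        params=ForestParams(rng_seed=4))
        # folds partition the cohort; every participant scored exactly once
        assert sorted(result.distances) == sorted(tiny_features.labels)
        assert sum(f.counts.tp + f.counts.fn for f in result.folds) == 6
        assert sum(f.counts.tn + f.counts.fp for f in result.folds) == 6
        again = run_cv(tiny_features.features, tiny_features.labels, k=3, seed=4,
                       params=ForestParams(rng_seed=4))
        assert again.averages == result.averages
        assert again.distances == result.distances

    def test_no_participant_leaks_across_the_split(self, tiny_features):
        """Train/test participant sets are disjoint within every fold."""
        result = run_cv(tiny_features.features, tiny_features.labels, k=3, seed=4)
        for fr in result.folds:
            test_pids = {r.participant_id for r in fr.results}
            assert test_pids == {
                p for p, f in result.fold_assignments.items() if f == fr.fold
            }
            train_pids = set(tiny_features.labels) - test_pids
            assert not (test_pids & train_pids)

    def test_boundary_distance_consistent_with_probability(self, tiny_features):
        result = run_cv(tiny_features.features, tiny_features.labels, k=3, seed=4)
        for fr in result.folds:
            for r in fr.results:
                assert r.boundary_distance == pytest.approx(2 * r.asd_probability - 1)
                assert -1.0 <= r.boundary_distance <= 1.0
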