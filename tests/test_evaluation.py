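"""Cross-validation protocol, metrics and the case-study simulation."""

import warnings

import numpy as np
import pytest

from dtimf import (
    CVConfig,
    HyperParams,
    WKNKNConfig,
    aupr,
    auc,
    case_study_mask_and_rank,
    export_pr_curve,
    generate_synthetic_dataset,
    make_folds,
    mask_test_block,
    precision_recall_points,
    run_cross_validation,
    wknkn_impute,
)
from dtimf.evaluation import _fit_and_score
from oracles import brute_force_aupr, brute_force_auc


class TestMakeFolds:
    def test_singletons_when_folds_equal_items(self):
        blocks = make_folds(10, 10, seed=0)
        assert len(blocks) == 10 and all(len(b) == 1 for b in blocks)

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            make_folds(9, 10, seed=0)

    def test_exact_partition_property(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 60))
            f = int(rng.integers(2, min(n, 10) + 1))
            blocks = make_folds(n, f, seed=int(rng.integers(0, 1000)))
            flat = np.concatenate(blocks)
            assert len(flat) == n
            assert set(flat.tolist()) == set(range(n))


class TestMaskTestBlock:
    def test_cvd_masks_rows(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        train, entries = mask_test_block(Y, [1], "CVd")
        assert train[1].sum() == 0
        assert entries == [(1, 0, 0.0), (1, 1, 1.0)]
        np.testing.assert_array_equal(train[[0, 2]], Y[[0, 2]])

    def test_cvt_masks_columns(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        train, entries = mask_test_block(Y, [0], "CVt")
        assert train[:, 0].sum() == 0
        assert {(i, j) for i, j, _ in entries} == {(0, 0), (1, 0)}


class TestMetrics:
    def test_pr_points_hand_example(self):
        pts = precision_recall_points([0.9, 0.8, 0.1], [1, 0, 1])
        assert pts == [(0.5, 1.0), (0.5, 0.5), (1.0, pytest.approx(2 / 3))]

    def test_perfect_and_reversed_rankings(self):
        assert aupr([0.9, 0.5, 0.1], [1, 1, 0]) == 1.0
        assert auc([0.9, 0.5, 0.1], [1, 1, 0]) == 1.0
        assert auc([0.1, 0.5, 0.9], [1, 0, 0]) == 0.0

    def test_all_positive_labels_precision_one(self):
        pts = precision_recall_points([0.3, 0.2, 0.9], [1, 1, 1])
        assert all(p == 1.0 for _, p in pts)

    def test_degenerate_labels_error(self):
        with pytest.raises(ValueError):
            aupr([0.1, 0.2], [0, 0])
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_threshold_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            # coarse scores force frequent ties
            scores = rng.integers(0, 5, size=n) / 4.0
            labels = rng.integers(0, 2, size=n).astype(float)
            if labels.sum() == 0:
                labels[int(rng.integers(0, n))] = 1.0
            assert aupr(scores, labels) == pytest.approx(
                brute_force_aupr(scores, labels), abs=1e-12
            )
            if 0 < labels.sum() < n:
                assert auc(scores, labels) == pytest.approx(
                    brute_force_auc(scores, labels), abs=1e-12
                )

    def test_random_scores_aupr_near_prevalence(self, planted_dataset, rng):
        labels = planted_dataset.Y.ravel()
        prev = labels.mean()
        vals = [
            aupr(rng.random(labels.size), labels) for _ in range(50)
        ]
        assert abs(np.mean(vals) - prev) < 0.05


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_synthetic_dataset(24, 16, 3, density=0.15, noise=0.05, seed=9)


class TestRunCrossValidation:
    def test_degenerate_config_equals_single_fit(self, tiny_dataset):
        hp = HyperParams(k=4, max_iter=60)
        cfg = CVConfig(scenario="CVt", folds=2, repeats=1, seed=3,
                       grid={"lambda_l": [0.5]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = run_cross_validation(tiny_dataset, "grmf", False, cfg, hp)
        # recompute the first fold by hand through the same public pieces
        blocks = make_folds(16, 2, np.random.SeedSequence([3, 0]), "CVt")
        train_Y, entries = mask_test_block(tiny_dataset.Y, blocks[0], "CVt")
        s, lab = _fit_and_score(
            tiny_dataset, train_Y, blocks[0], "CVt", "grmf", False, None,
            HyperParams(k=4, max_iter=60, lambda_l=0.5), entries,
        )
        assert summary.fold_aupr[0][0] == pytest.approx(aupr(s, lab))

    def test_summary_aggregation_and_determinism(self, tiny_dataset):
        hp = HyperParams(k=4, max_iter=60)
        cfg = CVConfig(scenario="CVd", folds=4, repeats=2, seed=5,
                       grid={"lambda_l": [0.5]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = run_cross_validation(tiny_dataset, "l21grmf", False, cfg, hp)
            s2 = run_cross_validation(tiny_dataset, "l21grmf", False, cfg, hp)
        assert s1.fold_aupr == s2.fold_aupr
        assert s1.mean_aupr == pytest.approx(np.mean(s1.repeat_mean_aupr))
        for r in s1.repeat_mean_aupr:
            assert 0 <= r <= 1
        assert s1.mean_aupr == pytest.approx(
            np.mean([np.mean(f) for f in s1.fold_aupr])
        )

    def test_wknkn_sees_no_test_information(self, tiny_dataset):
        """Imputed training matrix must not change when only masked test
        cells of the original Y are altered."""
        block = [0, 1, 2]
        train_Y, _ = mask_test_block(tiny_dataset.Y, block, "CVt")
        imputed1 = wknkn_impute(tiny_dataset.copy_with(train_Y), WKNKNConfig())
        Y2 = tiny_dataset.Y.copy()
        Y2[:, block] = 1.0 - Y2[:, block]  # flip every masked cell
        train_Y2, _ = mask_test_block(Y2, block, "CVt")
        imputed2 = wknkn_impute(tiny_dataset.copy_with(train_Y2), WKNKNConfig())
        np.testing.assert_array_equal(imputed1, imputed2)

    def test_grid_search_runs_and_records_choice(self, tiny_dataset):
        hp = HyperParams(k=4, max_iter=40)
        cfg = CVConfig(scenario="CVt", folds=4, repeats=1, seed=2,
                       grid={"lambda_l": [0.25, 1.0]}, inner_folds=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = run_cross_validation(tiny_dataset, "grmf", False, cfg, hp)
        assert all(p["lambda_l"] in (0.25, 1.0) for rep in s.chosen_params for p in rep)

    def test_unknown_method(self, tiny_dataset):
        with pytest.raises(ValueError):
            run_cross_validation(tiny_dataset, "nonsense")


class TestCaseStudy:
    def test_zero_hide_ranks_only_never_known_pairs(self, tiny_dataset):
        hp = HyperParams(k=4, max_iter=40)
        res = case_study_mask_and_rank(tiny_dataset, "d0", 0, "grmf", hp, seed=1)
        known = {
            tiny_dataset.target_ids[j]
            for j in np.flatnonzero(tiny_dataset.Y[0] == 1)
        }
        ranked = {pid for pid, _, _ in res.ranking}
        assert ranked.isdisjoint(known)
        assert res.hidden == [] and res.hidden_ranks == []

    def test_hiding_all_makes_new_drug_row(self, tiny_dataset):
        i = int(np.argmax(tiny_dataset.Y.sum(axis=1)))
        entity = tiny_dataset.drug_ids[i]
        n_known = int(tiny_dataset.Y[i].sum())
        hp = HyperParams(k=4, max_iter=40)
        res = case_study_mask_and_rank(tiny_dataset, entity, n_known, "grmf", hp, seed=1)
        assert len(res.hidden) == n_known
        assert len(res.ranking) == tiny_dataset.n_targets  # whole row is candidate

    def test_hidden_rank_above_median_of_true_zeros(self):
        """On noise-free planted data a hidden interaction should land in the
        upper half of the entity's candidate ranking in >= 80% of trials."""
        ds = generate_synthetic_dataset(24, 16, 3, density=0.15, noise=0.0, seed=4)
        hp = HyperParams(k=4, max_iter=80)
        hits = 0
        for trial in range(20):
            rng = np.random.default_rng(trial)
            rows = np.flatnonzero(ds.Y.sum(axis=1) >= 2)
            i = int(rng.choice(rows))
            res = case_study_mask_and_rank(
                ds, ds.drug_ids[i], 1, "l21grmf", hp, seed=trial
            )
            median_rank = (len(res.ranking) + 1) / 2
            if res.hidden_ranks[0] <= median_rank:
                hits += 1
        assert hits >= 16

    def test_unknown_entity(self, tiny_dataset):
        with pytest.raises(ValueError):
            case_study_mask_and_rank(tiny_dataset, "nope", 1)


class TestExportPrCurve:
    def test_round_trip_and_monotone_recall(self, tmp_path):
        pts = precision_recall_points([0.9, 0.8, 0.1, 0.05], [1, 0, 1, 0])
        path = tmp_path / "pr.tsv"
        export_pr_curve(pts, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "recall\tprecision"
        back = [tuple(map(float, l.split("\t"))) for l in lines[1:]]
        assert back == [(pytest.approx(r), pytest.approx(p)) for r, p in pts]
        recalls = [r for r, _ in back]
        assert recalls == sorted(recalls)

    def test_empty_points_header_only(self, tmp_path):
        path = tmp_path / "pr.tsv"
        export_pr_curve([], path)
        assert path.read_text() == "recall\tprecision\n"
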