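"""Recognition experiments: scores, classification, ROC, permutation, bands."""

import numpy as np
import pandas as pd
import pytest

from ffrbio.cohort import CohortDesign, ResponseModel, generate_cohort
from ffrbio.recognition import (
    ExperimentConfig,
    RecognitionResult,
    _fold_split,
    _permute_within_sessions,
    band_profile,
    categorize_roc,
    classify,
    p_value_from_scores,
    permutation_null,
    roc_analysis,
    run_recognition,
)

SMALL_CFG = ExperimentConfig(
    averaging_sizes=(10,),
    training_size_trials=None,
    hmm_restarts=2,
    hmm_iter=50,
    kmeans_restarts=1,
    master_seed=0,
)


@pytest.fixture(scope="module")
def strong_result(strong_cohort):
    return run_recognition(strong_cohort, SMALL_CFG)


class TestRunRecognition:
    def test_one_model_per_subject_session_size(self, strong_result):
        assert strong_result.n_models == 3  # 3 subjects x 1 session x 1 size
        agg = strong_result.aggregated()
        assert len(agg) == 3
        assert agg.recognition_score.notna().all()

    def test_own_model_outscores_other_models(self, strong_result):
        """With strong signatures and mild noise, each sequence's own-model
        log-probability beats every other model's in >90% of cases."""
        m = strong_result.matrices[("s1", 10)]
        scores, labels = m["scores"], m["labels"]
        own = scores[np.arange(len(labels)), labels]
        comparisons = []
        for j in range(scores.shape[1]):
            mask = labels != j
            comparisons.append(own[mask] > scores[mask, j])
        frac = np.concatenate(comparisons).mean()
        assert frac > 0.9

    def test_fold_scores_carry_test_counts(self, strong_result):
        assert (strong_result.scores.n_test_sequences > 0).all()
        assert set(strong_result.scores.fold) == {0, 1}

    def test_single_subject_recognition_runs_but_roc_refuses(self):
        design = CohortDesign(
            n_trials=60, noise_sd_uv=1.0,
            response_model=ResponseModel(artifact_rate=0.0),
        )
        cohort = generate_cohort(
            n_infants=1, sessions=("s1",), design=design, master_seed=1
        )
        res = run_recognition(cohort, SMALL_CFG)
        assert res.n_models == 1
        with pytest.raises(ValueError, match="two subjects"):
            roc_analysis(res)

    def test_insufficient_training_trials_error_names_subject(self, strong_cohort):
        cfg = ExperimentConfig(
            averaging_sizes=(10,), training_size_trials=500, master_seed=0
        )
        with pytest.raises(ValueError, match="infant00/s1"):
            run_recognition(strong_cohort, cfg)

    def test_fold_split_disjoint_and_capped(self):
        cfg = ExperimentConfig(training_size_trials=40, master_seed=0)
        train, test = _fold_split(100, 0, cfg, "x")
        assert np.intersect1d(train, test).size == 0
        assert train.size == 40
        train2, test2 = _fold_split(100, 1, cfg, "x")
        assert np.intersect1d(train2, test2).size == 0


class TestClassify:
    def test_argmax_and_tie_break_to_lowest_index(self):
        m = np.array([[0.0, 1.0, 0.5], [2.0, 2.0, 1.0]])
        assert classify(m).tolist() == [1, 0]

    def test_label_mapping(self):
        m = np.array([[0.0, 1.0]])
        assert classify(m, ["a", "b"]).tolist() == ["b"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            classify(np.zeros((2, 0)))


class TestCategorizeRoc:
    @pytest.mark.parametrize(
        "area,label",
        [
            (0.95, "excellent"),
            (0.82, "good"),
            (0.75, "fair"),
            (0.70, "poor"),  # strict inequalities: 0.70 is not > 0.7
            (0.65, "poor"),
            (0.55, "bad"),
            (0.60, "bad"),
        ],
    )
    def test_banding(self, area, label):
        assert categorize_roc(area) == label

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            categorize_roc(1.2)
        with pytest.raises(ValueError):
            categorize_roc(-0.1)


def _result_from_matrix(scores, labels, infants):
    rows = [
        {
            "infant_id": infants[i],
            "session": "s1",
            "averaging_size": 1,
            "band_low": 80.0,
            "band_high": 980.0,
            "fold": 0,
            "recognition_score": 0.0,
            "n_test_sequences": int(np.sum(labels == i)),
        }
        for i in range(len(infants))
    ]
    return RecognitionResult(
        scores=pd.DataFrame(rows),
        matrices={("s1", 1): {"scores": scores, "labels": labels, "infants": infants}},
        infants=list(infants),
        sessions=["s1"],
    )


class TestRocAnalysis:
    def test_perfect_separation_gives_area_one(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([[5.0, 0.0], [4.0, 1.0], [0.0, 5.0], [1.0, 4.0]])
        res = roc_analysis(_result_from_matrix(scores, labels, ["a", "b"]))[0]
        assert res.area == pytest.approx(1.0)
        assert res.discrimination_accuracy == pytest.approx(100.0)
        assert res.category == "excellent"

    def test_hand_computed_trapezoid_area(self):
        """Four sequences, two classes; both one-vs-rest curves integrate
        to 0.75 by hand (steps at FPR 0 and 0.5)."""
        labels = np.array([0, 0, 1, 1])
        scores = np.array([[2.0, 1.0], [0.0, -1.0], [1.0, 2.0], [-1.0, 0.0]])
        res = roc_analysis(_result_from_matrix(scores, labels, ["a", "b"]))[0]
        assert res.area == pytest.approx(0.75, abs=1e-12)

    def test_label_independent_scores_sixteen_classes_near_chance(self):
        rng = np.random.default_rng(0)
        n, k = 10000, 16
        labels = rng.integers(0, k, size=n)
        scores = rng.normal(size=(n, k))
        res = roc_analysis(_result_from_matrix(scores, labels, [str(i) for i in range(k)]))[0]
        sd = 100.0 * np.sqrt((1 / k) * (1 - 1 / k) / n)
        assert abs(res.discrimination_accuracy - 100.0 / k) < 3 * sd
        assert res.area == pytest.approx(0.5, abs=0.02)

    def test_single_class_errors(self):
        labels = np.zeros(4, dtype=int)
        scores = np.zeros((4, 2))
        with pytest.raises(ValueError, match="single-class"):
            roc_analysis(_result_from_matrix(scores, labels, ["a", "b"]))


class TestPermutation:
    def test_p_value_is_exact_proportion_on_grid(self):
        chance = np.array([1.0, 2.0, 3.0, 4.0])
        assert p_value_from_scores(chance, 2.5) == 0.5
        assert p_value_from_scores(chance, 0.0) == 1.0
        assert p_value_from_scores(chance, 5.0) == 0.0

    def test_p_value_uniform_under_null(self):
        """truth drawn from the null itself -> p uniform over {0, .05, ..., 1}."""
        rng = np.random.default_rng(1)
        n_chance, reps = 20, 2000
        ps = np.array(
            [
                p_value_from_scores(rng.normal(size=n_chance), rng.normal())
                for _ in range(reps)
            ]
        )
        grid = np.round(ps * n_chance)
        assert np.allclose(ps * n_chance, grid, atol=1e-12)
        assert abs(ps.mean() - 0.5) < 0.03

    def test_permuted_labels_destroy_recognition(self, strong_cohort):
        """Shuffling trials across subjects drops accuracy to chance."""
        from ffrbio.recognition import _group_cohort

        sessions, infants, by_key = _group_cohort(strong_cohort)
        rng = np.random.default_rng(7)
        permuted = _permute_within_sessions(by_key, sessions, infants, rng)
        res = run_recognition(permuted, SMALL_CFG, reject=False)
        roc = roc_analysis(res)[0]
        n_seq = len(res.matrices[("s1", 10)]["labels"])
        chance = 100.0 / 3
        mc_sd = 100.0 * np.sqrt((1 / 3) * (2 / 3) / n_seq)
        assert abs(roc.discrimination_accuracy - chance) < 3 * mc_sd

    def test_emits_requested_number_of_chance_scores(self, strong_cohort):
        cfg = ExperimentConfig(
            averaging_sizes=(10,),
            training_size_trials=None,
            n_permutations=5,
            hmm_restarts=1,
            hmm_iter=30,
            kmeans_restarts=1,
            master_seed=0,
        )
        perm = permutation_null(strong_cohort, cfg)
        for infant in ("infant00", "infant01", "infant02"):
            assert perm.null_for(infant, "s1", 10).size == 5
        row = perm.pvalues.iloc[0]
        per_perm = (
            perm.chance.groupby("permutation")["chance_score"].mean().to_numpy()
        )
        assert row.p_value == p_value_from_scores(per_perm, row.truth_score)


class TestBandProfile:
    def test_planted_band_signatures_peak_inside_their_range(self):
        """Signatures restricted to 180-480 Hz: discrimination is best there."""
        design = CohortDesign(
            n_trials=120,
            noise_sd_uv=2.8,
            base_signature_strength_uv=0.4,
            maturation_factor=1.0,
            signature_band_range_hz=(180.0, 480.0),
            # keep gain/latency identical so the spectral signature is the
            # only subject-identifying cue
            gain_sd=0.0,
            latency_ms_range=(7.0, 7.0),
            response_model=ResponseModel(artifact_rate=0.0),
        )
        cohort = generate_cohort(
            n_infants=3, sessions=("s1",), design=design, master_seed=21
        )
        cfg = ExperimentConfig(
            averaging_sizes=(10,),
            training_size_trials=None,
            hmm_restarts=1,
            hmm_iter=30,
            kmeans_restarts=1,
            master_seed=21,
        )
        scores, summary = band_profile(cohort, cfg, band_size=10)
        assert len(summary) == 9
        inside = summary[(summary.band_low >= 180) & (summary.band_high <= 480)]
        outside = summary[(summary.band_low < 180) | (summary.band_high > 480)]
        best = summary.loc[summary.discrimination_accuracy_percent.idxmax()]
        assert 180.0 <= best.band_low and best.band_high <= 480.0
        assert (
            inside.discrimination_accuracy_percent.mean()
            > outside.discrimination_accuracy_percent.mean()
        )

    def test_grid_cardinality(self, strong_cohort):
        cfg = ExperimentConfig(
            averaging_sizes=(10,),
            training_size_trials=None,
            band_grid=((80.0, 180.0), (180.0, 280.0)),
            hmm_restarts=1,
            hmm_iter=20,
            kmeans_restarts=1,
            master_seed=3,
        )
        scores, summary = band_profile(strong_cohort, cfg, band_size=10)
        # 2 bands x 3 subjects x 1 session x 2 folds
        assert len(scores) == 12
        assert len(summary) == 2

    def test_band_outside_slice_limits_errors(self, strong_cohort):
        cfg = ExperimentConfig(
            averaging_sizes=(10,),
            training_size_trials=None,
            band_grid=((2000.0, 3000.0),),
            master_seed=3,
        )
        with pytest.raises(ValueError, match="no bins"):
            band_profile(strong_cohort, cfg, band_size=10)
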