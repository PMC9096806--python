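"""Recognition experiments: per-subject HMMs, chance levels, ROC, bands.

For every (subject x session x averaging size), accepted trials are split
into k contiguous folds; per fold the training partition is sub-averaged,
sliced into dB spectral vectors, pooled across subjects to fit one
150-cell codebook, and encoded; one Bakis HMM per subject is trained on
its own training emissions and scored on the held-out emissions.  The mean
held-out log-probability, averaged over test sequences and folds, is the
subject's recognition score for that model.

Chance levels come from a permutation scheme that reassigns accepted
trials to subject labels uniformly at random within each session and
reruns the identical train/test procedure.  Discrimination is quantified
by argmax classification accuracy and one-vs-rest ROC curves
macro-averaged across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TrialEpochSet
from .hmm import BakisHMM
from .preprocessing import (
    SliceConfig,
    SubAverageConfig,
    _band_mask,
    default_band_grid,
    reject_artifacts,
    stft_slices,
    subaverage,
)
from .quantize import VectorQuantizer

__all__ = [
    "ExperimentConfig",
    "RecognitionResult",
    "PermutationResult",
    "ROCResult",
    "run_recognition",
    "permutation_null",
    "classify",
    "roc_analysis",
    "roc_table",
    "categorize_roc",
    "band_profile",
    "p_value_from_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of the recognition experiments.

    ``training_size_trials`` limits how many training-partition trials are
    used per fold (None = all available); the default 750 matches the
    2-fold split of 1500 accepted trials.  ``codebook_max_slices`` caps the
    number of slices the codebook is fitted on (seeded subsample) — a
    runtime control for reduced-scale runs that leaves encoding untouched.
    """

    averaging_sizes: tuple[int, ...] = (1, 5, 50, 200)
    training_size_trials: int | None = 750
    k_folds: int = 2
    codebook_k: int = 150
    n_permutations: int = 100
    band_hz: tuple[float, float] = (80.0, 980.0)
    band_grid: tuple[tuple[float, float], ...] | None = None
    slice_ms: float = 20.0
    overlap_ms: float = 15.0
    window_step_trials: int = 2
    reject_threshold_uv: float = 40.0
    n_states: int = 3
    hmm_restarts: int = 5
    hmm_iter: int = 100
    hmm_tol: float = 1e-4
    kmeans_restarts: int = 5
    kmeans_max_iter: int = 100
    codebook_max_slices: int | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if any(s < 1 for s in self.averaging_sizes):
            raise ValueError("averaging sizes must be >= 1")

    def slice_config(self) -> SliceConfig:
        return SliceConfig(
            slice_ms=self.slice_ms, overlap_ms=self.overlap_ms, band_hz=self.band_hz
        )


@dataclass
class ROCResult:
    """Macro-averaged one-vs-rest ROC for one (session, averaging size)."""

    session: str
    averaging_size: int
    fpr: np.ndarray
    tpr: np.ndarray
    area: float
    category: str
    discrimination_accuracy: float


@dataclass
class RecognitionResult:
    """Fold-level recognition scores plus cross-scoring matrices."""

    scores: pd.DataFrame
    matrices: dict = field(default_factory=dict)
    infants: list = field(default_factory=list)
    sessions: list = field(default_factory=list)

    def aggregated(self) -> pd.DataFrame:
        """One recognition score per model (test-sequence and fold average)."""
        keys = ["infant_id", "session", "averaging_size", "band_low", "band_high"]
        return (
            self.scores.groupby(keys, sort=False)["recognition_score"]
            .mean()
            .reset_index()
        )

    @property
    def n_models(self) -> int:
        """Distinct trained models: one per subject x session x size x band."""
        keys = ["infant_id", "session", "averaging_size", "band_low", "band_high"]
        return int(self.scores[keys].drop_duplicates().shape[0])


@dataclass
class PermutationResult:
    """Permutation chance scores and group-level p-values."""

    chance: pd.DataFrame
    pvalues: pd.DataFrame
    truth: RecognitionResult

    def null_for(self, infant_id: str, session: str, averaging_size: int) -> np.ndarray:
        """The chance-score distribution (one value per permutation)."""
        sel = self.chance[
            (self.chance.infant_id == infant_id)
            & (self.chance.session == session)
            & (self.chance.averaging_size == averaging_size)
        ].sort_values("permutation")
        return sel["chance_score"].to_numpy()


def _derive_seed(*key: int) -> int:
    return int(np.random.SeedSequence(tuple(int(k) for k in key)).generate_state(1)[0])


def _group_cohort(cohort: list[TrialEpochSet]):
    sessions: list[str] = []
    infants: list[str] = []
    by_key: dict[tuple[str, str], TrialEpochSet] = {}
    for ts in cohort:
        if ts.session not in sessions:
            sessions.append(ts.session)
        if ts.infant_id not in infants:
            infants.append(ts.infant_id)
        key = (ts.infant_id, ts.session)
        if key in by_key:
            raise ValueError(f"duplicate epoch set for {key}")
        by_key[key] = ts
    for s in sessions:
        for i in infants:
            if (i, s) not in by_key:
                raise ValueError(f"cohort is missing {i}/{s}")
    return sessions, infants, by_key


def _fold_split(n: int, fold: int, cfg: ExperimentConfig, who: str):
    """Contiguous k-fold split of trial indices; optional training cap."""
    k = cfg.k_folds
    block = n // k
    if block < 1:
        raise ValueError(f"{who}: {n} accepted trials cannot form {k} folds")
    test = np.arange(fold * block, (fold + 1) * block if fold < k - 1 else n)
    train = np.setdiff1d(np.arange(n), test)
    if cfg.training_size_trials is not None:
        if train.size < cfg.training_size_trials:
            raise ValueError(
                f"{who}: training partition holds {train.size} trials, "
                f"fewer than training_size_trials={cfg.training_size_trials}"
            )
        train = train[: cfg.training_size_trials]
    # leakage audit: fitting inputs and scoring inputs must be disjoint
    assert np.intersect1d(train, test).size == 0
    return train, test


def _features(
    ts: TrialEpochSet,
    idx: np.ndarray,
    size: int,
    cfg: ExperimentConfig,
    band: tuple[float, float] | None,
) -> np.ndarray:
    """(n_sequences, n_slices, n_bins) dB features for a trial subset."""
    sub = subaverage(
        ts.subset(idx), SubAverageConfig(size, cfg.window_step_trials)
    )
    resp = sub.epochs[:, ts.t0_index :]
    db, _, freqs = stft_slices(resp, ts.sample_rate_hz, cfg.slice_config())
    if band is not None:
        db = db[..., _band_mask(freqs, *band)]
    return db


def run_recognition(
    cohort: list[TrialEpochSet],
    cfg: ExperimentConfig,
    sizes: tuple[int, ...] | None = None,
    band: tuple[float, float] | None = None,
    collect_matrices: bool = True,
    reject: bool = True,
    seed_salt: int = 0,
    band_index: int = 0,
) -> RecognitionResult:
    """Train and score the full factorial of per-subject HMMs.

    Returns fold-level recognition scores and (optionally) the full
    cross-scoring matrices used for classification and ROC analysis.
    """
    sizes = tuple(cfg.averaging_sizes) if sizes is None else tuple(sizes)
    sessions, infants, by_key = _group_cohort(cohort)
    if reject:
        by_key = {
            k: reject_artifacts(ts, cfg.reject_threshold_uv)
            for k, ts in by_key.items()
        }
    band_low, band_high = band if band is not None else cfg.band_hz
    rows = []
    matrices: dict = {}
    for si, session in enumerate(sessions):
        sets = [by_key[(i, session)] for i in infants]
        for size in sizes:
            fold_mats, fold_labels = [], []
            for fold in range(cfg.k_folds):
                train_feats, test_feats = [], []
                for inf_i, ts in enumerate(sets):
                    who = f"{ts.infant_id}/{ts.session}"
                    train_idx, test_idx = _fold_split(ts.n_trials, fold, cfg, who)
                    try:
                        train_feats.append(_features(ts, train_idx, size, cfg, band))
                        test_feats.append(_features(ts, test_idx, size, cfg, band))
                    except ValueError as err:
                        raise ValueError(f"{who}: {err}") from err
                n_bins = train_feats[0].shape[2]
                pooled = np.concatenate(
                    [f.reshape(-1, n_bins) for f in train_feats], axis=0
                )
                codebook = VectorQuantizer(
                    n_codes=cfg.codebook_k,
                    n_restarts=cfg.kmeans_restarts,
                    max_iter=cfg.kmeans_max_iter,
                    max_training_vectors=cfg.codebook_max_slices,
                    random_state=_derive_seed(
                        cfg.master_seed, 101, seed_salt, si, size, fold, band_index
                    ),
                ).fit(pooled)
                models = []
                test_syms = []
                for inf_i in range(len(infants)):
                    tf = train_feats[inf_i]
                    syms = codebook.transform(tf.reshape(-1, n_bins)).reshape(
                        tf.shape[0], tf.shape[1]
                    )
                    model = BakisHMM(
                        n_states=cfg.n_states,
                        n_symbols=cfg.codebook_k,
                        n_iter=cfg.hmm_iter,
                        tol=cfg.hmm_tol,
                        n_restarts=cfg.hmm_restarts,
                        random_state=_derive_seed(
                            cfg.master_seed, 103, seed_salt, si, size, fold,
                            band_index, inf_i,
                        ),
                    ).fit(syms)
                    models.append(model)
                    sf = test_feats[inf_i]
                    test_syms.append(
                        codebook.transform(sf.reshape(-1, n_bins)).reshape(
                            sf.shape[0], sf.shape[1]
                        )
                    )
                all_test = np.concatenate(test_syms, axis=0)
                labels = np.concatenate(
                    [np.full(s.shape[0], i) for i, s in enumerate(test_syms)]
                )
                score_mat = np.column_stack(
                    [m.score_sequences(all_test) for m in models]
                )
                for inf_i, infant in enumerate(infants):
                    own = score_mat[labels == inf_i, inf_i]
                    rows.append(
                        {
                            "infant_id": infant,
                            "session": session,
                            "averaging_size": int(size),
                            "band_low": float(band_low),
                            "band_high": float(band_high),
                            "fold": int(fold),
                            "recognition_score": float(own.mean()),
                            "n_test_sequences": int(own.size),
                        }
                    )
                if collect_matrices:
                    fold_mats.append(score_mat)
                    fold_labels.append(labels)
            if collect_matrices:
                matrices[(session, int(size))] = {
                    "scores": np.concatenate(fold_mats, axis=0),
                    "labels": np.concatenate(fold_labels),
                    "infants": list(infants),
                }
    return RecognitionResult(
        scores=pd.DataFrame(rows),
        matrices=matrices,
        infants=list(infants),
        sessions=list(sessions),
    )


def classify(score_matrix: np.ndarray, infants: list[str] | None = None) -> np.ndarray:
    """Assign each test sequence to the model with the largest log-probability.

    Ties break to the lowest model index and are logged.
    """
    m = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    if m.shape[1] < 1:
        raise ValueError("classify needs at least one model column")
    winners = np.argmax(m, axis=1)
    n_ties = int(np.sum((m == m.max(axis=1, keepdims=True)).sum(axis=1) > 1))
    if n_ties:
        logger.info("classify: %d tied sequences broken to the lowest index", n_ties)
    if infants is not None:
        return np.asarray(infants)[winners]
    return winners


def categorize_roc(area: float) -> str:
    """Qualitative ROC-area band (excellent/good/fair/poor/bad)."""
    if not (0.0 <= area <= 1.0):
        raise ValueError(f"ROC area {area} outside [0, 1]")
    if area > 0.9:
        return "excellent"
    if area > 0.8:
        return "good"
    if area > 0.7:
        return "fair"
    if area > 0.6:
        return "poor"
    return "bad"


def roc_analysis(
    result: RecognitionResult, grid_points: int = 101
) -> list[ROCResult]:
    """One-vs-rest ROC per subject, macro-averaged per (session, size).

    Each test sequence's log-probability under subject i's model is the
    decision score for the binary problem "is this sequence subject i's";
    per-subject curves are interpolated onto a common FPR grid and
    averaged, and the area follows by trapezoidal integration.
    """
    from sklearn.metrics import roc_curve

    if not result.matrices:
        raise ValueError("RecognitionResult carries no score matrices")
    if len(result.infants) < 2:
        raise ValueError(
            "ROC/discrimination analysis needs at least two subjects; "
            "recognition scores alone are available for a single subject"
        )
    grid = np.linspace(0.0, 1.0, grid_points)
    out = []
    for (session, size), m in result.matrices.items():
        scores, labels = m["scores"], m["labels"]
        if np.unique(labels).size < 2:
            raise ValueError(f"single-class test set for {session}, size {size}")
        tprs, aucs = [], []
        for j in range(scores.shape[1]):
            y = labels == j
            fpr, tpr, _ = roc_curve(y, scores[:, j])
            tprs.append(np.interp(grid, fpr, tpr))
            aucs.append(np.trapezoid(tpr, fpr))
        tpr_avg = np.mean(tprs, axis=0)
        # macro-average of exact per-subject areas (the gridded average
        # curve is kept for display only)
        area = float(np.mean(aucs))
        acc = 100.0 * float(np.mean(classify(scores) == labels))
        out.append(
            ROCResult(
                session=session,
                averaging_size=int(size),
                fpr=grid,
                tpr=tpr_avg,
                area=area,
                category=categorize_roc(area),
                discrimination_accuracy=acc,
            )
        )
    return out


def roc_table(results: list[ROCResult]) -> pd.DataFrame:
    """Tidy summary of ROC results (one row per session x size)."""
    return pd.DataFrame(
        [
            {
                "session": r.session,
                "averaging_size": r.averaging_size,
                "roc_area": r.area,
                "category": r.category,
                "discrimination_accuracy_percent": r.discrimination_accuracy,
            }
            for r in results
        ]
    )


def p_value_from_scores(chance_means: np.ndarray, truth_mean: float) -> float:
    """Proportion of averaged chance scores >= the averaged truth score."""
    chance_means = np.asarray(chance_means, dtype=float)
    if chance_means.size == 0:
        raise ValueError("empty chance distribution")
    return float(np.mean(chance_means >= truth_mean))


def _permute_within_sessions(
    by_key: dict, sessions: list[str], infants: list[str], rng: np.random.Generator
) -> list[TrialEpochSet]:
    """Reassign accepted trials to subject labels at random within session."""
    permuted = []
    for session in sessions:
        sets = [by_key[(i, session)] for i in infants]
        epochs = np.concatenate([ts.epochs for ts in sets], axis=0)
        pol = np.concatenate([ts.polarity for ts in sets])
        order = rng.permutation(epochs.shape[0])
        offset = 0
        for ts in sets:
            take = order[offset : offset + ts.n_trials]
            offset += ts.n_trials
            permuted.append(
                TrialEpochSet(
                    epochs=epochs[take],
                    sample_rate_hz=ts.sample_rate_hz,
                    t0_index=ts.t0_index,
                    prestim_ms=ts.prestim_ms,
                    polarity=pol[take],
                    infant_id=ts.infant_id,
                    session=session,
                    meta={"permuted": True},
                )
            )
    return permuted


def permutation_null(
    cohort: list[TrialEpochSet],
    cfg: ExperimentConfig,
    sizes: tuple[int, ...] | None = None,
) -> PermutationResult:
    """Empirical chance levels by shuffling trials across subjects.

    Emits ``cfg.n_permutations`` chance-level recognition scores per model
    and a group-level p-value per (session, averaging size): the
    proportion of session/size-averaged chance scores that are >= the
    corresponding averaged ground-truth score.
    """
    sizes = tuple(cfg.averaging_sizes) if sizes is None else tuple(sizes)
    sessions, infants, by_key = _group_cohort(cohort)
    by_key = {
        k: reject_artifacts(ts, cfg.reject_threshold_uv) for k, ts in by_key.items()
    }
    accepted = [by_key[(i, s)] for i in infants for s in sessions]
    truth = run_recognition(
        accepted, cfg, sizes=sizes, collect_matrices=False, reject=False
    )
    chance_rows = []
    for perm in range(cfg.n_permutations):
        rng = np.random.default_rng(
            np.random.SeedSequence((int(cfg.master_seed), 577, perm))
        )
        permuted = _permute_within_sessions(by_key, sessions, infants, rng)
        res = run_recognition(
            permuted,
            cfg,
            sizes=sizes,
            collect_matrices=False,
            reject=False,
            seed_salt=1 + perm,
        )
        agg = res.aggregated()
        for _, r in agg.iterrows():
            chance_rows.append(
                {
                    "permutation": perm,
                    "infant_id": r.infant_id,
                    "session": r.session,
                    "averaging_size": int(r.averaging_size),
                    "chance_score": float(r.recognition_score),
                }
            )
    chance = pd.DataFrame(chance_rows)
    truth_agg = truth.aggregated()
    pvals = []
    for session in sessions:
        for size in sizes:
            t = truth_agg[
                (truth_agg.session == session)
                & (truth_agg.averaging_size == size)
            ]["recognition_score"].mean()
            per_perm = (
                chance[
                    (chance.session == session) & (chance.averaging_size == size)
                ]
                .groupby("permutation")["chance_score"]
                .mean()
                .to_numpy()
            )
            pvals.append(
                {
                    "session": session,
                    "averaging_size": int(size),
                    "truth_score": float(t),
                    "mean_chance_score": float(per_perm.mean()),
                    "p_value": p_value_from_scores(per_perm, t),
                }
            )
    return PermutationResult(
        chance=chance, pvalues=pd.DataFrame(pvals), truth=truth
    )


def band_profile(
    cohort: list[TrialEpochSet],
    cfg: ExperimentConfig,
    band_size: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recognition repeated per 100-Hz frequency channel at one size.

    Returns fold-level scores (with band columns) and a per-band summary
    with macro-ROC area and classification accuracy.
    """
    grid = (
        tuple(cfg.band_grid)
        if cfg.band_grid is not None
        else tuple(default_band_grid())
    )
    all_scores = []
    summaries = []
    for bi, band in enumerate(grid):
        res = run_recognition(
            cohort,
            cfg,
            sizes=(band_size,),
            band=band,
            band_index=bi,
            seed_salt=9000,
        )
        all_scores.append(res.scores)
        rocs = roc_analysis(res) if len(res.infants) >= 2 else []
        for r in rocs:
            summaries.append(
                {
                    "band_low": band[0],
                    "band_high": band[1],
                    "session": r.session,
                    "averaging_size": r.averaging_size,
                    "roc_area": r.area,
                    "discrimination_accuracy_percent": r.discrimination_accuracy,
                }
            )
    return pd.concat(all_scores, ignore_index=True), pd.DataFrame(summaries)
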