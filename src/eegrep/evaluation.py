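"""Classification harness: tasks, train/test scenarios, channel selection,
and balanced-accuracy reporting.

Three tasks probe what the EEG representations carry:

* ``score``     — attentive (score 0) vs inattentive (score 1) epochs,
                  separately for Target and Distractor stimuli;
* ``stimulus``  — Target vs Distractor among perfectly handled (score 0)
                  epochs, separately per condition (so the classifier sees
                  stimulus identity, not the accompanying support);
* ``condition`` — C1 vs C2 vs C3 vs C4 among score-0 epochs, separately per
                  stimulus kind.

Each task equalizes participant contributions: every participant contributes
the same number of epochs (the minimum available across participants),
sampled without replacement.  Classification is a linear maximum-margin
classifier (L2-regularized hinge loss, fixed C=1) on standardized features,
scored by balanced accuracy — the unweighted mean of per-class recalls, 0.5
being binary chance.  Three scenarios probe cross-subject generalization:
``per_participant`` (train and test within one subject), ``seen_participants``
(epoch-level split over everyone) and ``new_participants`` (disjoint subject
sets in train and test).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from . import mts_features, tda_features, uts_features

__all__ = [
    "PIPELINES",
    "CHANNEL_LIMITED_PIPELINES",
    "FeatureMatrix",
    "featurize_epochs",
    "balanced_accuracy",
    "SplitSpec",
    "Split",
    "make_splits",
    "subsample_quota",
    "select_top_channels",
    "TaskSpec",
    "build_task_dataset",
    "EvalResult",
    "run_task",
    "results_frame",
]

SCENARIOS = ("per_participant", "seen_participants", "new_participants")

#: The eight feature pipelines, by tag.
PIPELINES = ("uts", "uts-rp", "uts-tdf", "uts-ph", "gfp", "fbn", "fbn-gt", "fbn-ph")

#: Pipelines whose feature count explodes with channels; these are limited to
#: the top channels identified by the UTS pipeline.
CHANNEL_LIMITED_PIPELINES = ("uts-rp", "uts-tdf", "uts-ph")


class EvaluationError(ValueError):
    """Raised on invalid task, split or scoring inputs."""


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Epochs x features matrix with pipeline tag and channel provenance.

    ``channel_of_feature`` maps each column to the EEG channel it came from,
    or -1 for features without a single-channel provenance (GFP, FBN,
    FBN-PH and the global graph metrics).
    """

    values: np.ndarray
    pipeline_tag: str
    channel_of_feature: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise EvaluationError("feature matrix must be 2-D")
        if not np.all(np.isfinite(values)):
            raise EvaluationError("feature matrix contains non-finite entries")
        chans = np.asarray(self.channel_of_feature, dtype=int)
        if chans.shape[0] != values.shape[1]:
            raise EvaluationError("channel_of_feature length must match columns")
        self.values = values
        self.channel_of_feature = chans

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _per_epoch(values: np.ndarray, fn: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    return np.stack([fn(epoch) for epoch in values])


def featurize_epochs(values: np.ndarray, pipeline: str,
                     channels: Sequence[int] | None = None) -> FeatureMatrix:
    """Compute one pipeline's feature matrix for an (epochs, C, T) array.

    ``channels`` restricts the per-channel pipelines (uts, uts-rp, uts-tdf,
    uts-ph) to a subset of channels; the multivariate pipelines always use
    every channel.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise EvaluationError(f"expected (epochs, C, T) array, got shape {values.shape}")
    n, C, T = values.shape
    chans = np.arange(C) if channels is None else np.asarray(list(channels), dtype=int)

    if pipeline == "uts":
        feats = _per_epoch(values, lambda ep: uts_features.uts_vector(ep, channels))
        provenance = np.repeat(chans, T)
    elif pipeline == "uts-rp":
        feats = _per_epoch(values, lambda ep: uts_features.uts_rp_vector(ep, channels))
        provenance = np.repeat(chans, T * T)
    elif pipeline == "uts-tdf":
        feats = _per_epoch(values, lambda ep: uts_features.uts_tdf_vector(ep, channels))
        provenance = np.repeat(chans, 10)
    elif pipeline == "uts-ph":
        feats = _per_epoch(values, lambda ep: tda_features.uts_ph_vector(ep, channels))
        provenance = np.repeat(chans, 100)
    elif pipeline == "gfp":
        feats = _per_epoch(values, mts_features.gfp)
        provenance = np.full(T, -1)
    elif pipeline == "fbn":
        feats = _per_epoch(values, lambda ep: mts_features.fbn_vector(mts_features.pearson_distance(ep)))
        provenance = np.full(C * (C - 1) // 2, -1)
    elif pipeline == "fbn-gt":
        feats = _per_epoch(
            values,
            lambda ep: mts_features.graph_metric_vector(
                mts_features.threshold_graph(mts_features.pearson_distance(ep))
            ),
        )
        provenance = np.concatenate([np.full(3, -1), np.tile(np.arange(C), 3)])
    elif pipeline == "fbn-ph":
        feats = _per_epoch(values, lambda ep: tda_features.fbn_ph_vector(mts_features.pearson_distance(ep)))
        provenance = np.full(200, -1)
    else:
        raise EvaluationError(f"unknown pipeline {pipeline!r}; expected one of {PIPELINES}")
    return FeatureMatrix(values=feats, pipeline_tag=pipeline, channel_of_feature=provenance)


# ---------------------------------------------------------------------------
# Balanced accuracy
# ---------------------------------------------------------------------------


def balanced_accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    """Unweighted mean of per-class recalls.

    For two classes this is (TP/(TP+FN) + TN/(TN+FP)) / 2.  Every class
    present in ``y_true`` must have at least one instance (guaranteed by
    construction); a class never predicted simply scores recall 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise EvaluationError("y_true and y_pred must be equal-length and non-empty")
    recalls = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        if not mask.any():  # pragma: no cover - unique() guarantees presence
            raise EvaluationError(f"true class {cls!r} has no instances")
        recalls.append(np.mean(y_pred[mask] == cls))
    return float(np.mean(recalls))


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """How to split train and test: scenario, fraction, repeats, seed."""

    scenario: str = "seen_participants"
    train_fraction: float = 0.7
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise EvaluationError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if not 0.0 < self.train_fraction < 1.0:
            raise EvaluationError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class Split:
    """One train/test partition (positional indices into the task dataset)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    repeat_index: int
    participant: str | None = None


def _stratified_split(indices: np.ndarray, strata_candidates: list,
                      train_fraction: float, rng_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-level split, stratified by the finest stratification that fits.

    Candidates are tried in order (e.g. participant x label, then label
    alone, then unstratified) — a stratification fails when some stratum has
    fewer than two members or more strata than test samples exist."""
    for strata in strata_candidates:
        if strata is not None:
            counts = pd.Series(strata).value_counts()
            if counts.min() < 2 or len(counts) < 2:
                continue
        try:
            train, test = train_test_split(
                indices, train_size=train_fraction, random_state=rng_seed,
                stratify=strata,
            )
            return np.sort(train), np.sort(test)
        except ValueError:
            continue
    train, test = train_test_split(indices, train_size=train_fraction, random_state=rng_seed)
    return np.sort(train), np.sort(test)


def make_splits(meta: pd.DataFrame, spec: SplitSpec,
                labels: np.ndarray | None = None) -> list[Split]:
    """Build the train/test splits for one scenario.

    ``meta`` must carry a ``participant_id`` column aligned with the task
    dataset rows.  Splits are stratified by (participant, label) — or by
    label alone when strata get too small — to avoid single-class folds.
    ``new_participants`` splits subjects, never epochs, so train and test
    share no participant.
    """
    if "participant_id" not in meta.columns:
        raise EvaluationError("meta must have a participant_id column")
    n = len(meta)
    participants = meta["participant_id"].to_numpy()
    unique_participants = pd.unique(participants)
    if labels is None:
        label_arr = None
        combined = participants.astype(str)
    else:
        label_arr = np.asarray(labels).astype(str)
        combined = np.char.add(np.char.add(participants.astype(str), "|"), label_arr)
    splits: list[Split] = []
    if spec.scenario == "per_participant":
        if n < 2:
            raise EvaluationError("per_participant needs at least 2 epochs")
        for pid in unique_participants:
            idx = np.flatnonzero(participants == pid)
            candidates = [None if label_arr is None else label_arr[idx]]
            for rep in range(spec.n_repeats):
                train, test = _stratified_split(
                    idx, candidates, spec.train_fraction,
                    rng_seed=_derive_seed(spec.seed, str(pid), rep),
                )
                splits.append(Split(train, test, rep, participant=str(pid)))
    elif spec.scenario == "seen_participants":
        if n < 2:
            raise EvaluationError("seen_participants needs at least 2 epochs")
        idx = np.arange(n)
        candidates = [combined, label_arr]
        for rep in range(spec.n_repeats):
            train, test = _stratified_split(
                idx, candidates, spec.train_fraction,
                rng_seed=_derive_seed(spec.seed, "seen", rep),
            )
            splits.append(Split(train, test, rep))
    else:  # new_participants
        if len(unique_participants) < 2:
            raise EvaluationError("new_participants needs at least 2 participants")
        n_train = int(round(spec.train_fraction * len(unique_participants)))
        n_train = min(max(n_train, 1), len(unique_participants) - 1)
        for rep in range(spec.n_repeats):
            rng = np.random.default_rng(_derive_seed(spec.seed, "new", rep))
            order = rng.permutation(unique_participants)
            train_p = set(order[:n_train])
            train = np.flatnonzero([p in train_p for p in participants])
            test = np.flatnonzero([p not in train_p for p in participants])
            splits.append(Split(train, test, rep))
    return splits


def _derive_seed(seed: int, tag: str, rep: int) -> int:
    tag_code = zlib.crc32(tag.encode("utf-8"))
    return int(np.random.SeedSequence([seed, tag_code, rep]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Quota subsampling and channel selection
# ---------------------------------------------------------------------------


def subsample_quota(participant_ids: Sequence[str], seed: int,
                    quota: int | None = None) -> np.ndarray:
    """Equalize participant contributions: each participant keeps exactly
    ``quota`` epochs (default: the minimum available across participants),
    sampled without replacement.  Returns sorted positional indices."""
    participants = np.asarray(participant_ids)
    if participants.size == 0:
        raise EvaluationError("no epochs to subsample")
    counts = pd.Series(participants).value_counts()
    min_count = int(counts.min())
    if quota is None:
        quota = min_count
    if quota > min_count:
        worst = counts.idxmin()
        raise EvaluationError(
            f"participant {worst!r} has only {min_count} eligible epochs (< quota {quota})"
        )
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for pid in pd.unique(participants):
        idx = np.flatnonzero(participants == pid)
        keep.append(rng.choice(idx, size=quota, replace=False))
    return np.sort(np.concatenate(keep))


def select_top_channels(coefficients: np.ndarray, channel_of_feature: np.ndarray,
                        n_channels: int, k: int = 10) -> np.ndarray:
    """Top-k channels by summed absolute classifier coefficient.

    ``coefficients`` is the (n_classes, n_features) or (n_features,) weight
    matrix of a fitted linear classifier; a channel's importance is the sum
    of |coefficient| over its features.  Ties break toward the lower channel
    index.  Returns the selected channel indices in ascending order.
    """
    coefs = np.atleast_2d(np.asarray(coefficients, dtype=float))
    importance = np.zeros(n_channels)
    per_feature = np.abs(coefs).sum(axis=0)
    for chan, weight in zip(np.asarray(channel_of_feature, dtype=int), per_feature):
        if chan >= 0:
            importance[chan] += weight
    if k > n_channels:
        raise EvaluationError(f"cannot select {k} of {n_channels} channels")
    order = np.lexsort((np.arange(n_channels), -importance))
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# Tasks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskSpec:
    """One classification task: name, stratum, and the quota seed.

    ``name`` is ``score`` (labels 0/1 from the conclusive attention scores,
    stratum = stimulus kind), ``stimulus`` (labels Target/Distractor among
    score-0 epochs, stratum = condition) or ``condition`` (labels C1-C4
    among score-0 epochs, stratum = stimulus kind).
    """

    name: str
    stratum: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("score", "stimulus", "condition"):
            raise EvaluationError(f"unknown task {self.name!r}")


def build_task_dataset(meta: pd.DataFrame, task: TaskSpec) -> tuple[np.ndarray, np.ndarray]:
    """Select epochs and labels for one task.

    ``meta`` is the scored epoch metadata (columns participant_id, kind,
    condition, score).  Returns (row indices into ``meta``, label array)
    after the per-participant quota subsampling.
    """
    required = {"participant_id", "kind", "condition", "score"}
    missing = required - set(meta.columns)
    if missing:
        raise EvaluationError(f"meta lacks columns {sorted(missing)}")
    if task.name == "score":
        pool = meta[(meta["kind"] == task.stratum) & meta["score"].isin([0.0, 1.0])]
        labels = pool["score"].astype(int).to_numpy()
    elif task.name == "stimulus":
        pool = meta[(meta["condition"] == task.stratum) & (meta["score"] == 0.0)]
        labels = pool["kind"].to_numpy()
    else:  # condition
        pool = meta[(meta["kind"] == task.stratum) & (meta["score"] == 0.0)]
        labels = pool["condition"].to_numpy()
    if pool.empty:
        raise EvaluationError(f"no eligible epochs for task {task.name}/{task.stratum}")
    keep = subsample_quota(pool["participant_id"].to_numpy(), seed=task.seed)
    return pool.index.to_numpy()[keep], labels[keep]


# ---------------------------------------------------------------------------
# Running a task
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalResult:
    """Balanced accuracy of one (task, pipeline, scenario, split)."""

    task: str
    stratum: str
    pipeline_tag: str
    scenario: str
    repeat_index: int
    balanced_accuracy: float
    n_train: int
    n_test: int
    participant: str | None = None
    valid: bool = True


def _fit_and_score(train_x: np.ndarray, train_y: np.ndarray,
                   test_x: np.ndarray, test_y: np.ndarray) -> tuple[float, bool]:
    if len(np.unique(train_y)) < 2 or len(np.unique(test_y)) < 2:
        return float("nan"), False
    scaler = StandardScaler().fit(train_x)
    clf = LinearSVC(C=1.0, max_iter=10000)
    clf.fit(scaler.transform(train_x), train_y)
    predictions = clf.predict(scaler.transform(test_x))
    return balanced_accuracy(test_y, predictions), True


def run_task(values: np.ndarray, meta: pd.DataFrame, pipeline_tag: str,
             task: TaskSpec, split_spec: SplitSpec,
             top_channels: int | None = 10) -> list[EvalResult]:
    """Evaluate one pipeline on one task under one scenario.

    ``values`` is the (epochs, C, T) array aligned with ``meta`` (scored
    metadata).  The high-dimensional per-channel pipelines (uts-rp, uts-tdf,
    uts-ph) are restricted to the ``top_channels`` most important channels,
    identified from the absolute coefficients of the linear classifier of
    the UTS pipeline fitted on the complete task data.  Single-class folds
    are flagged invalid rather than silently scored.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(meta):
        raise EvaluationError("values and meta are misaligned")
    rows, labels = build_task_dataset(meta.reset_index(drop=True), task)
    task_values = values[rows]
    task_meta = meta.reset_index(drop=True).iloc[rows].reset_index(drop=True)

    channels = None
    if pipeline_tag in CHANNEL_LIMITED_PIPELINES and top_channels is not None:
        n_channels = values.shape[1]
        k = min(top_channels, n_channels)
        uts = featurize_epochs(task_values, "uts")
        scaler = StandardScaler().fit(uts.values)
        probe = LinearSVC(C=1.0, max_iter=10000)
        probe.fit(scaler.transform(uts.values), labels)
        channels = select_top_channels(probe.coef_, uts.channel_of_feature, n_channels, k=k)

    features = featurize_epochs(task_values, pipeline_tag, channels=channels)
    splits = make_splits(task_meta, split_spec, labels=labels)
    results: list[EvalResult] = []
    for split in splits:
        accuracy, valid = _fit_and_score(
            features.values[split.train_idx], labels[split.train_idx],
            features.values[split.test_idx], labels[split.test_idx],
        )
        results.append(
            EvalResult(
                task=task.name, stratum=task.stratum, pipeline_tag=pipeline_tag,
                scenario=split_spec.scenario, repeat_index=split.repeat_index,
                balanced_accuracy=accuracy, n_train=len(split.train_idx),
                n_test=len(split.test_idx), participant=split.participant,
                valid=valid,
            )
        )
    return results


def results_frame(results: Iterable[EvalResult]) -> pd.DataFrame:
    """Tidy table of evaluation results, one row per split."""
    return pd.DataFrame([r.__dict__ for r in results])
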