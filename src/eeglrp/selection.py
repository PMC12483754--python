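"""Relevance-score-based automatic channel selection.

From a fold's full-montage model: relevance is computed for every
validation subject, averaged over time points per channel, class-wise
averaged and normalised into a channels x 2 matrix, reduced to a
per-channel class maximum, and sorted descending.  The top-k channels then
feed a freshly trained k-channel model of the same train/validation split,
evaluated on the fold's held-out test subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NetSpec, RunConfig
from .lrp import channel_relevance, subject_relevance
from .montage import Montage
from .net import (
    FoldResult,
    TrainedModel,
    _fit_fold,
    predict_subject,
    subject_seed,
)
from .preprocessing import SegmentSet


@dataclass(frozen=True)
class ClassRelevanceMatrix:
    """channels x 2 class-aggregated relevance (columns: control, patient).

    Each column is the L1-normalised absolute mean relevance of its class:
    non-negative, summing to 1.
    """

    values: np.ndarray  # (n_channels, 2)
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.channel_names), 2):
            raise ValueError(f"expected ({len(self.channel_names)}, 2), got {v.shape}")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ChannelRanking:
    """Channels sorted by descending class-max relevance."""

    channel_names: tuple[str, ...]  # descending score order
    scores: tuple[float, ...]
    class_of_max: tuple[int, ...]
    source_fold: str = ""

    def top(self, k: int) -> tuple[str, ...]:
        if not 1 <= k <= len(self.channel_names):
            raise ValueError(
                f"k must be in 1..{len(self.channel_names)}, got {k}"
            )
        return self.channel_names[:k]


def validation_relevance(
    trained: TrainedModel,
    val_sets: list[SegmentSet],
    *,
    epsilon: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel relevance of every validation subject.

    Returns ``(matrix, labels)`` where column j of the (channels x n_val)
    matrix is the time-averaged relevance of validation subject j (relevance
    of each subject's segments averaged when there are several).
    """
    if not val_sets:
        raise ValueError("validation set is empty")
    cols, labels = [], []
    for ss in val_sets:
        per_segment = [
            channel_relevance(
                subject_relevance(
                    trained, seg, epsilon=epsilon, subject_id=ss.subject_id
                )
            )
            for seg in ss.segments
        ]
        cols.append(np.mean(per_segment, axis=0))
        labels.append(ss.label)
    return np.column_stack(cols), np.asarray(labels, dtype=int)


def classwise_aggregate(
    matrix: np.ndarray, labels, channel_names, *, rectify: bool = True
) -> ClassRelevanceMatrix:
    """Mean per class, absolute value, then L1 normalisation per column.

    ``rectify=False`` keeps the class means signed and normalises by the
    column's total absolute mass instead (the signed variant).
    """
    labels = np.asarray(labels, dtype=int)
    if matrix.shape[1] != labels.size:
        raise ValueError("one label per matrix column required")
    cols = []
    for cls in (0, 1):
        members = matrix[:, labels == cls]
        if members.shape[1] == 0:
            raise ValueError(f"no validation subjects of class {cls}")
        mean = members.mean(axis=1)
        if rectify:
            mean = np.abs(mean)
        total = np.abs(mean).sum()
        cols.append(mean / total if total > 0 else mean)
    return ClassRelevanceMatrix(np.column_stack(cols), tuple(channel_names))


def rank_channels(crm: ClassRelevanceMatrix, *, source_fold: str = "") -> ChannelRanking:
    """Per-channel class max, sorted descending (ties: montage order)."""
    scores = crm.values.max(axis=1)
    class_of_max = crm.values.argmax(axis=1)
    order = np.argsort(-scores, kind="stable")  # stable: ties keep montage order
    return ChannelRanking(
        channel_names=tuple(crm.channel_names[i] for i in order),
        scores=tuple(float(scores[i]) for i in order),
        class_of_max=tuple(int(class_of_max[i]) for i in order),
        source_fold=source_fold,
    )


def fold_ranking(
    trained: TrainedModel,
    val_sets: list[SegmentSet],
    channel_names,
    *,
    epsilon: float = 1e-6,
    source_fold: str = "",
) -> ChannelRanking:
    """Validation relevance -> class aggregation -> ranking, in one step."""
    matrix, labels = validation_relevance(trained, val_sets, epsilon=epsilon)
    crm = classwise_aggregate(matrix, labels, channel_names)
    return rank_channels(crm, source_fold=source_fold)


def select_and_retrain(
    segment_sets: list[SegmentSet],
    fold: FoldResult,
    k: int,
    montage: Montage,
    config: RunConfig,
    *,
    net_spec: NetSpec | None = None,
    ranking: ChannelRanking | None = None,
    keep_model: bool = False,
) -> FoldResult:
    """Retrain one fold on its top-k relevance-selected channels.

    The ranking comes from the fold's full-montage model applied to its own
    validation subjects (pass ``ranking`` to reuse a precomputed one); the
    k-channel model is trained on the identical train/validation split and
    evaluated on the fold's test subject.  The test subject's data never
    influences the ranking.
    """
    by_id = {ss.subject_id: ss for ss in segment_sets}
    if ranking is None:
        if fold.model is None:
            raise ValueError(
                "fold carries no trained model; rerun loocv with keep_models=True "
                "or pass a precomputed ranking"
            )
        ranking = fold_ranking(
            fold.model,
            [by_id[s] for s in fold.val_subject_ids],
            montage.channel_names,
            epsilon=config.lrp_epsilon,
            source_fold=fold.test_subject_id,
        )
    selected = ranking.top(k)
    channel_idx = montage.indices(selected)
    seed = subject_seed(config.seed, fold.test_subject_id)
    net_spec = net_spec if net_spec is not None else config.net_spec()
    trained = _fit_fold(
        by_id,
        fold.train_subject_ids,
        fold.val_subject_ids,
        selected,
        channel_idx,
        config,
        net_spec,
        seed,
    )
    test_ss = by_id[fold.test_subject_id].pick_channel_indices(channel_idx)
    pred, probs = predict_subject(trained, test_ss)
    return FoldResult(
        test_subject_id=fold.test_subject_id,
        true_label=fold.true_label,
        predicted_label=pred,
        class_probabilities=(float(probs[0]), float(probs[1])),
        train_subject_ids=fold.train_subject_ids,
        val_subject_ids=fold.val_subject_ids,
        selected_channels=selected,
        model=trained if keep_model else None,
    )


def selection_frequency(rankings: list[ChannelRanking], k: int, channel_names) -> dict[str, int]:
    """How often each channel appears in the top-k across folds."""
    counts = {name: 0 for name in channel_names}
    for r in rankings:
        for name in r.top(k):
            counts[name] += 1
    return counts
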