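"""Performance grid and group statistics.

The evaluation grid crosses channel-count settings with data lengths (the
default configuration yields 10 x 8 = 80 cells), running one leave-one-out
cross-validation — with relevance-based channel selection whenever fewer
than all channels are used — per cell.  Group statistics are independent
two-sample t-tests with Benjamini-Hochberg FDR correction: between grid
cells on per-subject correctness, and between classes on per-subject
L1-normalised absolute channel relevance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .config import NetSpec, RunConfig
from .io import EEGRecording
from .montage import Montage
from .net import CohortMetrics, loocv
from .preprocessing import segment
from .selection import select_and_retrain

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------


def ttest_independent(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample (equal-variance) t statistic with two-sided p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate samples: zero variance, unequal means")
    t, p = sstats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR-adjusted q-values (order-preserving, q <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# evaluation grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridResult:
    """One (channel count, data length) cell of the evaluation grid."""

    n_channels: int
    data_length_s: float
    accuracy: float
    sensitivity: float
    specificity: float
    #: per-subject 0/1 correctness, keyed by subject id (the replicate unit
    #: for between-cell t-tests)
    correct: tuple[tuple[str, int], ...]


def grid_cells(config: RunConfig) -> list[tuple[int, float]]:
    """The (channel count, data length) combinations the grid enumerates."""
    return list(itertools.product(config.channel_counts, config.data_lengths_s))


def run_grid(
    recordings: list[EEGRecording],
    config: RunConfig,
    *,
    net_spec: NetSpec | None = None,
) -> list[GridResult]:
    """Run one LOOCV (plus channel selection when k < all) per grid cell.

    ``recordings`` must already be preprocessed; each cell segments them at
    its data length independently.
    """
    montage = recordings[0].montage
    n_all = len(montage)
    results = []
    for k, length in grid_cells(config):
        min_dur = min(r.duration for r in recordings)
        if length > min_dur + 1e-9:
            raise ValueError(
                f"grid cell (k={k}, length={length}s): data length exceeds the "
                f"shortest recording ({min_dur:.1f}s)"
            )
        segment_sets = [segment(r, length) for r in recordings]
        if k >= n_all:
            folds, metrics = loocv(
                segment_sets, montage, config, net_spec=net_spec
            )
        else:
            folds, _ = loocv(
                segment_sets, montage, config, net_spec=net_spec, keep_models=True
            )
            folds = [
                select_and_retrain(
                    segment_sets, f, k, montage, config, net_spec=net_spec
                )
                for f in folds
            ]
            metrics = CohortMetrics.from_folds(folds)
        results.append(
            GridResult(
                n_channels=min(k, n_all),
                data_length_s=float(length),
                accuracy=metrics.accuracy,
                sensitivity=metrics.sensitivity,
                specificity=metrics.specificity,
                correct=tuple(
                    (f.test_subject_id, int(f.predicted_label == f.true_label))
                    for f in folds
                ),
            )
        )
        logger.info(
            "grid cell k=%d length=%gs: accuracy %.1f%%", k, length, metrics.accuracy
        )
    return results


def grid_to_frame(grid: list[GridResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n_channels": [g.n_channels for g in grid],
            "data_length_s": [g.data_length_s for g in grid],
            "accuracy": [g.accuracy for g in grid],
            "sensitivity": [g.sensitivity for g in grid],
            "specificity": [g.specificity for g in grid],
        }
    )


def compare_grid_cells(grid: list[GridResult], alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise t-tests between cells on subject correctness, BH-corrected.

    Cells whose indicator vectors are identical (or both degenerate with the
    same mean) get t = 0, p = 1.  Rows with q > alpha are flagged
    ``not_different``.
    """
    for g in grid:
        if not g.correct:
            raise ValueError(
                f"cell (k={g.n_channels}, length={g.data_length_s}) has no "
                "per-subject indicators"
            )
    rows = []
    pvals = []
    for (i, a), (j, b) in itertools.combinations(enumerate(grid), 2):
        xa = np.array([c for _, c in a.correct], dtype=float)
        xb = np.array([c for _, c in b.correct], dtype=float)
        if xa.var(ddof=1) + xb.var(ddof=1) == 0:
            t, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf, 0.0)
        else:
            t, p = ttest_independent(xa, xb)
        rows.append(
            {
                "cell_a": f"k={a.n_channels},len={a.data_length_s:g}",
                "cell_b": f"k={b.n_channels},len={b.data_length_s:g}",
                "t": t,
                "p": p,
            }
        )
        pvals.append(p)
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = benjamini_hochberg(pvals)
        df["not_different"] = df["q"] > alpha
    return df


# ---------------------------------------------------------------------------
# relevance group statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelStat:
    """Group comparison of normalised relevance at one channel."""

    channel: str
    mean_control: float
    mean_patient: float
    t: float
    p: float
    q: float


def normalize_subject_relevance(vector) -> np.ndarray:
    """|channel relevance| scaled to sum to 1 (per-subject L1 normalisation)."""
    v = np.abs(np.asarray(vector, dtype=float))
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero relevance vector")
    return v / total


def relevance_group_stats(
    relevance_per_subject: dict[str, np.ndarray],
    labels: dict[str, int],
    channel_names,
) -> list[ChannelStat]:
    """Per-channel patient-vs-control t-tests on normalised relevance.

    Subjects with an all-zero relevance vector are excluded with a warning.
    Raw p drives significance calls; BH q is attached alongside.
    """
    norm, used_labels = [], []
    for sid, vec in relevance_per_subject.items():
        try:
            norm.append(normalize_subject_relevance(vec))
        except ValueError:
            logger.warning("subject %s has all-zero relevance; excluded", sid)
            continue
        used_labels.append(labels[sid])
    used_labels = np.asarray(used_labels)
    if set(used_labels) != {0, 1}:
        raise ValueError("both classes required for group statistics")
    matrix = np.stack(norm)  # subjects x channels

    ts, ps = [], []
    for c in range(matrix.shape[1]):
        a = matrix[used_labels == 1, c]  # patients
        b = matrix[used_labels == 0, c]  # controls
        if a.var(ddof=1) + b.var(ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = ttest_independent(a, b)
        ts.append(t)
        ps.append(p)
    qs = benjamini_hochberg(ps)
    return [
        ChannelStat(
            channel=str(name),
            mean_control=float(matrix[used_labels == 0, c].mean()),
            mean_patient=float(matrix[used_labels == 1, c].mean()),
            t=ts[c],
            p=ps[c],
            q=float(qs[c]),
        )
        for c, name in enumerate(channel_names)
    ]


def channel_stats_to_frame(stats: list[ChannelStat]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


def topography_frame(montage: Montage, values) -> pd.DataFrame:
    """(channel, x, y, value) table for topographic-map rendering."""
    values = np.asarray(values, dtype=float)
    if values.size != len(montage):
        raise ValueError("one value per montage channel required")
    return pd.DataFrame(
        {
            "channel": montage.channel_names,
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
            "value": values,
        }
    )
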