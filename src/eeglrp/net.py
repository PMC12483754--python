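"""Shallow convolutional two-class EEG decoder.

Architecture (FBCSP-inspired shallow ConvNet): a temporal convolution
applied per channel, a spatial convolution collapsing the channel axis,
ReLU, mean pooling over time, dropout, and a dense softmax readout.
Training is mini-batch Adam on the cross-entropy, with the parameter
snapshot of the best validation epoch retained.

The network is implemented directly on NumPy arrays with explicit forward
and backward passes; this keeps every intermediate activation addressable,
which the relevance-propagation engine (:mod:`eeglrp.lrp`) relies on.
Training math runs in float32.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import train_test_split

from .config import NetSpec, RunConfig
from .preprocessing import SegmentSet


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class ShallowConvNet:
    """channels x samples -> 2 class scores.

    Parameters (Glorot-uniform init, zero biases, deterministic per seed):

    * ``Wt`` (F_t, K): temporal kernels shared across channels
    * ``Ws`` (F_s, C, F_t): spatial filters mixing channels and temporal maps
    * ``Wd`` (2, F_s * P): dense readout over pooled features
    """

    def __init__(self, n_channels: int, n_samples: int, spec: NetSpec, seed: int = 0):
        if n_channels < 1 or n_samples < 1:
            raise ValueError("input dimensions must be positive")
        if spec.temporal_kernel >= n_samples:
            raise ValueError(
                f"temporal kernel {spec.temporal_kernel} must be shorter than "
                f"the input ({n_samples} samples)"
            )
        self.spec = spec
        self.n_channels = n_channels
        self.n_samples = n_samples
        self.t_conv = n_samples - spec.temporal_kernel + 1
        if spec.pool_length > self.t_conv:
            raise ValueError(
                f"pool length {spec.pool_length} exceeds the post-convolution "
                f"feature length {self.t_conv} "
                f"(input {n_samples}, kernel {spec.temporal_kernel})"
            )
        self.n_pool = (self.t_conv - spec.pool_length) // spec.pool_stride + 1

        rng = np.random.default_rng(seed)
        ft, fs, k = spec.n_temporal_filters, spec.n_spatial_filters, spec.temporal_kernel

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape).astype(np.float32)

        self.params = {
            "Wt": glorot((ft, k), k, ft),
            "bt": np.zeros(ft, dtype=np.float32),
            "Ws": glorot((fs, n_channels, ft), n_channels * ft, fs),
            "bs": np.zeros(fs, dtype=np.float32),
            "Wd": glorot((2, fs * self.n_pool), fs * self.n_pool, 2),
            "bd": np.zeros(2, dtype=np.float32),
        }

    # -- forward -----------------------------------------------------------

    def forward(self, x, *, train: bool = False, dropout_rng=None, win=None) -> dict:
        """Forward pass for a batch ``x`` of shape (B, C, T).

        ``win`` may carry precomputed temporal windows (B, C, T', K) to avoid
        re-materialising them every step during training.

        Returns a cache of every intermediate (used by backward and LRP):
        ``h1`` (B, C, T', F_t) temporal-conv output, ``z2`` (B, F_s, T')
        spatial pre-activation, ``a2`` post-activation, ``pooled``,
        ``flat``, ``logits`` (B, 2).
        """
        p = self.params
        spec = self.spec
        x = np.ascontiguousarray(x)
        if x.ndim != 3 or x.shape[1:] != (self.n_channels, self.n_samples):
            raise ValueError(
                f"expected input (B, {self.n_channels}, {self.n_samples}), "
                f"got {x.shape}"
            )
        B = x.shape[0]
        if win is None:
            # windows laid out (B, T', C, K): the temporal conv is one GEMM
            # and its output lands directly in the spatial conv's layout
            win = np.ascontiguousarray(
                sliding_window_view(x, spec.temporal_kernel, axis=2).transpose(0, 2, 1, 3)
            )
        h1 = win @ p["Wt"].T + p["bt"]  # (B,T',C,F)
        ft, fs = spec.n_temporal_filters, spec.n_spatial_filters
        h1f = h1.reshape(B, self.t_conv, self.n_channels * ft)
        # spatial conv: sum over channels and temporal maps
        z2 = h1f @ p["Ws"].reshape(fs, -1).T + p["bs"]  # (B,T',Fs)
        if spec.activation == "relu":
            a2 = np.maximum(z2, 0.0)
        else:  # square_log variant of the reference architecture
            a2 = z2 * z2
        pw = sliding_window_view(a2, spec.pool_length, axis=1)  # B,P*,Fs,L
        pooled_raw = pw[:, :: spec.pool_stride].mean(axis=3)[:, : self.n_pool]  # B,P,Fs
        if spec.activation == "square_log":
            pooled = np.log(np.maximum(pooled_raw, 1e-6))
        else:
            pooled = pooled_raw
        flat = pooled.reshape(B, -1)  # index order (pool position, spatial filter)
        if train and spec.dropout > 0.0:
            if dropout_rng is None:
                raise ValueError("training forward pass needs a dropout rng")
            mask = (
                dropout_rng.random(flat.shape) >= spec.dropout
            ).astype(flat.dtype) / (1.0 - spec.dropout)
            flat = flat * mask
        else:
            mask = None
        logits = flat @ p["Wd"].T + p["bd"]
        return {
            "x": x, "win": win, "h1": h1, "z2": z2, "a2": a2,
            "pooled": pooled, "pooled_raw": pooled_raw, "mask": mask,
            "flat": flat, "logits": logits,
        }

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, dlogits) -> dict:
        """Gradients of the loss w.r.t. every parameter."""
        p, spec = self.params, self.spec
        B = cache["x"].shape[0]
        ft, fs = spec.n_temporal_filters, spec.n_spatial_filters
        grads = {}
        grads["Wd"] = dlogits.T @ cache["flat"]
        grads["bd"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["Wd"]
        if cache["mask"] is not None:
            dflat = dflat * cache["mask"]
        dpool = dflat.reshape(B, self.n_pool, fs)
        if spec.activation == "square_log":
            raw = cache["pooled_raw"]
            dpool = np.where(raw > 1e-6, dpool / np.maximum(raw, 1e-6), 0.0)
        da2 = np.zeros_like(cache["a2"])  # (B,T',Fs)
        L, S = spec.pool_length, spec.pool_stride
        for j in range(self.n_pool):
            da2[:, j * S : j * S + L] += dpool[:, j : j + 1] / L
        if spec.activation == "relu":
            dz2 = da2 * (cache["z2"] > 0)  # (B,T',Fs)
        else:
            dz2 = da2 * 2.0 * cache["z2"]
        grads["bs"] = dz2.sum(axis=(0, 1))
        h1f = cache["h1"].reshape(B * self.t_conv, self.n_channels * ft)
        dz2f = dz2.reshape(B * self.t_conv, fs)
        grads["Ws"] = (dz2f.T @ h1f).reshape(fs, self.n_channels, ft)
        dh1 = (dz2f @ p["Ws"].reshape(fs, -1)).reshape(B, self.t_conv, self.n_channels, ft)
        grads["bt"] = dh1.sum(axis=(0, 1, 2))
        win = cache["win"]  # (B,T',C,K)
        grads["Wt"] = (
            dh1.reshape(-1, ft).T @ win.reshape(-1, spec.temporal_kernel)
        )
        return grads

    def logits(self, x) -> np.ndarray:
        """Evaluation-mode class scores for a batch (B, C, T)."""
        return self.forward(np.asarray(x, dtype=np.float32))["logits"]

    def snapshot(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, params: dict) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


def build_model(
    n_channels: int, n_samples: int, spec: NetSpec, seed: int = 0
) -> ShallowConvNet:
    """Construct a shallow ConvNet for the given input geometry."""
    return ShallowConvNet(n_channels, n_samples, spec, seed)


def softmax(logits) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# standardisation (training-set statistics only, to avoid leakage)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Standardizer:
    """Per-channel z-scoring with statistics from the training set."""

    mean: np.ndarray  # (C,)
    std: np.ndarray  # (C,)

    @classmethod
    def fit(cls, examples) -> "Standardizer":
        stacked = np.concatenate([x for x, _ in examples], axis=1)
        mean = stacked.mean(axis=1)
        std = stacked.std(axis=1)
        return cls(mean=mean, std=np.where(std > 1e-12, std, 1.0))

    def transform(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=np.float32) - self.mean[:, None].astype(np.float32)) / self.std[
            :, None
        ].astype(np.float32)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_acc: float
    val_loss: float
    val_acc: float


@dataclass
class TrainedModel:
    """A trained network plus everything needed to apply it to new data."""

    model: ShallowConvNet
    standardizer: Standardizer
    channel_names: tuple[str, ...]
    best_epoch: int
    log: list[EpochRecord] = field(repr=False, default_factory=list)

    def predict_proba(self, x) -> np.ndarray:
        """Softmax probabilities for one standardised-on-entry input (C, T)."""
        xs = self.standardizer.transform(x)
        return softmax(self.model.logits(xs[None]))[0]


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )


def _eval(model: ShallowConvNet, X, y, win=None) -> tuple[float, float]:
    """Mean cross-entropy and accuracy in evaluation mode."""
    losses, correct = [], 0
    for i in range(0, len(X), 16):
        xb, yb = X[i : i + 16], y[i : i + 16]
        wb = None if win is None else win[i : i + 16]
        probs = softmax(model.forward(xb, win=wb)["logits"])
        losses.extend(-np.log(np.maximum(probs[np.arange(len(yb)), yb], 1e-12)))
        correct += int((probs.argmax(axis=1) == yb).sum())
    return float(np.mean(losses)), correct / len(y)


#: training caches precomputed temporal windows up to this many bytes
_WINDOW_CACHE_BYTES = 600_000_000


def _maybe_cache_windows(X: np.ndarray, kernel: int):
    n, c, t = X.shape
    nbytes = n * c * (t - kernel + 1) * kernel * 4
    if nbytes > _WINDOW_CACHE_BYTES:
        return None
    return np.ascontiguousarray(
        sliding_window_view(X, kernel, axis=2).transpose(0, 2, 1, 3)
    )


def train(
    model: ShallowConvNet,
    train_examples,
    val_examples,
    config: RunConfig,
    *,
    seed: int = 0,
) -> tuple[ShallowConvNet, list[EpochRecord], int]:
    """Mini-batch Adam training with best-validation-epoch snapshotting.

    ``train_examples``/``val_examples`` are lists of ``(x, y)`` with ``x``
    already standardised, shape (C, T).  Returns the model restored to the
    snapshot with the highest validation accuracy (ties: lowest validation
    loss, then earliest epoch), the per-epoch log, and the best epoch index.
    """
    if not train_examples or not val_examples:
        raise ValueError("training and validation sets must be non-empty")
    ys = {y for _, y in train_examples}
    if ys != {0, 1}:
        raise ValueError(f"training set must contain both classes, found {sorted(ys)}")

    Xtr = np.stack([x for x, _ in train_examples]).astype(np.float32)
    ytr = np.array([y for _, y in train_examples], dtype=int)
    Xva = np.stack([x for x, _ in val_examples]).astype(np.float32)
    yva = np.array([y for _, y in val_examples], dtype=int)

    rng = np.random.default_rng(seed)
    opt = _Adam(model.params, config.learning_rate)
    log: list[EpochRecord] = []
    best = None  # (acc, -loss, -epoch) maximised
    best_params = model.snapshot()
    best_epoch = 0
    win_tr = _maybe_cache_windows(Xtr, model.spec.temporal_kernel)
    win_va = _maybe_cache_windows(Xva, model.spec.temporal_kernel)

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(Xtr))
        ep_losses, ep_correct = [], 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            wb = None if win_tr is None else win_tr[idx]
            cache = model.forward(xb, train=True, dropout_rng=rng, win=wb)
            probs = softmax(cache["logits"])
            ep_losses.extend(
                -np.log(np.maximum(probs[np.arange(len(yb)), yb], 1e-12))
            )
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = (probs - np.eye(2)[yb]) / len(yb)
            grads = model.backward(cache, dlogits.astype(np.float32))
            opt.step(model.params, grads)
        val_loss, val_acc = _eval(model, Xva, yva, win_va)
        log.append(
            EpochRecord(
                epoch=epoch,
                train_loss=float(np.mean(ep_losses)),
                train_acc=ep_correct / len(ytr),
                val_loss=val_loss,
                val_acc=val_acc,
            )
        )
        key = (val_acc, -val_loss, -epoch)
        if best is None or key > best:
            best = key
            best_params = model.snapshot()
            best_epoch = epoch
    model.restore(best_params)
    return model, log, best_epoch


# ---------------------------------------------------------------------------
# subject-level prediction and leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldResult:
    """Outcome of one leave-one-out fold."""

    test_subject_id: str
    true_label: int
    predicted_label: int
    class_probabilities: tuple[float, float]
    train_subject_ids: tuple[str, ...]
    val_subject_ids: tuple[str, ...]
    selected_channels: tuple[str, ...] | None = None
    model: TrainedModel | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class CohortMetrics:
    """Subject-level LOOCV metrics, in percent."""

    accuracy: float
    sensitivity: float  # recall on the patient class (label 1)
    specificity: float  # recall on the control class (label 0)
    tp: int
    tn: int
    fp: int
    fn: int

    @classmethod
    def from_folds(cls, folds) -> "CohortMetrics":
        tp = sum(1 for f in folds if f.true_label == 1 and f.predicted_label == 1)
        fn = sum(1 for f in folds if f.true_label == 1 and f.predicted_label == 0)
        tn = sum(1 for f in folds if f.true_label == 0 and f.predicted_label == 0)
        fp = sum(1 for f in folds if f.true_label == 0 and f.predicted_label == 1)
        n = tp + tn + fp + fn
        return cls(
            accuracy=100.0 * (tp + tn) / n if n else float("nan"),
            sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
            specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
            tp=tp, tn=tn, fp=fp, fn=fn,
        )


def predict_subject(trained: TrainedModel, segments: SegmentSet) -> tuple[int, np.ndarray]:
    """Average per-segment softmax probabilities; argmax is the prediction."""
    if segments.n_segments == 0:
        raise ValueError("empty segment set")
    probs = np.mean([trained.predict_proba(s) for s in segments.segments], axis=0)
    return int(probs.argmax()), probs


def subject_seed(global_seed: int, subject_id: str) -> int:
    """Stable per-subject seed, independent of cohort ordering."""
    return (int(global_seed) * 1000003 + zlib.crc32(subject_id.encode())) % (2**31)


def split_train_val(
    subject_ids, labels, val_fraction: float, seed: int, max_retries: int = 5
):
    """Stratified train/validation split of fold-remainder subjects (4:1)."""
    for attempt in range(max_retries):
        tr, va = train_test_split(
            list(subject_ids),
            test_size=val_fraction,
            stratify=list(labels),
            random_state=(seed + attempt) % (2**32 - 1),
        )
        labs = dict(zip(subject_ids, labels))
        if {labs[s] for s in tr} == {0, 1} and {labs[s] for s in va} == {0, 1}:
            return tuple(tr), tuple(va)
    raise ValueError("could not produce a split with both classes on both sides")


def _fit_fold(
    segment_sets: dict[str, SegmentSet],
    train_ids,
    val_ids,
    channel_names,
    channel_idx,
    config: RunConfig,
    net_spec: NetSpec,
    seed: int,
) -> TrainedModel:
    def examples(ids):
        out = []
        for sid in ids:
            ss = segment_sets[sid]
            for seg in ss.segments:
                out.append((seg[channel_idx], ss.label))
        return out

    train_ex = examples(train_ids)
    val_ex = examples(val_ids)
    scaler = Standardizer.fit(train_ex)
    train_ex = [(scaler.transform(x), y) for x, y in train_ex]
    val_ex = [(scaler.transform(x), y) for x, y in val_ex]
    n_samples = train_ex[0][0].shape[1]
    model = build_model(len(channel_idx), n_samples, net_spec, seed=seed)
    model, log, best_epoch = train(model, train_ex, val_ex, config, seed=seed)
    return TrainedModel(
        model=model,
        standardizer=scaler,
        channel_names=tuple(channel_names),
        best_epoch=best_epoch,
        log=log,
    )


def loocv(
    segment_sets: list[SegmentSet],
    montage,
    config: RunConfig,
    *,
    channel_subset=None,
    net_spec: NetSpec | None = None,
    keep_models: bool = False,
) -> tuple[list[FoldResult], CohortMetrics]:
    """Subject-wise leave-one-out cross-validation.

    Every subject is the test case exactly once; the N-1 remainder is split
    4:1 (stratified, seeded per test subject) into training and validation
    sets.  No segment of the test subject enters training or validation.
    """
    by_id = {ss.subject_id: ss for ss in segment_sets}
    if len(by_id) != len(segment_sets):
        raise ValueError("duplicate subject ids in cohort")
    labels = {sid: ss.label for sid, ss in by_id.items()}
    for sid, lab in labels.items():
        if lab not in (0, 1):
            raise ValueError(f"subject {sid} has no class label")
    counts = [sum(1 for l in labels.values() if l == c) for c in (0, 1)]
    if min(counts) < 3:
        raise ValueError("LOOCV needs at least 3 subjects per class")

    net_spec = net_spec if net_spec is not None else config.net_spec()
    if channel_subset is None:
        channel_names = tuple(montage.channel_names)
    else:
        channel_names = tuple(channel_subset)
    channel_idx = montage.indices(channel_names)

    folds = []
    for test_id in sorted(by_id):  # sorted: order-independent results
        seed = subject_seed(config.seed, test_id)
        rest = [s for s in sorted(by_id) if s != test_id]
        train_ids, val_ids = split_train_val(
            rest, [labels[s] for s in rest], config.val_fraction, seed
        )
        trained = _fit_fold(
            by_id, train_ids, val_ids, channel_names, channel_idx,
            config, net_spec, seed,
        )
        test_ss = by_id[test_id].pick_channel_indices(channel_idx)
        pred, probs = predict_subject(trained, test_ss)
        folds.append(
            FoldResult(
                test_subject_id=test_id,
                true_label=labels[test_id],
                predicted_label=pred,
                class_probabilities=(float(probs[0]), float(probs[1])),
                train_subject_ids=train_ids,
                val_subject_ids=val_ids,
                selected_channels=None if channel_subset is None else channel_names,
                model=trained if keep_models else None,
            )
        )
    return folds, CohortMetrics.from_folds(folds)
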