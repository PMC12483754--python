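"""Layer-wise relevance propagation through the shallow ConvNet.

The predicted (or requested) class's pre-softmax score is decomposed into
per-input relevance by propagating backwards through the network with the
epsilon-stabilised proportional rule:

    R_i = sum_j  (w_ij x_i) / (z_j + eps * sign(z_j))  R_j,
    z_j = sum_i w_ij x_i + b_j

at dense and convolutional layers, with ``eps`` scaled to the layer
(``epsilon * mean |z_j|``).  Mean pooling redistributes relevance equally
over its window; ReLU and dropout are pass-throughs.  Relevance absorbed by
bias terms and the stabiliser is tracked per layer as a "leak" so the
conservation audit is exact: at every layer,
``sum(R) + leak_above == output score`` up to floating-point error.

Relevance is signed end-to-end; consumers take absolute values only where
they explicitly say so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .net import ShallowConvNet, TrainedModel


@dataclass(frozen=True)
class RelevanceMap:
    """Per-input relevance for one subject/segment.

    ``layer_totals`` records ``sum(R)`` after propagating through each layer
    (outermost first); ``layer_leaks`` the relevance absorbed by biases and
    the epsilon stabiliser at that layer.
    """

    subject_id: str
    relevance: np.ndarray  # (n_channels, n_samples), signed
    target_class: int
    output_score: float
    layer_totals: tuple[tuple[str, float], ...]
    layer_leaks: tuple[tuple[str, float], ...]

    @property
    def total_leak(self) -> float:
        return float(sum(v for _, v in self.layer_leaks))


def _stabilised(z, epsilon: float):
    """Denominator z + eps*sign(z) with eps scaled to the layer's mean |z|."""
    eps = epsilon * np.mean(np.abs(z))
    if eps == 0.0:
        eps = np.finfo(float).tiny
    return z + eps * np.where(z >= 0, 1.0, -1.0)


def linear_relevance(w, x, R_out: float, *, bias: float = 0.0, epsilon: float = 1e-6):
    """Epsilon rule for a single linear unit y = w.x + b.

    Returns the per-input relevance; as epsilon -> 0 and with zero bias this
    is exactly the decomposition R_i = w_i x_i scaled to R_out / y.
    """
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    z = float(w @ x + bias)
    denom = float(_stabilised(np.array(z), epsilon))
    return (w * x) / denom * R_out


def lrp_relevance(
    model: ShallowConvNet,
    x,
    target_class: int,
    epsilon: float = 1e-6,
    *,
    subject_id: str = "",
) -> RelevanceMap:
    """Decompose the target class's pre-softmax score into input relevance."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 or 1")
    if model.spec.activation != "relu":
        raise NotImplementedError("LRP is defined here for the ReLU variant")
    p64 = {k: v.astype(np.float64) for k, v in model.params.items()}
    for k, v in p64.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"model parameter {k!r} contains non-finite values")

    x = np.asarray(x, dtype=np.float64)
    cache = _forward64(model, p64, x)
    score = float(cache["logits"][target_class])

    totals: list[tuple[str, float]] = []
    leaks: list[tuple[str, float]] = []
    if abs(score) <= 1e-12:
        zero = np.zeros_like(x)
        return RelevanceMap(subject_id, zero, target_class, score, (), ())

    spec = model.spec

    # dense readout: single output unit carries the score
    R_flat = linear_relevance(
        p64["Wd"][target_class],
        cache["flat"],
        score,
        bias=float(p64["bd"][target_class]),
        epsilon=epsilon,
    )
    totals.append(("dense", float(R_flat.sum())))
    leaks.append(("dense", score - float(R_flat.sum())))

    # dropout: identity at propagation (evaluation mode)
    R_pool = R_flat.reshape(model.n_pool, spec.n_spatial_filters)

    # mean pooling: the epsilon rule applied to the pool seen as a linear
    # layer (weights 1/L): each window member receives relevance in
    # proportion to its activation, so ReLU-silenced units receive none
    R_a2 = np.zeros_like(cache["a2"])  # (T', Fs)
    L, S = spec.pool_length, spec.pool_stride
    denom_pool = _stabilised(cache["pooled"], epsilon)  # (P, Fs)
    ratio = R_pool / denom_pool
    a2 = cache["a2"]
    for j in range(model.n_pool):
        R_a2[j * S : j * S + L] += (a2[j * S : j * S + L] / L) * ratio[j : j + 1]
    totals.append(("pool", float(R_a2.sum())))
    leaks.append(("pool", float(R_pool.sum() - R_a2.sum())))

    # ReLU: pass-through
    R_z2 = R_a2

    # spatial convolution
    z2 = cache["z2"]  # (T', Fs)
    s = R_z2 / _stabilised(z2, epsilon)
    Ws_flat = p64["Ws"].reshape(spec.n_spatial_filters, -1)  # (Fs, C*Ft)
    h1_flat = cache["h1"].reshape(model.t_conv, -1)  # (T', C*Ft)
    R_h1 = (h1_flat * (s @ Ws_flat)).reshape(
        model.t_conv, model.n_channels, spec.n_temporal_filters
    )
    totals.append(("spatial_conv", float(R_h1.sum())))
    leaks.append(("spatial_conv", float(R_z2.sum() - R_h1.sum())))

    # temporal convolution, back to the input
    h1 = cache["h1"].transpose(1, 0, 2)  # (C, T', Ft)
    R_h1 = R_h1.transpose(1, 0, 2)
    s1 = R_h1 / _stabilised(h1, epsilon)
    tmp = s1 @ p64["Wt"]  # (C, T', K)
    R_x = np.zeros_like(x)
    K = spec.temporal_kernel
    Tc = model.t_conv
    for k in range(K):
        R_x[:, k : k + Tc] += x[:, k : k + Tc] * tmp[:, :, k]
    totals.append(("temporal_conv", float(R_x.sum())))
    leaks.append(("temporal_conv", float(R_h1.sum() - R_x.sum())))

    return RelevanceMap(
        subject_id=subject_id,
        relevance=R_x,
        target_class=target_class,
        output_score=score,
        layer_totals=tuple(totals),
        layer_leaks=tuple(leaks),
    )


def _forward64(model: ShallowConvNet, p64: dict, x: np.ndarray) -> dict:
    """Evaluation-mode forward pass in float64 for a single input (C, T)."""
    from numpy.lib.stride_tricks import sliding_window_view

    spec = model.spec
    if x.shape != (model.n_channels, model.n_samples):
        raise ValueError(
            f"expected input ({model.n_channels}, {model.n_samples}), got {x.shape}"
        )
    win = np.ascontiguousarray(
        sliding_window_view(x, spec.temporal_kernel, axis=1).transpose(1, 0, 2)
    )  # (T',C,K), matching the training forward's layout
    h1 = win @ p64["Wt"].T + p64["bt"]  # (T',C,Ft)
    z2 = (
        h1.reshape(model.t_conv, -1) @ p64["Ws"].reshape(spec.n_spatial_filters, -1).T
        + p64["bs"]
    )  # (T', Fs)
    a2 = np.maximum(z2, 0.0)
    pw = sliding_window_view(a2, spec.pool_length, axis=0)  # P*,Fs,L
    pooled = pw[:: spec.pool_stride].mean(axis=2)[: model.n_pool]  # (P, Fs)
    flat = pooled.reshape(-1)
    logits = p64["Wd"] @ flat + p64["bd"]
    return {"h1": h1, "z2": z2, "a2": a2, "pooled": pooled, "flat": flat, "logits": logits}


def conservation_error(rmap: RelevanceMap) -> float:
    """Worst relative conservation violation over the audited layers.

    At each layer, ``sum(R at that layer) + leak absorbed above`` must equal
    the propagated output score.
    """
    if abs(rmap.output_score) <= 1e-12:
        return 0.0
    worst = 0.0
    leak_above = 0.0
    for (name, total), (_, leak) in zip(rmap.layer_totals, rmap.layer_leaks):
        leak_above += leak
        err = abs(total + leak_above - rmap.output_score) / abs(rmap.output_score)
        worst = max(worst, err)
    return worst


def channel_relevance(rmap: RelevanceMap) -> np.ndarray:
    """Per-channel relevance: arithmetic mean over the time axis."""
    return rmap.relevance.mean(axis=1)


def relevance_to_csv(rmap: RelevanceMap, channel_names, path) -> None:
    """Write a channels x time relevance map as CSV, channels as row labels."""
    import pandas as pd

    if len(channel_names) != rmap.relevance.shape[0]:
        raise ValueError("one channel name per relevance row required")
    pd.DataFrame(rmap.relevance, index=list(channel_names)).to_csv(path)


def subject_relevance(
    trained: TrainedModel,
    x,
    *,
    target_class: int | None = None,
    epsilon: float = 1e-6,
    subject_id: str = "",
) -> RelevanceMap:
    """Relevance for one raw (unstandardised) input through a trained model.

    Propagates the predicted class's score unless ``target_class`` is given.
    """
    xs = trained.standardizer.transform(x).astype(np.float64)
    if target_class is None:
        target_class = int(trained.model.logits(xs[None])[0].argmax())
    return lrp_relevance(
        trained.model, xs, target_class, epsilon, subject_id=subject_id
    )
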