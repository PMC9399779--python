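"""Stacked generalization over scales with per-finding softmax weights.

For finding ``f`` and scale ``s`` the ensemble weight is

    w_fs = exp(V_fs) / sum_s' exp(V_fs')

so each finding's weights are nonnegative and sum to one; V = 0 gives
uniform weights. The ensemble probability of finding ``f`` on image ``x_i``
is the convex combination of the per-scale sigmoid probabilities,

    PL_f(x_i) = sum_s w_fs * sigmoid(logit_fs(x_i)),

each finding handled independently. V is fit on validation logits by
minibatch gradient descent on mean binary cross-entropy, 100 epochs,
initial learning rate 0.1 with exponential decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import ProbTensor
from .nn import sigmoid

__all__ = ["StackingParams", "softmax_weights", "ensemble_predict",
           "train_stacking", "weight_report"]


def softmax_weights(V: np.ndarray) -> np.ndarray:
    """Row-wise softmax of the raw parameter matrix (findings x scales).

    Numerically stabilized by max subtraction; rejects non-finite input.
    """
    v = np.asarray(V, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("V must contain only finite entries")
    shifted = v - v.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class StackingParams:
    """Raw parameters V and (always re-derived) softmax image W."""

    V: np.ndarray  # (F, S)
    findings: list[str]
    scales: list[int]

    @property
    def W(self) -> np.ndarray:
        return softmax_weights(self.V)

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps({
            "findings": self.findings,
            "scales": self.scales,
            "V": self.V.tolist(),
            "W": self.W.tolist(),
        }, indent=2))


def ensemble_predict(
    W: np.ndarray, probs: ProbTensor, combine: str = "mean_of_sigmoids"
) -> np.ndarray:
    """Per-image, per-finding ensemble probability.

    ``combine='mean_of_sigmoids'`` (default) takes the w-weighted convex
    combination of per-scale probabilities; ``'sigmoid_of_mean'`` is the
    alternative reading (sigmoid of the weighted logits), kept behind this
    flag for comparison.
    """
    w = np.asarray(W, dtype=np.float64)
    if w.shape != (len(probs.findings), len(probs.scales)):
        raise ValueError(f"W shape {w.shape} does not match probs "
                         f"({len(probs.findings)} findings x {len(probs.scales)} scales)")
    if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("W rows must sum to 1")
    if combine == "mean_of_sigmoids":
        return np.einsum("fs,nfs->nf", w, probs.probabilities)
    if combine == "sigmoid_of_mean":
        return sigmoid(np.einsum("fs,nfs->nf", w, probs.logits))
    raise ValueError(f"unknown combine mode {combine!r}")


def train_stacking(
    val_probs: ProbTensor,
    labels: np.ndarray,
    epochs: int = 100,
    lr0: float = 0.1,
    decay: float = 0.995,
    batch_size: int = 8,
    seed: int = 0,
    combine: str = "mean_of_sigmoids",
) -> tuple[StackingParams, pd.DataFrame]:
    """Fit V on validation logits by minibatch gradient descent.

    100 epochs over the validation set in shuffled minibatches, learning
    rate lr0 * decay^epoch. V starts at zeros (uniform weights); every
    finding is fit independently — gradients average over the batch's
    images only, so the finding count does not dilute the step size.
    Deterministic under ``seed`` (which drives the shuffling). Returns the
    fitted parameters and a per-epoch log (epoch, lr, bce on the full set).
    """
    y = np.asarray(labels, dtype=np.float64)
    n, f_count, s_count = val_probs.logits.shape
    if y.shape != (n, f_count):
        raise ValueError(f"labels shape {y.shape} != ({n}, {f_count})")
    p = val_probs.probabilities  # (N, F, S), constant during stacking
    logits = val_probs.logits
    V = np.zeros((f_count, s_count), dtype=np.float64)
    eps = 1e-12
    rng = np.random.default_rng(seed)
    rows = []

    def full_bce(W: np.ndarray) -> float:
        if combine == "mean_of_sigmoids":
            ens = np.einsum("fs,nfs->nf", W, p)
        else:
            ens = sigmoid(np.einsum("fs,nfs->nf", W, logits))
        return float(-np.mean(y * np.log(ens + eps)
                              + (1 - y) * np.log(1 - ens + eps)))

    for epoch in range(epochs):
        lr = lr0 * decay**epoch
        rows.append({"epoch": epoch, "lr": lr, "bce": full_bce(softmax_weights(V))})
        order = rng.permutation(n)
        for k in range(0, n, batch_size):
            idx = order[k : k + batch_size]
            W = softmax_weights(V)
            if combine == "mean_of_sigmoids":
                ens = np.einsum("fs,nfs->nf", W, p[idx])
                dens = (ens - y[idx]) / np.maximum(ens * (1 - ens), eps) / idx.size
                dW = np.einsum("nf,nfs->fs", dens, p[idx])
            else:
                ens = sigmoid(np.einsum("fs,nfs->nf", W, logits[idx]))
                dz = (ens - y[idx]) / idx.size
                dW = np.einsum("nf,nfs->fs", dz, logits[idx])
            # softmax Jacobian: dV = W * (dW - sum_s W*dW)
            dV = W * (dW - (W * dW).sum(axis=1, keepdims=True))
            V -= lr * dV
    params = StackingParams(V=V, findings=list(val_probs.findings),
                            scales=list(val_probs.scales))
    log = pd.DataFrame(rows)
    log.loc[len(log)] = {"epoch": epochs, "lr": 0.0,
                         "bce": full_bce(softmax_weights(V))}
    return params, log


def weight_report(W: np.ndarray, findings: list[str] | None = None,
                  scales: list[int] | None = None) -> pd.DataFrame:
    """Express each finding's weights as percentages totaling exactly 100.0.

    Largest-remainder rounding at one decimal: each row is floored to tenths
    of a percent and the leftover tenths go to the largest remainders, so the
    printed row always sums to 100.0.
    """
    w = np.asarray(W, dtype=np.float64)
    if w.ndim != 2 or not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("W must be a row-stochastic matrix")
    f_count, s_count = w.shape
    findings = findings or [f"finding_{i}" for i in range(f_count)]
    scales = scales or list(range(s_count))
    rows = []
    for i in range(f_count):
        tenths = w[i] * 1000.0
        base = np.floor(tenths).astype(np.int64)
        short = 1000 - int(base.sum())
        order = np.argsort(-(tenths - base), kind="stable")
        base[order[:short]] += 1
        rows.append({"finding": findings[i],
                     **{str(s): base[j] / 10.0 for j, s in enumerate(scales)}})
    return pd.DataFrame(rows)
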