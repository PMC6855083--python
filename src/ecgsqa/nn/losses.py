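"""Classification losses on softmax output probabilities.

The default training loss sums an independent Bernoulli cross-entropy term
over every output class,

    loss_i = - sum_j [ y_ij * log p_ij + (1 - y_ij) * log(1 - p_ij) ],

penalizing both a low probability on the true class and residual mass on
the wrong classes.  The familiar categorical cross-entropy (the y*log p
term alone) is provided as an alternative.  Both return the minibatch-mean
loss and the gradient with respect to the probabilities, to be chained
through a Softmax layer's backward pass.
"""

from __future__ import annotations

import numpy as np

_CLIP = 1e-12


def bernoulli_sum_loss(probs: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Summed per-class Bernoulli cross-entropy.

    Parameters
    ----------
    probs:
        (N, K) softmax outputs.
    targets:
        (N, K) one-hot true labels.

    Returns
    -------
    (mean loss over the minibatch, dL/dprobs of the mean loss)
    """
    if probs.shape != targets.shape:
        raise ValueError("probs and targets must share a shape")
    # clip in float64: 1 - 1e-12 is unrepresentable in float32
    p = np.clip(probs.astype(np.float64), _CLIP, 1.0 - _CLIP)
    t = targets.astype(np.float64)
    n = p.shape[0]
    loss = -(t * np.log(p) + (1.0 - t) * np.log1p(-p)).sum() / n
    dp = (-t / p + (1.0 - t) / (1.0 - p)) / n
    return float(loss), dp.astype(probs.dtype)


def categorical_cross_entropy_loss(
    probs: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Standard categorical cross-entropy, -sum_j y_ij log p_ij."""
    if probs.shape != targets.shape:
        raise ValueError("probs and targets must share a shape")
    p = np.clip(probs.astype(np.float64), _CLIP, 1.0 - _CLIP)
    t = targets.astype(np.float64)
    n = p.shape[0]
    loss = -(t * np.log(p)).sum() / n
    dp = (-t / p) / n
    return float(loss), dp.astype(probs.dtype)


def bernoulli_sum_loss_fused(probs: np.ndarray, targets: np.ndarray
                             ) -> tuple[float, np.ndarray]:
    """Summed Bernoulli loss with its gradient taken directly in the
    softmax pre-activations (logits).

    The chained form dL/dp -> softmax Jacobian is numerically fragile once
    a probability saturates (an unbounded 1/(1-p) term multiplied by a
    vanishing p); writing dL/dz_k = a_k - p_k * sum_j a_j with
    a_j = -y_j + (1 - y_j) * p_j / (1 - p_j) cancels the large terms
    exactly, so confidently-wrong predictions keep a finite, non-zero
    gradient.  Use with the model's ``from_logits`` backward path.
    """
    if probs.shape != targets.shape:
        raise ValueError("probs and targets must share a shape")
    p = probs.astype(np.float64)
    t = targets.astype(np.float64)
    n = p.shape[0]
    pc = np.clip(p, _CLIP, 1.0 - _CLIP)
    loss = -(t * np.log(pc) + (1.0 - t) * np.log1p(-pc)).sum() / n
    r = p / np.maximum(1.0 - p, _CLIP)
    a = -t + (1.0 - t) * r
    dz = (a - p * a.sum(axis=-1, keepdims=True)) / n
    return float(loss), dz.astype(probs.dtype)


def categorical_cross_entropy_loss_fused(probs: np.ndarray, targets: np.ndarray
                                         ) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy with the classic fused gradient p - y."""
    if probs.shape != targets.shape:
        raise ValueError("probs and targets must share a shape")
    p = probs.astype(np.float64)
    t = targets.astype(np.float64)
    n = p.shape[0]
    pc = np.clip(p, _CLIP, 1.0 - _CLIP)
    loss = -(t * np.log(pc)).sum() / n
    dz = (p - t) / n
    return float(loss), dz.astype(probs.dtype)
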