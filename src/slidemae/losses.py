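"""Restoration loss, Cox partial likelihood, and slide-level metrics.

The pretext restoration loss for a pooled batch of k masked patches mixes a
squared-L2 reconstruction term with a contrastive InfoNCE term::

    L_i = alpha * ||x_i - y_i||^2 + beta * l(x_i, y_i)
    l(x_i, y_i) = -log [ exp(-||x_i - y_i||^2 / tau)
                         / sum_j exp(-||x_j - y_i||^2 / tau) ]

where x are the original (unmasked) patch features, y the transformer
outputs at the masked positions, and the pool runs over all masked
foreground patches of the whole batch regardless of region or slide.  The
contrastive softmax uses *negated* squared distances as logits, so a small
positive-pair distance maximises the softmax probability; tau defaults to
0.1.  The loss reduces by the arithmetic mean over the pool.

Survival fine-tuning minimises the negative log Cox partial likelihood with
Breslow handling of ties; evaluation uses Harrell's concordance index and,
for classification, the macro-averaged one-vs-rest AUC.

Functions suffixed ``_t`` are the differentiable (autodiff Tensor)
counterparts used inside the training loops; the plain functions are the
numpy reference surface.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

from .nn import Tensor

__all__ = [
    "concordance_index",
    "cox_loss",
    "cox_loss_t",
    "cross_entropy_t",
    "infonce_term",
    "macro_auc",
    "restoration_loss",
    "restoration_loss_t",
]

DEFAULT_TAU = 0.1
DEFAULT_ALPHA = 2.0
DEFAULT_BETA = 1.0


def _pair_sq_dists(targets: np.ndarray, outputs: np.ndarray) -> np.ndarray:
    """D[i, j] = ||x_j - y_i||^2 for target rows x and output rows y."""
    diff = outputs[:, None, :] - targets[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def infonce_term(
    i: int,
    targets: np.ndarray,
    outputs: np.ndarray,
    tau: float = DEFAULT_TAU,
) -> float:
    """Contrastive term for pool entry ``i``.

    ``targets``/``outputs`` are the k x d pooled matrices (x and y rows in
    correspondence).  Non-negative; exactly 0 for a pool of one.
    """
    if tau <= 0:
        raise ValueError(f"temperature tau must be positive, got {tau}")
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    outputs = np.atleast_2d(np.asarray(outputs, dtype=np.float64))
    if targets.shape != outputs.shape or targets.shape[0] < 1:
        raise ValueError("targets and outputs must be matching non-empty k x d matrices")
    d_row = _pair_sq_dists(targets, outputs[i : i + 1])[0]  # ||x_j - y_i||^2 over j
    logits = -d_row / tau
    return float(logsumexp(logits) - logits[i])


def restoration_loss(
    targets: np.ndarray,
    outputs: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    tau: float = DEFAULT_TAU,
) -> float:
    """Mean of alpha * ||x_i - y_i||^2 + beta * InfoNCE over the pooled batch."""
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    outputs = np.atleast_2d(np.asarray(outputs, dtype=np.float64))
    if targets.shape[0] == 0:
        raise ValueError("empty restoration pool: mask plan produced no masked foreground patch")
    if targets.shape != outputs.shape:
        raise ValueError("targets and outputs must have matching shapes")
    if tau <= 0:
        raise ValueError(f"temperature tau must be positive, got {tau}")
    D = _pair_sq_dists(targets, outputs)  # (k, k): D[i, j] = ||x_j - y_i||^2
    pos = np.diag(D)
    logits = -D / tau
    nce = logsumexp(logits, axis=1) - np.diag(logits)
    return float(np.mean(alpha * pos + beta * nce))


def restoration_loss_t(
    targets: np.ndarray,
    outputs: Tensor,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    tau: float = DEFAULT_TAU,
) -> Tensor:
    """Differentiable restoration loss; gradients flow into ``outputs`` only."""
    targets = np.asarray(targets, dtype=np.float64)
    k, d = targets.shape
    if k == 0:
        raise ValueError("empty restoration pool: mask plan produced no masked foreground patch")
    xsq = (targets**2).sum(axis=1)  # (k,)
    ysq = (outputs * outputs).sum(axis=1, keepdims=True)  # (k, 1)
    cross = outputs @ Tensor(targets.T)  # (k, k): y_i . x_j
    D = ysq + Tensor(xsq[None, :]) - 2.0 * cross  # D[i, j] = ||x_j - y_i||^2
    eye = np.eye(k)
    pos = (D * Tensor(eye)).sum(axis=1)  # (k,) diagonal
    logits = D * (-1.0 / tau)
    m = logits.data.max(axis=1, keepdims=True)  # constant shift for stability
    lse = (logits - Tensor(m)).exp().sum(axis=1).log() + Tensor(m[:, 0])
    nce = lse - (logits * Tensor(eye)).sum(axis=1)
    return (pos * alpha + nce * beta).mean()


def cox_loss(risks: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Negative log Cox partial likelihood, averaged over events.

    The risk set of subject i is everyone still under observation at T_i,
    i.e. {j : T_j >= T_i}; tied event times share the same denominator
    (Breslow).  Censored subjects enter only through risk sets.
    """
    risks = np.asarray(risks, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events)
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    event_idx = np.flatnonzero(events == 1)
    if len(event_idx) == 0:
        raise ValueError("no events in batch: Cox partial likelihood undefined")
    total = 0.0
    for i in event_idx:
        in_risk = times >= times[i]
        total += risks[i] - logsumexp(risks[in_risk])
    return float(-total / len(event_idx))


def cox_loss_t(risks: Tensor, times: np.ndarray, events: np.ndarray) -> Tensor:
    """Differentiable Cox loss over a (N,) risk tensor."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events)
    n_events = int((events == 1).sum())
    if n_events == 0:
        raise ValueError("no events in batch: Cox partial likelihood undefined")
    risk_set = (times[None, :] >= times[:, None]).astype(np.float64)  # [i, j]
    m = float(risks.data.max())
    exp_shift = (risks - m).exp()  # (N,)
    denom = (Tensor(risk_set) @ exp_shift.reshape(-1, 1)).reshape(-1)  # (N,)
    log_denom = denom.log() + m
    event_w = (events == 1).astype(np.float64)
    contrib = (risks - log_denom) * Tensor(event_w)
    return -contrib.sum() / float(n_events)


def cross_entropy_t(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer labels under row logits."""
    labels = np.asarray(labels, dtype=np.int64)
    n, c = logits.shape
    m = logits.data.max(axis=1, keepdims=True)
    lse = (logits - Tensor(m)).exp().sum(axis=1).log() + Tensor(m[:, 0])
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    picked = (logits * Tensor(onehot)).sum(axis=1)
    return (lse - picked).mean()


def concordance_index(risks: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Harrell's c-index: concordant comparable pairs, ties in risk as 1/2.

    A pair (i, j) is comparable when the earlier time belongs to an event;
    it is concordant when the earlier-failing subject has the higher
    predicted risk.
    """
    risks = np.asarray(risks, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    comparable = (events[:, None] == 1) & (times[:, None] < times[None, :])
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pair for the concordance index")
    higher = risks[:, None] > risks[None, :]
    tied = risks[:, None] == risks[None, :]
    conc = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(conc / n_comp)


def macro_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted mean of per-class one-vs-rest AUCs.

    Classes with a score column but no observed label are excluded with a
    warning; with two classes this is the plain binary AUC.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.ndim != 2:
        raise ValueError("scores must be an N x C matrix")
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("need at least two observed classes for an AUC")
    absent = sorted(set(range(scores.shape[1])) - set(present.tolist()))
    if absent:
        warnings.warn(f"classes {absent} absent from labels; excluded from macro AUC", stacklevel=2)
    aucs = [roc_auc_score((labels == c).astype(int), scores[:, c]) for c in present]
    return float(np.mean(aucs))
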