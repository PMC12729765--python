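"""Similarity matrices, soft target distributions, the bidirectional KL
contrastive objective, and prompt-ensemble classification.

For a minibatch of B video embeddings x and B text embeddings y (all unit
norm), S[i, j] = tau * <x_i, y_j>.  Row-softmax of S gives the video-to-text
similarity distribution p_x2y; row-softmax of S^T gives text-to-video
p_y2x.  The target q for row i is uniform over the batch entries sharing
row i's class label (soft targets: with small batches and two classes,
duplicated labels are the norm, so one-hot targets would be wrong).  The
loss is the mean over rows of KL(q || p), averaged over the two directions:

    L = 1/2 [ mean_i KL(q_x2y_i || p_x2y_i) + mean_j KL(q_y2x_j || p_y2x_j) ]

KL is taken with the target as the first argument so that (near) one-hot
targets give the familiar cross-entropy form and the loss stays finite; an
epsilon floor guards the logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax

EPS = 1e-8


@dataclass
class BatchSimilarity:
    S: Tensor  # (B, B) scaled similarities, rows = videos
    p_x2y: Tensor  # row-stochastic, rows = videos
    p_y2x: Tensor  # row-stochastic, rows = texts


@dataclass
class TargetDistribution:
    q_x2y: np.ndarray
    q_y2x: np.ndarray


def similarity_matrix(V: Tensor, T: Tensor, tau) -> BatchSimilarity:
    """Scaled cosine similarities with both softmax directions.

    V, T: (B, d_shared) with L2-normalized rows; tau: positive scalar
    (float or scalar Tensor, e.g. the exponential of a learnable log-scale).
    """
    for M, name in ((V, "video"), (T, "text")):
        norms = np.linalg.norm(M.data, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError(f"{name} embeddings are not L2-normalized")
    tau_t = tau if isinstance(tau, Tensor) else Tensor(np.array(float(tau)))
    if float(tau_t.data) <= 0:
        raise ValueError("tau must be positive")
    S = (V @ T.T) * tau_t
    return BatchSimilarity(S=S, p_x2y=softmax(S, axis=-1), p_y2x=softmax(S.T, axis=-1))


def target_distribution(labels) -> TargetDistribution:
    """Row-uniform distribution over same-label columns; identity when all
    labels are distinct.  Label symmetry makes the two directions transposes
    of one another."""
    labels = np.asarray(labels)
    if labels.shape[0] < 2:
        raise ValueError("need a batch of at least 2")
    match = (labels[:, None] == labels[None, :]).astype(np.float64)
    q = match / match.sum(axis=1, keepdims=True)
    return TargetDistribution(q_x2y=q, q_y2x=q.T.copy())


def kl_contrastive_loss(batch: BatchSimilarity, targets: TargetDistribution) -> Tensor:
    """Bidirectional soft-target KL objective (scalar Tensor, >= 0)."""

    def direction(p: Tensor, q: np.ndarray) -> Tensor:
        if p.shape != q.shape:
            raise ValueError("shape mismatch between p and q")
        qlogq = np.where(q > 0, q * np.log(q + EPS), 0.0).sum(axis=1)
        cross = (Tensor(q) * (p + EPS).log()).sum(axis=1)
        return (Tensor(qlogq) - cross).mean()

    return 0.5 * (direction(batch.p_x2y, targets.q_x2y) + direction(batch.p_y2x, targets.q_y2x))


def classify(video_emb: Tensor | np.ndarray, class_prompt_embs: list[np.ndarray],
             tau: float = 14.0, aggregate: str = "mean") -> np.ndarray:
    """Class probabilities for one video from per-class prompt ensembles.

    Per-class score = mean (or max) cosine similarity between the video
    embedding and that class's rendered-prompt embeddings; probabilities are
    the softmax of tau * scores.  Ties in the argmax go to the lower class
    index (numpy argmax convention).
    """
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    v = video_emb.data if isinstance(video_emb, Tensor) else np.asarray(video_emb)
    scores = []
    for embs in class_prompt_embs:
        embs = embs.data if isinstance(embs, Tensor) else np.asarray(embs)
        if embs.size == 0:
            raise ValueError("empty prompt ensemble")
        sims = embs @ v
        scores.append(sims.mean() if aggregate == "mean" else sims.max())
    scores = np.asarray(scores)
    z = tau * (scores - scores.max())
    e = np.exp(z)
    return e / e.sum()


def predict_class(probabilities: np.ndarray) -> int:
    return int(np.argmax(probabilities))
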