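"""Adaptive fine-tuning optimizer (AFTO): residual adapters with a learned
mixing coefficient.

A lightweight bottleneck adapter refines a branch's shared-space embedding:

    F_new = W2 relu(W1 F_raw + b1) + b2
    F_mix = alpha * F_new + (1 - alpha) * F_raw

The blending ratio ``alpha`` is the logistic squash of an unconstrained
scalar, so it stays in (0, 1) and is adjusted by backpropagation alongside
the adapter weights instead of being hand-tuned.  The mixed embedding is
re-normalized so downstream cosine similarities stay on the unit sphere.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .autodiff import Tensor, l2_normalize

WHERE_CHOICES = ("video", "text", "both", "none")


class Adapter(nn.Module):
    def __init__(self, d_shared: int, bottleneck: int | None = None,
                 alpha_init: float = 0.5, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        if bottleneck is None:
            bottleneck = max(1, d_shared // 4)
        if bottleneck >= d_shared:
            raise ValueError("bottleneck must be smaller than d_shared")
        if not 0.0 < alpha_init < 1.0:
            raise ValueError("alpha_init must lie in (0, 1)")
        self.d_shared = d_shared
        self.bottleneck = bottleneck
        self.down = nn.Linear(d_shared, bottleneck, rng)
        # small-variance up-projection => near-identity start (F_new ~ 0 is
        # avoided by the residual mix staying close to F_raw)
        self.up = nn.Linear(bottleneck, d_shared, rng, scale=1e-3)
        self.alpha_logit = nn.Parameter(np.array(math.log(alpha_init / (1.0 - alpha_init))))

    @property
    def alpha(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.alpha_logit.data)))

    def new_features(self, f_raw: Tensor) -> Tensor:
        return self.up(self.down(f_raw).relu())

    def __call__(self, f_raw: Tensor, renormalize: bool = True,
                 alpha: float | None = None) -> Tensor:
        """Mix adapted and raw features; ``alpha=None`` uses the learned
        coefficient (differentiable), a float pins it (limit checks)."""
        if f_raw.shape[-1] != self.d_shared:
            raise ValueError("embedding dimension mismatch")
        f_new = self.new_features(f_raw)
        a = self.alpha_logit.sigmoid() if alpha is None else Tensor(np.array(float(alpha)))
        mixed = a * f_new + (1.0 - a) * f_raw
        return l2_normalize(mixed) if renormalize else mixed


def adapter_parameter_count(d_shared: int, bottleneck: int) -> int:
    """Trainable scalars per adapter: two linears + biases + alpha logit."""
    return d_shared * bottleneck + bottleneck * d_shared + bottleneck + d_shared + 1


def attach(model, where: str, bottleneck: int | None = None,
           alpha_init: float = 0.5, rng: np.random.Generator | None = None):
    """Insert adapters after the designated encoder projections of a
    :class:`~ceusalnm.model.DualBranchModel`; returns the model."""
    if where not in WHERE_CHOICES:
        raise ValueError(f"where must be one of {WHERE_CHOICES}")
    d = model.d_shared
    if where in ("video", "both"):
        model.video_adapter = Adapter(d, bottleneck, alpha_init, rng)
    if where in ("text", "both"):
        model.text_adapter = Adapter(d, bottleneck, alpha_init, rng)
    return model
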