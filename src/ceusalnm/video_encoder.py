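"""Video encoder: spatio-temporal transformer over patch tokens + LSTM.

Each sampled frame is cut into fixed-size patches; every patch is linearly
projected to a token, given a spatial position embedding, and every token of
frame *i* additionally receives that frame's temporal position embedding
(TPE).  Tokens of all frames are concatenated frame-major and encoded
jointly by a transformer (cross-frame attention allowed), so temporal
structure is visible to the attention.  Per-frame representations (mean over
each frame's output tokens) are then consumed in temporal order by an LSTM
whose final hidden state is projected to the shared space and L2-normalized.

An ablation switch replaces the LSTM with mean pooling over frames, which
makes the encoder frame-order-invariant (given identical TPE) — useful for
testing where temporal information enters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, l2_normalize


@dataclass(frozen=True)
class VideoEncoderParams:
    frame_size: tuple[int, int] = (64, 64)
    patch_size: int = 16
    embed_dim: int = 32
    n_layers: int = 2  # paper-faithful configuration uses 6
    n_heads: int = 2
    max_frames: int = 32
    d_shared: int = 32
    temporal_pool: str = "lstm"  # "lstm" | "mean"

    def __post_init__(self):
        H, W = self.frame_size
        if H % self.patch_size or W % self.patch_size:
            raise ValueError("frame size must be divisible by patch_size")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.temporal_pool not in ("lstm", "mean"):
            raise ValueError("temporal_pool must be 'lstm' or 'mean'")

    @property
    def patches_per_frame(self) -> int:
        H, W = self.frame_size
        return (H // self.patch_size) * (W // self.patch_size)


@dataclass
class VideoTokenSequence:
    """Frame-major token matrix for one clip: row t*P+j is patch j of frame t."""

    tokens: Tensor  # (T*P, d)
    frame_index: np.ndarray  # (T*P,)
    n_frames: int
    patches_per_frame: int


class VideoEncoder(nn.Module):
    def __init__(self, params: VideoEncoderParams, rng: np.random.Generator):
        self.params = params
        d = params.embed_dim
        p = params.patch_size
        self.patch_projection = nn.Linear(p * p, d, rng)
        self.spatial_embedding = nn.Parameter(
            rng.normal(0.0, 0.01, size=(params.patches_per_frame, d))
        )
        self.temporal_embedding = nn.Parameter(
            rng.normal(0.0, 0.01, size=(params.max_frames, d))
        )
        self.layers = [
            nn.TransformerEncoderLayer(d, params.n_heads, rng)
            for _ in range(params.n_layers)
        ]
        self.ln_final = nn.LayerNorm(d)
        self.lstm = nn.LSTM(d, d, rng)
        self.projection = nn.Linear(d, params.d_shared, rng, bias=False)

    # -- tokenization ------------------------------------------------------
    def _patches(self, frames: np.ndarray) -> np.ndarray:
        """(..., T, H, W) -> (..., T, P, patch*patch), row-major patch order."""
        p = self.params.patch_size
        *lead, T, H, W = frames.shape
        x = frames.reshape(*lead, T, H // p, p, W // p, p)
        x = np.moveaxis(x, -3, -2)  # (..., T, H/p, W/p, p, p)
        return x.reshape(*lead, T, (H // p) * (W // p), p * p)

    def patchify(self, frames: np.ndarray) -> VideoTokenSequence:
        """One clip (T, H, W) in [0, 1] -> frame-major token sequence with
        spatial and temporal position embeddings added."""
        frames = np.asarray(frames, dtype=np.float64)
        T = frames.shape[0]
        if T > self.params.max_frames:
            raise ValueError("clip longer than the temporal embedding table")
        P = self.params.patches_per_frame
        patches = self._patches(frames)  # (T, P, p*p)
        tok = self.patch_projection(Tensor(patches))  # (T, P, d)
        tok = tok + self.spatial_embedding
        tok = tok + self.temporal_embedding[:T].reshape(T, 1, self.params.embed_dim)
        return VideoTokenSequence(
            tokens=tok.reshape(T * P, self.params.embed_dim),
            frame_index=np.repeat(np.arange(T), P),
            n_frames=T,
            patches_per_frame=P,
        )

    # -- encoding ----------------------------------------------------------
    def _encode_token_batch(self, tokens: Tensor, T: int, P: int) -> Tensor:
        """tokens: (B, T*P, d) -> (B, d_shared) normalized."""
        B = tokens.shape[0]
        d = self.params.embed_dim
        x = tokens
        for layer in self.layers:
            x = layer(x)
        x = self.ln_final(x)
        frame_feats = x.reshape(B, T, P, d).mean(axis=2)  # (B, T, d)
        if self.params.temporal_pool == "lstm":
            h = self.lstm(frame_feats)
        else:
            h = frame_feats.mean(axis=1)
        return l2_normalize(self.projection(h))

    def encode_tokens(self, seq: VideoTokenSequence) -> Tensor:
        """Encode one clip's token sequence -> (d_shared,) normalized."""
        T, P = seq.n_frames, seq.patches_per_frame
        out = self._encode_token_batch(
            seq.tokens.reshape(1, T * P, self.params.embed_dim), T, P
        )
        return out[0]

    def __call__(self, frames: np.ndarray) -> Tensor:
        """Batch of clips (B, T, H, W) in [0, 1] -> (B, d_shared) normalized."""
        frames = np.asarray(frames, dtype=np.float64)
        B, T, H, W = frames.shape
        if T > self.params.max_frames:
            raise ValueError("clip longer than the temporal embedding table")
        P = self.params.patches_per_frame
        d = self.params.embed_dim
        patches = self._patches(frames)  # (B, T, P, p*p)
        tok = self.patch_projection(Tensor(patches))
        tok = tok + self.spatial_embedding
        tok = tok + self.temporal_embedding[:T].reshape(1, T, 1, d)
        return self._encode_token_batch(tok.reshape(B, T * P, d), T, P)
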