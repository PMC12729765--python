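"""Transformer text encoder mapping a prompt string to the shared embedding
space used for video-text similarity.

Token embeddings plus a learned positional table feed a stack of
bidirectional transformer encoder layers; padding positions are masked out
of the attention so they can never influence the result.  The sequence is
pooled at the end-marker position, linearly projected to the shared space
and L2-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, l2_normalize
from .tokenizer import TokenIds, Vocabulary, tokenize


@dataclass(frozen=True)
class TextEncoderParams:
    vocab_size: int
    embed_dim: int = 32
    n_layers: int = 2  # paper-faithful configuration uses 6
    n_heads: int = 2
    context_length: int = 32
    d_shared: int = 32

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")


class TextEncoder(nn.Module):
    def __init__(self, params: TextEncoderParams, rng: np.random.Generator):
        self.params = params
        d = params.embed_dim
        self.token_embedding = nn.Embedding(params.vocab_size, d, rng)
        self.positional_embedding = nn.Parameter(
            rng.normal(0.0, 0.01, size=(params.context_length, d))
        )
        self.layers = [
            nn.TransformerEncoderLayer(d, params.n_heads, rng)
            for _ in range(params.n_layers)
        ]
        self.ln_final = nn.LayerNorm(d)
        self.projection = nn.Linear(d, params.d_shared, rng, bias=False)

    def __call__(self, ids: np.ndarray, end_positions: np.ndarray) -> Tensor:
        """ids: (B, L) int array; end_positions: (B,). Returns (B, d_shared)
        L2-normalized embeddings."""
        ids = np.asarray(ids)
        if ids.max() >= self.params.vocab_size or ids.min() < 0:
            raise ValueError("token id out of vocabulary range")
        B, L = ids.shape
        key_mask = np.arange(L)[None, :] <= np.asarray(end_positions)[:, None]
        x = self.token_embedding(ids) + self.positional_embedding[:L]
        for layer in self.layers:
            x = layer(x, key_mask)
        x = self.ln_final(x)
        pooled = x[np.arange(B), np.asarray(end_positions)]
        return l2_normalize(self.projection(pooled))

    def encode_tokens(self, tokens: TokenIds) -> Tensor:
        out = self(tokens.ids[None, :], np.array([tokens.end_pos]))
        return out[0]


def encode_text(texts: list[str], encoder: TextEncoder, vocab: Vocabulary) -> Tensor:
    """Tokenize and encode a batch of strings -> (B, d_shared)."""
    toks = [tokenize(t, vocab, encoder.params.context_length) for t in texts]
    ids = np.stack([t.ids for t in toks])
    ends = np.array([t.end_pos for t in toks])
    return encoder(ids, ends)
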