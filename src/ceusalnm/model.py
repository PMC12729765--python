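"""Dual-branch text-video contrastive model.

Combines the video encoder, text encoder, optional AFTO adapters on either
branch, and a learnable similarity temperature into one trainable unit.
Classification renders every pool template with each class label, encodes
the resulting prompt ensemble once, and assigns the class whose ensemble is
most similar to the video embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import afto as afto_mod
from . import nn
from .autodiff import Tensor, no_grad
from .contrastive import classify, kl_contrastive_loss, similarity_matrix, target_distribution
from .prompts import PromptPool, class_prompt_texts
from .text_encoder import TextEncoder, TextEncoderParams, encode_text
from .tokenizer import Vocabulary, default_vocab
from .video_encoder import VideoEncoder, VideoEncoderParams


@dataclass(frozen=True)
class AftoConfig:
    where: str = "none"  # video | text | both | none
    bottleneck: int | None = None  # default: d_shared // 4
    alpha_init: float = 0.5
    freeze_backbone: bool = True


@dataclass(frozen=True)
class ModelConfig:
    embed_dim: int = 32
    d_shared: int = 32
    n_layers: int = 2
    n_heads: int = 2
    frame_size: tuple[int, int] = (64, 64)
    patch_size: int = 16
    max_frames: int = 32
    context_length: int = 32
    tau_init: float = 14.0  # initial exp(log-scale) of the similarity logits
    temporal_pool: str = "lstm"
    afto: AftoConfig = field(default_factory=AftoConfig)
    ensemble: str = "mean"  # prompt aggregation at inference: mean | max


class DualBranchModel(nn.Module):
    def __init__(self, config: ModelConfig, vocab: Vocabulary | None = None,
                 seed: int = 0):
        self.config = config
        self.vocab = vocab if vocab is not None else default_vocab()
        self.d_shared = config.d_shared
        rng = np.random.default_rng(seed)
        self.video_encoder = VideoEncoder(
            VideoEncoderParams(
                frame_size=config.frame_size,
                patch_size=config.patch_size,
                embed_dim=config.embed_dim,
                n_layers=config.n_layers,
                n_heads=config.n_heads,
                max_frames=config.max_frames,
                d_shared=config.d_shared,
                temporal_pool=config.temporal_pool,
            ),
            rng,
        )
        self.text_encoder = TextEncoder(
            TextEncoderParams(
                vocab_size=len(self.vocab),
                embed_dim=config.embed_dim,
                n_layers=config.n_layers,
                n_heads=config.n_heads,
                context_length=config.context_length,
                d_shared=config.d_shared,
            ),
            rng,
        )
        self.log_tau = nn.Parameter(np.array(np.log(config.tau_init)))
        self.video_adapter: afto_mod.Adapter | None = None
        self.text_adapter: afto_mod.Adapter | None = None
        if config.afto.where != "none":
            afto_mod.attach(
                self, config.afto.where, config.afto.bottleneck,
                config.afto.alpha_init, rng,
            )

    # -- encoding ----------------------------------------------------------
    def encode_videos(self, frames: np.ndarray) -> Tensor:
        """(B, T, H, W) in [0, 1] -> (B, d_shared), adapter applied if attached."""
        emb = self.video_encoder(frames)
        if self.video_adapter is not None:
            emb = self.video_adapter(emb)
        return emb

    def encode_texts(self, texts: list[str]) -> Tensor:
        emb = encode_text(texts, self.text_encoder, self.vocab)
        if self.text_adapter is not None:
            emb = self.text_adapter(emb)
        return emb

    @property
    def tau(self) -> Tensor:
        return self.log_tau.exp()

    # -- training / inference ----------------------------------------------
    def contrastive_loss(self, frames: np.ndarray, texts: list[str], labels) -> Tensor:
        V = self.encode_videos(frames)
        T = self.encode_texts(texts)
        batch = similarity_matrix(V, T, self.tau)
        targets = target_distribution(labels)
        return kl_contrastive_loss(batch, targets)

    def class_prompt_embeddings(self, pool: PromptPool) -> list[np.ndarray]:
        """Encode the full prompt ensemble of every class (no grad)."""
        with no_grad():
            return [
                self.encode_texts(class_prompt_texts(pool, c, mode="all")).data
                for c in range(len(pool.class_labels))
            ]

    def predict_proba(self, frames: np.ndarray, pool: PromptPool,
                      prompt_embs: list[np.ndarray] | None = None) -> np.ndarray:
        """(B, T, H, W) -> (B, n_classes) prompt-ensemble probabilities."""
        if prompt_embs is None:
            prompt_embs = self.class_prompt_embeddings(pool)
        with no_grad():
            V = self.encode_videos(frames).data
        tau = float(np.exp(self.log_tau.data))
        return np.stack(
            [classify(v, prompt_embs, tau, self.config.ensemble) for v in V]
        )

    # -- parameter selection -------------------------------------------------
    def trainable_parameters(self) -> list[nn.Parameter]:
        """Parameters updated during fine-tuning.

        With adapters attached and ``freeze_backbone=True`` only the adapters
        and the temperature train (the parameter-efficient regime meant for
        imported pretrained backbones); otherwise everything trains.
        """
        adapters = [a for a in (self.video_adapter, self.text_adapter) if a is not None]
        if adapters and self.config.afto.freeze_backbone:
            params: list[nn.Parameter] = [self.log_tau]
            for a in adapters:
                params.extend(a.parameters())
            return params
        return self.parameters()

    # -- optional pretrained-weight import -----------------------------------
    def import_backbone_weights(self, state: dict[str, np.ndarray],
                                key_map: dict[str, str] | None = None) -> list[str]:
        """Load matching backbone arrays from a checkpoint-style mapping.

        ``key_map`` renames checkpoint keys to this model's parameter names
        (dotted paths as produced by ``named_parameters``).  Arrays whose
        name or shape does not match are skipped and reported, so partial
        imports (e.g. text tower only) are possible.  Temporal embeddings and
        the LSTM are always freshly initialized by design.
        """
        own = dict(self.named_parameters())
        skipped = []
        for key, array in state.items():
            name = key_map.get(key, key) if key_map else key
            if name in own and own[name].data.shape == np.asarray(array).shape:
                own[name].data = np.asarray(array, dtype=np.float64).copy()
            else:
                skipped.append(key)
        return skipped
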