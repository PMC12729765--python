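"""Desk-scale experiment presets.

The full study protocol (6-layer encoders, 224x224 inputs, >=50 epochs)
targets GPU hardware and a real clinical cohort.  The presets here are the
package's CPU-scale counterpart used by the examples, the test-suite
end-to-end checks and ``scripts/acceptance.py``: a 2+2-layer model at
64x64/patch-16 with width 32, a 60-patient synthetic cohort, and a short
fixed-length training schedule (24 epochs, AdamW, lr 6e-4, batch 4,
similarity temperature starting at 4) that reliably extracts the
class-dependent wash-in signal in seconds per fold.  Documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import replace

from .evaluation import TrainConfig
from .model import ModelConfig
from .synthetic import SyntheticConfig


def desk_synthetic_config(n_patients: int = 60, seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(n_patients=n_patients, metastatic_fraction=0.5, seed=seed)


def desk_pretrain_config(n_patients: int = 60, seed: int = 0) -> SyntheticConfig:
    """Source cohort standing in for pretraining data: same generating
    process, disjoint patients (distinct ids and an independent seed
    stream)."""
    return SyntheticConfig(n_patients=n_patients, metastatic_fraction=0.5,
                           seed=seed + 10_000, patient_prefix="S")


def desk_model_config(**overrides) -> ModelConfig:
    # temperature starts at 4 rather than the CLIP-style 14: with a randomly
    # initialized backbone a sharp softmax stalls early optimization, and the
    # log-scale is learnable anyway
    defaults = dict(tau_init=4.0)
    defaults.update(overrides)
    return replace(ModelConfig(), **defaults)


def desk_train_config(seed: int = 0, **overrides) -> TrainConfig:
    tc = TrainConfig(min_epochs=24, max_epochs=24, patience=10, lr=6e-4, seed=seed)
    return replace(tc, **overrides) if overrides else tc
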