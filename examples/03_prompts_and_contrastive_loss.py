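"""Prompt pool, dual-branch embeddings and the KL contrastive objective.

One random template per instance is rendered with the class label (plus the
patient's clinical attribute text), both branches embed into the shared
space, and the bidirectional KL loss compares the batch similarity softmax
against soft label-match targets.
"""

import numpy as np

from ceusalnm import (
    DualBranchModel, ModelConfig, SyntheticConfig, default_pool,
    generate_dataset, kl_contrastive_loss, preprocess_clip, render,
    sample_prompt, similarity_matrix, target_distribution,
)

pool = default_pool()
rng = np.random.default_rng(0)
print(f"pool: {len(pool.templates)} templates over pre/mid/post, "
      f"classes {pool.class_labels}")
t = sample_prompt(pool, rng)
print(f"sampled template ({t.position}): {t.text!r}")
print(f"rendered: {render(t, 'metastatic')!r}")

samples = generate_dataset(SyntheticConfig(n_patients=4, seed=0))
model = DualBranchModel(ModelConfig(), seed=0)
clips = np.stack([preprocess_clip(s.frames, s.keyframe_index)[0] for s in samples])
texts = [render(sample_prompt(pool, rng), pool.class_labels[s.class_label])
         for s in samples]
labels = [s.class_label for s in samples]

V = model.encode_videos(clips)
T = model.encode_texts(texts)
batch = similarity_matrix(V, T, model.tau)
targets = target_distribution(labels)
loss = kl_contrastive_loss(batch, targets)
print(f"batch labels {labels}; target row 0: {np.round(targets.q_x2y[0], 2)}")
print(f"video-to-text softmax row 0: {np.round(batch.p_x2y.data[0], 3)}")
print(f"KL contrastive loss at random init: {loss.item():.4f} "
      "(0 would mean similarity softmax already matches the label structure)")
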