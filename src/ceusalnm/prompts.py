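"""Random prompt pool for the text branch.

Training texts are built by filling a class label into a template drawn at
random from a pool of pre-, mid- and post-positioned prompts.  Randomising
the phrasing diversifies the text inputs seen during fine-tuning and reduces
overfitting to any single prompt wording; at inference all templates are
rendered with each class label and aggregated into a prompt ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

POSITIONS = ("pre", "mid", "post")


@dataclass(frozen=True)
class PromptTemplate:
    position: str
    text: str

    def __post_init__(self):
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")
        if not self.text:
            raise ValueError("empty template text")
        if self.text.count("{}") != 1:
            raise ValueError("template must contain exactly one '{}' slot")


def render(template: PromptTemplate, label: str) -> str:
    """Fill the class label into the template's slot, verbatim."""
    if not label:
        raise ValueError("empty label")
    return template.text.replace("{}", label)


@dataclass(frozen=True)
class PromptPool:
    templates: tuple[PromptTemplate, ...]
    class_labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "templates", tuple(self.templates))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        present = {t.position for t in self.templates}
        if set(POSITIONS) - present:
            raise ValueError("pool must contain at least one template per position")
        if len(self.class_labels) < 2:
            raise ValueError("need at least two class labels")

    def by_position(self, position: str) -> list[PromptTemplate]:
        return [t for t in self.templates if t.position == position]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            **{pos: [t.text for t in self.by_position(pos)] for pos in POSITIONS},
            "class_labels": list(self.class_labels),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PromptPool":
        templates = [
            PromptTemplate(pos, text) for pos in POSITIONS for text in data.get(pos, [])
        ]
        return cls(tuple(templates), tuple(data["class_labels"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PromptPool":
        return cls.from_dict(json.loads(Path(path).read_text()))


def sample_prompt(pool: PromptPool, rng: np.random.Generator) -> PromptTemplate:
    """Uniform draw over all templates, positions pooled together."""
    if not pool.templates:
        raise ValueError("empty pool")
    return pool.templates[int(rng.integers(len(pool.templates)))]


def fixed_prompt(pool: PromptPool) -> PromptTemplate:
    """The degenerate no-randomisation choice (ablation baseline): the first
    template of the pool, fixed for every instance."""
    return pool.templates[0]


def class_prompt_texts(pool: PromptPool, class_id: int, mode: str = "all",
                       rng: np.random.Generator | None = None) -> list[str]:
    """Render prompts for one class.

    mode="all": every template rendered with the class label (the inference
    prompt ensemble).  mode="sampled": one random rendering (training).
    """
    if not 0 <= class_id < len(pool.class_labels):
        raise ValueError("invalid class id")
    label = pool.class_labels[class_id]
    if mode == "all":
        return [render(t, label) for t in pool.templates]
    if mode == "sampled":
        if rng is None:
            raise ValueError("mode='sampled' needs an rng")
        return [render(sample_prompt(pool, rng), label)]
    raise ValueError("mode must be 'all' or 'sampled'")


def default_pool() -> PromptPool:
    """Default pre/mid/post pool: generic video-classification phrasings plus
    breast-CEUS-specific wording; the label slot takes the class string."""
    pre = [
        "{}, an action",
        "{} this is an disease",
        "{}, a video of symptom",
        "{}, seen on breast contrast-enhanced ultrasound",
        "{}, judged from the lesion wash-in pattern",
        "{}, a breast lesion perfusion clip",
        "{}, axillary lymph node status on ceus",
    ]
    mid = [
        "video classification of {}, a disease",
        "the disease is {}, look here",
        "Can you recognize {}? a Symptom of disease",
        "a contrast-enhanced ultrasound video showing {}, note the enhancement",
        "the breast lesion appears {}, based on microbubble perfusion",
        "this ceus clip suggests {}, from wash-in and wash-out dynamics",
        "lymph node status {}, according to lesion vascularity",
    ]
    post = [
        "a video of action {}",
        "a sample of disease {}",
        "Human of {}",
        "a breast ceus recording of a {} lesion",
        "dynamic contrast ultrasound frames of {}",
        "a two minute perfusion study of {}",
    ]
    templates = (
        [PromptTemplate("pre", t) for t in pre]
        + [PromptTemplate("mid", t) for t in mid]
        + [PromptTemplate("post", t) for t in post]
    )
    return PromptPool(tuple(templates), ("non-metastatic", "metastatic"))
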