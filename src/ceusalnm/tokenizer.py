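"""Subword tokenization for the text branch.

Texts are lowercased, split into words, and segmented into subword units
mapped onto a fixed vocabulary, in the byte-pair-encoding style: when a
merge table is supplied (``Vocabulary.from_bpe_files``) the standard BPE
merge procedure is applied; the built-in default vocabulary instead uses
whole words from the prompt/clinical vocabulary with greedy longest-match
character fallback, so nothing has to be downloaded.

Token id sequences carry start/end markers and are padded to a fixed
context length, truncating (end marker preserved) when too long.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

START_TOKEN = "<|startoftext|>"
END_TOKEN = "<|endoftext|>"
PAD_TOKEN = "<|pad|>"
UNK_TOKEN = "<|unk|>"

_WORD_RE = re.compile(r"[a-z0-9]+|[^\sa-z0-9]")


@dataclass(frozen=True)
class TokenIds:
    """Fixed-length id sequence: [start, subwords..., end, pad...]."""

    ids: np.ndarray  # (context_length,) int64
    end_pos: int  # index of the end marker

    def __post_init__(self):
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=np.int64))


class Vocabulary:
    def __init__(self, tokens: list[str], merges: list[tuple[str, str]] | None = None):
        specials = [PAD_TOKEN, START_TOKEN, END_TOKEN, UNK_TOKEN]
        ordered = specials + [t for t in tokens if t not in specials]
        self.token_to_id = {t: i for i, t in enumerate(ordered)}
        self.id_to_token = ordered
        self.merge_ranks = (
            {pair: r for r, pair in enumerate(merges)} if merges else None
        )
        self._cache: dict[str, list[str]] = {}

    def __len__(self) -> int:
        return len(self.id_to_token)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD_TOKEN]

    @property
    def start_id(self) -> int:
        return self.token_to_id[START_TOKEN]

    @property
    def end_id(self) -> int:
        return self.token_to_id[END_TOKEN]

    # -- segmentation -----------------------------------------------------
    def segment_word(self, word: str) -> list[str]:
        if word in self._cache:
            return self._cache[word]
        if self.merge_ranks is not None:
            pieces = self._bpe(word)
        elif word in self.token_to_id:
            pieces = [word]
        else:
            pieces = self._greedy(word)
        self._cache[word] = pieces
        return pieces

    def _bpe(self, word: str) -> list[str]:
        """Standard byte-pair merge procedure with end-of-word marker."""
        symbols = list(word[:-1]) + [word[-1] + "</w>"]
        while len(symbols) > 1:
            pairs = [(symbols[i], symbols[i + 1]) for i in range(len(symbols) - 1)]
            ranked = [(self.merge_ranks.get(p, None), i) for i, p in enumerate(pairs)]
            ranked = [(r, i) for r, i in ranked if r is not None]
            if not ranked:
                break
            _, i = min(ranked)
            symbols = symbols[:i] + [symbols[i] + symbols[i + 1]] + symbols[i + 2 :]
        return [s if s in self.token_to_id else UNK_TOKEN for s in symbols]

    def _greedy(self, word: str) -> list[str]:
        """Greedy longest-match segmentation against the vocabulary."""
        pieces = []
        i = 0
        while i < len(word):
            for j in range(len(word), i, -1):
                if word[i:j] in self.token_to_id:
                    pieces.append(word[i:j])
                    i = j
                    break
            else:
                pieces.append(UNK_TOKEN)
                i += 1
        return pieces

    @classmethod
    def from_bpe_files(cls, vocab_path, merges_path) -> "Vocabulary":
        import json
        from pathlib import Path

        vocab = json.loads(Path(vocab_path).read_text())
        tokens = [t for t, _ in sorted(vocab.items(), key=lambda kv: kv[1])]
        merges = []
        for line in Path(merges_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()
            merges.append((a, b))
        return cls(tokens, merges)


def tokenize(text: str, vocab: Vocabulary, context_length: int = 77) -> TokenIds:
    """Lowercase, segment, and map to padded ids with start/end markers."""
    if not text:
        raise ValueError("empty text")
    words = _WORD_RE.findall(text.lower())
    body: list[int] = []
    for w in words:
        body.extend(vocab.token_to_id[p] for p in vocab.segment_word(w))
    body = body[: context_length - 2]  # room for start + end markers
    ids = np.full(context_length, vocab.pad_id, dtype=np.int64)
    ids[0] = vocab.start_id
    ids[1 : 1 + len(body)] = body
    end_pos = 1 + len(body)
    ids[end_pos] = vocab.end_id
    return TokenIds(ids=ids, end_pos=end_pos)


def default_vocab() -> Vocabulary:
    """Word-level vocabulary over the default prompt pool and clinical
    attribute vocabulary, with a-z/0-9 fallback pieces."""
    from . import prompts, synthetic

    words: set[str] = set()
    pool = prompts.default_pool()
    for template in pool.templates:
        for label in pool.class_labels:
            words.update(_WORD_RE.findall(prompts.render(template, label).lower()))
    for values, _, _ in synthetic._ATTRIBUTE_TABLE.values():
        for v in values:
            words.update(_WORD_RE.findall(v.lower()))
    fallback = [chr(c) for c in range(ord("a"), ord("z") + 1)] + [str(d) for d in range(10)]
    return Vocabulary(sorted(words) + [c for c in fallback if c not in words])
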