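"""Corpus container: feature sequences paired with transcriptions and splits."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

SPLITS = ("train", "fitness", "test")


@dataclass
class Sentence:
    """One utterance: an acoustic feature matrix plus its transcriptions.

    ``features`` is a (frames × dim) float array.  ``words`` is the
    word-level transcription; ``phones`` the phone-level one (silence
    included at sentence boundaries), which is what embedded training
    consumes.  ``split`` tags the sentence as train / fitness / test.
    """

    features: np.ndarray
    words: tuple[str, ...]
    phones: tuple[str, ...] = ()
    split: str = ""
    sent_id: str = ""

    @property
    def n_frames(self) -> int:
        return int(self.features.shape[0])


@dataclass
class Corpus:
    sentences: list[Sentence] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[Sentence]:
        return iter(self.sentences)

    @property
    def feature_dim(self) -> int:
        if not self.sentences:
            raise ValueError("empty corpus has no feature dimension")
        return int(self.sentences[0].features.shape[1])

    def subset(self, split: str) -> "Corpus":
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}; expected one of {SPLITS}")
        return Corpus([s for s in self.sentences if s.split == split])

    def phones_present(self) -> set[str]:
        out: set[str] = set()
        for s in self.sentences:
            out.update(s.phones)
        return out

    def total_frames(self) -> int:
        return sum(s.n_frames for s in self.sentences)

    def retagged(self, tags: Sequence[str]) -> "Corpus":
        """Copy of the corpus with per-sentence split tags replaced."""
        if len(tags) != len(self.sentences):
            raise ValueError("one tag per sentence required")
        return Corpus(
            [replace(s, split=t) for s, t in zip(self.sentences, tags)]
        )
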