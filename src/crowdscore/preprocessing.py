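"""Turn raw free-recall text into the token sets on which all scoring operates.

A response is reduced to its *token set*: the deduplicated vocabulary that
remains after lower-casing, punctuation stripping and stop-word removal.
Repeated words within one response count once, and no morphological
normalization is applied ("read" and "reading" stay distinct, as do "book"
and "books"), so two responses match only on literally shared word forms.

Tokenization is deliberately simple and deterministic: apostrophes are
deleted (``man's`` becomes ``mans``), the text is folded to lowercase with
``str.lower`` (locale-independent), and split on any run of non-alphanumeric
characters.  Pure-digit tokens are kept.  No external language tooling is
involved, so results are bit-reproducible across installs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "RawResponse",
    "StopWordList",
    "TokenSet",
    "normalize_text",
    "remove_stop_words",
    "to_token_set",
    "preprocess_response",
    "preprocess_responses",
    "default_stop_words",
]

# Apostrophe variants (ASCII, typographic, backtick) deleted before splitting.
_APOSTROPHES = "'’‘`"
_SPLIT_RE = re.compile(r"[^0-9a-z]+")


@dataclass(frozen=True)
class RawResponse:
    """One free-recall description with its identifying metadata.

    ``text`` may be empty (an empty description is data, not an error: under
    severe stimulus degradation subjects may report nothing usable).
    """

    response_id: str
    clip_id: str
    subject_id: str
    condition: str = ""
    text: str = ""


@dataclass(frozen=True)
class StopWordList:
    """A set of lowercase tokens removed from responses before scoring.

    Stop words are high-frequency, low-information words ("of", "the") plus
    spoken-language interjections ("um", "sorry") that carry no stimulus
    content.
    """

    words: frozenset[str]

    def __post_init__(self):
        for w in self.words:
            if w != w.lower():
                raise ValueError(f"stop word not lowercase: {w!r}")
            if re.search(r"\s", w):
                raise ValueError(f"stop word contains whitespace: {w!r}")

    def __contains__(self, token: str) -> bool:
        return token in self.words

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self) -> Iterator[str]:
        return iter(self.words)

    @classmethod
    def from_iterable(cls, words: Iterable[str]) -> "StopWordList":
        return cls(frozenset(w.strip().lower() for w in words if w.strip()))

    @classmethod
    def from_file(cls, path: str | Path) -> "StopWordList":
        """Read a plain-text list, one token per line; ``#`` starts a comment."""
        words = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            words.append(line)
        return cls.from_iterable(words)


@dataclass(frozen=True)
class TokenSet:
    """The deduplicated, stop-word-free vocabulary of one response."""

    response_id: str
    clip_id: str
    subject_id: str
    condition: str
    tokens: frozenset[str]

    def __len__(self) -> int:
        return len(self.tokens)


def default_stop_words() -> StopWordList:
    """The stop-word list shipped with the package (English function words
    plus common spoken interjections)."""
    text = resources.files("crowdscore").joinpath("data/stopwords.txt").read_text(
        encoding="utf-8"
    )
    words = [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]
    return StopWordList.from_iterable(words)


def normalize_text(text: str) -> list[str]:
    """Lowercase, strip punctuation and split ``text`` into tokens.

    Order is preserved: windowed co-occurrence statistics in the similarity
    module need the original word order.  Empty input yields an empty list.
    """
    lowered = text.lower()
    for ch in _APOSTROPHES:
        if ch in lowered:
            lowered = lowered.replace(ch, "")
    return [t for t in _SPLIT_RE.split(lowered) if t]


def remove_stop_words(
    tokens: Sequence[str], stoplist: StopWordList
) -> list[str]:
    """Delete every stop-list member from ``tokens``, preserving order."""
    return [t for t in tokens if t not in stoplist]


def to_token_set(
    tokens: Iterable[str],
    *,
    response_id: str,
    clip_id: str,
    subject_id: str = "",
    condition: str = "",
) -> TokenSet:
    """Deduplicate a filtered token sequence into a :class:`TokenSet`."""
    ts = TokenSet(
        response_id=response_id,
        clip_id=clip_id,
        subject_id=subject_id,
        condition=condition,
        tokens=frozenset(tokens),
    )
    if not ts.tokens:
        logger.info("response %s has an empty token set", response_id)
    return ts


def preprocess_response(response: RawResponse, stoplist: StopWordList) -> TokenSet:
    """Full pipeline for one response: normalize, filter, deduplicate."""
    tokens = remove_stop_words(normalize_text(response.text), stoplist)
    return to_token_set(
        tokens,
        response_id=response.response_id,
        clip_id=response.clip_id,
        subject_id=response.subject_id,
        condition=response.condition,
    )


def preprocess_responses(
    responses: Iterable[RawResponse], stoplist: StopWordList
) -> list[TokenSet]:
    """Preprocess a batch of responses.

    Responses that come out empty are retained (they score zero against any
    normative set) and counted in a log message; dropping them would bias
    dose-response analyses in which severe degradation yields near-empty
    descriptions.
    """
    out = [preprocess_response(r, stoplist) for r in responses]
    n_empty = sum(1 for ts in out if not ts.tokens)
    if n_empty:
        logger.warning("%d of %d responses have empty token sets", n_empty, len(out))
    return out
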