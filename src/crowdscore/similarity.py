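"""Passage similarity: the shared-word rule and semantic-space alternatives.

The primary statistic of the package is the *mean shared-word score*: a
target response's average number of unique, stop-word-filtered words in
common with each normative response to the same stimulus.  Because the mean
of intersection counts equals the sum, over the target's words, of the
fraction of normative responses containing each word, words mentioned by
many members of the crowd are effectively weighted more heavily — the
"wisdom of crowds" weighting arises from the arithmetic, not from an
explicit weight table.

Two corpus-driven comparators are also provided for benchmarking against
the shared-word rule:

* latent semantic analysis (LSA): words are embedded by truncated SVD of a
  term-document count matrix, so words that co-occur in the same documents
  (or with common neighbours) are drawn together;
* a windowed vector space model (VSM): co-occurrence is counted within a
  symmetric window of 2 or 20 tokens around each word instead of within
  whole documents.

Passages are embedded as the (sum or mean) of their word vectors and
compared by cosine.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .errors import (
    EmptyNormativeSetError,
    RankDeficiencyError,
    UnrepresentablePassageError,
    ValidationError,
)
from .preprocessing import StopWordList, TokenSet, normalize_text, remove_stop_words

logger = logging.getLogger(__name__)

__all__ = [
    "NormativeSet",
    "NormativeDataset",
    "SemanticSpace",
    "METHODS",
    "pairwise_shared_words",
    "mean_shared_word_score",
    "mean_semantic_score",
    "build_semantic_space",
    "semantic_passage_similarity",
    "passage_vector",
    "score_responses",
]

#: Scoring method labels accepted throughout the package, mapped to the
#: context mode of the semantic space they require (None = no space needed).
METHODS: Mapping[str, Optional[str]] = {
    "shared-words": None,
    "lsa": "document",
    "vsm2": "window-2",
    "vsm20": "window-20",
}


@dataclass
class NormativeSet:
    """All reference token sets for one stimulus: the per-clip "crowd"."""

    clip_id: str
    members: list[TokenSet]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"normative set for {self.clip_id!r} is empty")
        bad = [m.response_id for m in self.members if m.clip_id != self.clip_id]
        if bad:
            raise ValidationError(
                f"members {bad} do not carry clip_id {self.clip_id!r}"
            )

    def __len__(self) -> int:
        return len(self.members)


class NormativeDataset:
    """Normative token sets grouped by stimulus (clip) identifier."""

    def __init__(self, sets: Mapping[str, NormativeSet]):
        self._sets = dict(sets)
        seen: set[str] = set()
        for ns in self._sets.values():
            for m in ns.members:
                if m.response_id in seen:
                    raise ValidationError(
                        f"duplicate response_id {m.response_id!r} in dataset"
                    )
                seen.add(m.response_id)

    @classmethod
    def from_token_sets(cls, token_sets: Iterable[TokenSet]) -> "NormativeDataset":
        groups: dict[str, list[TokenSet]] = {}
        for ts in token_sets:
            groups.setdefault(ts.clip_id, []).append(ts)
        return cls({cid: NormativeSet(cid, members) for cid, members in groups.items()})

    @classmethod
    def from_responses(cls, responses, stoplist: StopWordList) -> "NormativeDataset":
        from .preprocessing import preprocess_responses

        return cls.from_token_sets(preprocess_responses(responses, stoplist))

    @classmethod
    def merged(cls, *datasets: "NormativeDataset") -> "NormativeDataset":
        """Pool several datasets clip-wise (e.g. lab + crowdsourced)."""
        all_ts = [ts for d in datasets for ts in d.responses()]
        return cls.from_token_sets(all_ts)

    def __getitem__(self, clip_id: str) -> NormativeSet:
        return self._sets[clip_id]

    def __contains__(self, clip_id: str) -> bool:
        return clip_id in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def clip_ids(self) -> list[str]:
        return sorted(self._sets)

    def responses(self) -> list[TokenSet]:
        """All member token sets, in sorted-clip then insertion order."""
        return [m for cid in self.clip_ids for m in self._sets[cid].members]

    def sizes(self) -> dict[str, int]:
        return {cid: len(self._sets[cid]) for cid in self.clip_ids}

    def subsample(self, n: int, rng: np.random.Generator) -> "NormativeDataset":
        """Draw ``n`` members per clip without replacement."""
        out: dict[str, NormativeSet] = {}
        for cid in self.clip_ids:
            members = self._sets[cid].members
            if n > len(members):
                raise ValidationError(
                    f"cannot sample {n} from clip {cid!r} with {len(members)} responses"
                )
            idx = rng.choice(len(members), size=n, replace=False)
            out[cid] = NormativeSet(cid, [members[i] for i in sorted(idx)])
        return NormativeDataset(out)


def pairwise_shared_words(a: TokenSet, b: TokenSet) -> int:
    """Number of unique words shared between two responses: ``|a ∩ b|``."""
    return len(a.tokens & b.tokens)


def mean_shared_word_score(
    target: TokenSet,
    norm: NormativeSet,
    exclude_response_id: Optional[str] = None,
) -> float:
    """Average shared-word count between ``target`` and each member of ``norm``.

    ``exclude_response_id`` implements take-one-out scoring: when the target
    itself belongs to the normative set, it must not be compared to itself.

    Raises :class:`EmptyNormativeSetError` if exclusion empties the set.
    """
    members = [
        m for m in norm.members if m.response_id != exclude_response_id
    ]
    if not members:
        raise EmptyNormativeSetError(
            f"normative set for {norm.clip_id!r} is empty after excluding "
            f"{exclude_response_id!r}"
        )
    total = sum(pairwise_shared_words(target, m) for m in members)
    return total / len(members)


@dataclass
class SemanticSpace:
    """Word embeddings from a truncated SVD of a co-occurrence matrix.

    ``vectors[i]`` is the coordinate row of ``vocabulary[i]``; rows of words
    with identical co-occurrence profiles are identical, and the cosine of
    any nonzero vector with itself is 1.
    """

    vocabulary: tuple[str, ...]
    vectors: np.ndarray
    context_mode: str
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValidationError("one vector per vocabulary word required")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    @property
    def dimensionality(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]


def _window_cooccurrence(
    docs: Sequence[Sequence[str]], vocab_index: dict[str, int], window: int
) -> sp.csr_matrix:
    """Symmetric word-word co-occurrence counts within ±``window`` tokens.

    C[a, b] counts ordered token pairs (i, j) with i != j, |i - j| <= window,
    within one document; the matrix is symmetric by construction.
    """
    counts: Counter[tuple[int, int]] = Counter()
    for doc in docs:
        ids = [vocab_index[t] for t in doc]
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, min(i + window, n - 1) + 1):
                counts[(ids[i], ids[j])] += 1
                counts[(ids[j], ids[i])] += 1
    if not counts:
        v = len(vocab_index)
        return sp.csr_matrix((v, v))
    rows, cols = zip(*counts)
    v = len(vocab_index)
    return sp.csr_matrix(
        (np.fromiter(counts.values(), float), (rows, cols)), shape=(v, v)
    )


def _document_counts(
    docs: Sequence[Sequence[str]], vocab_index: dict[str, int]
) -> sp.csr_matrix:
    """Term-document count matrix (vocabulary rows, document columns)."""
    rows, cols, vals = [], [], []
    for j, doc in enumerate(docs):
        for t, c in Counter(doc).items():
            rows.append(vocab_index[t])
            cols.append(j)
            vals.append(float(c))
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(vocab_index), len(docs))
    )


def _apply_weighting(mat: sp.csr_matrix, weighting: str) -> sp.csr_matrix:
    if weighting == "raw":
        return mat
    if weighting == "log-entropy":
        # log(1 + tf) scaled by 1 - (normalized entropy of the word across
        # contexts); the classic LSA weighting.
        mat = mat.tocsr()
        n_ctx = mat.shape[1]
        row_sums = np.asarray(mat.sum(axis=1)).ravel()
        entropy = np.zeros(mat.shape[0])
        for i in range(mat.shape[0]):
            row = mat.getrow(i)
            if row.nnz == 0 or row_sums[i] == 0:
                continue
            p = row.data / row_sums[i]
            entropy[i] = -(p * np.log(p)).sum() / np.log(max(n_ctx, 2))
        weighted = mat.copy().astype(float)
        weighted.data = np.log1p(weighted.data)
        g = sp.diags(1.0 - entropy)
        return (g @ weighted).tocsr()
    if weighting == "ppmi":
        mat = mat.tocoo().astype(float)
        total = mat.data.sum()
        if total == 0:
            return mat.tocsr()
        row_sums = np.asarray(mat.tocsr().sum(axis=1)).ravel()
        col_sums = np.asarray(mat.tocsr().sum(axis=0)).ravel()
        pmi = np.log(
            (mat.data * total)
            / (row_sums[mat.row] * col_sums[mat.col])
        )
        mat.data = np.maximum(pmi, 0.0)
        out = mat.tocsr()
        out.eliminate_zeros()
        return out
    raise ValidationError(f"unknown weighting {weighting!r}")


def build_semantic_space(
    corpus: Sequence[Sequence[str]],
    context_mode: str = "document",
    dimensionality: int = 50,
    weighting: str = "raw",
) -> SemanticSpace:
    """Embed the corpus vocabulary by truncated SVD of co-occurrence counts.

    Parameters
    ----------
    corpus
        Preprocessed documents: sequences of normalized, stop-word-filtered
        tokens in original order (order matters for windowed modes).
    context_mode
        ``"document"`` (LSA-style term-document counts) or ``"window-2"`` /
        ``"window-20"`` (symmetric token windows).
    dimensionality
        Number of retained singular components; must not exceed the
        achievable rank of the count matrix.
    weighting
        ``"raw"``, ``"log-entropy"`` or ``"ppmi"`` reweighting of counts
        before decomposition.
    """
    docs = [list(d) for d in corpus if len(d) > 0]
    if not docs:
        raise ValidationError("corpus is empty after preprocessing")
    vocab = sorted({t for d in docs for t in d})
    vocab_index = {w: i for i, w in enumerate(vocab)}

    if context_mode == "document":
        mat = _document_counts(docs, vocab_index)
    elif context_mode in ("window-2", "window-20"):
        window = int(context_mode.split("-")[1])
        mat = _window_cooccurrence(docs, vocab_index, window)
    else:
        raise ValidationError(f"unknown context mode {context_mode!r}")

    mat = _apply_weighting(mat, weighting)

    max_rank = min(mat.shape) - 1
    if dimensionality < 1 or dimensionality > max_rank:
        raise RankDeficiencyError(dimensionality, max(max_rank, 0))
    u, s, _ = svds(mat.astype(float), k=dimensionality)
    order = np.argsort(s)[::-1]
    u, s = u[:, order], s[order]
    tol = max(mat.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    n_pos = int((s > tol).sum())
    if n_pos < dimensionality:
        raise RankDeficiencyError(dimensionality, n_pos)
    return SemanticSpace(
        vocabulary=tuple(vocab), vectors=u * s, context_mode=context_mode
    )


def passage_vector(
    tokens: Iterable[str],
    space: SemanticSpace,
    composition: Literal["sum", "mean"] = "sum",
) -> np.ndarray:
    """Compose a passage vector from its in-vocabulary word vectors.

    Out-of-vocabulary words contribute nothing.  Cosine similarity is
    invariant to the sum/mean choice; both are offered for completeness.
    """
    vecs = [space.vector(t) for t in tokens if t in space]
    if not vecs:
        return np.zeros(space.dimensionality)
    v = np.sum(vecs, axis=0)
    if composition == "mean":
        v = v / len(vecs)
    return v


def semantic_passage_similarity(
    a: TokenSet,
    b: TokenSet,
    space: SemanticSpace,
    composition: Literal["sum", "mean"] = "sum",
    on_empty: Literal["raise", "zero"] = "raise",
) -> float:
    """Cosine between the two passages' composed vectors, in [-1, 1].

    A passage with no in-vocabulary words is unrepresentable: by default an
    :class:`UnrepresentablePassageError` is raised; in batch mode
    (``on_empty="zero"``) the pair scores 0 with a warning.
    """
    va = passage_vector(a.tokens, space, composition)
    vb = passage_vector(b.tokens, space, composition)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        which = a.response_id if na == 0 else b.response_id
        if on_empty == "raise":
            raise UnrepresentablePassageError(
                f"passage {which!r} has no in-vocabulary words"
            )
        logger.warning("passage %s unrepresentable; scored 0", which)
        return 0.0
    return float(np.dot(va, vb) / (na * nb))


def mean_semantic_score(
    target: TokenSet,
    norm: NormativeSet,
    space: SemanticSpace,
    exclude_response_id: Optional[str] = None,
) -> float:
    """Mean cosine similarity between ``target`` and each normative member."""
    members = [m for m in norm.members if m.response_id != exclude_response_id]
    if not members:
        raise EmptyNormativeSetError(
            f"normative set for {norm.clip_id!r} is empty after exclusion"
        )
    return float(
        np.mean(
            [
                semantic_passage_similarity(target, m, space, on_empty="zero")
                for m in members
            ]
        )
    )


def score_responses(
    targets: Sequence[TokenSet],
    dataset: NormativeDataset,
    method: str = "shared-words",
    space: Optional[SemanticSpace] = None,
    exclude_self: bool = True,
) -> pd.DataFrame:
    """Score each target against the normative set of its own clip.

    Returns a table with columns ``response_id, clip_id, method, score``.
    Targets whose ``response_id`` occurs in the reference set are scored
    take-one-out when ``exclude_self`` is set.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    if method != "shared-words" and space is None:
        raise ValidationError(f"method {method!r} requires a semantic space")
    rows = []
    for ts in targets:
        if ts.clip_id not in dataset:
            raise ValidationError(f"clip {ts.clip_id!r} absent from reference dataset")
        norm = dataset[ts.clip_id]
        excl = None
        if exclude_self and any(m.response_id == ts.response_id for m in norm.members):
            excl = ts.response_id
        if method == "shared-words":
            score = mean_shared_word_score(ts, norm, exclude_response_id=excl)
        else:
            score = mean_semantic_score(ts, norm, space, exclude_response_id=excl)
        rows.append(
            {
                "response_id": ts.response_id,
                "clip_id": ts.clip_id,
                "method": method,
                "score": score,
            }
        )
    return pd.DataFrame(rows, columns=["response_id", "clip_id", "method", "score"])
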