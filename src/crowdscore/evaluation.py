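"""Evaluation machinery: take-one-out classification, cross-dataset
classification, normative-set-size resampling, and the saturating-curve fit.

Classification is the benchmark used to compare scoring methods: each
response is scored against every clip's normative set and assigned to the
clip with the highest mean similarity.  For responses that are themselves
part of the reference dataset, the response is removed from its own clip's
set before scoring (take-one-out), so a response never contributes to its
own comparison standard.  With C clips and uniformly random assignment the
chance rate is 1/C.

The resampling analysis asks how large the per-clip crowd needs to be:
classification is recomputed on random per-clip subsets of size n, and the
resulting accuracy-versus-n curve is summarized by a two-parameter
saturating exponential y(n) = A·(1 − exp(−n/τ)), whose 99%-of-asymptote
size is n99 = τ·ln(100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import curve_fit

from .errors import (
    DegenerateCurveError,
    EmptyNormativeSetError,
    FitConvergenceError,
    SmallClipError,
    ValidationError,
)
from .preprocessing import TokenSet
from .similarity import (
    METHODS,
    NormativeDataset,
    SemanticSpace,
    mean_shared_word_score,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationResult",
    "ResamplingCurve",
    "ExponentialFit",
    "ScoreErrorResult",
    "take_one_out_classify",
    "cross_dataset_classify",
    "resample_classification_curve",
    "fit_exponential",
    "score_error_distribution",
    "simulate_chance_rate",
]


@dataclass
class ClassificationResult:
    """Per-response predictions plus the aggregate fraction correct.

    ``table`` columns: response_id, true_clip_id, predicted_clip_id, score
    (the winning mean similarity), n_tied (how many clips attained the top
    score).  A response with a tied top score counts as correct only if the
    true clip is the *unique* maximum; this conservative rule avoids
    seed-dependent accuracies.
    """

    table: pd.DataFrame
    method: str

    @property
    def n_responses(self) -> int:
        return len(self.table)

    @property
    def fraction_correct(self) -> float:
        t = self.table
        correct = (t["n_tied"] == 1) & (t["predicted_clip_id"] == t["true_clip_id"])
        return float(correct.mean())


def _shared_word_score_matrix(
    targets: Sequence[TokenSet], reference: NormativeDataset
) -> tuple[np.ndarray, list[str]]:
    """Mean shared-word score of every target against every clip.

    Take-one-out exclusion is applied wherever a target's response_id occurs
    among the reference members of the same clip.  Vectorized as a sparse
    product of the binary target-by-vocabulary matrix with the per-clip
    token occurrence counts.
    """
    clip_ids = reference.clip_ids
    clip_index = {c: j for j, c in enumerate(clip_ids)}
    members = reference.responses()

    vocab: dict[str, int] = {}
    for ts in members:
        for t in ts.tokens:
            vocab.setdefault(t, len(vocab))
    for ts in targets:
        for t in ts.tokens:
            vocab.setdefault(t, len(vocab))
    n_v = max(len(vocab), 1)

    # member-id -> (clip column, token count) for exclusion bookkeeping
    member_info = {
        m.response_id: (clip_index[m.clip_id], len(m.tokens)) for m in members
    }

    # per-clip token occurrence counts T (vocab x clips)
    t_rows, t_cols, t_vals = [], [], []
    for m in members:
        j = clip_index[m.clip_id]
        for t in m.tokens:
            t_rows.append(vocab[t])
            t_cols.append(j)
            t_vals.append(1.0)
    T = sp.csr_matrix(
        (t_vals, (t_rows, t_cols)), shape=(n_v, len(clip_ids))
    ).toarray()

    x_rows, x_cols = [], []
    for i, ts in enumerate(targets):
        for t in ts.tokens:
            x_rows.append(i)
            x_cols.append(vocab[t])
    X = sp.csr_matrix(
        (np.ones(len(x_rows)), (x_rows, x_cols)), shape=(len(targets), n_v)
    )

    raw = X @ T  # total shared words with each clip's members
    sizes = np.array([len(reference[c]) for c in clip_ids], dtype=float)
    denom = np.tile(sizes, (len(targets), 1))
    for i, ts in enumerate(targets):
        info = member_info.get(ts.response_id)
        if info is not None:
            j, n_tok = info
            # the member row equals the target row, so X_i · X_i = |tokens_i|
            raw[i, j] -= n_tok
            denom[i, j] -= 1.0
    if np.any(denom <= 0):
        bad = sorted(
            {clip_ids[j] for j in np.unique(np.nonzero(denom <= 0)[1])}
        )
        raise EmptyNormativeSetError(
            f"take-one-out leaves empty normative sets for clips {bad}"
        )
    return raw / denom, clip_ids


def _semantic_score_matrix(
    targets: Sequence[TokenSet],
    reference: NormativeDataset,
    space: SemanticSpace,
) -> tuple[np.ndarray, list[str]]:
    """Mean cosine similarity of every target against every clip's members.

    Passages are embedded as unit-normalized sums of word vectors; the mean
    cosine against a clip is then a dot product with the sum of its members'
    unit vectors.  Unrepresentable passages (no in-vocabulary words) get a
    zero vector: they score 0 against everything and contribute 0 as
    members, with a warning.
    """

    def unit_rows(token_sets: Sequence[TokenSet]) -> np.ndarray:
        out = np.zeros((len(token_sets), space.dimensionality))
        n_empty = 0
        for i, ts in enumerate(token_sets):
            vecs = [space.vector(t) for t in ts.tokens if t in space]
            if not vecs:
                n_empty += 1
                continue
            v = np.sum(vecs, axis=0)
            nv = np.linalg.norm(v)
            if nv == 0:
                n_empty += 1
                continue
            out[i] = v / nv
        if n_empty:
            logger.warning("%d unrepresentable passages scored as 0", n_empty)
        return out

    clip_ids = reference.clip_ids
    clip_index = {c: j for j, c in enumerate(clip_ids)}
    members = reference.responses()
    P = unit_rows(targets)
    M = unit_rows(members)
    member_clip = np.array([clip_index[m.clip_id] for m in members])
    member_sums = np.zeros((len(clip_ids), space.dimensionality))
    np.add.at(member_sums, member_clip, M)

    raw = P @ member_sums.T
    sizes = np.array([len(reference[c]) for c in clip_ids], dtype=float)
    denom = np.tile(sizes, (len(targets), 1))
    member_row = {m.response_id: k for k, m in enumerate(members)}
    for i, ts in enumerate(targets):
        k = member_row.get(ts.response_id)
        if k is not None:
            j = int(member_clip[k])
            raw[i, j] -= float(P[i] @ M[k])
            denom[i, j] -= 1.0
    if np.any(denom <= 0):
        bad = sorted({clip_ids[j] for j in np.unique(np.nonzero(denom <= 0)[1])})
        raise EmptyNormativeSetError(
            f"take-one-out leaves empty normative sets for clips {bad}"
        )
    return raw / denom, clip_ids


def _classify(
    targets: Sequence[TokenSet],
    reference: NormativeDataset,
    method: str,
    space: Optional[SemanticSpace],
) -> ClassificationResult:
    if method not in METHODS:
        raise ValidationError(
            f"unknown method {method!r}; choose from {sorted(METHODS)}"
        )
    if method == "shared-words":
        scores, clip_ids = _shared_word_score_matrix(targets, reference)
    else:
        if space is None:
            raise ValidationError(f"method {method!r} requires a semantic space")
        scores, clip_ids = _semantic_score_matrix(targets, reference, space)

    best = scores.max(axis=1)
    tied = scores == best[:, None]
    n_tied = tied.sum(axis=1)
    pred_idx = scores.argmax(axis=1)
    n_tie_events = int((n_tied > 1).sum())
    if n_tie_events:
        logger.info(
            "%d responses had tied top scores (counted incorrect unless the "
            "true clip is the unique maximum)",
            n_tie_events,
        )
    table = pd.DataFrame(
        {
            "response_id": [t.response_id for t in targets],
            "true_clip_id": [t.clip_id for t in targets],
            "predicted_clip_id": [clip_ids[j] for j in pred_idx],
            "score": best,
            "n_tied": n_tied.astype(int),
        }
    )
    return ClassificationResult(table=table, method=method)


def take_one_out_classify(
    dataset: NormativeDataset,
    method: str = "shared-words",
    space: Optional[SemanticSpace] = None,
) -> ClassificationResult:
    """Classify every dataset response against all clips, self excluded.

    Each response is removed from its own clip's normative set, scored
    against every clip, and assigned to the clip with the highest mean
    similarity.  Requires every clip to have at least 2 responses.
    """
    small = [c for c, n in dataset.sizes().items() if n < 2]
    if small:
        raise SmallClipError(
            f"clips with fewer than 2 responses cannot be scored take-one-out: {small}"
        )
    return _classify(dataset.responses(), dataset, method, space)


def cross_dataset_classify(
    targets: NormativeDataset | Sequence[TokenSet],
    reference: NormativeDataset,
    method: str = "shared-words",
    space: Optional[SemanticSpace] = None,
) -> ClassificationResult:
    """Classify one dataset's responses against another dataset's clips.

    Any target whose response_id also occurs in the reference pool (e.g.
    when classifying against a pooled dataset built with
    :meth:`NormativeDataset.merged`) is scored take-one-out; disjoint
    targets are scored against full sets.  Every target clip must exist in
    the reference.
    """
    target_list = (
        targets.responses() if isinstance(targets, NormativeDataset) else list(targets)
    )
    if not target_list:
        raise ValidationError("no target responses to classify")
    missing = sorted({t.clip_id for t in target_list} - set(reference.clip_ids))
    if missing:
        raise ValidationError(
            f"target clips absent from reference dataset: {missing}"
        )
    return _classify(target_list, reference, method, space)


@dataclass
class ResamplingCurve:
    """Classification accuracy as a function of normative-set size n.

    ``fractions[i, r]`` is the fraction correct for ``n_values[i]`` in
    replicate ``r``; per-replicate values are kept so successive n can be
    compared with paired standard errors.
    """

    n_values: tuple[int, ...]
    fractions: np.ndarray
    replicates: int
    seed: int
    method: str

    @property
    def mean_fraction_correct(self) -> np.ndarray:
        return self.fractions.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, n in enumerate(self.n_values):
            for r in range(self.replicates):
                rows.append(
                    {"n": n, "replicate": r, "fraction_correct": self.fractions[i, r]}
                )
        return pd.DataFrame(rows, columns=["n", "replicate", "fraction_correct"])


def resample_classification_curve(
    dataset: NormativeDataset,
    n_values: Sequence[int],
    replicates: int,
    seed: int,
    method: str = "shared-words",
    space: Optional[SemanticSpace] = None,
) -> ResamplingCurve:
    """Take-one-out accuracy on random per-clip subsets of each size n.

    For every replicate an independent subsample of n responses per clip is
    drawn without replacement; take-one-out classification runs on the
    subsampled dataset (its own responses are both targets and reference).
    Fully reproducible from ``seed``.
    """
    n_values = tuple(int(n) for n in n_values)
    if not n_values or replicates < 1:
        raise ValidationError("need at least one n value and one replicate")
    min_size = min(dataset.sizes().values())
    bad = [n for n in n_values if n < 2 or n > min_size]
    if bad:
        raise ValidationError(
            f"n values {bad} outside the valid range [2, {min_size}]"
        )
    rng = np.random.default_rng(seed)
    fractions = np.empty((len(n_values), replicates))
    for i, n in enumerate(n_values):
        for r in range(replicates):
            sub = dataset.subsample(n, rng)
            fractions[i, r] = take_one_out_classify(sub, method, space).fraction_correct
    return ResamplingCurve(
        n_values=n_values,
        fractions=fractions,
        replicates=replicates,
        seed=seed,
        method=method,
    )


@dataclass
class ExponentialFit:
    """Least-squares fit of y(n) = A·(1 − exp(−n/τ)).

    ``n99 = τ·ln(100)`` is the set size at which the curve reaches 99% of
    its asymptote A; it is a closed-form function of τ, not a third
    parameter.
    """

    asymptote: float
    tau: float
    n99: float
    residual_norm: float


def fit_exponential(
    curve: ResamplingCurve | Sequence[float],
    y: Optional[Sequence[float]] = None,
) -> ExponentialFit:
    """Fit the saturating exponential to per-n mean accuracies.

    Accepts either a :class:`ResamplingCurve` (fitted to its per-n means) or
    explicit ``(n, y)`` arrays.  y may be fractions or percentages; A simply
    scales with the units.  Initialization: A₀ = max(y), τ₀ = half the n
    range; both parameters bounded positive.
    """
    if isinstance(curve, ResamplingCurve):
        n = np.asarray(curve.n_values, dtype=float)
        yv = curve.mean_fraction_correct
    else:
        if y is None:
            raise ValidationError("explicit fit needs both n and y")
        n = np.asarray(curve, dtype=float)
        yv = np.asarray(y, dtype=float)
    if n.size < 3:
        raise DegenerateCurveError("need at least 3 points to fit 2 parameters")
    if np.allclose(yv, yv[0]):
        raise DegenerateCurveError("flat curve: asymptote and rate are unidentifiable")

    def model(x, a, tau):
        return a * (1.0 - np.exp(-x / tau))

    a0 = float(yv.max())
    tau0 = max((n.max() - n.min()) / 2.0, 1e-6)
    try:
        popt, _ = curve_fit(
            model,
            n,
            yv,
            p0=(a0 if a0 > 0 else 1.0, tau0),
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitConvergenceError(f"exponential fit did not converge: {exc}") from exc
    a_hat, tau_hat = float(popt[0]), float(popt[1])
    resid = float(np.linalg.norm(yv - model(n, a_hat, tau_hat)))
    return ExponentialFit(
        asymptote=a_hat, tau=tau_hat, n99=tau_hat * np.log(100.0), residual_norm=resid
    )


@dataclass
class ScoreErrorResult:
    """Subset-score errors relative to full-dataset scores.

    ``samples`` columns: response_id, n, replicate, error where
    error = (score against the size-n subsample) − (score against the full
    dataset), both computed take-one-out.  ``summary`` holds per-n mean, SD
    and interquartile range of the pooled errors.
    """

    samples: pd.DataFrame
    summary: pd.DataFrame
    seed: int


def score_error_distribution(
    dataset: NormativeDataset,
    n_values: Sequence[int],
    replicates: int,
    seed: int,
) -> ScoreErrorResult:
    """Distribution of shared-word score error for reduced normative sets.

    For each replicate a per-clip subsample of size n is drawn (the same
    scheme as the classification curve); every response of the clip is then
    scored against the subsample, excluding itself if it was drawn, and the
    error relative to its full-dataset take-one-out score is recorded.  At
    n = full clip size the subsample is the whole set and every error is
    exactly 0.
    """
    n_values = tuple(int(n) for n in n_values)
    min_size = min(dataset.sizes().values())
    bad = [n for n in n_values if n < 2 or n > min_size]
    if bad:
        raise ValidationError(f"n values {bad} outside the valid range [2, {min_size}]")
    small = [c for c, n in dataset.sizes().items() if n < 2]
    if small:
        raise SmallClipError(f"clips too small for take-one-out: {small}")

    full_scores: dict[str, float] = {}
    for cid in dataset.clip_ids:
        norm = dataset[cid]
        for m in norm.members:
            full_scores[m.response_id] = mean_shared_word_score(
                m, norm, exclude_response_id=m.response_id
            )

    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        for r in range(replicates):
            for cid in dataset.clip_ids:
                members = dataset[cid].members
                idx = rng.choice(len(members), size=n, replace=False)
                chosen = [members[i] for i in sorted(idx)]
                chosen_ids = {m.response_id for m in chosen}
                # token -> number of chosen members containing it
                counts: dict[str, int] = {}
                for m in chosen:
                    for t in m.tokens:
                        counts[t] = counts.get(t, 0) + 1
                for m in members:
                    total = sum(counts.get(t, 0) for t in m.tokens)
                    if m.response_id in chosen_ids:
                        total -= len(m.tokens)
                        denom = n - 1
                    else:
                        denom = n
                    if denom == 0:
                        continue  # n=1 subsample containing the target itself
                    err = total / denom - full_scores[m.response_id]
                    rows.append(
                        {
                            "response_id": m.response_id,
                            "n": n,
                            "replicate": r,
                            "error": err,
                        }
                    )
    samples = pd.DataFrame(rows, columns=["response_id", "n", "replicate", "error"])
    gb = samples.groupby("n")["error"]
    summary = pd.DataFrame(
        {
            "n": list(gb.groups),
            "mean_error": gb.mean().to_numpy(),
            "sd_error": gb.std(ddof=1).to_numpy(),
            "iqr_error": (gb.quantile(0.75) - gb.quantile(0.25)).to_numpy(),
        }
    )
    return ScoreErrorResult(samples=samples, summary=summary, seed=seed)


def simulate_chance_rate(
    n_clips: int, n_assignments: int = 100_000, seed: int = 0
) -> float:
    """Empirical accuracy of uniformly random clip assignment.

    The analytic chance floor for C clips is 1/C; this Monte-Carlo check
    draws ``n_assignments`` uniform predictions against fixed true labels.
    """
    if n_clips < 1 or n_assignments < 1:
        raise ValidationError("n_clips and n_assignments must be positive")
    rng = np.random.default_rng(seed)
    true = rng.integers(0, n_clips, size=n_assignments)
    pred = rng.integers(0, n_clips, size=n_assignments)
    return float(np.mean(true == pred))
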