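"""Trend and contrast statistics for scores across ordered degradation levels.

A valid measure of information acquisition must fall as the stimulus (or the
observer's view of it) is degraded in ordered steps — a dose-response
effect.  Two complementary tests are provided on a table of scored trials
(one row per subject × clip × condition):

* :func:`spearman_trend` — the uncorrected Spearman rank correlation
  between condition rank and score, pooling all trials, with a permutation
  p-value.
* :func:`stratified_condition_contrast` — a two-condition mean-difference
  test whose null distribution permutes condition labels only *within* each
  subject's own trials, honoring the fully-crossed design in which subject
  and clip are random factors.

Permutation p-values use the add-one estimator (b + 1)/(m + 1), which is
never exactly zero and is valid (stochastically larger than uniform) under
the null by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantScoresError, MissingStrataError, ValidationError
from .preprocessing import RawResponse, StopWordList, preprocess_responses
from .similarity import NormativeDataset, score_responses

logger = logging.getLogger(__name__)

__all__ = [
    "TrendResult",
    "ContrastResult",
    "TRIAL_COLUMNS",
    "validate_trials",
    "score_study",
    "spearman_trend",
    "stratified_condition_contrast",
]

TRIAL_COLUMNS = ["subject_id", "clip_id", "condition", "rank", "score"]


@dataclass(frozen=True)
class TrendResult:
    """Spearman trend of score against condition rank."""

    rho: float
    p_value: float
    permutations: int
    seed: Optional[int]


@dataclass(frozen=True)
class ContrastResult:
    """Stratified permutation contrast between two conditions."""

    condition_a: str
    condition_b: str
    mean_difference: float  # mean(a) - mean(b)
    p_value: float
    permutations: int
    n_strata: int
    seed: Optional[int]


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the scored-trial table invariants and return it.

    Requires the columns of :data:`TRIAL_COLUMNS`; each (subject, clip)
    pair may appear at most once per condition; scores must be numeric.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    dup = trials.duplicated(subset=["subject_id", "clip_id", "condition"])
    if dup.any():
        pairs = trials.loc[dup, ["subject_id", "clip_id", "condition"]]
        raise ValidationError(
            f"duplicate (subject, clip, condition) trials:\n{pairs.to_string(index=False)}"
        )
    if trials["score"].isna().any():
        raise ValidationError("trial table contains missing scores")
    return trials


def score_study(
    responses: Sequence[RawResponse],
    reference: NormativeDataset,
    stoplist: StopWordList,
    rank_map: dict[str, int],
    method: str = "shared-words",
    space=None,
) -> pd.DataFrame:
    """Score experiment responses against a normative dataset into a trial table.

    Each response is preprocessed with ``stoplist`` and scored against its
    own clip's normative set (take-one-out applies automatically only if the
    response_id occurs in the reference).  ``rank_map`` assigns each
    condition label its dose order; the package does not parse acuity
    notation, the caller states the order.
    """
    token_sets = preprocess_responses(responses, stoplist)
    scores = score_responses(token_sets, reference, method=method, space=space)
    by_id = {r.response_id: r for r in responses}
    rows = []
    for rec in scores.itertuples(index=False):
        raw = by_id[rec.response_id]
        if raw.condition not in rank_map:
            raise ValidationError(
                f"condition {raw.condition!r} has no entry in rank_map"
            )
        rows.append(
            {
                "subject_id": raw.subject_id,
                "clip_id": raw.clip_id,
                "condition": raw.condition,
                "rank": rank_map[raw.condition],
                "score": rec.score,
            }
        )
    return validate_trials(pd.DataFrame(rows, columns=TRIAL_COLUMNS))


def spearman_trend(
    trials: pd.DataFrame,
    permutations: int = 10_000,
    seed: Optional[int] = None,
) -> TrendResult:
    """Spearman rank correlation between condition rank and score.

    Ties are handled by midranks.  The two-sided p-value permutes scores
    across all trials (the uncorrected, pooled analysis), comparing |rho|
    of each permutation to the observed |rho|.
    """
    trials = validate_trials(trials)
    if trials["condition"].nunique() < 2 or trials["rank"].nunique() < 2:
        raise ValidationError("need at least 2 distinct condition ranks")
    if len(trials) < 3:
        raise ValidationError("need at least 3 trials")
    scores = trials["score"].to_numpy(dtype=float)
    ranks = trials["rank"].to_numpy(dtype=float)
    if np.allclose(scores, scores[0]):
        raise ConstantScoresError("all scores identical; rho is undefined")
    if permutations < 1:
        raise ValidationError("permutations must be >= 1")

    rho = float(stats.spearmanr(ranks, scores).statistic)

    # Spearman rho is the Pearson correlation of midranks; with the rank-x
    # vector fixed, permuting scores permutes their midranks, so the null
    # distribution is a matrix product with permuted midrank rows.
    rx = stats.rankdata(ranks)
    ry = stats.rankdata(scores)
    u = rx - rx.mean()
    u = u / np.linalg.norm(u)
    v = ry - ry.mean()
    v = v / np.linalg.norm(v)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(
        np.broadcast_to(v, (permutations, v.size)).copy(), axis=1
    )
    null_rho = perm @ u
    b = int(np.sum(np.abs(null_rho) >= abs(rho) - 1e-12))
    p = (b + 1) / (permutations + 1)
    return TrendResult(rho=rho, p_value=p, permutations=permutations, seed=seed)


def stratified_condition_contrast(
    trials: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    permutations: int = 10_000,
    seed: Optional[int] = None,
) -> ContrastResult:
    """Permutation test of the mean score difference between two conditions.

    The statistic is mean(score | a) − mean(score | b) over all trials in
    the two conditions.  The null distribution shuffles the condition
    labels *within each subject's trials* (each subject's clip set is fixed
    by design, so the subject is the stratum), preserving each subject's
    number of a- and b-trials.  Two-sided p with the add-one estimator.
    """
    trials = validate_trials(trials)
    sub = trials[trials["condition"].isin([condition_a, condition_b])]
    for cond in (condition_a, condition_b):
        if not (sub["condition"] == cond).any():
            raise ValidationError(f"condition {cond!r} absent from trial table")
    if permutations < 1:
        raise ValidationError("permutations must be >= 1")

    strata = []
    for _, grp in sub.groupby("subject_id"):
        conds = set(grp["condition"])
        if condition_a in conds and condition_b in conds:
            strata.append(grp)
    if not strata:
        raise MissingStrataError(
            f"no subject has trials in both {condition_a!r} and {condition_b!r}"
        )
    kept = pd.concat(strata)
    n_a = int((kept["condition"] == condition_a).sum())
    n_b = int((kept["condition"] == condition_b).sum())
    observed = float(
        kept.loc[kept["condition"] == condition_a, "score"].mean()
        - kept.loc[kept["condition"] == condition_b, "score"].mean()
    )

    # Within-stratum label shuffles keep each subject's a/b counts fixed, so
    # sum(a-scores) across strata determines the statistic:
    #   diff = S_a / n_a - (S_total - S_a) / n_b
    rng = np.random.default_rng(seed)
    total = float(kept["score"].sum())
    s_a = np.zeros(permutations)
    for grp in strata:
        x = grp["score"].to_numpy(dtype=float)
        k = int((grp["condition"] == condition_a).sum())
        tiled = rng.permuted(np.broadcast_to(x, (permutations, x.size)).copy(), axis=1)
        s_a += tiled[:, :k].sum(axis=1)
    null = s_a / n_a - (total - s_a) / n_b
    b = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    p = (b + 1) / (permutations + 1)
    return ContrastResult(
        condition_a=condition_a,
        condition_b=condition_b,
        mean_difference=observed,
        p_value=p,
        permutations=permutations,
        n_strata=len(strata),
        seed=seed,
    )
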