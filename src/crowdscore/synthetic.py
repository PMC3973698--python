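"""Synthetic normative datasets with the structure the scoring method assumes.

Real free-recall crowds have a characteristic shape: a handful of salient
details of each stimulus are mentioned by most viewers, many peripheral
details are mentioned by a minority, and some vocabulary (generic scene
words) is shared across stimuli.  The generator models each clip as a
vocabulary of abstract word tokens with per-word mention probabilities:

* ``n_core`` core words mentioned with high probability ``p_core``;
* ``n_peripheral`` peripheral words at low probability ``p_peripheral``;
* a distractor pool shared across *all* clips at ``p_distractor``,
  emulating generic vocabulary that carries no clip information;
* optionally a fraction of core/peripheral slots filled from shared pools
  (``overlap_fraction``), emulating clips with common content.

Word mentions are independent Bernoulli draws, which keeps the expected
mean shared-word score available in closed form
(:func:`expected_mean_score`) for exact oracle tests.  Subjects carry a
verbosity multiplier on all mention probabilities and an idiosyncrasy rate:
the probability that a mentioned word is replaced by that subject's private
synonym token, modeling viewers with distinctive vocabulary whose responses
diverge from the crowd.

Degradation (the analogue of viewing through defocus lenses) multiplies
every mention probability by a retention factor r ∈ [0, 1]: blur removes
acquired detail rather than words per se, so the response gets sparser, not
merely shorter.

Words are abstract tokens like ``clip017core03``; the scorer is
string-agnostic and abstract tokens make the analytic oracles exact.
Responses are serialized as text with shuffled word order and interleaved
filler stop words, so the preprocessing stage has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .preprocessing import RawResponse

__all__ = [
    "ClipVocabularyModel",
    "SubjectModel",
    "DegradationLevel",
    "GeneratorConfig",
    "DEFAULT_DEGRADATION_LEVELS",
    "build_clip_models",
    "generate_normative_dataset",
    "generate_degraded_responses",
    "generate_dose_response_study",
    "expected_mean_score",
    "level_ranks",
]

# Filler stop words interleaved into serialized responses.
_FILLERS = ("the", "a", "and", "of", "um", "it", "was", "there", "sorry")


@dataclass(frozen=True)
class ClipVocabularyModel:
    """Generative word-mention probabilities for one synthetic stimulus."""

    clip_id: str
    core_words: tuple[str, ...]
    p_core: float
    peripheral_words: tuple[str, ...]
    p_peripheral: float
    distractor_words: tuple[str, ...] = ()
    p_distractor: float = 0.0

    def __post_init__(self):
        for p in (self.p_core, self.p_peripheral, self.p_distractor):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"mention probability {p} outside [0, 1]")
        own = list(self.core_words) + list(self.peripheral_words)
        if len(own) != len(set(own)):
            raise ValidationError(f"duplicate words within clip {self.clip_id!r}")

    def word_probability_pairs(self) -> list[tuple[str, float]]:
        return (
            [(w, self.p_core) for w in self.core_words]
            + [(w, self.p_peripheral) for w in self.peripheral_words]
            + [(w, self.p_distractor) for w in self.distractor_words]
        )


@dataclass(frozen=True)
class SubjectModel:
    """Per-subject response style.

    ``verbosity`` multiplies every mention probability (capped at 1);
    ``idiosyncrasy`` is the probability that a mentioned word is replaced by
    the subject's private synonym for it.  A private synonym is stable per
    (subject, word), so an idiosyncratic subject is *consistently*
    idiosyncratic, as real distinctive-vocabulary subjects are.
    """

    subject_id: str
    verbosity: float = 1.0
    idiosyncrasy: float = 0.0

    def __post_init__(self):
        if self.verbosity <= 0:
            raise ValidationError("verbosity multiplier must be positive")
        if not 0.0 <= self.idiosyncrasy <= 1.0:
            raise ValidationError("idiosyncrasy rate outside [0, 1]")


@dataclass(frozen=True)
class DegradationLevel:
    """One ordered degradation condition (e.g. an induced acuity level).

    ``retention`` r multiplies every mention probability; r = 1 is the
    undegraded condition.
    """

    label: str
    retention: float

    def __post_init__(self):
        if not 0.0 <= self.retention <= 1.0:
            raise ValidationError("retention must lie in [0, 1]")


#: Five ordered conditions labelled with the Snellen acuities of the defocus
#: design they emulate.  Retentions are a synthetic knob, not a calibrated
#: acuity model: mild blur spares most salient content, severe blur removes
#: about half of the reportable detail.
DEFAULT_DEGRADATION_LEVELS = (
    DegradationLevel("20/20", 1.0),
    DegradationLevel("20/50", 0.9),
    DegradationLevel("20/125", 0.8),
    DegradationLevel("20/320", 0.65),
    DegradationLevel("20/800", 0.5),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror a lab-style normative collection: 200 clips with 12
    responses each from a roster of 60 subjects, five salient details per
    clip mentioned by most viewers (p = 0.8) and twenty peripheral details
    mentioned by a minority (p = 0.15), plus a shared pool of generic
    distractor vocabulary and a 20% cross-clip overlap of content words.
    """

    n_clips: int = 200
    responses_per_clip: int = 12
    n_core: int = 5
    p_core: float = 0.8
    n_peripheral: int = 20
    p_peripheral: float = 0.15
    distractor_pool_size: int = 150
    p_distractor: float = 0.02
    overlap_fraction: float = 0.2
    n_subjects: int = 60
    verbosity_sd: float = 0.0
    idiosyncrasy: float = 0.0
    degradation_levels: tuple[DegradationLevel, ...] = DEFAULT_DEGRADATION_LEVELS

    def __post_init__(self):
        for name in ("n_clips", "responses_per_clip", "n_core", "n_subjects"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.n_peripheral < 0 or self.distractor_pool_size < 0:
            raise ValidationError("pool sizes must be non-negative")
        for name in ("p_core", "p_peripheral", "p_distractor", "overlap_fraction",
                     "idiosyncrasy"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]")
        if self.verbosity_sd < 0:
            raise ValidationError("verbosity_sd must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        levels = d.pop("degradation_levels", None)
        if levels is not None:
            d["degradation_levels"] = tuple(
                DegradationLevel(str(lv["label"]), float(lv["retention"]))
                for lv in levels
            )
        return cls(**d)


def build_clip_models(config: GeneratorConfig) -> list[ClipVocabularyModel]:
    """Construct the per-clip vocabulary models (deterministic, no RNG).

    With ``overlap_fraction`` f, round(f·n_core) core slots and
    round(f·n_peripheral) peripheral slots are filled from pools shared by
    every clip; remaining slots get clip-specific words.
    """
    n_shared_core = round(config.overlap_fraction * config.n_core)
    n_shared_peri = round(config.overlap_fraction * config.n_peripheral)
    shared_core = tuple(f"sharedcore{i:02d}" for i in range(n_shared_core))
    shared_peri = tuple(f"sharedperi{i:02d}" for i in range(n_shared_peri))
    distractors = tuple(
        f"distr{i:03d}" for i in range(config.distractor_pool_size)
    )
    models = []
    for c in range(config.n_clips):
        cid = f"clip{c:03d}"
        # tokens are purely alphanumeric so text normalization keeps them whole
        core = shared_core + tuple(
            f"{cid}core{i:02d}" for i in range(config.n_core - n_shared_core)
        )
        peri = shared_peri + tuple(
            f"{cid}peri{i:02d}" for i in range(config.n_peripheral - n_shared_peri)
        )
        models.append(
            ClipVocabularyModel(
                clip_id=cid,
                core_words=core,
                p_core=config.p_core,
                peripheral_words=peri,
                p_peripheral=config.p_peripheral,
                distractor_words=distractors,
                p_distractor=config.p_distractor,
            )
        )
    return models


def _subject_roster(config: GeneratorConfig, rng: np.random.Generator) -> list[SubjectModel]:
    # verbosity multipliers are lognormal around 1; drawn even when sd=0 so
    # the RNG stream (hence all downstream draws) does not depend on sd
    draws = rng.normal(0.0, 1.0, size=config.n_subjects)
    return [
        SubjectModel(
            subject_id=f"subj{i:03d}",
            verbosity=float(np.exp(config.verbosity_sd * draws[i])),
            idiosyncrasy=config.idiosyncrasy,
        )
        for i in range(config.n_subjects)
    ]


def _emit_words(
    model: ClipVocabularyModel,
    subject: SubjectModel,
    retention: float,
    rng: np.random.Generator,
) -> list[str]:
    pairs = model.word_probability_pairs()
    probs = np.minimum(
        np.array([p for _, p in pairs]) * subject.verbosity * retention, 1.0
    )
    hits = rng.random(len(pairs)) < probs
    words = [pairs[i][0] for i in np.nonzero(hits)[0]]
    if subject.idiosyncrasy > 0 and words:
        swap = rng.random(len(words)) < subject.idiosyncrasy
        words = [
            f"{subject.subject_id}x{w}" if s else w for w, s in zip(words, swap)
        ]
    return words


def _serialize(words: Sequence[str], rng: np.random.Generator) -> str:
    """Shuffle words and interleave filler stop words into a text line."""
    words = list(words)
    rng.shuffle(words)
    n_fill = int(rng.binomial(len(words) + 1, 0.35))
    for _ in range(n_fill):
        pos = int(rng.integers(0, len(words) + 1))
        words.insert(pos, _FILLERS[int(rng.integers(0, len(_FILLERS)))])
    if not words:
        return ""
    text = " ".join(words)
    return text[0].upper() + text[1:] + "."


def _generate(
    config: GeneratorConfig,
    retention: float,
    label: str,
    seed: int,
) -> tuple[list[RawResponse], dict[str, list[str]]]:
    rng = np.random.default_rng(seed)
    models = build_clip_models(config)
    roster = _subject_roster(config, rng)
    prefix = label.replace("/", "-") + "_" if label else ""
    responses: list[RawResponse] = []
    truth: dict[str, list[str]] = {}
    slot = 0
    for model in models:
        for r in range(config.responses_per_clip):
            subject = roster[slot % len(roster)]
            slot += 1
            words = _emit_words(model, subject, retention, rng)
            rid = f"{prefix}{model.clip_id}_r{r:02d}"
            responses.append(
                RawResponse(
                    response_id=rid,
                    clip_id=model.clip_id,
                    subject_id=subject.subject_id,
                    condition=label,
                    text=_serialize(words, rng),
                )
            )
            truth[rid] = words
    return responses, truth


def generate_normative_dataset(
    config: GeneratorConfig, seed: int, return_truth: bool = False
):
    """Generate the undegraded normative response table.

    Each clip × response slot draws every model word independently with its
    (verbosity-adjusted) probability; the subject roster is assigned
    round-robin.  Byte-identical output for identical (config, seed).  With
    ``return_truth`` the per-response list of emitted model words is
    returned alongside, for ground-truth assertions.
    """
    responses, truth = _generate(config, retention=1.0, label="", seed=seed)
    return (responses, truth) if return_truth else responses


def generate_degraded_responses(
    config: GeneratorConfig,
    level: DegradationLevel,
    seed: int,
    return_truth: bool = False,
):
    """Generate responses under one degradation level.

    Identical to the normative generator except every mention probability is
    multiplied by ``level.retention`` and the condition field carries the
    level label.  With r = 1 and an empty label this reproduces
    :func:`generate_normative_dataset` exactly at the same seed.
    """
    responses, truth = _generate(
        config, retention=level.retention, label=level.label, seed=seed
    )
    return (responses, truth) if return_truth else responses


def generate_dose_response_study(
    config: GeneratorConfig,
    levels: Optional[Sequence[DegradationLevel]] = None,
    n_subjects: int = 15,
    trials_per_level: int = 4,
    seed: int = 0,
) -> list[RawResponse]:
    """Simulate a within-subject degradation experiment.

    Each of ``n_subjects`` fresh subjects (not in the normative roster)
    views ``trials_per_level × len(levels)`` distinct clips, with levels
    assigned in shuffled order across that subject's clips — the synthetic
    analogue of switching defocus lenses between trials.  Returns responses
    whose ``condition`` field is the level label.
    """
    levels = tuple(levels if levels is not None else config.degradation_levels)
    if not levels:
        raise ValidationError("at least one degradation level required")
    n_trials = trials_per_level * len(levels)
    if n_trials > config.n_clips:
        raise ValidationError(
            f"{n_trials} trials per subject exceed {config.n_clips} clips"
        )
    rng = np.random.default_rng(seed)
    models = build_clip_models(config)
    responses: list[RawResponse] = []
    for s in range(n_subjects):
        subject = SubjectModel(
            subject_id=f"dsub{s:02d}",
            verbosity=float(
                np.exp(config.verbosity_sd * rng.normal(0.0, 1.0))
            ),
            idiosyncrasy=config.idiosyncrasy,
        )
        clip_idx = rng.choice(config.n_clips, size=n_trials, replace=False)
        level_seq = np.repeat(np.arange(len(levels)), trials_per_level)
        rng.shuffle(level_seq)
        for t, (ci, li) in enumerate(zip(clip_idx, level_seq)):
            model = models[int(ci)]
            level = levels[int(li)]
            words = _emit_words(model, subject, level.retention, rng)
            rid = f"{subject.subject_id}_t{t:02d}"
            responses.append(
                RawResponse(
                    response_id=rid,
                    clip_id=model.clip_id,
                    subject_id=subject.subject_id,
                    condition=level.label,
                    text=_serialize(words, rng),
                )
            )
    return responses


def level_ranks(levels: Iterable[DegradationLevel]) -> dict[str, int]:
    """Map level labels to their 0-based dose order (as supplied)."""
    return {lv.label: i for i, lv in enumerate(levels)}


def expected_mean_score(
    model: ClipVocabularyModel,
    r_target: float = 1.0,
    r_norm: float = 1.0,
    norm_size: Optional[int] = None,
) -> float:
    """Closed-form expectation of the mean shared-word score.

    With independent mentions, a word with probability p is in both the
    target (at retention r_target) and a given normative member (at
    retention r_norm) with probability (p·r_target)(p·r_norm); summing over
    model words gives the expected pairwise intersection, and the mean over
    i.i.d. members has the same expectation regardless of ``norm_size``
    (accepted for interface symmetry, unused).  Assumes unit verbosity and
    zero idiosyncrasy.
    """
    del norm_size
    total = 0.0
    for _, p in model.word_probability_pairs():
        total += min(p * r_target, 1.0) * min(p * r_norm, 1.0)
    return total
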