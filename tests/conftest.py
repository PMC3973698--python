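import pytest

import crowdscore as cs
from crowdscore.preprocessing import TokenSet


def make_ts(tokens, rid="r0", cid="c0", sid="s0", cond=""):
    """Shorthand TokenSet constructor for hand-built fixtures."""
    return TokenSet(
        response_id=rid,
        clip_id=cid,
        subject_id=sid,
        condition=cond,
        tokens=frozenset(tokens),
    )


@pytest.fixture(scope="session")
def stoplist():
    return cs.default_stop_words()


@pytest.fixture(scope="session")
def small_config():
    # small heterogeneous crowd: enough structure for classification to be
    # non-trivial but fast to regenerate
    return cs.GeneratorConfig(
        n_clips=8,
        responses_per_clip=6,
        n_subjects=10,
        idiosyncrasy=0.2,
        verbosity_sd=0.3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, stoplist):
    responses = cs.generate_normative_dataset(small_config, seed=11)
    return cs.NormativeDataset.from_responses(responses, stoplist)
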