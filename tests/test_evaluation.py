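"""Take-one-out classification, resampling curves and the saturating fit."""

import numpy as np
import pytest

import crowdscore as cs
from conftest import make_ts
from crowdscore.errors import (
    DegenerateCurveError,
    SmallClipError,
    ValidationError,
)
from crowdscore.evaluation import (
    fit_exponential,
    resample_classification_curve,
    score_error_distribution,
    simulate_chance_rate,
    take_one_out_classify,
    cross_dataset_classify,
)
from crowdscore.similarity import NormativeDataset, mean_shared_word_score


def dataset_from_vocab(spec):
    """spec: {clip_id: [token-set, ...]}"""
    ts = []
    for cid, members in spec.items():
        for i, toks in enumerate(members):
            ts.append(make_ts(toks, rid=f"{cid}_m{i}", cid=cid))
    return NormativeDataset.from_token_sets(ts)


class TestTakeOneOut:
    def test_disjoint_identical_clips_classify_perfectly(self):
        ds = dataset_from_vocab(
            {
                "c0": [{"boat", "sea"}] * 3,
                "c1": [{"dog", "park"}] * 3,
            }
        )
        res = take_one_out_classify(ds)
        assert res.fraction_correct == 1.0

    def test_matches_brute_force_on_constructed_dataset(self):
        # 3 clips x 3 responses with one deliberately ambiguous response
        spec = {
            "c0": [{"boat", "sea", "wave"}, {"boat", "sea"}, {"boat", "wave", "dock"}],
            "c1": [{"dog", "park", "ball"}, {"dog", "ball"}, {"dog", "park", "leash"}],
            # c2_m2 mentions mostly c0 vocabulary: ambiguous on purpose
            "c2": [{"cat", "roof", "moon"}, {"cat", "moon"}, {"boat", "sea", "cat"}],
        }
        ds = dataset_from_vocab(spec)
        res = take_one_out_classify(ds)

        # independent brute force over all pairwise scores
        for row in res.table.itertuples(index=False):
            target = next(
                m for m in ds.responses() if m.response_id == row.response_id
            )
            scores = {}
            for cid in ds.clip_ids:
                excl = row.response_id if cid == target.clip_id else None
                scores[cid] = mean_shared_word_score(
                    target, ds[cid], exclude_response_id=excl
                )
            best = max(scores.values())
            winners = [c for c, s in scores.items() if s == best]
            assert row.predicted_clip_id in winners
            assert row.n_tied == len(winners)
            assert row.score == pytest.approx(best)

    def test_own_response_never_compared_to_itself(self):
        # a unique response whose clip-mates share nothing with it would get
        # score |tokens| from itself; take-one-out must score it 0
        ds = dataset_from_vocab(
            {
                "c0": [{"unique", "words"}, {"other", "stuff"}, {"other", "thing"}],
                "c1": [{"dog"}, {"dog"}],
            }
        )
        res = take_one_out_classify(ds)
        row = res.table.set_index("response_id").loc["c0_m0"]
        assert row.score == 0.0  # would be 2.0 if compared to itself

    def test_tied_top_score_counts_as_incorrect(self):
        ds = dataset_from_vocab(
            {
                "c0": [{"x", "boat"}, {"x", "boat"}],
                "c1": [{"x", "dog"}, {"x", "dog"}],
            }
        )
        res = take_one_out_classify(ds)
        # every response shares exactly {x, boat}/{x} -> own mean 2, other 1
        assert res.fraction_correct == 1.0
        ds_tie = dataset_from_vocab(
            {
                "c0": [{"x"}, {"x"}],
                "c1": [{"x"}, {"x"}],
            }
        )
        res_tie = take_one_out_classify(ds_tie)
        assert (res_tie.table["n_tied"] == 2).all()
        assert res_tie.fraction_correct == 0.0

    def test_single_response_clip_rejected(self):
        ds = dataset_from_vocab({"c0": [{"a"}], "c1": [{"b"}, {"c"}]})
        with pytest.raises(SmallClipError):
            take_one_out_classify(ds)

    def test_semantic_method_requires_space(self, small_dataset):
        with pytest.raises(ValidationError):
            take_one_out_classify(small_dataset, method="lsa")

    def test_semantic_classification_on_separable_clips(self):
        ds = dataset_from_vocab(
            {
                "c0": [{"boat", "sea"}, {"boat", "wave"}, {"sea", "wave"}],
                "c1": [{"dog", "park"}, {"dog", "ball"}, {"park", "ball"}],
            }
        )
        corpus = [list(m.tokens) for m in ds.responses()]
        space = cs.build_semantic_space(corpus, "document", dimensionality=2)
        res = take_one_out_classify(ds, method="lsa", space=space)
        assert res.fraction_correct == 1.0


class TestCrossDataset:
    def test_reference_matching_target_vocabulary(self):
        ref = dataset_from_vocab(
            {"c0": [{"boat", "sea"}] * 2, "c1": [{"dog", "park"}] * 2}
        )
        targets = [
            make_ts({"boat"}, rid="t0", cid="c0"),
            make_ts({"park", "dog"}, rid="t1", cid="c1"),
        ]
        res = cross_dataset_classify(targets, ref)
        assert res.fraction_correct == 1.0

    def test_missing_target_clips_error(self):
        ref = dataset_from_vocab({"c0": [{"a"}, {"b"}]})
        targets = [make_ts({"a"}, rid="t0", cid="c9")]
        with pytest.raises(ValidationError):
            cross_dataset_classify(targets, ref)

    def test_cross_population_matches_brute_force(self, stoplist):
        cfg = cs.GeneratorConfig(n_clips=6, responses_per_clip=5, n_subjects=8)
        noisy = cs.GeneratorConfig(
            n_clips=6, responses_per_clip=4, n_subjects=8,
            idiosyncrasy=0.4, verbosity_sd=0.5,
        )
        ref = NormativeDataset.from_responses(
            cs.generate_normative_dataset(cfg, seed=5), stoplist
        )
        raw_targets = cs.generate_normative_dataset(noisy, seed=6)
        targets = [
            make_ts(t.tokens, rid="x" + t.response_id, cid=t.clip_id)
            for t in cs.preprocess_responses(raw_targets, stoplist)
        ]
        res = cross_dataset_classify(targets, ref)
        # brute-force reimplementation with the scalar scorer
        n_correct = 0
        for t in targets:
            scores = {
                cid: mean_shared_word_score(t, ref[cid]) for cid in ref.clip_ids
            }
            best = max(scores.values())
            winners = [c for c, s in scores.items() if s == best]
            if winners == [t.clip_id]:
                n_correct += 1
        assert res.fraction_correct == pytest.approx(n_correct / len(targets))

    def test_pooled_dataset_uses_take_one_out_for_members(self, stoplist):
        cfg = cs.GeneratorConfig(n_clips=4, responses_per_clip=3, n_subjects=6)
        a = NormativeDataset.from_responses(
            cs.generate_normative_dataset(cfg, seed=1), stoplist
        )
        b_raw = cs.generate_degraded_responses(
            cfg, cs.DegradationLevel("alt", 1.0), seed=2
        )
        b = NormativeDataset.from_responses(b_raw, stoplist)
        pooled = NormativeDataset.merged(a, b)
        res = cross_dataset_classify(a, pooled)
        # members of the pool: each must have been scored without itself
        for row in res.table.itertuples(index=False):
            target = next(m for m in a.responses() if m.response_id == row.response_id)
            expected = {
                cid: mean_shared_word_score(
                    target,
                    pooled[cid],
                    exclude_response_id=row.response_id if cid == target.clip_id else None,
                )
                for cid in pooled.clip_ids
            }
            assert row.score == pytest.approx(max(expected.values()))


class TestResamplingCurve:
    def test_full_size_point_equals_full_classification(self, small_dataset):
        full_n = min(small_dataset.sizes().values())
        curve = resample_classification_curve(
            small_dataset, [full_n], replicates=2, seed=9
        )
        expected = take_one_out_classify(small_dataset).fraction_correct
        assert np.allclose(curve.fractions, expected)

    def test_seed_determinism(self, small_dataset):
        a = resample_classification_curve(small_dataset, [2, 4], 3, seed=123)
        b = resample_classification_curve(small_dataset, [2, 4], 3, seed=123)
        np.testing.assert_array_equal(a.fractions, b.fractions)
        c = resample_classification_curve(small_dataset, [2, 4], 3, seed=124)
        assert not np.array_equal(a.fractions, c.fractions)

    def test_n_out_of_range_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            resample_classification_curve(small_dataset, [1], 2, seed=0)
        with pytest.raises(ValidationError):
            resample_classification_curve(small_dataset, [99], 2, seed=0)


class TestExponentialFit:
    def test_recovers_noiseless_parameters(self):
        n = np.arange(2, 13, dtype=float)
        y = 80.0 * (1.0 - np.exp(-n / 2.0))
        fit = fit_exponential(n, y)
        assert fit.asymptote == pytest.approx(80.0, rel=1e-6)
        assert fit.tau == pytest.approx(2.0, rel=1e-6)
        assert fit.n99 == pytest.approx(2.0 * np.log(100.0), rel=1e-6)
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-8)

    def test_scaling_y_scales_asymptote_only(self):
        n = np.arange(2, 13, dtype=float)
        y = 0.8 * (1.0 - np.exp(-n / 3.0))
        f1 = fit_exponential(n, y)
        f2 = fit_exponential(n, 100.0 * y)
        assert f2.asymptote == pytest.approx(100.0 * f1.asymptote, rel=1e-6)
        assert f2.tau == pytest.approx(f1.tau, rel=1e-6)
        assert f2.n99 == pytest.approx(f1.n99, rel=1e-6)

    def test_n99_tau_ratio_is_log_100(self):
        rng = np.random.default_rng(5)
        n = np.arange(2, 13, dtype=float)
        for _ in range(20):
            a, tau = rng.uniform(10, 90), rng.uniform(0.5, 6)
            y = a * (1 - np.exp(-n / tau)) + rng.normal(0, 1.0, n.size)
            fit = fit_exponential(n, np.clip(y, 0, None))
            assert fit.n99 / fit.tau == pytest.approx(np.log(100.0))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateCurveError):
            fit_exponential([2.0, 3.0], [1.0, 2.0])
        with pytest.raises(DegenerateCurveError):
            fit_exponential([2.0, 3.0, 4.0], [5.0, 5.0, 5.0])

    def test_accepts_resampling_curve_object(self, small_dataset):
        curve = resample_classification_curve(
            small_dataset, [2, 3, 4, 5, 6], replicates=5, seed=21
        )
        fit = fit_exponential(curve)
        assert fit.asymptote > 0 and fit.tau > 0


class TestScoreErrors:
    def test_full_size_errors_exactly_zero(self, small_dataset):
        full_n = min(small_dataset.sizes().values())
        res = score_error_distribution(small_dataset, [full_n], replicates=2, seed=3)
        assert (res.samples["error"] == 0.0).all()

    def test_seed_determinism(self, small_dataset):
        a = score_error_distribution(small_dataset, [2, 4], 3, seed=77)
        b = score_error_distribution(small_dataset, [2, 4], 3, seed=77)
        assert a.samples.equals(b.samples)

    def test_summary_columns(self, small_dataset):
        res = score_error_distribution(small_dataset, [2, 3], 4, seed=1)
        assert list(res.summary.columns) == ["n", "mean_error", "sd_error", "iqr_error"]
        assert set(res.summary["n"]) == {2, 3}


def test_chance_rate_near_reciprocal_clip_count():
    # binomial check: with p = 1/C and m draws the empirical rate should sit
    # within 4 standard errors of p
    c, m = 40, 50_000
    rate = simulate_chance_rate(c, m, seed=8)
    se = np.sqrt((1 / c) * (1 - 1 / c) / m)
    assert abs(rate - 1 / c) < 4 * se
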