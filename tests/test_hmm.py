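"""Acoustic-model core: flat start, forward likelihoods, embedded EM,
mixture splitting and model sampling, checked against independent
oracles (exhaustive path enumeration, hmmlearn, closed-form EM facts)."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

import phonotop as pt
from phonotop.corpus import Corpus, Sentence
from phonotop.hmm import (
    CompositeHMM,
    _logspace_forward_backward,
    _scaled_forward_backward,
)
from phonotop.topology import BAKIS1, ERGODIC, TopologySpec

from conftest import random_phone_hmm


def brute_force_loglik(chain, x):
    """Forward probability by explicit summation over every state path."""
    comp = CompositeHMM(chain)
    T = x.shape[0]
    S = comp.n_states
    log_b, _ = comp.emission_log_probs(x)
    terms = []
    for path in itertools.product(range(S), repeat=T):
        lp = comp.log_pi[path[0]] + log_b[0, path[0]]
        for t in range(1, T):
            lp += comp.log_A[path[t - 1], path[t]] + log_b[t, path[t]]
        lp += comp.log_exit[path[-1]]
        terms.append(lp)
    return logsumexp(terms)


# ---------------------------------------------------------------------------
# forward log-likelihood
# ---------------------------------------------------------------------------

class TestSequenceLoglik:
    def test_matches_brute_force_enumeration(self):
        """Exact forward sum vs exhaustive path enumeration on small
        models (<= 3 states, <= 5 frames), within 1e-8."""
        rng = np.random.default_rng(7)
        for topo, n_states, t_frames in [
            (BAKIS1, 3, 4),
            (ERGODIC, 3, 3),
            (ERGODIC, 3, 5),
            (BAKIS1, 3, 5),
        ]:
            hmm = random_phone_hmm("a", topo, n_states, 2, rng)
            x = rng.normal(0, 2, size=(t_frames, 2))
            got = pt.sequence_loglik([hmm], x)
            want = brute_force_loglik([hmm], x)
            assert got == pytest.approx(want, abs=1e-8)

    def test_two_phone_chain_matches_brute_force(self):
        rng = np.random.default_rng(8)
        a = random_phone_hmm("a", BAKIS1, 3, 2, rng)
        b = random_phone_hmm("b", ERGODIC, 3, 2, rng, n_components=2)
        x = rng.normal(0, 2, size=(4, 2))
        assert pt.sequence_loglik([a, b], x) == pytest.approx(
            brute_force_loglik([a, b], x), abs=1e-8
        )

    def test_single_frame_closed_form(self):
        """One frame at the Gaussian mean: log N(mu|mu,var) plus the
        entry and exit transition terms."""
        rng = np.random.default_rng(9)
        hmm = random_phone_hmm("a", ERGODIC, 3, 2, rng)
        for s in range(3):
            e = hmm.emissions[s]
            x = e.means[0:1].copy()
            expected_state = (
                np.log(hmm.entry_probs[s])
                + norm.logpdf(x[0], e.means[0], np.sqrt(e.variances[0])).sum()
                + np.log(hmm.exit_probs[s])
            )
            # forward sums over all states; the chosen state is one term
            assert pt.sequence_loglik([hmm], x) >= expected_state - 1e-12

    def test_reversal_sensitivity_left_to_right(self):
        """A left-to-right model with distinct state means assigns
        different likelihoods to a ramp and its reversal."""
        rng = np.random.default_rng(10)
        hmm = random_phone_hmm("a", BAKIS1, 3, 1, rng)
        for s, e in enumerate(hmm.emissions):
            e.means[:] = float(s)
            e.variances[:] = 0.25
        x = np.array([[0.0], [1.0], [2.0]])
        fwd = pt.sequence_loglik([hmm], x)
        rev = pt.sequence_loglik([hmm], x[::-1])
        assert fwd > rev + 1.0
        assert fwd == pytest.approx(brute_force_loglik([hmm], x), abs=1e-8)

    def test_hmmlearn_cross_check(self):
        """Ergodic model with a constant exit probability e from every
        state factors as P_ours = e·(1−e)^(T−1)·P_hmmlearn."""
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(11)
        n, d, eps = 3, 2, 0.2
        inner = rng.dirichlet(np.ones(n), size=n)  # proper stochastic
        startprob = rng.dirichlet(np.ones(n))
        spec = TopologySpec(ERGODIC, n)
        trans = np.zeros((n + 2, n + 2))
        trans[0, 1 : n + 1] = startprob
        trans[1 : n + 1, 1 : n + 1] = (1 - eps) * inner
        trans[1 : n + 1, n + 1] = eps
        means = rng.normal(0, 2, size=(n, d))
        variances = rng.uniform(0.5, 2.0, size=(n, d))
        ours = pt.PhoneHMM(
            "a",
            spec,
            trans,
            [
                pt.GaussianMixtureEmission(
                    np.ones(1), means[s : s + 1], variances[s : s + 1]
                )
                for s in range(n)
            ],
        )
        ref = hmmlearn_hmm.GaussianHMM(
            n_components=n, covariance_type="diag", init_params=""
        )
        ref.startprob_ = startprob
        ref.transmat_ = inner
        ref.means_ = means
        ref.covars_ = variances
        x = rng.normal(0, 2, size=(6, d))
        expected = ref.score(x) + 5 * np.log(1 - eps) + np.log(eps)
        assert pt.sequence_loglik([ours], x) == pytest.approx(expected, abs=1e-8)

    def test_empty_sequence_rejected(self, tiny_truth):
        hmm = next(iter(tiny_truth[0].hmms.values()))
        with pytest.raises(ValueError):
            pt.sequence_loglik([hmm], np.empty((0, 3)))


# ---------------------------------------------------------------------------
# flat start
# ---------------------------------------------------------------------------

class TestFlatStart:
    def _corpus(self, frames_list):
        return Corpus(
            [
                Sentence(np.asarray(f, dtype=float), ("w",), ("a",))
                for f in frames_list
            ]
        )

    def test_all_states_share_global_gaussian(self, tiny_corpus, tiny_spec):
        ms = pt.build_model_set(
            pt.uniform_assignment(tiny_spec.inventory(), BAKIS1, 3), 3
        )
        out = pt.flat_start(ms, tiny_corpus.subset("train"))
        frames = np.concatenate(
            [s.features for s in tiny_corpus.subset("train")]
        )
        ref_mean, ref_var = frames.mean(axis=0), frames.var(axis=0)
        for hmm in out.hmms.values():
            for e in hmm.emissions:
                np.testing.assert_allclose(e.means[0], ref_mean)
                np.testing.assert_allclose(e.variances[0], ref_var)

    def test_constant_frames_hit_variance_floor(self):
        corpus = self._corpus([np.full((5, 2), 3.0), np.full((4, 2), 3.0)])
        ms = pt.build_model_set({"a": TopologySpec(BAKIS1, 3)}, 2)
        out = pt.flat_start(ms, corpus)
        e = out.hmms["a"].emissions[0]
        np.testing.assert_allclose(e.means[0], 3.0)
        np.testing.assert_allclose(
            e.variances[0], np.asarray(out.variance_floor)
        )
        assert np.all(np.asarray(out.variance_floor) > 0)

    def test_identical_pooled_statistics_identical_init(self):
        """Two differently-sliced corpora with the same pooled frames
        flat-start identically (pooled mean/var oracle by direct sums)."""
        rng = np.random.default_rng(12)
        frames = rng.normal(1.5, 2.0, size=(30, 2))
        c1 = self._corpus([frames[:10], frames[10:]])
        c2 = self._corpus([frames[:25], frames[25:]])
        ms = pt.build_model_set({"a": TopologySpec(BAKIS1, 3)}, 2)
        o1, o2 = pt.flat_start(ms, c1), pt.flat_start(ms, c2)
        pooled_mean = frames.sum(axis=0) / len(frames)
        pooled_var = (frames**2).sum(axis=0) / len(frames) - pooled_mean**2
        e1 = o1.hmms["a"].emissions[1]
        np.testing.assert_allclose(e1.means[0], pooled_mean)
        np.testing.assert_allclose(e1.variances[0], pooled_var)
        np.testing.assert_allclose(
            e1.means, o2.hmms["a"].emissions[1].means
        )

    def test_missing_phoneme_named_in_error(self):
        corpus = self._corpus([np.zeros((4, 2))])
        ms = pt.build_model_set(
            {"a": TopologySpec(BAKIS1, 3), "zz": TopologySpec(BAKIS1, 3)}, 2
        )
        with pytest.raises(ValueError, match="zz"):
            pt.flat_start(ms, corpus)


# ---------------------------------------------------------------------------
# embedded re-estimation
# ---------------------------------------------------------------------------

class TestEmbeddedReestimation:
    def test_loglik_nondecreasing(self, trained_models, tiny_corpus):
        _, lls = pt.embedded_reestimate(
            trained_models, tiny_corpus.subset("train"), n_iter=6
        )
        assert len(lls) >= 2
        assert all(b - a >= -1e-6 for a, b in zip(lls, lls[1:]))

    def test_scaled_and_logspace_estep_agree(self, tiny_truth, tiny_corpus):
        sent = tiny_corpus.sentences[0]
        comp = CompositeHMM([tiny_truth[0].hmms[p] for p in sent.phones])
        log_b, _ = comp.emission_log_probs(sent.features)
        g1, x1, ll1 = _scaled_forward_backward(comp, log_b)
        g2, x2, ll2 = _logspace_forward_backward(comp, log_b)
        assert ll1 == pytest.approx(ll2, abs=1e-8)
        np.testing.assert_allclose(g1, g2, atol=1e-10)
        np.testing.assert_allclose(x1, x2, atol=1e-10)
        np.testing.assert_allclose(g1.sum(axis=1), 1.0, atol=1e-10)

    def test_single_state_fixed_point_is_sample_mean(self):
        """A 1-state self-loop-only model trained by EM must place its
        mean at the overall frame mean (closed-form fixed point)."""
        spec = TopologySpec.__new__(TopologySpec)
        object.__setattr__(spec, "topo_type", BAKIS1)
        object.__setattr__(spec, "n_states", 1)
        trans = np.array([[0, 1.0, 0], [0, 0.7, 0.3], [0, 0, 0]])
        hmm = pt.PhoneHMM(
            "a",
            spec,
            trans,
            [pt.GaussianMixtureEmission(np.ones(1), np.zeros((1, 2)), np.ones((1, 2)))],
        )
        ms = pt.ModelSet({"a": hmm}, 2, np.full(2, 1e-6))
        rng = np.random.default_rng(13)
        sentences = [
            Sentence(rng.normal(2.0, 1.0, size=(rng.integers(3, 8), 2)), ("w",), ("a",))
            for _ in range(10)
        ]
        corpus = Corpus(sentences)
        out, lls = pt.embedded_reestimate(ms, corpus, n_iter=3)
        frames = np.concatenate([s.features for s in corpus])
        np.testing.assert_allclose(
            out.hmms["a"].emissions[0].means[0], frames.mean(axis=0), atol=1e-8
        )
        assert all(b - a >= -1e-6 for a, b in zip(lls, lls[1:]))

    def test_rows_stochastic_and_masked_arcs_zero(self, trained_models):
        trained_models.validate()  # row sums, masks, floors all enforced

    def test_variances_respect_floor(self, trained_models):
        floor = np.asarray(trained_models.variance_floor)
        for hmm in trained_models.hmms.values():
            for e in hmm.emissions:
                assert np.all(e.variances >= floor - 1e-12)

    def test_too_short_sentences_skipped(self, tiny_truth, caplog):
        """A sentence with fewer frames than the shortest path is skipped
        (not fatal) and training proceeds on the rest."""
        truth = tiny_truth[0]
        labels = truth.labels[:3]
        rng = np.random.default_rng(14)
        good = Sentence(
            rng.normal(size=(40, 3)), ("w",), tuple(labels)
        )
        short = Sentence(rng.normal(size=(2, 3)), ("w",), tuple(labels))
        ms = pt.flat_start(
            pt.build_model_set(
                {l: truth.hmms[l].spec for l in labels}, 3
            ),
            Corpus([good]),
        )
        out, lls = pt.embedded_reestimate(ms, Corpus([good, short]), n_iter=2)
        assert np.isfinite(lls).all()

    def test_parameter_recovery_improves_with_data(self):
        """State-mean recovery error decreases with corpus size when
        training on data sampled from a known generator."""
        errors = []
        for n_sent, seed in [(20, 1), (80, 2), (320, 3)]:
            err = _recovery_error(n_sent, seed)
            errors.append(err)
        assert errors[2] < errors[0]
        assert errors[1] < errors[0] * 1.5  # allow noise, trend must hold


def _recovery_error(n_sentences: int, seed: int) -> float:
    """Train on samples from a known 3-state Bakis-1 bank; return the max
    absolute state-mean error after alignment-free matching (states are
    identifiable by position in a left-to-right model)."""
    rng = np.random.default_rng(seed)
    labels = ["sil", "a", "b"]
    truth = {}
    for i, label in enumerate(labels):
        spec = TopologySpec(BAKIS1, 3)
        trans = np.zeros((5, 5))
        trans[0, 1] = 1.0
        for s in range(1, 4):
            trans[s, s] = 0.5
            trans[s, s + 1] = 0.5
        emissions = [
            pt.GaussianMixtureEmission(
                np.ones(1),
                np.array([[4.0 * i + s, -4.0 * i - s]]),
                np.full((1, 2), 0.8),
            )
            for s in range(3)
        ]
        truth[label] = pt.PhoneHMM(label, spec, trans, emissions)
    truth_set = pt.ModelSet(truth, 2, 1e-8)

    sentences = []
    for _ in range(n_sentences):
        phones = ("sil", "a", "b", "sil")
        feats, _ = pt.sample_from_models(
            [truth_set.hmms[p] for p in phones], rng
        )
        sentences.append(Sentence(feats, ("w",), phones))
    corpus = Corpus(sentences)

    ms = pt.flat_start(
        pt.build_model_set({l: truth[l].spec for l in labels}, 2), corpus
    )
    ms, _ = pt.embedded_reestimate(ms, corpus, n_iter=20)
    errs = [
        np.abs(ms.hmms[l].emissions[s].means[0] - truth[l].emissions[s].means[0]).max()
        for l in labels
        for s in range(3)
    ]
    return max(errs)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

class TestSampling:
    def test_deterministic_under_seed(self, tiny_truth):
        chain = [tiny_truth[0].hmms[l] for l in tiny_truth[0].labels[:3]]
        f1, a1 = pt.sample_from_models(chain, 42)
        f2, a2 = pt.sample_from_models(chain, 42)
        np.testing.assert_array_equal(f1, f2)
        assert a1 == a2

    def test_forced_path_length(self):
        """Self-loop probability 0 forces exactly one frame per state."""
        spec = TopologySpec(BAKIS1, 3)
        trans = np.zeros((5, 5))
        trans[0, 1] = 1.0
        trans[1, 2] = trans[2, 3] = trans[3, 4] = 1.0
        hmm = pt.PhoneHMM(
            "a",
            spec,
            trans,
            [
                pt.GaussianMixtureEmission(np.ones(1), np.zeros((1, 2)), np.ones((1, 2)))
                for _ in range(3)
            ],
        )
        feats, align = pt.sample_from_models([hmm], 0)
        assert feats.shape == (3, 2)
        assert [a[2] for a in align] == [0, 1, 2]

    def test_mean_dwell_matches_geometric(self):
        """Self-loop 0.5 gives mean dwell ~ 2 frames per state."""
        spec = TopologySpec(BAKIS1, 3)
        trans = np.zeros((5, 5))
        trans[0, 1] = 1.0
        for s in range(1, 4):
            trans[s, s] = 0.5
            trans[s, s + 1] = 0.5
        hmm = pt.PhoneHMM(
            "a",
            spec,
            trans,
            [
                pt.GaussianMixtureEmission(np.ones(1), np.zeros((1, 1)), np.ones((1, 1)))
                for _ in range(3)
            ],
        )
        rng = np.random.default_rng(15)
        total_frames = sum(
            pt.sample_from_models([hmm], rng)[0].shape[0] for _ in range(2000)
        )
        mean_dwell = total_frames / (3 * 2000)
        assert mean_dwell == pytest.approx(2.0, rel=0.05)


# ---------------------------------------------------------------------------
# mixture splitting
# ---------------------------------------------------------------------------

class TestSplitMixtures:
    def test_single_split_exact(self, trained_models):
        ms = pt.split_mixtures(trained_models, 4)
        for hmm in ms.hmms.values():
            for e in hmm.emissions:
                assert e.n_components == 4
                assert e.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_one_to_two_split_rule(self):
        e = pt.GaussianMixtureEmission(
            np.ones(1), np.array([[1.0, 2.0]]), np.array([[4.0, 9.0]])
        )
        spec = TopologySpec(BAKIS1, 3)
        from phonotop.hmm import uniform_transitions

        hmm = pt.PhoneHMM("a", spec, uniform_transitions(spec), [e] * 3)
        ms = pt.ModelSet({"a": hmm}, 2, 1e-8)
        out = pt.split_mixtures(ms, 2)
        e2 = out.hmms["a"].emissions[0]
        np.testing.assert_allclose(e2.weights, [0.5, 0.5])
        np.testing.assert_allclose(
            e2.means, [[1.0 + 0.2 * 2, 2.0 + 0.2 * 3], [1.0 - 0.2 * 2, 2.0 - 0.2 * 3]]
        )

    def test_identity_when_target_equals_current(self, trained_models):
        out = pt.split_mixtures(trained_models, trained_models.max_components())
        for label in trained_models.labels:
            np.testing.assert_array_equal(
                out.hmms[label].emissions[0].means,
                trained_models.hmms[label].emissions[0].means,
            )

    def test_grow_to_sixteen(self, trained_models):
        out = pt.split_mixtures(trained_models, 16)
        for hmm in out.hmms.values():
            for e in hmm.emissions:
                assert e.n_components == 16
                assert e.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_shrink_rejected(self, trained_models):
        with pytest.raises(ValueError):
            pt.split_mixtures(trained_models, 1)
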