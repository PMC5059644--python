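import itertools

import numpy as np
import pytest

from eogdeco.char_ngram import NgramScorer, train_ngram
from eogdeco.context_units import unit_names
from eogdeco.decoder import DecodeConfig, build_decoding_graph, decode
from eogdeco.features import FeatureSequence, six_channel_features
from eogdeco.gmm_hmm import Chain, GmmHmm
from eogdeco.protocol import Protocol
from eogdeco.synthetic_eog import SIL, UserProfile, generate_recording
from eogdeco.experiments import ExperimentConfig, train_system
from eogdeco.protocol import word_to_motions


def toy_protocol():
    """Two characters with 2-motion codes (non-standard, strict off)."""
    return Protocol(
        table={"A": ("up", "center"), "B": ("down", "center")},
        strict=False,
    )


def toy_models(n_states=2, dim=1, sep=4.0):
    """Context-free unit models with well separated means per motion."""
    mu = {"up": sep, "down": -sep, "center": 0.0, "left": 2 * sep,
          "right": -2 * sep, SIL: 0.0}
    models = {}
    for name, m in mu.items():
        model = GmmHmm.left_to_right(name, n_states, np.full(dim, m),
                                     np.ones(dim))
        models[name] = model
    return models


def synth_obs(motions, models, frames_per_state=3):
    """Deterministic observations tracing the unit means."""
    out = []
    for m in motions:
        for g in models[m].states:
            out.extend([g.means[0]] * frames_per_state)
    return FeatureSequence(np.asarray(out, dtype=float), 100.0)


class TestGraphStructure:
    def test_mono_graph_chains_per_character(self):
        models = toy_models()
        cfg = DecodeConfig(unit_kind="mono", use_sil=False)
        g = build_decoding_graph(toy_models(), toy_protocol(), None, cfg)
        # 2 chars x 2 units x 2 states
        assert g.n_nodes == 8
        assert len(g.entries) == 2  # one entry per character
        assert {tuple(c) for c in g.char_motions} == {("up", "center"),
                                                      ("down", "center")}

    def test_zero_vs_unigram_topology_identical(self, rng):
        models = toy_models()
        lm = train_ngram([["A", "B", "A"]], 1)
        cfg = DecodeConfig(unit_kind="mono", use_sil=False)
        g0 = build_decoding_graph(models, toy_protocol(), None, cfg)
        g1 = build_decoding_graph(models, toy_protocol(), lm, cfg)
        assert g0.n_nodes == g1.n_nodes
        assert g0.arcs == g1.arcs
        assert {n: (c, tuple(s)) for n, (c, s) in g0.entries.items()} == {
            n: (c, tuple(s)) for n, (c, s) in g1.entries.items()}

    def test_cross_boundary_tri_units(self):
        """The boundary units of adjacent characters carry each other's
        contexts, matching the expansion of the concatenated sequence."""
        seen = []

        class Spy(dict):
            def __getitem__(self, key):
                seen.append(key)
                raise KeyError(key)

        models = toy_models(n_states=1)
        cfg = DecodeConfig(unit_kind="tri", use_sil=False)
        graph = build_decoding_graph(models, toy_protocol(), None, cfg)
        # decode graph resolvable via mono backoff; instead verify unit
        # naming directly against the sequence expansion rule
        joint = unit_names(["up", "center", "down", "center"], "tri")
        # boundary: last unit of A with right ctx "down", first of B with
        # left ctx "center"
        assert joint[1] == "up-center+down"
        assert joint[2] == "center-down+center"

    def test_unresolvable_unit_is_named(self):
        models = {"center": toy_models()["center"]}  # missing "up"/"down"
        cfg = DecodeConfig(unit_kind="mono", use_sil=False)
        with pytest.raises(KeyError, match="up"):
            build_decoding_graph(models, toy_protocol(), None, cfg)


class TestDecodeExactness:
    def oracle_best(self, graph_models, protocol, obs, lm, cfg, max_chars=3):
        """Exhaustive hypothesis enumeration with forced-alignment scoring."""
        chars = sorted(protocol.table)
        scorer = NgramScorer(lm) if lm is not None else None
        best = (-np.inf, None)
        for n in range(1, max_chars + 1):
            for word in itertools.product(chars, repeat=n):
                motions = []
                ok = True
                for c in word:
                    code = protocol.table[c]
                    if motions and motions[-1] == code[0]:
                        ok = False
                        break
                    motions.extend(code)
                if not ok:
                    continue
                units = unit_names(motions, cfg.unit_kind)
                chain = Chain([graph_models[u] if u in graph_models
                               else graph_models[u.split("-")[-1].split("+")[0]]
                               for u in units])
                _, ac = chain.viterbi(obs.vectors)
                score = ac + cfg.insertion_penalty * len(word)
                if scorer is not None:
                    h = scorer.start()
                    for c in word:
                        lp, h = scorer.step(h, c)
                        score += cfg.lm_weight * lp
                    score += cfg.lm_weight * scorer.final(h)
                if score > best[0]:
                    best = (score, list(word))
        return best

    @pytest.mark.parametrize("lm_order", [0, 2])
    def test_exact_search_equals_enumeration(self, lm_order, rng):
        """Beam-free decoding equals brute-force hypothesis enumeration."""
        protocol = toy_protocol()
        models = toy_models()
        lm = (train_ngram([["A", "B"], ["A", "A"], ["B", "A"]], lm_order)
              if lm_order else None)
        cfg = DecodeConfig(unit_kind="mono", use_sil=False, beam=None,
                           insertion_penalty=-1.0)
        graph = build_decoding_graph(models, protocol, lm, cfg)
        for trial in range(5):
            true_word = [["A", "B"], ["B", "A", "B"], ["A"]][trial % 3]
            motions = [m for c in true_word for m in protocol.table[c]]
            obs = synth_obs(motions, models)
            noisy = FeatureSequence(
                obs.vectors + rng.normal(0, 0.8, obs.vectors.shape), 100.0)
            hyp = decode(noisy, graph, cfg)
            score, word = self.oracle_best(models, protocol, noisy, lm, cfg)
            assert hyp.characters == word
            assert hyp.log_score == pytest.approx(score, abs=1e-6)

    def test_clean_word_recovered(self):
        protocol = toy_protocol()
        models = toy_models()
        cfg = DecodeConfig(unit_kind="mono", use_sil=False, beam=None)
        graph = build_decoding_graph(models, protocol, None, cfg)
        obs = synth_obs(["up", "center", "down", "center"], models)
        hyp = decode(obs, graph, cfg)
        assert hyp.characters == ["A", "B"]
        assert hyp.motions == ["up", "center", "down", "center"]
        assert hyp.complete

    def test_no_path_yields_incomplete_empty(self):
        protocol = toy_protocol()
        models = toy_models()
        cfg = DecodeConfig(unit_kind="mono", use_sil=False, beam=None)
        graph = build_decoding_graph(models, protocol, None, cfg)
        # shorter than the minimal 4-state chain
        hyp = decode(FeatureSequence(np.zeros((2, 1)), 100.0), graph, cfg)
        assert hyp.characters == [] and not hyp.complete
        assert hyp.log_score == -np.inf

    def test_decode_deterministic(self, rng):
        protocol = toy_protocol()
        models = toy_models()
        cfg = DecodeConfig(unit_kind="mono", use_sil=False)
        graph = build_decoding_graph(models, protocol, None, cfg)
        obs = FeatureSequence(rng.normal(0, 3, size=(30, 1)), 100.0)
        h1 = decode(obs, graph, cfg)
        h2 = decode(obs, graph, cfg)
        assert h1.characters == h2.characters
        assert h1.log_score == h2.log_score


class TestInsertionPenalty:
    def test_stronger_penalty_never_adds_characters(self, rng):
        protocol = toy_protocol()
        models = toy_models()
        graph = build_decoding_graph(
            models, protocol, None,
            DecodeConfig(unit_kind="mono", use_sil=False))
        obs = FeatureSequence(rng.normal(0, 2.0, size=(60, 1)), 100.0)
        lengths = []
        scores = []
        for pen in (0.0, -5.0, -20.0):
            cfg = DecodeConfig(unit_kind="mono", use_sil=False, beam=None,
                               insertion_penalty=pen)
            hyp = decode(obs, graph, cfg)
            lengths.append(len(hyp.characters))
            scores.append(hyp.log_score)
        assert lengths == sorted(lengths, reverse=True)
        assert scores == sorted(scores, reverse=True)


class TestEndToEndTrained:
    def test_high_snr_word_recovery_with_tri_models(self):
        """Clean synthetic input decoded exactly by user-trained tri models."""
        from eogdeco.synthetic_eog import generate_corpus
        from eogdeco.protocol import build_default_protocol

        cfg = ExperimentConfig(seed=5, units_per_user=1, mixture_schedule=(1,),
                               n_iterations=3, tie_threshold=1000.0)
        profile = UserProfile(
            amplitude_scale=600.0, motion_duration_mean=0.3,
            motion_duration_std=0.04, noise_std=10.0, drift_rate=2.0,
            gain_jitter_std=0.05, seed=5)
        rng = np.random.default_rng(5)
        corpus = generate_corpus(22, profile, rng=rng)
        tied = train_system(corpus, "tri", cfg)
        protocol = build_default_protocol(0).restrict(["a", "ko", "e"])
        dcfg = DecodeConfig(unit_kind="tri", beam=None)
        graph = build_decoding_graph(tied, protocol, None, dcfg)
        word = ["ko", "a"]
        rec = generate_recording(word_to_motions(word, protocol), profile,
                                 rng=rng)
        hyp = decode(six_channel_features(rec), graph, dcfg)
        assert hyp.characters == word
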