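"""Desk-scale experiment drivers on synthetic data.

Three experiment designs are scripted end to end on generated EOG
corpora: the threshold-baseline versus HMM comparison (motion error
rate, 2-channel versus 6-channel features), the unit-kind x N-gram-order
character-error grid (mono/bi/tri units, 0- to 3-gram), and the user
adaptation curves (no adaptation / MLLR / MAP / MAP with insertion
penalty tuning, as a function of the amount of adaptation data).

One *unit* of training data is a set of 22 random motion sequences of
4-8 motions (about 136 motions), the recording session granularity
also used to measure adaptation amounts.  Users are emulated as
sampled :class:`~eogdeco.synthetic_eog.UserProfile` instances differing
in amplitude, speed, noise and electrode geometry; the adaptation
target user is drawn deliberately outside the pooled training range
(weaker signal, faster motions), since between-user differences in
amplitude and eye-motion speed are what degrade a user-independent
model.

All runs are bit-reproducible given ``ExperimentConfig.seed``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import char_ngram as cn
from .adaptation import map_adapt, mllr_adapt
from .baseline_threshold import ThresholdConfig, baseline_recognize
from .context_units import (
    default_questions,
    state_stats_from_accumulator,
    tie_states,
    unit_names,
)
from .decoder import DecodeConfig, build_decoding_graph, decode
from .evaluation import evaluate_corpus, relative_reduction
from .features import six_channel_features, two_channel_features
from .gmm_hmm import TrainingConfig, baum_welch, collect_stats, flat_start_models
from .protocol import Protocol, build_default_protocol, word_to_motions
from .synthetic_eog import SIL, UserProfile, generate_corpus, generate_recording

__all__ = [
    "ExperimentConfig",
    "SEQUENCES_PER_UNIT",
    "sample_profiles",
    "make_experiment_protocol",
    "make_test_words",
    "train_system",
    "run_unit_comparison",
    "run_adaptation_curve",
    "run_baseline_comparison",
    "relative_reduction_report",
]

logger = logging.getLogger(__name__)

#: One unit of training data is 22 sequences (~136 motions).
SEQUENCES_PER_UNIT = 22


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared experimental conditions (desk scale by default)."""

    n_users: int = 5
    units_per_user: int = 2
    n_vocab_chars: int = 16
    n_test_words: int = 8
    test_word_len: tuple[int, int] = (2, 4)
    unit_kinds: tuple[str, ...] = ("mono", "bi", "tri")
    ngram_orders: tuple[int, ...] = (0, 1, 2, 3)
    adaptation_amounts: tuple[float, ...] = (0.2, 0.3, 0.5, 1.0, 2.0, 5.0)
    n_repeats: int = 3
    adapt_ngram_order: int = 3
    penalty_grid: tuple[float, ...] = (-30.0, -15.0, -5.0, 0.0, 5.0, 15.0, 30.0)
    mixture_schedule: tuple[int, ...] = (1, 2)
    n_iterations: int = 4
    n_states: int = 4
    tie_threshold: float = 1000.0
    beam: Optional[float] = 40.0
    lm_corpus_sentences: int = 300
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_users, self.units_per_user, self.n_test_words,
               self.n_repeats) < 1:
            raise ValueError("counts must be >= 1")
        if any(a <= 0 for a in self.adaptation_amounts):
            raise ValueError("adaptation amounts must be positive")


# ---------------------------------------------------------------------------
# Synthetic study population


def sample_profiles(config: ExperimentConfig, rng: np.random.Generator,
                    n: Optional[int] = None) -> list[UserProfile]:
    """Pooled-population user profiles (amplitude, speed, noise vary).

    The population emulates practised fast continuous input: motions of
    roughly a quarter second whose saccade rise time is longer than the
    hold, so the gaze undershoots and adjacent motions fuse -- the
    regime in which context effects dominate.  Broadband noise covers
    measurement noise plus myoelectric and electrode artifacts.
    """
    out = []
    for _ in range(n if n is not None else config.n_users):
        out.append(
            UserProfile(
                amplitude_scale=float(rng.uniform(450.0, 850.0)),
                motion_duration_mean=float(rng.uniform(0.24, 0.30)),
                motion_duration_std=0.05,
                noise_std=float(rng.uniform(150.0, 220.0)),
                drift_rate=float(rng.uniform(20.0, 35.0)),
                rise_time=0.40,
                gain_jitter_std=0.13,
                geometry_jitter=0.25,
                geometry_seed=int(rng.integers(2**31)),
            )
        )
    return out


def mismatched_target_profile(rng: np.random.Generator) -> UserProfile:
    """A fast, weak-signal user outside the pooled training range.

    Low corneoretinal amplitude with unabated artifact noise is the
    hard case for a pooled model: the pooled Gaussians sit at the
    population's larger deflections, so the target's compressed signal
    space misranks confusable characters until the means are adapted.
    """
    return UserProfile(
        amplitude_scale=float(rng.uniform(300.0, 340.0)),
        motion_duration_mean=0.19,
        motion_duration_std=0.03,
        noise_std=180.0,
        drift_rate=25.0,
        rise_time=0.40,
        gain_jitter_std=0.13,
        geometry_jitter=0.25,
        geometry_seed=int(rng.integers(2**31)),
    )


def make_experiment_protocol(config: ExperimentConfig,
                             rng: np.random.Generator) -> Protocol:
    """A seeded sub-protocol restricted to a small decoding vocabulary."""
    full = build_default_protocol(seed=config.seed)
    chars = list(full.basic)
    idx = rng.choice(len(chars), size=config.n_vocab_chars, replace=False)
    return full.restrict([chars[i] for i in sorted(idx)])


def make_test_words(protocol: Protocol, config: ExperimentConfig,
                    rng: np.random.Generator,
                    source: Optional[cn.KanaTextModel] = None) -> list[list[str]]:
    """Test words; drawn from ``source`` when given, so that they follow
    the same character statistics as the language-model training text."""
    chars = sorted(set(protocol.basic) | set(protocol.derived))
    lo, hi = config.test_word_len
    words = []
    for _ in range(config.n_test_words):
        length = int(rng.integers(lo, hi + 1))
        if source is not None:
            words.append(source.sample(length, rng))
        else:
            words.append([chars[rng.integers(len(chars))] for _ in range(length)])
    return words


def _training_unit(profile: UserProfile, config: ExperimentConfig,
                   rng: np.random.Generator):
    return generate_corpus(SEQUENCES_PER_UNIT, profile, (4, 8),
                           sample_rate=config.sample_rate, rng=rng)


def _word_recordings(words, protocol, profile, config, rng):
    items = []
    for word in words:
        motions = word_to_motions(word, protocol)
        rec = generate_recording(motions, profile,
                                 sample_rate=config.sample_rate, rng=rng)
        items.append((word, rec))
    return items


def _labelled_features(corpus, kind: str, featurizer=six_channel_features):
    out = []
    for seq, rec in corpus:
        names = [SIL] + unit_names(seq, kind) + [SIL]
        out.append((names, featurizer(rec)))
    return out


# ---------------------------------------------------------------------------
# System training


def pretie_training_pass(
    corpus,
    kind: str,
    config: ExperimentConfig,
    featurizer=six_channel_features,
):
    """Single-Gaussian embedded training pass and its per-state stats.

    Returns ``(models, stats)``: the untied context-dependent models and
    the pooled (occupancy, sum, sum-of-squares) statistics per unit
    state that :func:`~eogdeco.context_units.tie_states` consumes.
    """
    data = _labelled_features(corpus, kind, featurizer)
    names = sorted({n for labels, _ in data for n in labels})
    tcfg = TrainingConfig(n_iterations=config.n_iterations,
                          mixture_schedule=(1,))
    models = flat_start_models(names, data, n_states=config.n_states, config=tcfg)
    baum_welch(models, data, tcfg)
    acc = collect_stats(models, data)
    return models, state_stats_from_accumulator(models, acc)


def train_system(
    corpus,
    kind: str,
    config: ExperimentConfig,
    featurizer=six_channel_features,
):
    """Train a unit-HMM system of the given kind on labelled recordings.

    Mono systems are flat-started and trained with embedded Baum-Welch
    directly.  Context-dependent systems (bi and tri) are first trained
    with single Gaussians, their states are tied with the likelihood
    decision tree (only left-context questions can split a bi set), and
    training then continues on the tied set through the mixture
    schedule.  Returns a plain model dict (mono) or a
    :class:`~eogdeco.context_units.TiedModelSet` (bi/tri).
    """
    data = _labelled_features(corpus, kind, featurizer)
    names = sorted({n for labels, _ in data for n in labels})
    tcfg = TrainingConfig(
        n_iterations=config.n_iterations,
        mixture_schedule=config.mixture_schedule,
    )
    if kind == "mono":
        models = flat_start_models(names, data, n_states=config.n_states,
                                   config=tcfg)
        baum_welch(models, data, tcfg)
        return models
    # context-dependent: single-Gaussian pass, tie, then grow mixtures
    models, stats = pretie_training_pass(corpus, kind, config, featurizer)
    _, tied = tie_states(models, stats, default_questions(),
                         threshold=config.tie_threshold)
    tied_models = tied.all_cached()
    baum_welch(tied_models, data, tcfg)
    return tied


def _text_source(protocol: Protocol, config: ExperimentConfig,
                 rng: np.random.Generator) -> cn.KanaTextModel:
    chars = sorted(set(protocol.basic) | set(protocol.derived))
    return cn.KanaTextModel(chars, seed=int(rng.integers(2**31)))


def _train_lms(source: cn.KanaTextModel, config: ExperimentConfig,
               rng: np.random.Generator, orders) -> dict[int, Optional[cn.CharNgram]]:
    text = source.corpus(config.lm_corpus_sentences, rng)
    lms: dict[int, Optional[cn.CharNgram]] = {}
    for order in orders:
        lms[order] = None if order == 0 else cn.train_ngram(text, order)
    return lms


def _decode_cer(models, protocol, lm, kind, config, test_items,
                insertion_penalty: float = 0.0) -> float:
    dcfg = DecodeConfig(unit_kind=kind, beam=config.beam,
                        insertion_penalty=insertion_penalty)
    graph = build_decoding_graph(models, protocol, lm, dcfg)
    hyps, refs = [], []
    for word, rec in test_items:
        hyp = decode(six_channel_features(rec), graph, dcfg)
        hyps.append(hyp.characters)
        refs.append(list(word))
    return evaluate_corpus(hyps, refs)


# ---------------------------------------------------------------------------
# Experiment 1: unit kind x N-gram order grid


def run_unit_comparison(config: ExperimentConfig = ExperimentConfig()) -> pd.DataFrame:
    """User-dependent CER for each unit kind and N-gram order.

    Returns a DataFrame indexed by unit kind with one column per
    N-gram order, pooled over users.
    """
    root = np.random.default_rng(config.seed)
    proto_rng, lm_rng, word_rng = (np.random.default_rng(s)
                                   for s in root.integers(2**31, size=3))
    protocol = make_experiment_protocol(config, proto_rng)
    source = _text_source(protocol, config, lm_rng)
    words = make_test_words(protocol, config, word_rng, source)
    lms = _train_lms(source, config, lm_rng, config.ngram_orders)

    table = pd.DataFrame(index=list(config.unit_kinds),
                         columns=list(config.ngram_orders), dtype=float)
    # pool hypothesis/reference pairs over users, then score once
    pairs: dict[tuple[str, int], tuple[list, list]] = {
        (k, o): ([], []) for k in config.unit_kinds for o in config.ngram_orders
    }
    for u in range(config.n_users):
        user_rng = np.random.default_rng(root.integers(2**31))
        profile = sample_profiles(config, user_rng, n=1)[0]
        train = []
        for _ in range(config.units_per_user):
            train.extend(_training_unit(profile, config, user_rng))
        test_items = _word_recordings(words, protocol, profile, config, user_rng)
        for kind in config.unit_kinds:
            t0 = time.perf_counter()
            models = train_system(train, kind, config)
            logger.info("user %d %s training: %.1fs", u, kind,
                        time.perf_counter() - t0)
            for order in config.ngram_orders:
                dcfg = DecodeConfig(unit_kind=kind, beam=config.beam)
                graph = build_decoding_graph(models, protocol, lms[order], dcfg)
                t0 = time.perf_counter()
                for word, rec in test_items:
                    hyp = decode(six_channel_features(rec), graph, dcfg)
                    pairs[(kind, order)][0].append(hyp.characters)
                    pairs[(kind, order)][1].append(list(word))
                logger.info("user %d %s %d-gram decoding: %.1fs", u, kind,
                            order, time.perf_counter() - t0)
    for (kind, order), (hyps, refs) in pairs.items():
        table.loc[kind, order] = evaluate_corpus(hyps, refs)
    return table


def relative_reduction_report(table: pd.DataFrame) -> pd.DataFrame:
    """Relative CER reduction of bi/tri over mono, per N-gram order."""
    rows = []
    for order in table.columns:
        mono = table.loc["mono", order]
        for kind in table.index:
            if kind == "mono":
                continue
            rows.append({
                "order": order,
                "unit": kind,
                "cer_mono": mono,
                "cer": table.loc[kind, order],
                "relative_reduction": relative_reduction(mono, table.loc[kind, order])
                if mono > 0 else float("nan"),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment 2: user adaptation curves


def run_adaptation_curve(config: ExperimentConfig = ExperimentConfig()) -> pd.DataFrame:
    """Mean CER per adaptation method and adaptation amount.

    A user-independent tri system is trained on all pooled users, then
    adapted with MLLR / MAP / MAP + insertion-penalty tuning on
    ``n_repeats`` independently sampled adaptation subsets of the
    mismatched target user's data.  Returns a DataFrame indexed by
    method with one column per amount (units of adaptation data).
    """
    root = np.random.default_rng(config.seed)
    proto_rng, lm_rng, word_rng = (np.random.default_rng(s)
                                   for s in root.integers(2**31, size=3))
    protocol = make_experiment_protocol(config, proto_rng)
    source = _text_source(protocol, config, lm_rng)
    words = make_test_words(protocol, config, word_rng, source)
    lm = _train_lms(source, config, lm_rng,
                    [config.adapt_ngram_order])[config.adapt_ngram_order]
    kind = "tri"

    # pooled user-independent training set
    pool_rng = np.random.default_rng(root.integers(2**31))
    pool = []
    for profile in sample_profiles(config, pool_rng):
        for _ in range(config.units_per_user):
            pool.extend(_training_unit(profile, config, pool_rng))
    ui_models = train_system(pool, kind, config)

    target_rng = np.random.default_rng(root.integers(2**31))
    target = mismatched_target_profile(target_rng)
    test_items = _word_recordings(words, protocol, target, config, target_rng)
    max_units = int(np.ceil(max(config.adaptation_amounts)))
    target_train = []
    for _ in range(max_units):
        target_train.extend(_training_unit(target, config, target_rng))

    dcfg = DecodeConfig(unit_kind=kind, beam=config.beam)

    def cer_with(models, penalty=0.0):
        return _decode_cer(models, protocol, lm, kind, config, test_items,
                           insertion_penalty=penalty)

    no_adapt_cer = cer_with(ui_models)
    methods = ["none", "mllr", "map", "map+ins"]
    sums = {(m, a): [] for m in methods for a in config.adaptation_amounts}
    for rep in range(config.n_repeats):
        rep_rng = np.random.default_rng(root.integers(2**31))
        for amount in config.adaptation_amounts:
            n_seq = max(1, round(amount * SEQUENCES_PER_UNIT))
            idx = rep_rng.choice(len(target_train),
                                 size=min(n_seq, len(target_train)), replace=False)
            subset = [target_train[i] for i in idx]
            adapt_data = _labelled_features(subset, kind)
            if hasattr(ui_models, "model_for"):
                # materialise any tri units unseen in UI training through
                # the tying trees so the adaptation data is alignable
                for labels, _ in adapt_data:
                    for n in labels:
                        if n != SIL:
                            ui_models.model_for(n)
                model_dict = ui_models.all_cached()
            else:
                model_dict = ui_models
            mllr_models = mllr_adapt(model_dict, adapt_data)
            map_models = map_adapt(model_dict, adapt_data)
            sums[("none", amount)].append(no_adapt_cer)
            sums[("mllr", amount)].append(cer_with(mllr_models))
            sums[("map", amount)].append(cer_with(map_models))
            # tune the penalty on the adaptation data itself (held out
            # from the test words)
            map_graph = build_decoding_graph(map_models, protocol, lm, dcfg)
            dev_pairs = subset[: min(6, len(subset))]
            best_pen = _tune_penalty_on_motions(map_graph, dev_pairs, protocol,
                                                config, dcfg)
            sums[("map+ins", amount)].append(cer_with(map_models, best_pen))
    table = pd.DataFrame(index=methods,
                         columns=list(config.adaptation_amounts), dtype=float)
    for (m, a), vals in sums.items():
        table.loc[m, a] = float(np.mean(vals))
    return table


def _tune_penalty_on_motions(graph, dev_pairs, protocol, config, dcfg):
    """Insertion-penalty grid search scored on motion-sequence dev data.

    Adaptation sequences are free motion sequences, not protocol words,
    so they are scored at the motion level against the decoded
    hypothesis' motions.
    """
    best = None
    refs = [list(seq) for seq, _ in dev_pairs]
    for pen in config.penalty_grid:
        cfg = replace(dcfg, insertion_penalty=float(pen))
        hyps = []
        for _, rec in dev_pairs:
            hyp = decode(six_channel_features(rec), graph, cfg)
            hyps.append(hyp.motions)
        rate = evaluate_corpus(hyps, refs)
        key = (rate, abs(pen), -pen)
        if best is None or key < best[0]:
            best = (key, float(pen))
    return best[1]


# ---------------------------------------------------------------------------
# Experiment 3: threshold baseline vs HMMs (motion error rate)


def run_baseline_comparison(config: ExperimentConfig = ExperimentConfig()) -> dict:
    """Motion error rates: threshold baseline, 2-channel HMM, 6-channel HMM.

    Run on the default (high-noise, fused-input) population, where the
    instantaneous threshold decisions suffer most.  Returns a dict with
    keys ``threshold``, ``hmm_2ch``, ``hmm_6ch`` (percent).
    """
    root = np.random.default_rng(config.seed)
    results = {"threshold": ([], []), "hmm_2ch": ([], []), "hmm_6ch": ([], [])}
    motion_protocol = Protocol(
        table={m: (m,) for m in ("up", "down", "left", "right", "center")},
        strict=False,
    )
    for u in range(config.n_users):
        user_rng = np.random.default_rng(root.integers(2**31))
        profile = sample_profiles(config, user_rng, n=1)[0]
        train = []
        for _ in range(config.units_per_user):
            train.extend(_training_unit(profile, config, user_rng))
        test = _training_unit(profile, config, user_rng)
        # the vote window is sized to one typical motion (the stock
        # 1000 ms corresponds to ~1 s motions; ours are faster)
        thr_cfg = ThresholdConfig(
            center_threshold=0.5 * profile.amplitude_scale,
            vote_window_ms=1000.0 * profile.motion_duration_mean,
            vote_shift_ms=10.0,
            sample_rate=config.sample_rate)
        models6 = train_system(train, "mono", config)
        models2 = train_system(train, "mono", config, featurizer=two_channel_features)
        dcfg = DecodeConfig(unit_kind="mono", beam=config.beam)
        graph6 = build_decoding_graph(models6, motion_protocol, None, dcfg)
        graph2 = build_decoding_graph(models2, motion_protocol, None, dcfg)
        for seq, rec in test:
            ref = list(seq)
            results["threshold"][0].append(
                baseline_recognize(two_channel_features(rec), thr_cfg))
            results["threshold"][1].append(ref)
            results["hmm_2ch"][0].append(
                decode(two_channel_features(rec), graph2, dcfg).characters)
            results["hmm_2ch"][1].append(ref)
            results["hmm_6ch"][0].append(
                decode(six_channel_features(rec), graph6, dcfg).characters)
            results["hmm_6ch"][1].append(ref)
    return {k: evaluate_corpus(h, r) for k, (h, r) in results.items()}
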