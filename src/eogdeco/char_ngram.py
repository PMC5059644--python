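"""Backoff character N-gram language models over the Kana vocabulary.

Models of order 1-3 are trained with interpolated Witten-Bell
smoothing and stored in backoff form (log-probabilities for seen
n-grams plus a backoff weight per history), the representation used by
the ARPA interchange format.  For a history h with count c(h) and T(h)
distinct continuations, the Witten-Bell interpolation weight is
c(h)/(c(h)+T(h)); the unigram level interpolates with the uniform
distribution over the vocabulary, so every vocabulary symbol receives
non-zero probability.  Per-history distributions therefore sum to one
by construction.

Perplexity is the exponentiated mean negative log-probability per
scored character.  By default the sequence-final symbol is not scored;
``include_eos=True`` adds it.

Since the original 12-million-character Kana corpus used to train such
models is licensed, :func:`generate_kana_corpus` provides a synthetic
stand-in with Zipf-distributed character frequencies and first-order
Markov structure, so that higher-order models have something to learn.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "BOS",
    "EOS",
    "CharNgram",
    "train_ngram",
    "perplexity",
    "generate_kana_corpus",
    "write_arpa",
    "read_arpa",
    "NgramScorer",
    "NullScorer",
]

BOS = "<s>"
EOS = "</s>"

_LN10 = math.log(10.0)


@dataclass
class CharNgram:
    """A backoff character language model.

    ``logprob`` maps n-gram tuples (all orders, natural log) to their
    conditional log-probability; ``backoff`` maps history tuples to
    their backoff log-weight.  ``vocab`` lists the scorable symbols
    (characters plus the end-of-sequence symbol; the begin symbol
    appears only in histories).
    """

    order: int
    vocab: tuple[str, ...]
    logprob: dict[tuple, float]
    backoff: dict[tuple, float]
    smoothing: str = "witten-bell"

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def score(self, char: str, history: Sequence[str] = ()) -> float:
        """Natural-log conditional probability with backoff."""
        history = tuple(history)[-(self.order - 1):] if self.order > 1 else ()
        p = self.logprob.get(history + (char,))
        if p is not None:
            return p
        if self.smoothing == "none":
            warnings.warn(f"zero-probability event {history + (char,)!r}",
                          stacklevel=2)
            return -math.inf
        if not history:
            return -math.inf  # out-of-vocabulary symbol
        bow = self.backoff.get(history, 0.0)
        return bow + self.score(char, history[1:])

    def sequence_logprob(self, text: Sequence[str], include_eos: bool = True) -> float:
        history = [BOS] * (self.order - 1)
        total = 0.0
        for ch in text:
            total += self.score(ch, history)
            history.append(ch)
        if include_eos and self.order > 1:
            total += self.score(EOS, history)
        return total


def _count_ngrams(corpus, order):
    # Boundary symbols participate only for order >= 2; a unigram model
    # is a plain distribution over character tokens.
    counts = [dict() for _ in range(order + 1)]  # counts[k]: k-gram counts
    for seq in corpus:
        if order == 1:
            padded = list(seq)
        else:
            padded = [BOS] * (order - 1) + list(seq) + [EOS]
        for k in range(1, order + 1):
            start = max(0, order - k)
            for i in range(start, len(padded) - k + 1):
                gram = tuple(padded[i : i + k])
                if k == 1 and gram == (BOS,):
                    continue
                counts[k][gram] = counts[k].get(gram, 0) + 1
    return counts


def train_ngram(
    corpus: Iterable[Sequence[str]],
    order: int,
    smoothing: str = "witten-bell",
    vocab: Optional[Sequence[str]] = None,
) -> CharNgram:
    """Train a backoff character N-gram model.

    ``corpus`` is an iterable of character sequences; sentence boundary
    symbols are added internally.  ``smoothing`` is "witten-bell"
    (default) or "none" (maximum likelihood, zero mass for unseen
    events).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    corpus = [list(seq) for seq in corpus]
    if not corpus:
        raise ValueError("empty corpus")
    counts = _count_ngrams(corpus, order)
    if vocab is None:
        vocab_set = {w for (w,) in counts[1]}
        if order > 1:
            vocab_set.add(EOS)
        vocab = tuple(sorted(vocab_set))
    elif order > 1 and EOS not in vocab:
        vocab = tuple(vocab) + (EOS,)
    else:
        vocab = tuple(vocab)
    V = len(vocab)

    logprob: dict[tuple, float] = {}
    backoff: dict[tuple, float] = {}

    # probability of w given a history of length k-1, defined recursively
    def prob(gram: tuple) -> float:
        k = len(gram)
        c = counts[k].get(gram, 0)
        if smoothing == "none":
            if k == 1:
                total = sum(v for g, v in counts[1].items())
                return c / total if total else 0.0
            hist_count = _hist_count(gram[:-1])
            return c / hist_count if hist_count else 0.0
        if k == 1:
            total = sum(v for g, v in counts[1].items())
            T = len(counts[1])
            lam = total / (total + T) if total + T else 0.0
            return lam * (c / total if total else 0.0) + (1 - lam) / V
        hist = gram[:-1]
        hist_count = _hist_count(hist)
        T = _hist_types(hist)
        if hist_count + T == 0:
            return prob(gram[1:])
        lam = hist_count / (hist_count + T)
        mle = c / hist_count if hist_count else 0.0
        return lam * mle + (1 - lam) * prob(gram[1:])

    _hist_count_cache: dict[tuple, int] = {}
    _hist_types_cache: dict[tuple, int] = {}

    def _hist_count(hist: tuple) -> int:
        if hist not in _hist_count_cache:
            k = len(hist) + 1
            _hist_count_cache[hist] = sum(
                v for g, v in counts[k].items() if g[:-1] == hist
            )
        return _hist_count_cache[hist]

    def _hist_types(hist: tuple) -> int:
        if hist not in _hist_types_cache:
            k = len(hist) + 1
            _hist_types_cache[hist] = sum(1 for g in counts[k] if g[:-1] == hist)
        return _hist_types_cache[hist]

    for k in range(1, order + 1):
        for gram in counts[k]:
            p = prob(gram)
            if p > 0:
                logprob[gram] = math.log(p)
        if smoothing != "none" and k == 1:
            # give every vocabulary symbol a unigram entry
            for w in vocab:
                gram = (w,)
                if gram not in logprob:
                    p = prob(gram)
                    if p > 0:
                        logprob[gram] = math.log(p)
    if smoothing != "none":
        for k in range(1, order):
            for gram in counts[k]:
                hist = gram
                if hist == (EOS,) or (hist and hist[-1] == EOS):
                    continue
                hc = _hist_count(hist)
                T = _hist_types(hist)
                if hc + T > 0 and T > 0:
                    backoff[hist] = math.log(T / (hc + T))
        # histories made only of BOS symbols never occur as counted grams
        for k in range(1, order):
            hist = tuple([BOS] * k)
            hc = _hist_count(hist)
            T = _hist_types(hist)
            if T > 0:
                backoff[hist] = math.log(T / (hc + T))
    return CharNgram(order=order, vocab=vocab, logprob=logprob,
                     backoff=backoff, smoothing=smoothing)


def perplexity(model: CharNgram, text: Sequence[str], include_eos: bool = False) -> float:
    """Exponentiated mean negative log-probability per scored symbol."""
    text = list(text)
    if not text:
        raise ValueError("empty text")
    lp = model.sequence_logprob(text, include_eos=include_eos)
    n = len(text) + (1 if include_eos else 0)
    if not math.isfinite(lp):
        warnings.warn("zero-probability event; perplexity is infinite", stacklevel=2)
        return math.inf
    return math.exp(-lp / n)


# ---------------------------------------------------------------------------
# Synthetic training text


class KanaTextModel:
    """A fixed Zipf-frequency, first-order-Markov character source.

    Character unigram frequencies follow a Zipf law over a seeded
    permutation of the vocabulary; each character additionally biases
    the distribution of its successor (a rotated rank emphasis
    multiplied into the Zipf base, keeping the marginals skewed), so
    bigram and trigram models gain over the unigram.  One instance
    defines one language: training text and test words drawn from the
    same instance share their distribution.
    """

    def __init__(self, vocabulary: Sequence[str], seed: int):
        self.chars = list(vocabulary)
        V = len(self.chars)
        rng = np.random.default_rng(seed)
        ranks = rng.permutation(V)
        base = 1.0 / (np.argsort(ranks) + 2.0)
        self.base = base / base.sum()
        decay = 1.0 / (np.arange(V) + 1.0)
        rotations = rng.integers(1, V, size=V)
        self.trans = np.empty((V, V))
        for i in range(V):
            p = self.base * np.roll(decay, int(rotations[i]))
            self.trans[i] = p / p.sum()

    def sample(self, length: int, rng: np.random.Generator) -> list[str]:
        sent = []
        prev = None
        for _ in range(length):
            p = self.base if prev is None else self.trans[prev]
            prev = int(rng.choice(len(self.chars), p=p))
            sent.append(self.chars[prev])
        return sent

    def corpus(self, n_sentences: int, rng: np.random.Generator,
               mean_length: float = 12.0) -> list[list[str]]:
        return [self.sample(max(2, int(rng.poisson(mean_length))), rng)
                for _ in range(n_sentences)]


def generate_kana_corpus(
    n_sentences: int,
    vocabulary: Sequence[str],
    rng: np.random.Generator,
    mean_length: float = 12.0,
) -> list[list[str]]:
    """Sample a synthetic character corpus (see :class:`KanaTextModel`)."""
    source = KanaTextModel(vocabulary, seed=int(rng.integers(2**31)))
    return source.corpus(n_sentences, rng, mean_length)


# ---------------------------------------------------------------------------
# ARPA interchange format


_ARPA_SENTINEL = -99.0  # conventional "no probability" marker (log10)


def write_arpa(model: CharNgram, path: str | Path) -> None:
    """Write the model in the standard ARPA backoff format (log10).

    Histories that carry a backoff weight but no probability of their
    own (e.g. the begin symbol) get the conventional -99 entry.
    """
    grams_by_order = [[] for _ in range(model.order + 1)]
    for gram, lp in model.logprob.items():
        grams_by_order[len(gram)].append(gram)
    for hist in model.backoff:
        if hist not in model.logprob:
            grams_by_order[len(hist)].append(hist)
    with open(Path(path), "w") as fh:
        fh.write("\\data\\\n")
        for k in range(1, model.order + 1):
            fh.write(f"ngram {k}={len(grams_by_order[k])}\n")
        for k in range(1, model.order + 1):
            fh.write(f"\n\\{k}-grams:\n")
            for gram in sorted(grams_by_order[k]):
                lp = model.logprob.get(gram)
                lp10 = _ARPA_SENTINEL if lp is None else lp / _LN10
                line = f"{lp10:.10e}\t{' '.join(gram)}"
                if k < model.order and gram in model.backoff:
                    line += f"\t{model.backoff[gram] / _LN10:.10e}"
                fh.write(line + "\n")
        fh.write("\n\\end\\\n")


def read_arpa(path: str | Path) -> CharNgram:
    """Read an ARPA backoff model written by :func:`write_arpa`."""
    logprob: dict[tuple, float] = {}
    backoff: dict[tuple, float] = {}
    order = 0
    with open(Path(path)) as fh:
        section = None
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line == "\\data\\":
                section = "data"
                continue
            if line == "\\end\\":
                break
            if line.startswith("\\") and line.endswith("-grams:"):
                section = int(line[1:].split("-")[0])
                order = max(order, section)
                continue
            if section == "data":
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed ARPA line {line!r}")
            lp10 = float(parts[0])
            gram = tuple(parts[1].split(" "))
            if lp10 > _ARPA_SENTINEL + 0.5:
                logprob[gram] = lp10 * _LN10
            if len(parts) == 3:
                backoff[gram] = float(parts[2]) * _LN10
    vocab = tuple(sorted(w for (w,) in (g for g in logprob if len(g) == 1)
                         if w != BOS))
    return CharNgram(order=order, vocab=vocab, logprob=logprob, backoff=backoff)


# ---------------------------------------------------------------------------
# Decoder-facing scoring automaton


class NgramScorer:
    """Deterministic history automaton view of a :class:`CharNgram`."""

    def __init__(self, model: CharNgram):
        self.model = model

    def start(self) -> tuple:
        return tuple([BOS] * (self.model.order - 1))

    def step(self, history: tuple, char: str) -> tuple[float, tuple]:
        lp = self.model.score(char, history)
        if self.model.order == 1:
            return lp, ()
        new = (history + (char,))[-(self.model.order - 1):]
        return lp, new

    def final(self, history: tuple) -> float:
        if self.model.order == 1:
            return 0.0
        return self.model.score(EOS, history)


class NullScorer:
    """0-gram mode: no language-model scores."""

    def start(self) -> tuple:
        return ()

    def step(self, history: tuple, char: str) -> tuple[float, tuple]:
        return 0.0, ()

    def final(self, history: tuple) -> float:
        return 0.0
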