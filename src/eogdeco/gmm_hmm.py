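"""Left-to-right Gaussian-mixture hidden Markov models.

Each modelling unit (an eye motion, possibly context-dependent, or the
boundary silence) is a strict left-to-right HMM -- default four emitting
states, no skips -- whose state emissions are diagonal-covariance
Gaussian mixtures.  Every state row of the transition matrix carries an
extra exit column, so a model is a terminating process: entry is always
at state 0 and the exit transition of the last state leads out of the
unit.  Continuous training and recognition compose units into linear
chains by connecting each unit's exit to the next unit's entry.

Training is embedded Baum-Welch: per utterance, the labelled unit
sequence is composed into a chain, forward-backward occupancies are
accumulated for every state and mixture component, and all unit
parameters are re-estimated jointly.  Mixtures are grown along a
schedule (1 -> 2 -> 4 -> 8 -> 16 by default) by binary splitting of
every component with means perturbed by +/-0.2 standard deviations.
State tying is expressed through object sharing: two logical unit
states that share one :class:`StateGmm` instance (or one transition
array) are accumulated and updated as a single physical state.

All probability computations are carried out in the log domain.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .features import FeatureSequence

__all__ = [
    "StateGmm",
    "GmmHmm",
    "Chain",
    "TrainingConfig",
    "SuffStats",
    "Accumulator",
    "flat_start_models",
    "collect_stats",
    "baum_welch",
    "log_likelihood",
    "viterbi_align",
    "split_mixtures",
    "save_models",
    "load_models",
]

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
NEG_INF = -np.inf


class StateGmm:
    """Diagonal-covariance Gaussian mixture emission of one HMM state."""

    __slots__ = ("log_weights", "means", "variances")

    def __init__(self, weights, means, variances):
        weights = np.asarray(weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(variances, dtype=float))
        if weights.ndim != 1 or len(weights) != len(self.means):
            raise ValueError("weights/means shape mismatch")
        if self.means.shape != self.variances.shape:
            raise ValueError("means/variances shape mismatch")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if abs(weights.sum() - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1")
        with np.errstate(divide="ignore"):
            self.log_weights = np.log(weights)

    # -- basic properties ---------------------------------------------------
    @property
    def n_components(self) -> int:
        return len(self.means)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    @classmethod
    def single(cls, mean, variance) -> "StateGmm":
        return cls([1.0], [np.asarray(mean)], [np.asarray(variance)])

    def copy(self) -> "StateGmm":
        return StateGmm(self.weights, self.means.copy(), self.variances.copy())

    # -- densities ----------------------------------------------------------
    def component_log_pdf(self, X: np.ndarray) -> np.ndarray:
        """Per-component log densities, shape (T, M)."""
        X = np.atleast_2d(X)
        diff = X[:, None, :] - self.means[None, :, :]
        quad = np.sum(diff * diff / self.variances[None, :, :], axis=2)
        const = -0.5 * (self.dim * _LOG2PI + np.sum(np.log(self.variances), axis=1))
        return const[None, :] - 0.5 * quad

    def log_pdf(self, X: np.ndarray) -> np.ndarray:
        """Mixture log density per frame, shape (T,)."""
        return logsumexp(self.component_log_pdf(X) + self.log_weights[None, :], axis=1)

    # -- mixture growing ----------------------------------------------------
    def split(self, perturbation: float = 0.2) -> None:
        """Binary-split every component, means +/- ``perturbation`` sigma."""
        sigma = np.sqrt(self.variances)
        means = np.concatenate(
            [self.means + perturbation * sigma, self.means - perturbation * sigma]
        )
        variances = np.concatenate([self.variances, self.variances])
        log_w = np.concatenate([self.log_weights, self.log_weights]) - math.log(2.0)
        self.means, self.variances, self.log_weights = means, variances, log_w

    def set_params(self, weights, means, variances) -> None:
        with np.errstate(divide="ignore"):
            self.log_weights = np.log(np.asarray(weights, dtype=float))
        self.means = np.asarray(means, dtype=float)
        self.variances = np.asarray(variances, dtype=float)


class GmmHmm:
    """A left-to-right unit HMM over a list of (possibly shared) states.

    ``log_trans`` has shape (n_states, n_states + 1); column ``n`` is
    the exit transition.  Rows are log-probabilities summing to one with
    mass only on the diagonal, the superdiagonal and (for the last
    state) the exit column.
    """

    def __init__(self, name: str, states: list[StateGmm], log_trans: np.ndarray):
        self.name = name
        self.states = states
        self.log_trans = np.asarray(log_trans, dtype=float)
        n = len(states)
        if self.log_trans.shape != (n, n + 1):
            raise ValueError("log_trans must have shape (n_states, n_states+1)")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def dim(self) -> int:
        return self.states[0].dim

    @classmethod
    def left_to_right(
        cls,
        name: str,
        n_states: int,
        mean: np.ndarray,
        variance: np.ndarray,
        self_prob: float = 0.6,
    ) -> "GmmHmm":
        """Flat left-to-right model with identical single-Gaussian states."""
        states = [StateGmm.single(mean, variance) for _ in range(n_states)]
        trans = np.full((n_states, n_states + 1), NEG_INF)
        for i in range(n_states):
            trans[i, i] = math.log(self_prob)
            trans[i, i + 1] = math.log(1.0 - self_prob)
        return cls(name, states, trans)

    def log_likelihood(self, obs) -> float:
        return Chain([self]).log_likelihood(_as_array(obs))

    def sample(self, rng: np.random.Generator, max_len: int = 100000) -> np.ndarray:
        """Sample one observation sequence by running the model to exit."""
        out = []
        s = 0
        n = self.n_states
        for _ in range(max_len):
            g = self.states[s]
            comp = rng.choice(g.n_components, p=g.weights)
            out.append(rng.normal(g.means[comp], np.sqrt(g.variances[comp])))
            probs = np.exp(self.log_trans[s])
            nxt = rng.choice(n + 1, p=probs / probs.sum())
            if nxt == n:
                break
            s = nxt
        return np.asarray(out)


def _as_array(obs) -> np.ndarray:
    if isinstance(obs, FeatureSequence):
        return obs.vectors
    return np.atleast_2d(np.asarray(obs, dtype=float))


# ---------------------------------------------------------------------------
# Chain composition and forward-backward machinery


class Chain:
    """Linear composition of unit HMMs for one labelled sequence."""

    def __init__(self, models: Sequence[GmmHmm]):
        if not models:
            raise ValueError("empty chain")
        self.models = list(models)
        self.states: list[StateGmm] = []
        self.owner: list[tuple[GmmHmm, int]] = []  # (unit, local state index)
        log_stay, log_adv = [], []
        for m in self.models:
            n = m.n_states
            for i in range(n):
                self.states.append(m.states[i])
                self.owner.append((m, i))
                log_stay.append(m.log_trans[i, i])
                # advancing out of a unit-final state uses its exit prob
                log_adv.append(m.log_trans[i, i + 1] if i < n - 1 else m.log_trans[i, n])
        self.log_stay = np.asarray(log_stay)
        self.log_adv = np.asarray(log_adv)  # last entry = chain exit log-prob
        self.n_states = len(self.states)

    # -- emissions ----------------------------------------------------------
    def emissions(self, X: np.ndarray) -> np.ndarray:
        """Per-state frame log densities (T, S); shared states computed once."""
        cache: dict[int, np.ndarray] = {}
        cols = []
        for g in self.states:
            key = id(g)
            if key not in cache:
                cache[key] = g.log_pdf(X)
            cols.append(cache[key])
        return np.column_stack(cols)

    def forward(self, logB: np.ndarray) -> tuple[np.ndarray, float]:
        T, S = logB.shape
        alpha = np.full((T, S), NEG_INF)
        alpha[0, 0] = logB[0, 0]
        for t in range(1, T):
            stay = alpha[t - 1] + self.log_stay
            adv = np.full(S, NEG_INF)
            adv[1:] = alpha[t - 1, :-1] + self.log_adv[:-1]
            alpha[t] = logB[t] + np.logaddexp(stay, adv)
        ll = alpha[T - 1, S - 1] + self.log_adv[S - 1]
        return alpha, float(ll)

    def backward(self, logB: np.ndarray) -> np.ndarray:
        T, S = logB.shape
        beta = np.full((T, S), NEG_INF)
        beta[T - 1, S - 1] = self.log_adv[S - 1]
        for t in range(T - 2, -1, -1):
            stay = self.log_stay + logB[t + 1] + beta[t + 1]
            adv = np.full(S, NEG_INF)
            adv[:-1] = self.log_adv[:-1] + logB[t + 1, 1:] + beta[t + 1, 1:]
            beta[t] = np.logaddexp(stay, adv)
        return beta

    def log_likelihood(self, X: np.ndarray) -> float:
        X = _as_array(X)
        if len(X) < self.n_states:
            return NEG_INF  # no admissible path through a no-skip chain
        _, ll = self.forward(self.emissions(X))
        return ll

    def viterbi(self, X: np.ndarray):
        """Best state path; returns (list of (unit_name, local_state), score)."""
        X = _as_array(X)
        T, S = len(X), self.n_states
        if T < S:
            return None, NEG_INF
        logB = self.emissions(X)
        delta = np.full((T, S), NEG_INF)
        psi = np.zeros((T, S), dtype=np.int8)  # 0 = stay, 1 = advance
        delta[0, 0] = logB[0, 0]
        for t in range(1, T):
            stay = delta[t - 1] + self.log_stay
            adv = np.full(S, NEG_INF)
            adv[1:] = delta[t - 1, :-1] + self.log_adv[:-1]
            take_adv = adv > stay
            psi[t] = take_adv
            delta[t] = logB[t] + np.where(take_adv, adv, stay)
        score = delta[T - 1, S - 1] + self.log_adv[S - 1]
        if not np.isfinite(score):
            return None, NEG_INF
        path = np.empty(T, dtype=int)
        s = S - 1
        for t in range(T - 1, -1, -1):
            path[t] = s
            if t > 0 and psi[t, s]:
                s -= 1
        named = [(self.owner[s][0].name, self.owner[s][1]) for s in path]
        return named, float(score)


# ---------------------------------------------------------------------------
# Sufficient statistics and Baum-Welch


@dataclass
class SuffStats:
    """Zeroth/first/second-order mixture statistics of one physical state."""

    occ: np.ndarray  # (M,)
    sum_x: np.ndarray  # (M, d)
    sum_xx: np.ndarray  # (M, d)

    @classmethod
    def zeros(cls, n_components: int, dim: int) -> "SuffStats":
        return cls(np.zeros(n_components), np.zeros((n_components, dim)),
                   np.zeros((n_components, dim)))

    @property
    def total_occ(self) -> float:
        return float(self.occ.sum())

    def pooled(self) -> tuple[float, np.ndarray, np.ndarray]:
        """Single-Gaussian view: (occupancy, sum x, sum x^2)."""
        return self.total_occ, self.sum_x.sum(axis=0), self.sum_xx.sum(axis=0)


class Accumulator:
    """Occupancy statistics keyed by physical state / transition identity."""

    def __init__(self):
        self.state_stats: dict[int, SuffStats] = {}
        self.state_obj: dict[int, StateGmm] = {}
        self.trans_counts: dict[int, np.ndarray] = {}
        self.trans_obj: dict[int, np.ndarray] = {}
        self.total_ll = 0.0
        self.n_frames = 0

    def _stats_for(self, g: StateGmm) -> SuffStats:
        key = id(g)
        if key not in self.state_stats:
            self.state_stats[key] = SuffStats.zeros(g.n_components, g.dim)
            self.state_obj[key] = g
        return self.state_stats[key]

    def _trans_for(self, m: GmmHmm) -> np.ndarray:
        key = id(m.log_trans)
        if key not in self.trans_counts:
            self.trans_counts[key] = np.zeros_like(m.log_trans)
            self.trans_obj[key] = m.log_trans
        return self.trans_counts[key]

    def accumulate(self, chain: Chain, X: np.ndarray) -> float:
        """Forward-backward one utterance; returns its log-likelihood."""
        X = _as_array(X)
        T, S = len(X), chain.n_states
        if T < S:
            logger.warning("utterance shorter than its chain (%d < %d); skipped", T, S)
            return NEG_INF
        logB = chain.emissions(X)
        alpha, ll = chain.forward(logB)
        if not np.isfinite(ll):
            logger.warning("utterance has -inf likelihood; skipped")
            return NEG_INF
        beta = chain.backward(logB)
        log_gamma = alpha + beta - ll
        gamma = np.exp(log_gamma)

        # state/mixture occupancies
        for s, g in enumerate(chain.states):
            occ_t = gamma[:, s]
            nz = occ_t > 1e-12
            if not np.any(nz):
                continue
            stats = self._stats_for(g)
            if g.n_components == 1:
                w = occ_t[nz][:, None]
                stats.occ[0] += occ_t[nz].sum()
                stats.sum_x[0] += (w * X[nz]).sum(axis=0)
                stats.sum_xx[0] += (w * X[nz] ** 2).sum(axis=0)
            else:
                comp = g.component_log_pdf(X[nz]) + g.log_weights[None, :]
                comp -= logsumexp(comp, axis=1, keepdims=True)
                w = np.exp(comp) * occ_t[nz][:, None]  # (t, M)
                stats.occ += w.sum(axis=0)
                stats.sum_x += w.T @ X[nz]
                stats.sum_xx += w.T @ (X[nz] ** 2)

        # transition occupancies
        with np.errstate(invalid="ignore"):
            xi_stay = np.exp(
                alpha[:-1] + chain.log_stay[None, :] + logB[1:] + beta[1:] - ll
            )
            xi_adv = np.exp(
                alpha[:-1, :-1] + chain.log_adv[None, :-1] + logB[1:, 1:] + beta[1:, 1:] - ll
            )
        stay_tot = xi_stay.sum(axis=0)
        adv_tot = np.zeros(S)
        adv_tot[:-1] = xi_adv.sum(axis=0)
        adv_tot[-1] = 1.0  # the chain always exits from the final state
        for s, (m, i) in enumerate(chain.owner):
            counts = self._trans_for(m)
            counts[i, i] += stay_tot[s]
            if i < m.n_states - 1:
                counts[i, i + 1] += adv_tot[s]
            else:
                counts[i, m.n_states] += adv_tot[s]
        self.total_ll += ll
        self.n_frames += T
        return ll


@dataclass
class TrainingConfig:
    """Knobs of embedded Baum-Welch training."""

    n_iterations: int = 5
    mixture_schedule: tuple[int, ...] = (1, 2, 4, 8, 16)
    variance_floor_scale: float = 1e-4
    convergence_tol: float = 1e-4
    min_state_occupancy: float = 0.5
    min_component_occupancy: float = 1e-2
    split_perturbation: float = 0.2
    self_loop_init: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if any(b < a for a, b in zip(self.mixture_schedule, self.mixture_schedule[1:])):
            raise ValueError("mixture_schedule must be non-decreasing")


def _corpus_arrays(corpus) -> list[tuple[tuple[str, ...], np.ndarray]]:
    out = []
    for labels, obs in corpus:
        out.append((tuple(labels), _as_array(obs)))
    return out


def global_stats(corpus) -> tuple[np.ndarray, np.ndarray]:
    """Global mean and variance over all corpus frames."""
    data = np.concatenate([X for _, X in _corpus_arrays(corpus)])
    return data.mean(axis=0), data.var(axis=0)


def flat_start_models(
    unit_names: Iterable[str],
    corpus,
    n_states: int = 4,
    config: TrainingConfig | None = None,
) -> dict[str, GmmHmm]:
    """Identical single-Gaussian models initialised from global statistics."""
    config = config or TrainingConfig()
    mean, var = global_stats(corpus)
    var = np.maximum(var, 1e-8)
    return {
        name: GmmHmm.left_to_right(name, n_states, mean, var, config.self_loop_init)
        for name in unit_names
    }


def _build_chains(models: dict[str, GmmHmm], corpus):
    chains = []
    for labels, X in _corpus_arrays(corpus):
        try:
            chain = Chain([models[name] for name in labels])
        except KeyError as e:
            raise KeyError(f"no model for unit {e.args[0]!r}") from None
        chains.append((chain, X))
    return chains


def collect_stats(models: dict[str, GmmHmm], corpus) -> Accumulator:
    """One E-pass over the corpus (used for tying, MLLR and MAP)."""
    acc = Accumulator()
    for chain, X in _build_chains(models, corpus):
        acc.accumulate(chain, X)
    return acc


def _m_step(acc: Accumulator, var_floor: np.ndarray, config: TrainingConfig) -> None:
    for key, stats in acc.state_stats.items():
        g = acc.state_obj[key]
        if stats.total_occ < config.min_state_occupancy:
            logger.warning("state starved of occupancy (%.3g); keeping parameters",
                           stats.total_occ)
            continue
        occ = stats.occ
        keep = occ < config.min_component_occupancy
        weights = np.maximum(occ, 1e-30)
        weights = weights / weights.sum()
        means = np.where(keep[:, None], g.means,
                         stats.sum_x / np.maximum(occ, 1e-30)[:, None])
        var = stats.sum_xx / np.maximum(occ, 1e-30)[:, None] - means**2
        variances = np.where(keep[:, None], g.variances,
                             np.maximum(var, var_floor[None, :]))
        g.set_params(weights, means, variances)
    for key, counts in acc.trans_counts.items():
        trans = acc.trans_obj[key]
        rows = counts.sum(axis=1)
        for i in np.flatnonzero(rows > 0):
            with np.errstate(divide="ignore"):
                trans[i, :] = np.log(counts[i] / rows[i])


def baum_welch(
    models: dict[str, GmmHmm],
    corpus,
    config: TrainingConfig | None = None,
    var_floor: np.ndarray | None = None,
) -> tuple[dict[str, GmmHmm], list[float]]:
    """Embedded EM training with mixture growing.

    ``corpus`` is an iterable of ``(unit_label_sequence, observations)``
    pairs.  Models are updated in place (tying through shared state
    objects is respected); the per-iteration total log-likelihood
    history is returned alongside.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    config = config or TrainingConfig()
    if var_floor is None:
        _, gvar = global_stats(corpus)
        var_floor = np.maximum(config.variance_floor_scale * gvar, 1e-12)

    def unique_states():
        seen = {}
        for m in models.values():
            for g in m.states:
                seen[id(g)] = g
        return list(seen.values())

    history: list[float] = []
    current_mix = max(g.n_components for g in unique_states())
    for target_mix in config.mixture_schedule:
        while current_mix < target_mix:
            for g in unique_states():
                g.split(config.split_perturbation)
            current_mix *= 2
        prev_ll = None
        for _ in range(config.n_iterations):
            # chains are rebuilt so transition updates take effect
            acc = Accumulator()
            for chain, X in _build_chains(models, corpus):
                acc.accumulate(chain, X)
            _m_step(acc, var_floor, config)
            history.append(acc.total_ll)
            if prev_ll is not None and abs(acc.total_ll - prev_ll) <= (
                config.convergence_tol * max(1.0, abs(prev_ll))
            ):
                break
            prev_ll = acc.total_ll
    return models, history


# ---------------------------------------------------------------------------
# Convenience wrappers matching the operation-level API


def log_likelihood(model, obs) -> float:
    """Forward log-likelihood of ``obs`` under a unit model or chain."""
    if isinstance(model, Chain):
        return model.log_likelihood(_as_array(obs))
    return model.log_likelihood(obs)


def viterbi_align(graph, obs):
    """Best-path alignment through a chain (or single unit model)."""
    chain = graph if isinstance(graph, Chain) else Chain([graph])
    return chain.viterbi(_as_array(obs))


def split_mixtures(models: dict[str, GmmHmm], perturbation: float = 0.2) -> None:
    """Binary-split every unique physical state of a model set."""
    seen = set()
    for m in models.values():
        for g in m.states:
            if id(g) not in seen:
                seen.add(id(g))
                g.split(perturbation)


# ---------------------------------------------------------------------------
# JSON serialization (sharing-preserving)

MODEL_FORMAT = "eogdeco-models"
MODEL_VERSION = 1


def save_models(models: dict[str, GmmHmm], path: str | Path,
                metadata: Optional[dict] = None) -> None:
    state_ids: dict[int, int] = {}
    states_out = []
    trans_ids: dict[int, int] = {}
    trans_out = []
    units = {}
    for name in sorted(models):
        m = models[name]
        sids = []
        for g in m.states:
            if id(g) not in state_ids:
                state_ids[id(g)] = len(states_out)
                states_out.append({
                    "weights": np.exp(g.log_weights).tolist(),
                    "means": g.means.tolist(),
                    "variances": g.variances.tolist(),
                })
            sids.append(state_ids[id(g)])
        if id(m.log_trans) not in trans_ids:
            trans_ids[id(m.log_trans)] = len(trans_out)
            trans_out.append(np.where(np.isfinite(m.log_trans), m.log_trans, None).tolist())
        units[name] = {"states": sids, "trans": trans_ids[id(m.log_trans)]}
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "dim": next(iter(models.values())).dim if models else 0,
        "states": states_out,
        "transitions": trans_out,
        "units": units,
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_models(path: str | Path) -> dict[str, GmmHmm]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: not an {MODEL_FORMAT} file")
    states = [
        StateGmm(s["weights"], s["means"], s["variances"]) for s in doc["states"]
    ]
    transitions = [
        np.array([[NEG_INF if v is None else float(v) for v in row] for row in t])
        for t in doc["transitions"]
    ]
    models = {}
    for name, u in doc["units"].items():
        models[name] = GmmHmm(name, [states[i] for i in u["states"]],
                              transitions[u["trans"]])
    return models
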