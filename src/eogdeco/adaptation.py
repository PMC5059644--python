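"""User adaptation of a user-independent model set.

EOG signals differ across users in amplitude and eye-motion speed, so a
model pooled over other users misrecognises a new one.  Three
complementary remedies are provided:

* **MLLR** (maximum likelihood linear regression): Gaussian means are
  transformed as ``A mu + b`` per regression class, with the affine
  transform estimated from forward-backward occupancies of the
  adaptation data.  Mean-only, one global class by default.
* **MAP** (maximum a posteriori): per-component Bayesian interpolation
  between the prior mean and the occupancy-weighted data mean,
  ``mu' = (tau mu0 + sum gamma x) / (tau + sum gamma)``, with prior
  count ``tau`` (default 10 frames).  Components unseen in the
  adaptation data keep their prior.
* **Insertion-penalty tuning**: grid search of the decoder's insertion
  penalty minimising the character error rate on a development set,
  which compensates for user-specific input speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .decoder import DecodeConfig, DecodingGraph, decode
from .evaluation import evaluate_corpus
from .features import FeatureSequence
from .gmm_hmm import GmmHmm, StateGmm, collect_stats

__all__ = ["MllrTransform", "MapConfig", "mllr_adapt", "map_adapt",
           "tune_insertion_penalty"]

logger = logging.getLogger(__name__)


@dataclass
class MllrTransform:
    """Per-class affine mean transforms and the component class map."""

    A: list[np.ndarray]  # (d, d) per class
    b: list[np.ndarray]  # (d,) per class
    classes: dict[tuple[int, int], int]  # (state id, component) -> class


@dataclass(frozen=True)
class MapConfig:
    """MAP prior weight ``tau`` in frames of equivalent prior evidence."""

    tau: float = 10.0

    def __post_init__(self):
        if not np.isfinite(self.tau) or self.tau < 0:
            raise ValueError("tau must be finite and non-negative")


def _clone_model_set(models: dict[str, GmmHmm]) -> dict[str, GmmHmm]:
    """Deep-copy a model set preserving the state/transition sharing."""
    state_map: dict[int, StateGmm] = {}
    trans_map: dict[int, np.ndarray] = {}
    out = {}
    for name, m in models.items():
        states = []
        for g in m.states:
            if id(g) not in state_map:
                state_map[id(g)] = g.copy()
            states.append(state_map[id(g)])
        if id(m.log_trans) not in trans_map:
            trans_map[id(m.log_trans)] = m.log_trans.copy()
        out[name] = GmmHmm(name, states, trans_map[id(m.log_trans)])
    return out


def _unique_states(models: dict[str, GmmHmm]) -> list[StateGmm]:
    seen = {}
    for m in models.values():
        for g in m.states:
            seen[id(g)] = g
    return list(seen.values())


def mllr_adapt(
    models: dict[str, GmmHmm],
    adaptation_data,
    n_classes: int = 1,
    *,
    n_iterations: int = 2,
    min_class_occupancy: Optional[float] = None,
) -> dict[str, GmmHmm]:
    """Mean-only MLLR adaptation; returns a transformed copy of the set.

    ``adaptation_data`` is an iterable of ``(unit_labels, features)``
    pairs alignable with the models.  Components are grouped into
    ``n_classes`` regression classes by k-means on their means; a class
    whose occupancy falls below the feature dimensionality is merged
    into the global class.  The transform estimation is iterated
    (default twice): re-aligning with the adapted models removes most
    of the occupancy bias of the first pass.
    """
    adapted = models
    for _ in range(max(1, n_iterations)):
        adapted = _mllr_once(adapted, adaptation_data, n_classes,
                             min_class_occupancy)
    return adapted


def _mllr_once(models, adaptation_data, n_classes, min_class_occupancy):
    adapted = _clone_model_set(models)
    acc = collect_stats(adapted, adaptation_data)
    states = _unique_states(adapted)
    dim = states[0].dim
    if min_class_occupancy is None:
        min_class_occupancy = float(dim)

    comps = []  # (state, m, occ, sum_x)
    for g in states:
        stats = acc.state_stats.get(id(g))
        for m in range(g.n_components):
            occ = stats.occ[m] if stats is not None else 0.0
            sx = stats.sum_x[m] if stats is not None else np.zeros(dim)
            comps.append((g, m, occ, sx))

    if n_classes > 1:
        means = np.array([g.means[m] for g, m, _, _ in comps])
        labels = KMeans(n_clusters=n_classes, n_init=4, random_state=0).fit_predict(means)
    else:
        labels = np.zeros(len(comps), dtype=int)

    # merge starved classes into a single global class (label -1)
    class_occ = np.zeros(n_classes)
    for lab, (_, _, occ, _) in zip(labels, comps):
        class_occ[lab] += occ
    merged = class_occ < min_class_occupancy
    if merged.any() and n_classes > 1:
        logger.warning("%d MLLR class(es) starved; merged into global class",
                       int(merged.sum()))

    def solve(member_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # per-dimension row solution for diagonal covariances
        G = np.zeros((dim, dim + 1, dim + 1))
        k = np.zeros((dim, dim + 1))
        for i in member_idx:
            g, m, occ, sx = comps[i]
            if occ <= 0:
                continue
            xi = np.append(g.means[m], 1.0)
            outer = np.outer(xi, xi)
            for d in range(dim):
                inv = 1.0 / g.variances[m, d]
                G[d] += occ * inv * outer
                k[d] += sx[d] * inv * xi
        W = np.empty((dim, dim + 1))
        for d in range(dim):
            try:
                W[d] = np.linalg.solve(G[d] + 1e-8 * np.eye(dim + 1), k[d])
            except np.linalg.LinAlgError:
                W[d] = np.append(np.eye(dim)[d], 0.0)
        return W[:, :dim], W[:, dim]

    all_idx = np.arange(len(comps))
    if n_classes > 1 and merged.any():
        global_A, global_b = solve(all_idx)
    transforms = {}
    for c in range(n_classes):
        idx = all_idx[labels == c]
        if n_classes > 1 and merged[c]:
            transforms[c] = (global_A, global_b)
        else:
            transforms[c] = solve(idx)

    new_means = {id(g): g.means.copy() for g in states}
    for lab, (g, m, _, _) in zip(labels, comps):
        A, b = transforms[lab]
        new_means[id(g)][m] = A @ g.means[m] + b
    for g in states:
        g.means = new_means[id(g)]
    return adapted


def map_adapt(
    models: dict[str, GmmHmm],
    adaptation_data,
    config: MapConfig = MapConfig(),
) -> dict[str, GmmHmm]:
    """MAP mean update; returns an updated copy of the model set."""
    adapted = _clone_model_set(models)
    acc = collect_stats(adapted, adaptation_data)
    tau = config.tau
    for g in _unique_states(adapted):
        stats = acc.state_stats.get(id(g))
        if stats is None:
            continue
        occ = stats.occ[:, None]
        g.means = (tau * g.means + stats.sum_x) / (tau + occ)
    return adapted


def tune_insertion_penalty(
    graph: DecodingGraph,
    dev_data: Sequence[tuple[Sequence[str], FeatureSequence]],
    grid: Sequence[float],
    config: DecodeConfig = DecodeConfig(),
) -> tuple[float, float]:
    """Grid-search the insertion penalty minimising dev-set CER.

    ``dev_data`` pairs reference character sequences with observation
    sequences.  Returns ``(best_penalty, best_cer)``; ties prefer the
    penalty closest to zero (then the larger value).
    """
    if not grid or not dev_data:
        raise ValueError("empty grid or development set")
    refs = [list(ref) for ref, _ in dev_data]
    best = None
    for pen in grid:
        cfg = DecodeConfig(
            lm_weight=config.lm_weight,
            insertion_penalty=float(pen),
            beam=config.beam,
            unit_kind=config.unit_kind,
            cross_char_context=config.cross_char_context,
            use_sil=config.use_sil,
        )
        hyps = [decode(obs, graph, cfg).characters for _, obs in dev_data]
        cer = evaluate_corpus(hyps, refs)
        key = (cer, abs(pen), -pen)
        if best is None or key < best[0]:
            best = (key, float(pen), cer)
    return best[1], best[2]
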