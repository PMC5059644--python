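"""Continuous recognition: protocol-lexicon + N-gram Viterbi decoding.

The decoding graph composes, for every character of the protocol, the
chain of its motion-unit HMMs.  With context-dependent units the chain
depends on the neighbouring characters: the first unit's left context
is the last motion of the preceding character, and (for tri units) the
last unit's right context is the first motion of the following one.
The graph therefore expands each character into entry variants per
possible predecessor last-motion and exit variants per possible
successor first-motion; an exit variant for context ``f`` connects only
to characters that start with ``f``, so cross-character context is
exact.  Unseen context combinations are synthesised through the state
tying trees.  Optional silence models frame the utterance.

Search is time-synchronous token-passing Viterbi over (graph node,
language-model history) pairs.  Character arcs add the insertion
penalty and ``lm_weight`` times the N-gram log-probability; with no
beam the search is exact.  Ties between equal-scoring candidates are
broken deterministically by graph order (stay over advance, earlier
arcs first), which for equal acoustics prefers the character ordering
of the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .char_ngram import CharNgram, NgramScorer, NullScorer
from .context_units import ContextUnit, resolve_unit
from .features import FeatureSequence
from .gmm_hmm import GmmHmm, StateGmm, _as_array
from .protocol import Protocol
from .synthetic_eog import SIL

__all__ = ["DecodeConfig", "Hypothesis", "DecodingGraph", "build_decoding_graph", "decode"]

logger = logging.getLogger(__name__)

NEG_INF = -np.inf


@dataclass(frozen=True)
class DecodeConfig:
    """Search-time parameters.

    ``insertion_penalty`` is added (log domain) once per emitted
    character; negative values suppress insertions.  ``beam`` prunes
    tokens scoring more than ``beam`` below the frame-best; ``None``
    means exact search.
    """

    lm_weight: float = 1.0
    insertion_penalty: float = 0.0
    beam: Optional[float] = None
    unit_kind: str = "tri"
    cross_char_context: bool = True
    use_sil: bool = True

    def __post_init__(self):
        if self.beam is not None and self.beam <= 0:
            raise ValueError("beam must be positive when set")
        if self.lm_weight < 0:
            raise ValueError("lm_weight must be non-negative")
        if self.unit_kind not in ("mono", "bi", "tri"):
            raise ValueError(f"unknown unit kind {self.unit_kind!r}")


@dataclass
class Hypothesis:
    """A decoded character sequence with its underlying motions."""

    characters: list[str]
    motions: list[str]
    log_score: float
    complete: bool = True


class _CharPiece:
    """Node/arc bookkeeping for one character's expansion.

    ``entry`` maps a predecessor-last-motion context to the entry
    node(s) of the matching first-unit variant(s); ``exit`` maps a
    successor-first-motion context to the ``(node, exit logp)`` pairs
    of the matching last-unit variant(s).  Lists have one element
    except for single-motion characters, whose sole unit varies with
    both contexts at once.
    """

    def __init__(self):
        self.entry: dict[object, list[int]] = {}
        self.exit: dict[object, list[tuple[int, float]]] = {}


class DecodingGraph:
    """Flattened decoding network (topology and acoustic scores only).

    Language-model scores and the insertion penalty are applied at
    decode time, so one graph serves every penalty/LM-weight setting;
    0-gram decoding corresponds to ``lm=None``.
    """

    def __init__(self, chars, char_motions, lm):
        self.chars: list[str] = chars
        self.char_motions: list[tuple[str, ...]] = char_motions
        self.lm: Optional[CharNgram] = lm
        self.states: list[StateGmm] = []
        self.self_logp: list[float] = []
        self.arcs: list[tuple[int, int, float]] = []  # internal (src, dst, logp)
        # char arcs grouped by entry node: entry node -> (char_idx, [(src, logp)])
        self.entries: dict[int, tuple[int, list[tuple[int, float]]]] = {}
        self.start_items: list[tuple[int, float, int]] = []  # (node, logp, char or -1)
        self.end_items: list[tuple[int, float]] = []  # (node, exit logp)
        self._dp_cache = None

    # -- construction helpers ----------------------------------------------
    def add_state(self, gmm: StateGmm, self_logp: float) -> int:
        self.states.append(gmm)
        self.self_logp.append(self_logp)
        self._dp_cache = None
        return len(self.states) - 1

    def add_unit_chain(self, model: GmmHmm) -> tuple[int, int, float]:
        """Add one unit's states; returns (first node, last node, exit logp)."""
        first = None
        prev = None
        for i in range(model.n_states):
            node = self.add_state(model.states[i], model.log_trans[i, i])
            if first is None:
                first = node
            if prev is not None:
                self.arcs.append((prev, node, model.log_trans[i - 1, i]))
            prev = node
        exit_logp = float(model.log_trans[model.n_states - 1, model.n_states])
        return first, prev, exit_logp

    @property
    def n_nodes(self) -> int:
        return len(self.states)

    # -- decode-time compiled arrays ----------------------------------------
    def _compiled(self):
        if self._dp_cache is not None:
            return self._dp_cache
        N = self.n_nodes
        incoming: list[list[tuple[int, float]]] = [[] for _ in range(N)]
        for n in range(N):
            incoming[n].append((n, self.self_logp[n]))
        for src, dst, logp in self.arcs:
            incoming[dst].append((src, logp))
        # dense padded arrays for the typical small fan-in; the few
        # high-fan-in nodes (e.g. the terminal silence entry) go in a
        # separate per-node list so padding stays cheap
        K = min(4, max(len(v) for v in incoming))
        inc_src = np.zeros((N, K), dtype=np.int32)
        inc_logp = np.full((N, K), NEG_INF)
        heavy: list[tuple[int, np.ndarray, np.ndarray]] = []
        for n, lst in enumerate(incoming):
            for k, (s, lp) in enumerate(lst[:K]):
                inc_src[n, k] = s
                inc_logp[n, k] = lp
            if len(lst) > K:
                srcs = np.array([s for s, _ in lst[K:]], dtype=np.int32)
                lps = np.array([lp for _, lp in lst[K:]])
                heavy.append((n, srcs, lps))
        ent = []
        for node, (char_idx, srcs) in sorted(self.entries.items()):
            ent.append((node, char_idx, srcs))
        K2 = max((len(srcs) for _, _, srcs in ent), default=1)
        E = len(ent)
        ent_node = np.zeros(E, dtype=np.int32)
        ent_char = np.zeros(E, dtype=np.int32)
        ent_src = np.zeros((E, K2), dtype=np.int32)
        ent_logp = np.full((E, K2), NEG_INF)
        for e, (node, char_idx, srcs) in enumerate(ent):
            ent_node[e] = node
            ent_char[e] = char_idx
            for k, (s, lp) in enumerate(srcs):
                ent_src[e, k] = s
                ent_logp[e, k] = lp
        self._dp_cache = (inc_src, inc_logp, heavy, ent_node, ent_char,
                          ent_src, ent_logp)
        return self._dp_cache


def _unit_sequence(code: Sequence[str], kind: str, p, s) -> list[str]:
    """Unit names for one character code with external contexts p, s."""
    code = list(code)
    L = len(code)
    names = []
    for i, m in enumerate(code):
        left = right = None
        if kind in ("bi", "tri"):
            left = code[i - 1] if i > 0 else p
        if kind == "tri":
            right = code[i + 1] if i < L - 1 else s
        names.append(ContextUnit(m, left=left, right=right).name)
    return names


def build_decoding_graph(
    models,
    protocol: Protocol,
    lm: Optional[CharNgram] = None,
    config: DecodeConfig = DecodeConfig(),
) -> DecodingGraph:
    """Compose unit models, protocol lexicon and LM into a search network.

    The decoding vocabulary is every protocol character that stands on
    its own in the output (basic and derived characters; modification
    marks only occur inside derived codes).  Raises ``KeyError`` naming
    the first unit that cannot be resolved.
    """
    if protocol.strict:
        chars = sorted(set(protocol.basic) | set(protocol.derived))
    else:
        chars = sorted(protocol.table)
    if not chars:
        raise ValueError("protocol has no decodable characters")
    char_motions = [tuple(protocol.table[c]) for c in chars]
    kind = config.unit_kind
    cross = config.cross_char_context and kind != "mono"

    first_motions = sorted({code[0] for code in char_motions})
    last_motions = sorted({code[-1] for code in char_motions})
    p_set: list = [None] + (last_motions if cross else [])
    s_set: list = [None] + (first_motions if cross and kind == "tri" else [])
    # a context equal to the adjacent in-code motion is impossible (no-repeat)
    graph = DecodingGraph(chars, char_motions, lm)

    def get_model(name: str) -> GmmHmm:
        return resolve_unit(models, name)

    pieces: list[_CharPiece] = []
    for ci, code in enumerate(char_motions):
        piece = _CharPiece()
        L = len(code)
        valid_p = [p for p in p_set if p != code[0]]
        valid_s = [s for s in s_set if s != code[-1]]
        if L == 1:
            for p in valid_p:
                for s in valid_s:
                    names = _unit_sequence(code, kind, p, s)
                    f, l, e = graph.add_unit_chain(get_model(names[0]))
                    piece.entry.setdefault(p, []).append(f)
                    piece.exit.setdefault(s, []).append((l, e))
        else:
            # shared middle: positions 1..L-2 (empty when L == 2)
            mid_names = _unit_sequence(code, kind, None, None)[1 : L - 1]
            mid_first = mid_last = None
            prev_last, prev_exit = None, None
            for name in mid_names:
                f, l, e = graph.add_unit_chain(get_model(name))
                if mid_first is None:
                    mid_first = f
                if prev_last is not None:
                    graph.arcs.append((prev_last, f, prev_exit))
                prev_last, prev_exit = l, e
            mid_last, mid_exit = prev_last, prev_exit

            first_targets = []  # (node, logp) the first unit connects into
            last_entries = []  # first nodes of last-unit variants
            for s in valid_s:
                name = _unit_sequence(code, kind, None, s)[L - 1]
                f, l, e = graph.add_unit_chain(get_model(name))
                piece.exit[s] = [(l, e)]
                last_entries.append(f)
            for p in valid_p:
                name = _unit_sequence(code, kind, p, None)[0]
                f, l, e = graph.add_unit_chain(get_model(name))
                piece.entry[p] = [f]
                if mid_first is not None:
                    graph.arcs.append((l, mid_first, e))
                else:
                    for le in last_entries:
                        graph.arcs.append((l, le, e))
            if mid_first is not None:
                for le in last_entries:
                    graph.arcs.append((mid_last, le, mid_exit))
        pieces.append(piece)

    def exit_for(piece: _CharPiece, s) -> list[tuple[int, float]]:
        return piece.exit[s] if s in piece.exit else piece.exit[None]

    def entry_for(piece: _CharPiece, p) -> list[int]:
        return piece.entry[p] if p in piece.entry else piece.entry[None]

    # optional boundary silence
    sil_model = None
    if config.use_sil:
        try:
            sil_model = resolve_unit(models, SIL)
        except KeyError:
            logger.warning("no silence model; decoding without boundary sil")
    if sil_model is not None:
        s_first, s_last, s_exit = graph.add_unit_chain(sil_model)
        graph.start_items.append((s_first, 0.0, -1))
        start_sil = (s_last, s_exit)
        e_first, e_last, e_exit = graph.add_unit_chain(sil_model)
        end_sil = e_first
        graph.end_items.append((e_last, e_exit))
    else:
        start_sil = None
        end_sil = None

    # character entry arcs (emitting the character) and terminal arcs
    for ci, piece in enumerate(pieces):
        for entry0 in entry_for(piece, None):
            graph.start_items.append((entry0, 0.0, ci))
            if start_sil is not None:
                _, lst = graph.entries.setdefault(entry0, (ci, []))
                lst.append(start_sil)
        # termination from the s=None exit variant
        for node, elp in exit_for(piece, None):
            graph.end_items.append((node, elp))
            if end_sil is not None:
                graph.arcs.append((node, end_sil, elp))

    # char -> char arcs
    for apiece, acode in zip(pieces, char_motions):
        a_last = acode[-1]
        for bi, (bpiece, bcode) in enumerate(zip(pieces, char_motions)):
            if acode[-1] == bcode[0]:
                continue  # adjacency rule forbids this boundary
            for dst in entry_for(bpiece, a_last if cross else None):
                _, lst = graph.entries.setdefault(dst, (bi, []))
                for src_node, src_logp in exit_for(apiece, bcode[0]):
                    lst.append((src_node, src_logp))

    return graph


def _lm_tables(graph: DecodingGraph, config: DecodeConfig):
    """Enumerate reachable LM histories; build step/final score tables."""
    scorer = NgramScorer(graph.lm) if graph.lm is not None else NullScorer()
    C = len(graph.chars)
    states = [scorer.start()]
    index = {states[0]: 0}
    logp_rows, next_rows = [], []
    i = 0
    while i < len(states):
        h = states[i]
        lps = np.zeros(C)
        nxt = np.zeros(C, dtype=np.int32)
        for ci, ch in enumerate(graph.chars):
            lp, h2 = scorer.step(h, ch)
            lps[ci] = lp
            if h2 not in index:
                index[h2] = len(states)
                states.append(h2)
            nxt[ci] = index[h2]
        logp_rows.append(lps)
        next_rows.append(nxt)
        i += 1
    lm_logp = np.vstack(logp_rows)
    lm_next = np.vstack(next_rows)
    lm_final = np.array([scorer.final(h) for h in states])
    return lm_logp, lm_next, lm_final


def decode(obs: FeatureSequence, graph: DecodingGraph,
           config: DecodeConfig = DecodeConfig()) -> Hypothesis:
    """Best character sequence for one observation sequence.

    Returns an empty, ``complete=False`` hypothesis with ``-inf`` score
    when no admissible path exists (e.g. the input is shorter than any
    character's chain).
    """
    X = _as_array(obs)
    T = len(X)
    N = graph.n_nodes
    if T == 0 or N == 0:
        return Hypothesis([], [], NEG_INF, complete=False)
    inc_src, inc_logp, heavy, ent_node, ent_char, ent_src, ent_logp = graph._compiled()
    lm_logp, lm_next, lm_final = _lm_tables(graph, config)
    L = len(lm_final)
    w = config.lm_weight
    pen = config.insertion_penalty
    if w == 0:  # avoid 0 * -inf for symbols outside the LM
        lm_logp = np.zeros_like(lm_logp)
        lm_final = np.zeros_like(lm_final)
        w = 1.0

    # emission matrix, shared states computed once
    cache: dict[int, np.ndarray] = {}
    cols = []
    for g in graph.states:
        if id(g) not in cache:
            cache[id(g)] = g.log_pdf(X)
        cols.append(cache[id(g)])
    logB = np.column_stack(cols)

    score = np.full((L, N), NEG_INF)
    init_char = np.full((L, N), -1, dtype=np.int32)
    for node, logp, ci in graph.start_items:
        if ci < 0:
            if logp > score[0, node]:
                score[0, node] = logp
                init_char[0, node] = -1
        else:
            ls1 = lm_next[0, ci]
            val = logp + w * lm_logp[0, ci] + pen
            if val > score[ls1, node]:
                score[ls1, node] = val
                init_char[ls1, node] = ci
    score += logB[0]

    bp_node_hist, bp_ls_hist, bp_char_hist = [], [], []
    E = len(ent_node)
    # only LM-history rows holding a live token are propagated
    active = np.flatnonzero(np.isfinite(score).any(axis=1))
    for t in range(1, T):
        new = np.full((L, N), NEG_INF)
        bp_node = np.zeros((L, N), dtype=np.int32)
        bp_ls = np.broadcast_to(np.arange(L, dtype=np.int32)[:, None], (L, N)).copy()
        bp_char = np.full((L, N), -1, dtype=np.int32)

        # internal transitions (self loops and within-character arcs)
        cand = score[active][:, inc_src] + inc_logp[None, :, :]  # (A, N, K)
        arg = cand.argmax(axis=2)
        new[active] = np.take_along_axis(cand, arg[:, :, None], axis=2)[:, :, 0]
        A = len(active)
        bp_node[active] = np.take_along_axis(
            np.broadcast_to(inc_src, (A,) + inc_src.shape), arg[:, :, None], axis=2
        )[:, :, 0].astype(np.int32)
        for n, hsrcs, hlps in heavy:
            vals = score[active][:, hsrcs] + hlps[None, :]  # (A, H)
            hk = vals.argmax(axis=1)
            hv = vals[np.arange(A), hk]
            take = hv > new[active, n]
            if take.any():
                rows = active[take]
                new[rows, n] = hv[take]
                bp_node[rows, n] = hsrcs[hk[take]]

        # character-entry transitions (emit a character, move the LM state)
        if E:
            vals = score[active][:, ent_src] + ent_logp[None, :, :]  # (A, E, K2)
            argk = vals.argmax(axis=2)
            best = np.take_along_axis(vals, argk[:, :, None], axis=2)[:, :, 0]
            bsrc = np.take_along_axis(
                np.broadcast_to(ent_src, (A,) + ent_src.shape), argk[:, :, None], axis=2
            )[:, :, 0]
            for ai, ls in enumerate(active):
                tot = best[ai] + w * lm_logp[ls, ent_char] + pen  # (E,)
                dls = lm_next[ls, ent_char]
                for e in range(E):
                    v = tot[e]
                    if v > new[dls[e], ent_node[e]]:
                        new[dls[e], ent_node[e]] = v
                        bp_node[dls[e], ent_node[e]] = bsrc[ai, e]
                        bp_ls[dls[e], ent_node[e]] = ls
                        bp_char[dls[e], ent_node[e]] = ent_char[e]

        active = np.flatnonzero(np.isfinite(new).any(axis=1))
        new[active] += logB[t]
        if config.beam is not None:
            best_all = new.max()
            if np.isfinite(best_all):
                new[new < best_all - config.beam] = NEG_INF
                active = np.flatnonzero(np.isfinite(new).any(axis=1))
        score = new
        # store backpointers only for live tokens (sparse per frame)
        live = np.flatnonzero(np.isfinite(new).ravel())
        bp_node_hist.append((live, bp_node.ravel()[live]))
        bp_ls_hist.append(bp_ls.ravel()[live])
        bp_char_hist.append(bp_char.ravel()[live])

    # terminate
    best_score = NEG_INF
    best = None
    for node, logp in graph.end_items:
        vals = score[:, node] + logp + w * lm_final
        ls = int(np.argmax(vals))
        if vals[ls] > best_score:
            best_score = float(vals[ls])
            best = (ls, node)
    if best is None or not np.isfinite(best_score):
        return Hypothesis([], [], NEG_INF, complete=False)

    ls, node = best
    rev_chars: list[int] = []
    for t in range(T - 1, 0, -1):
        live, bpn = bp_node_hist[t - 1]
        pos = ls * N + node
        i = int(np.searchsorted(live, pos))
        if i >= len(live) or live[i] != pos:  # pragma: no cover - safety
            raise RuntimeError("traceback lost its token")
        ci = bp_char_hist[t - 1][i]
        pn = bpn[i]
        pl = bp_ls_hist[t - 1][i]
        if ci >= 0:
            rev_chars.append(int(ci))
        ls, node = int(pl), int(pn)
    ci = init_char[ls, node]
    if ci >= 0:
        rev_chars.append(int(ci))
    char_idxs = rev_chars[::-1]
    characters = [graph.chars[i] for i in char_idxs]
    motions = [m for i in char_idxs for m in graph.char_motions[i]]
    return Hypothesis(characters, motions, best_score, complete=True)
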