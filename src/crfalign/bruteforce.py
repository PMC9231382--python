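"""Exhaustive-enumeration reference implementations for small problems.

Everything here recomputes, by direct enumeration, quantities that the
dynamic-programming engine obtains by recursion: the partition function,
edge and match posteriors, the best path, the best co-linear match subset,
the best five-state labeling of a fixed path, and the best single tree
split.  These functions are exponential-time and exist to verify the fast
implementations on tiny instances; they share no code path with them.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .crf_engine import (
    DELTAS,
    FIVE_STATE_ALLOWED,
    AlignmentPath,
    EdgeScoreTable,
    default_allowed,
    iter_path_edges,
    is_match_state,
    scheme_states,
)


def enumerate_paths(scheme: str, Ls: int, Lt: int,
                    allowed: Optional[frozenset] = None
                    ) -> Iterator[AlignmentPath]:
    """Yield every global BEGIN -> END path on the (Ls, Lt) lattice."""
    states = scheme_states(scheme)
    if allowed is None:
        allowed = default_allowed(scheme)

    def rec(i: int, j: int, prev: Optional[str],
            acc_states: List[str], acc_cells: List[Tuple[int, int]]
            ) -> Iterator[AlignmentPath]:
        if (i, j) == (Ls, Lt) and acc_states:
            yield AlignmentPath(scheme=scheme, states=list(acc_states),
                                cells=list(acc_cells), Ls=Ls, Lt=Lt)
            return
        for s in states:
            if prev is not None and (prev, s) not in allowed:
                continue
            di, dj = DELTAS[s]
            ni, nj = i + di, j + dj
            if ni > Ls or nj > Lt:
                continue
            acc_states.append(s)
            acc_cells.append((ni, nj))
            yield from rec(ni, nj, s, acc_states, acc_cells)
            acc_states.pop()
            acc_cells.pop()

    yield from rec(0, 0, None, [], [])


def path_score_by_lookup(path: AlignmentPath, scores: EdgeScoreTable) -> float:
    S = len(scores.states)
    total = 0.0
    for p, s, i, j in iter_path_edges(path):
        total += float(scores.entry[s, i, j] if p == S
                       else scores.interior[p, s, i, j])
    return total


def enum_log_z(scores: EdgeScoreTable) -> float:
    """log sum over all enumerated global paths of exp(path score)."""
    vals = [path_score_by_lookup(p, scores)
            for p in enumerate_paths(scores.scheme, scores.Ls, scores.Lt,
                                     _allowed_from(scores))]
    m = max(vals)
    return m + math.log(sum(math.exp(v - m) for v in vals))


def _allowed_from(scores: EdgeScoreTable) -> frozenset:
    """Recover the allowed transition set from the -inf pattern of the table."""
    states = scores.states
    allowed = set()
    for pi, p in enumerate(states):
        for si, s in enumerate(states):
            if np.isfinite(scores.interior[pi, si]).any():
                allowed.add((p, s))
    return frozenset(allowed)


def enum_posteriors(scores: EdgeScoreTable
                    ) -> Tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """(log_Z, interior edge posteriors, begin posteriors, match posteriors)
    by summing path probabilities directly."""
    states = scores.states
    S, Ls, Lt = len(states), scores.Ls, scores.Lt
    paths = list(enumerate_paths(scores.scheme, Ls, Lt, _allowed_from(scores)))
    raw = np.array([path_score_by_lookup(p, scores) for p in paths])
    m = raw.max()
    w = np.exp(raw - m)
    Z = w.sum()
    log_z = m + math.log(Z)
    probs = w / Z
    interior = np.zeros_like(scores.interior)
    begin = np.zeros_like(scores.entry)
    match = np.zeros((Ls, Lt))
    for path, pr in zip(paths, probs):
        for p, s, i, j in iter_path_edges(path):
            if p == S:
                begin[s, i, j] += pr
            else:
                interior[p, s, i, j] += pr
        for i, j in path.pairs:
            match[i, j] += pr
    return log_z, interior, begin, match


def enum_viterbi(scores: EdgeScoreTable) -> Tuple[AlignmentPath, float]:
    """Global argmax path by enumeration; deterministic for unique optima."""
    best_path, best = None, -math.inf
    for p in enumerate_paths(scores.scheme, scores.Ls, scores.Lt,
                             _allowed_from(scores)):
        v = path_score_by_lookup(p, scores)
        if v > best:
            best_path, best = p, v
    return best_path, best


def enumerate_paths_between(scheme: str, Ls: int, Lt: int,
                            start_cell: Tuple[int, int],
                            end_cell: Tuple[int, int],
                            allowed: Optional[frozenset] = None
                            ) -> Iterator[AlignmentPath]:
    """Yield every path whose BEGIN sits at ``start_cell`` and that ends at
    ``end_cell`` (used to enumerate glocal/local path ensembles)."""
    states = scheme_states(scheme)
    if allowed is None:
        allowed = default_allowed(scheme)

    def rec(i, j, prev, acc_states, acc_cells):
        if (i, j) == end_cell and acc_states:
            yield AlignmentPath(scheme=scheme, states=list(acc_states),
                                cells=list(acc_cells), Ls=Ls, Lt=Lt)
        if i >= end_cell[0] and j >= end_cell[1]:
            return
        for s in states:
            if prev is not None and (prev, s) not in allowed:
                continue
            di, dj = DELTAS[s]
            ni, nj = i + di, j + dj
            if ni > end_cell[0] or nj > end_cell[1]:
                continue
            acc_states.append(s)
            acc_cells.append((ni, nj))
            yield from rec(ni, nj, s, acc_states, acc_cells)
            acc_states.pop()
            acc_cells.pop()

    yield from rec(start_cell[0], start_cell[1], None, [], [])


def enum_viterbi_mode(scores: EdgeScoreTable, mode: str) -> float:
    """Best admissible path score under a decoding mode, by enumeration."""
    Ls, Lt = scores.Ls, scores.Lt
    allowed = _allowed_from(scores)
    if mode == "global":
        starts = [(0, 0)]
        ends = [(Ls, Lt)]
    elif mode == "glocal":
        starts = sorted({(0, j) for j in range(Lt + 1)}
                        | {(i, 0) for i in range(Ls + 1)})
        ends = sorted({(Ls, j) for j in range(Lt + 1)}
                      | {(i, Lt) for i in range(Ls + 1)})
    elif mode == "local":
        starts = [(i, j) for i in range(Ls + 1) for j in range(Lt + 1)]
        ends = list(starts)
    else:
        raise ValueError(mode)
    best = -math.inf
    for sc in starts:
        for ec in ends:
            if ec[0] < sc[0] or ec[1] < sc[1] or ec == sc:
                continue
            for p in enumerate_paths_between(scores.scheme, Ls, Lt, sc, ec,
                                             allowed):
                v = path_score_by_lookup(p, scores)
                if np.isfinite(v):
                    best = max(best, v)
    return best


def enum_best_colinear_total(P: np.ndarray) -> float:
    """Max sum of P over strictly co-linear cell subsets, by enumeration."""
    Ls, Lt = P.shape
    cells = [(i, j) for i in range(Ls) for j in range(Lt)]
    best = 0.0
    for r in range(1, min(Ls, Lt) + 1):
        for combo in itertools.combinations(cells, r):
            ok = all(
                combo[k][0] < combo[k + 1][0] and combo[k][1] < combo[k + 1][1]
                for k in range(r - 1)
            )
            if ok:
                best = max(best, sum(P[i, j] for i, j in combo))
    return best


def enum_label_five_state(path3: AlignmentPath, scores5: EdgeScoreTable
                          ) -> Tuple[List[str], float]:
    """Best five-state labeling of a fixed three-state path, by enumerating
    all 2^(number of gap columns) label assignments."""
    options = []
    for s in path3.states:
        if s == "M":
            options.append(("MM",))
        elif s == "I":
            options.append(("MI", "DG"))
        else:
            options.append(("IM", "GD"))
    best_lab, best = None, -math.inf
    for labels in itertools.product(*options):
        ok = all(
            (labels[k], labels[k + 1]) in FIVE_STATE_ALLOWED
            for k in range(len(labels) - 1)
        )
        if not ok:
            continue
        path5 = AlignmentPath(scheme="five_state", states=list(labels),
                              cells=list(path3.cells), Ls=path3.Ls,
                              Lt=path3.Lt)
        v = path_score_by_lookup(path5, scores5)
        if v > best:
            best_lab, best = list(labels), v
    if best_lab is None:
        raise ValueError("no feasible five-state labeling")
    return best_lab, best


def exhaustive_best_split(X: np.ndarray, y: np.ndarray, min_leaf: int = 1
                          ) -> Optional[Tuple[int, float, float]]:
    """Best (feature, threshold, resulting SSE) by trying every midpoint."""
    n = len(y)
    best = None
    base_sse = float(((y - y.mean()) ** 2).sum())
    best_sse = base_sse - 1e-12
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (a + b)
            mask = X[:, f] <= thr
            nl = int(mask.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            yl, yr = y[mask], y[~mask]
            sse = float(((yl - yl.mean()) ** 2).sum()
                        + ((yr - yr.mean()) ** 2).sum())
            if sse < best_sse:
                best_sse = sse
                best = (f, thr, sse)
    return best


def random_edge_table(scheme: str, Ls: int, Lt: int,
                      rng: np.random.Generator, scale: float = 2.0
                      ) -> EdgeScoreTable:
    """A random finite score on every allowed edge (test instrument)."""
    table = EdgeScoreTable.zeros(scheme, Ls, Lt)
    m = np.isfinite(table.interior)
    table.interior[m] = rng.normal(0.0, scale, size=int(m.sum()))
    m = np.isfinite(table.entry)
    table.entry[m] = rng.normal(0.0, scale, size=int(m.sum()))
    return table
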