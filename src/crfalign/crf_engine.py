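"""Alignment-lattice probability engine.

A pairwise alignment of a template (structure) profile of length ``Ls`` and a
target profile of length ``Lt`` is a path on the ``Ls x Lt`` lattice whose
steps are pair states: in the three-state scheme M (diagonal), I (horizontal,
consumes the target) and D (vertical, consumes the template); in the
five-state scheme MM, MI, IM, GD, DG, where MI/DG consume the target only and
IM/GD the template only.

The conditional random field assigns each path ``a = (a_1..a_L)`` the
probability ``P(a|s,t) = exp(sum_i F(a_{i-1}, a_i)) / Z(s,t)``.  This module
implements the log-space forward/backward recursions for ``Z`` and the edge
and match posteriors, Viterbi decoding (global / glocal / local), maximum
posterior (MAP/MAC) decoding, path log-probabilities, and the functional
gradient ``delta(edge in A) - P(edge)`` used as the boosting regression
target.

All dynamic programming is in natural-log space with log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

NEG = -np.inf

THREE_STATES: Tuple[str, ...] = ("M", "D", "I")  # decoding preference order
FIVE_STATES: Tuple[str, ...] = ("MM", "IM", "GD", "MI", "DG")

DELTAS: Dict[str, Tuple[int, int]] = {
    "M": (1, 1), "D": (1, 0), "I": (0, 1),
    "MM": (1, 1), "IM": (1, 0), "GD": (1, 0), "MI": (0, 1), "DG": (0, 1),
}

#: five-state -> three-state reduction (MI and DG both reduce to I, IM and GD to D)
REDUCE_5_TO_3: Dict[str, str] = {
    "MM": "M", "MI": "I", "DG": "I", "IM": "D", "GD": "D",
}

#: allowed transitions of the five-state base scheme: self-loops plus MM <-> gap
FIVE_STATE_ALLOWED = frozenset(
    {(s, s) for s in FIVE_STATES}
    | {("MM", s) for s in FIVE_STATES if s != "MM"}
    | {(s, "MM") for s in FIVE_STATES if s != "MM"}
)
THREE_STATE_ALLOWED = frozenset(
    (a, b) for a in THREE_STATES for b in THREE_STATES
)


def scheme_states(scheme: str) -> Tuple[str, ...]:
    if scheme == "three_state":
        return THREE_STATES
    if scheme == "five_state":
        return FIVE_STATES
    raise ValueError(f"unknown scheme {scheme!r}")


def default_allowed(scheme: str) -> frozenset:
    return THREE_STATE_ALLOWED if scheme == "three_state" else FIVE_STATE_ALLOWED


def is_match_state(s: str) -> bool:
    return DELTAS[s] == (1, 1)


# ---------------------------------------------------------------------------
# paths
# ---------------------------------------------------------------------------


@dataclass
class AlignmentPath:
    """An alignment path: interior states ``a_1..a_L`` with lattice cells.

    ``cells[k]`` is the lattice cell *after* step ``states[k]``; cell ``(i, j)``
    means ``i`` template and ``j`` target residues consumed so far.  The BEGIN
    and END sentinels are implicit: BEGIN sits at :attr:`start_cell`, END
    follows the last cell.  Global paths run ``(0,0) -> (Ls,Lt)``.
    """

    scheme: str
    states: List[str]
    cells: List[Tuple[int, int]]
    Ls: int
    Lt: int

    def __post_init__(self) -> None:
        if len(self.states) != len(self.cells):
            raise ValueError("states and cells length mismatch")
        i, j = self.start_cell
        for s, (ci, cj) in zip(self.states, self.cells):
            di, dj = DELTAS[s]
            if (ci - i, cj - j) != (di, dj):
                raise ValueError(f"cell step to {(ci, cj)} inconsistent with state {s}")
            if not (0 <= ci <= self.Ls and 0 <= cj <= self.Lt):
                raise ValueError(f"cell {(ci, cj)} outside the lattice")
            i, j = ci, cj

    def __len__(self) -> int:
        return len(self.states)

    @property
    def start_cell(self) -> Tuple[int, int]:
        if not self.states:
            return (0, 0)
        ci, cj = self.cells[0]
        di, dj = DELTAS[self.states[0]]
        return (ci - di, cj - dj)

    @property
    def end_cell(self) -> Tuple[int, int]:
        return self.cells[-1] if self.cells else (0, 0)

    @property
    def pairs(self) -> List[Tuple[int, int]]:
        """0-based matched (template, target) residue pairs."""
        return [
            (ci - 1, cj - 1)
            for s, (ci, cj) in zip(self.states, self.cells)
            if is_match_state(s)
        ]

    def reduced(self) -> "AlignmentPath":
        """Map a five-state path onto the three-state scheme."""
        if self.scheme == "three_state":
            return self
        return AlignmentPath(
            scheme="three_state",
            states=[REDUCE_5_TO_3[s] for s in self.states],
            cells=list(self.cells),
            Ls=self.Ls,
            Lt=self.Lt,
        )

    def is_global(self) -> bool:
        return self.start_cell == (0, 0) and self.end_cell == (self.Ls, self.Lt)


# ---------------------------------------------------------------------------
# edge scores
# ---------------------------------------------------------------------------


@dataclass
class EdgeScoreTable:
    """Total edge scores ``F`` on one pair's lattice, in natural-log units.

    ``interior[p, s, i, j]`` is the score of the edge from state ``p`` at cell
    ``(i,j) - delta(s)`` to state ``s`` at cell ``(i, j)``; ``entry[s, i, j]``
    is the score of the BEGIN edge into that node (BEGIN and END edges carry
    no transition score of their own, so ``entry`` holds only the node's
    emission-type contributions).  Disallowed or out-of-lattice edges are
    ``-inf``.  Which BEGIN/END edges are usable is decided by the decoding
    mode, not stored here.
    """

    scheme: str
    Ls: int
    Lt: int
    interior: np.ndarray
    entry: np.ndarray

    @property
    def states(self) -> Tuple[str, ...]:
        return scheme_states(self.scheme)

    @classmethod
    def zeros(cls, scheme: str, Ls: int, Lt: int,
              allowed: Optional[frozenset] = None) -> "EdgeScoreTable":
        """A table with score 0 on every allowed edge (the trivial model)."""
        states = scheme_states(scheme)
        if allowed is None:
            allowed = default_allowed(scheme)
        S = len(states)
        interior = np.full((S, S, Ls + 1, Lt + 1), NEG)
        entry = np.full((S, Ls + 1, Lt + 1), NEG)
        for si, s in enumerate(states):
            nv = node_valid_mask(s, Ls, Lt)
            entry[si][nv] = 0.0
            for pi, p in enumerate(states):
                if (p, s) not in allowed:
                    continue
                ev = edge_valid_mask(p, s, Ls, Lt)
                interior[pi, si][ev] = 0.0
        return cls(scheme=scheme, Ls=Ls, Lt=Lt, interior=interior, entry=entry)

    def validate_finite(self) -> None:
        if np.isnan(self.interior).any() or np.isnan(self.entry).any():
            raise ValueError("NaN in edge score table")
        if self.Ls < 1 or self.Lt < 1:
            raise ValueError("empty lattice")


def node_valid_mask(s: str, Ls: int, Lt: int) -> np.ndarray:
    """Boolean (Ls+1, Lt+1) mask of cells where a node of state ``s`` exists."""
    di, dj = DELTAS[s]
    m = np.zeros((Ls + 1, Lt + 1), dtype=bool)
    m[di:, dj:] = True
    return m


def edge_valid_mask(p: str, s: str, Ls: int, Lt: int) -> np.ndarray:
    """Mask (over destination cells) of geometrically valid ``p -> s`` edges."""
    di, dj = DELTAS[s]
    dpi, dpj = DELTAS[p]
    m = np.zeros((Ls + 1, Lt + 1), dtype=bool)
    m[di + dpi:, dj + dpj:] = True
    return m


def _start_mask(scheme: str, Ls: int, Lt: int, mode: str) -> np.ndarray:
    """(S, Ls+1, Lt+1) mask of nodes a BEGIN edge may enter under ``mode``."""
    states = scheme_states(scheme)
    out = np.zeros((len(states), Ls + 1, Lt + 1), dtype=bool)
    for si, s in enumerate(states):
        di, dj = DELTAS[s]
        nv = node_valid_mask(s, Ls, Lt)
        if mode == "global":
            m = np.zeros_like(nv)
            m[di, dj] = True
            out[si] = m & nv
        elif mode == "glocal":
            # predecessor cell on the top row or left column
            ii = np.arange(Ls + 1)[:, None] - di
            jj = np.arange(Lt + 1)[None, :] - dj
            out[si] = nv & ((ii == 0) | (jj == 0))
        elif mode == "local":
            out[si] = nv
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def _end_mask(scheme: str, Ls: int, Lt: int, mode: str) -> np.ndarray:
    states = scheme_states(scheme)
    out = np.zeros((len(states), Ls + 1, Lt + 1), dtype=bool)
    for si, s in enumerate(states):
        nv = node_valid_mask(s, Ls, Lt)
        m = np.zeros_like(nv)
        if mode == "global":
            m[Ls, Lt] = True
        elif mode == "glocal":
            m[Ls, :] = True
            m[:, Lt] = True
        elif mode == "local":
            m[:, :] = True
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out[si] = m & nv
    return out


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _forward(scores: EdgeScoreTable, start: np.ndarray) -> np.ndarray:
    states = scores.states
    S, Ls, Lt = len(states), scores.Ls, scores.Lt
    A = np.full((S, Ls + 1, Lt + 1), NEG)
    entry = np.where(start, scores.entry, NEG)
    scan_states = [k for k, s in enumerate(states) if DELTAS[s] == (0, 1)]
    row_states = [k for k, s in enumerate(states) if DELTAS[s] != (0, 1)]
    for i in range(Ls + 1):
        for si in row_states:
            di, dj = DELTAS[states[si]]
            if i < di:
                continue
            cand = [entry[si, i, :]]
            for pi in range(S):
                prev = A[pi, i - di, :]
                if dj:
                    shifted = np.full(Lt + 1, NEG)
                    shifted[1:] = prev[:-1]
                else:
                    shifted = prev
                cand.append(shifted + scores.interior[pi, si, i, :])
            A[si, i, :] = np.logaddexp.reduce(np.stack(cand), axis=0)
        if scan_states:
            for j in range(1, Lt + 1):
                for si in scan_states:
                    acc = entry[si, i, j]
                    for pi in range(S):
                        v = A[pi, i, j - 1] + scores.interior[pi, si, i, j]
                        acc = np.logaddexp(acc, v)
                    A[si, i, j] = acc
    return A


def _backward(scores: EdgeScoreTable, end: np.ndarray) -> np.ndarray:
    states = scores.states
    S, Ls, Lt = len(states), scores.Ls, scores.Lt
    B = np.full((S, Ls + 1, Lt + 1), NEG)
    exit_score = np.where(end, 0.0, NEG)
    scan_states = [k for k, s in enumerate(states) if DELTAS[s] == (0, 1)]
    for i in range(Ls, -1, -1):
        # contributions through successors that consume the template (row i+1)
        base = [exit_score[si, i, :] for si in range(S)]
        for pi in range(S):
            cand = [base[pi]]
            for si in range(S):
                di, dj = DELTAS[states[si]]
                if di != 1 or i + 1 > Ls:
                    continue
                nxt = B[si, i + 1, :]
                sc = scores.interior[pi, si, i + 1, :]
                if dj:
                    v = np.full(Lt + 1, NEG)
                    v[:-1] = nxt[1:] + sc[1:]
                else:
                    v = nxt + sc
                cand.append(v)
            B[pi, i, :] = np.logaddexp.reduce(np.stack(cand), axis=0)
        # successors within the row (target-consuming), scanned right to left
        if scan_states:
            for j in range(Lt - 1, -1, -1):
                for pi in range(S):
                    acc = B[pi, i, j]
                    for si in scan_states:
                        v = scores.interior[pi, si, i, j + 1] + B[si, i, j + 1]
                        acc = np.logaddexp(acc, v)
                    B[pi, i, j] = acc
    return B


@dataclass
class PosteriorTables:
    """Forward/backward output: partition value and posterior probabilities.

    ``edge_posteriors[p, s, i, j]`` is ``P(a_{k-1}=p, a_k=s at cell (i,j))``;
    ``begin_posteriors[s, i, j]`` covers the BEGIN edges, ``end_posteriors[s]``
    the END edges; ``match_posteriors[i, j]`` (0-based residue indices, shape
    ``(Ls, Lt)``) is ``P(s_i ~ t_j)``.
    """

    scheme: str
    Ls: int
    Lt: int
    log_Z: float
    alpha: np.ndarray
    beta: np.ndarray
    edge_posteriors: np.ndarray
    begin_posteriors: np.ndarray
    end_posteriors: np.ndarray
    match_posteriors: np.ndarray

    @property
    def states(self) -> Tuple[str, ...]:
        return scheme_states(self.scheme)

    def node_posteriors(self) -> np.ndarray:
        """P(path passes through node (s, i, j)), shape (S, Ls+1, Lt+1)."""
        with np.errstate(invalid="ignore"):
            out = np.exp(self.alpha + self.beta - self.log_Z)
        return np.nan_to_num(out, nan=0.0)

    def template_gap_posteriors(self) -> np.ndarray:
        """P(template residue i consumed by a template-gap state), length Ls."""
        node = self.node_posteriors()
        out = np.zeros(self.Ls)
        for si, s in enumerate(self.states):
            if DELTAS[s] == (1, 0):
                out += node[si, 1:, :].sum(axis=1)
        return out

    def target_gap_posteriors(self) -> np.ndarray:
        node = self.node_posteriors()
        out = np.zeros(self.Lt)
        for si, s in enumerate(self.states):
            if DELTAS[s] == (0, 1):
                out += node[si, :, 1:].sum(axis=0)
        return out


def forward_backward(scores: EdgeScoreTable, mode: str = "global") -> PosteriorTables:
    """Run the log-space forward/backward recursions (global ensemble).

    Returns the log partition function, per-edge posteriors
    ``exp(alpha(src) + F(e) + beta(dst) - log Z)`` and the match posteriors
    ``P(s_i, t_j)`` (sum of posteriors of match-type edges entering ``(i,j)``).
    """
    if mode != "global":
        raise ValueError("forward_backward supports the global ensemble only")
    scores.validate_finite()
    states = scores.states
    S, Ls, Lt = len(states), scores.Ls, scores.Lt
    start = _start_mask(scores.scheme, Ls, Lt, mode)
    end = _end_mask(scores.scheme, Ls, Lt, mode)
    A = _forward(scores, start)
    B = _backward(scores, end)
    log_Z = float(np.logaddexp.reduce(A[:, Ls, Lt]))
    if not np.isfinite(log_Z):
        raise ValueError("no path through the lattice (log_Z not finite)")

    with np.errstate(invalid="ignore"):
        post = np.zeros_like(scores.interior)
        for si, s in enumerate(states):
            di, dj = DELTAS[s]
            for pi in range(S):
                src = np.full((Ls + 1, Lt + 1), NEG)
                src[di:, dj:] = A[pi, : Ls + 1 - di, : Lt + 1 - dj]
                val = src + scores.interior[pi, si] + B[si] - log_Z
                post[pi, si] = np.exp(np.nan_to_num(val, nan=NEG))
        entry = np.where(start, scores.entry, NEG)
        begin = np.exp(np.nan_to_num(entry + B - log_Z, nan=NEG))
        endp = np.exp(A[:, Ls, Lt] - log_Z)

    match = np.zeros((Ls, Lt))
    for si, s in enumerate(states):
        if is_match_state(s):
            with np.errstate(invalid="ignore"):
                node = np.exp(np.nan_to_num(A[si] + B[si] - log_Z, nan=NEG))
            match += node[1:, 1:]

    return PosteriorTables(
        scheme=scores.scheme, Ls=Ls, Lt=Lt, log_Z=log_Z, alpha=A, beta=B,
        edge_posteriors=post, begin_posteriors=begin, end_posteriors=endp,
        match_posteriors=match,
    )


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------


def viterbi(scores: EdgeScoreTable, mode: str = "global") -> Tuple[AlignmentPath, float]:
    """Highest-scoring path under ``mode``; deterministic tie-breaking.

    Ties are resolved by the fixed state preference order (M > D > I;
    five-state MM > IM > GD > MI > DG), then by smaller template coordinate,
    then smaller target coordinate.  Glocal paths start on the top or left
    lattice boundary and end on the bottom or right one; local paths start and
    end anywhere.  End gaps are never scored.
    """
    scores.validate_finite()
    states = scores.states
    S, Ls, Lt = len(states), scores.Ls, scores.Lt
    start = _start_mask(scores.scheme, Ls, Lt, mode)
    end = _end_mask(scores.scheme, Ls, Lt, mode)
    entry = np.where(start, scores.entry, NEG)

    A = np.full((S, Ls + 1, Lt + 1), NEG)
    PTR = np.full((S, Ls + 1, Lt + 1), -2, dtype=np.int8)  # S = BEGIN marker
    scan_states = [k for k, s in enumerate(states) if DELTAS[s] == (0, 1)]
    row_states = [k for k, s in enumerate(states) if DELTAS[s] != (0, 1)]
    for i in range(Ls + 1):
        for si in row_states:
            di, dj = DELTAS[states[si]]
            if i < di:
                continue
            cand = []
            for pi in range(S):
                prev = A[pi, i - di, :]
                if dj:
                    shifted = np.full(Lt + 1, NEG)
                    shifted[1:] = prev[:-1]
                else:
                    shifted = prev
                cand.append(shifted + scores.interior[pi, si, i, :])
            cand.append(entry[si, i, :])
            stack = np.stack(cand)
            with np.errstate(invalid="ignore"):
                best = np.max(stack, axis=0)
                arg = np.argmax(stack, axis=0)
            A[si, i, :] = best
            PTR[si, i, :] = np.where(np.isfinite(best), arg, -2)
        for j in range(1, Lt + 1):
            for si in scan_states:
                best, arg = NEG, -2
                for pi in range(S):
                    v = A[pi, i, j - 1] + scores.interior[pi, si, i, j]
                    if v > best:
                        best, arg = v, pi
                v = entry[si, i, j]
                if v > best:
                    best, arg = v, S
                A[si, i, j] = best
                PTR[si, i, j] = arg if np.isfinite(best) else -2

    # pick the end node: preference order, then smaller i, then smaller j
    best_val, best_node = NEG, None
    for si in range(S):
        masked = np.where(end[si], A[si], NEG)
        if not np.isfinite(masked).any():
            continue
        flat = int(np.argmax(masked))
        v = masked.flat[flat]
        if v > best_val:
            best_val = v
            best_node = (si, flat // (Lt + 1), flat % (Lt + 1))
    if best_node is None:
        raise ValueError("no admissible path for this mode")

    rev_states: List[str] = []
    rev_cells: List[Tuple[int, int]] = []
    si, i, j = best_node
    while True:
        rev_states.append(states[si])
        rev_cells.append((i, j))
        p = int(PTR[si, i, j])
        if p == len(states) or p == S:  # BEGIN
            break
        if p < 0:
            raise RuntimeError("traceback hit an invalid node")
        di, dj = DELTAS[states[si]]
        si, i, j = p, i - di, j - dj
    path = AlignmentPath(
        scheme=scores.scheme,
        states=rev_states[::-1],
        cells=rev_cells[::-1],
        Ls=Ls,
        Lt=Lt,
    )
    return path, float(best_val)


# ---------------------------------------------------------------------------
# MAP / maximum-accuracy decoding
# ---------------------------------------------------------------------------


def map_align(post: PosteriorTables, mode: str = "global",
              mth: float = 0.0) -> AlignmentPath:
    """Maximum-posterior (maximum accuracy) decoding of the match posteriors.

    Global mode maximises the plain sum of ``P(s_i, t_j)`` over co-linear
    match sets with zero gap cost.  Local and glocal modes maximise
    ``sum (P(s_i, t_j) - mth)`` with free end gaps (on both sequences for
    local, on one for glocal) and a penalty of ``0.5 * mth`` charged once per
    internal gap opening.  The returned path is three-state.
    """
    if not (0.0 <= mth <= 1.0):
        raise ValueError(f"mth must lie in [0, 1], got {mth}")
    Ls, Lt = post.Ls, post.Lt
    use_mth = mth if mode != "global" else 0.0
    gap_open = 0.5 * mth if mode != "global" else 0.0

    table = EdgeScoreTable.zeros("three_state", Ls, Lt)
    P = post.match_posteriors - use_mth
    grid = np.full((Ls + 1, Lt + 1), NEG)
    grid[1:, 1:] = P
    mi = THREE_STATES.index("M")
    for pi in range(3):
        mask = np.isfinite(table.interior[pi, mi])
        table.interior[pi, mi][mask] = grid[mask]
    table.entry[mi] = np.where(np.isfinite(table.entry[mi]), grid, NEG)
    for gs in ("D", "I"):
        gi = THREE_STATES.index(gs)
        m = np.isfinite(table.interior[mi, gi])
        table.interior[mi, gi][m] = -gap_open

    path, score = viterbi(table, mode=mode)
    if mode == "local":
        if score <= 0.0:
            return AlignmentPath(scheme="three_state", states=[], cells=[],
                                 Ls=Ls, Lt=Lt)
        path = _strip_flank_gaps(path)
    return path


def _strip_flank_gaps(path: AlignmentPath) -> AlignmentPath:
    ks = [k for k, s in enumerate(path.states) if is_match_state(s)]
    if not ks:
        return AlignmentPath(scheme=path.scheme, states=[], cells=[],
                             Ls=path.Ls, Lt=path.Lt)
    lo, hi = ks[0], ks[-1] + 1
    return AlignmentPath(
        scheme=path.scheme, states=path.states[lo:hi], cells=path.cells[lo:hi],
        Ls=path.Ls, Lt=path.Lt,
    )


# ---------------------------------------------------------------------------
# path probability and functional gradient
# ---------------------------------------------------------------------------


def iter_path_edges(path: AlignmentPath) -> Iterator[Tuple[int, int, int, int]]:
    """Yield ``(p_idx, s_idx, i, j)`` for each edge of the path.

    The BEGIN edge uses ``p_idx == S`` (one past the last state index).
    END edges are not yielded (they carry no score or features).
    """
    states = scheme_states(path.scheme)
    idx = {s: k for k, s in enumerate(states)}
    prev = len(states)
    for s, (i, j) in zip(path.states, path.cells):
        yield prev, idx[s], i, j
        prev = idx[s]


def path_score(path: AlignmentPath, scores: EdgeScoreTable) -> float:
    """Sum of edge scores along the path (BEGIN edge included, END free)."""
    if path.scheme != scores.scheme:
        raise ValueError("path and score table use different schemes")
    if path.Ls != scores.Ls or path.Lt != scores.Lt:
        raise ValueError("path leaves the score table's lattice")
    S = len(scores.states)
    total = 0.0
    for p, s, i, j in iter_path_edges(path):
        v = scores.entry[s, i, j] if p == S else scores.interior[p, s, i, j]
        if not np.isfinite(v):
            raise ValueError(f"path uses a disallowed edge at cell ({i}, {j})")
        total += float(v)
    return total


def path_log_probability(path: AlignmentPath, scores: EdgeScoreTable,
                         post: PosteriorTables) -> float:
    """``ln P(a|s,t)``: the path's total edge score minus ``log Z``."""
    if not path.is_global():
        raise ValueError("path log-probability is defined for global paths")
    return path_score(path, scores) - post.log_Z


def functional_gradient(path: AlignmentPath, post: PosteriorTables
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Regression labels ``delta(edge in A) - P(edge)`` for every lattice edge.

    Returns ``(interior_labels, begin_labels)`` with the same shapes as the
    posterior tables: ``1 - P`` on the reference path's edges, ``-P``
    elsewhere.
    """
    if path.scheme != post.scheme:
        raise ValueError("path and posteriors use different schemes")
    if path.Ls != post.Ls or path.Lt != post.Lt:
        raise ValueError("reference path incompatible with the lattice")
    interior = -post.edge_posteriors.copy()
    begin = -post.begin_posteriors.copy()
    S = len(post.states)
    for p, s, i, j in iter_path_edges(path):
        if p == S:
            begin[s, i, j] += 1.0
        else:
            interior[p, s, i, j] += 1.0
    return interior, begin
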