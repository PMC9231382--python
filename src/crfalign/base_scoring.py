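"""HHalign-style zeroth-order alignment model.

The base score of an alignment sums, per column, an HMM-HMM profile
co-emission score ``Saa``, a pair-transition propensity ``Str`` and a
secondary-structure agreement score ``S2`` (all in bits; converted to natural
log when a lattice table is built).

Pair states are written with the target HMM letter first: MM aligns two
columns; MI and DG consume a target column only; IM and GD a template column
only.  The three-state scheme reduces MM->M, MI/DG->I, IM/GD->D; a reduced
edge takes the larger of its candidate five-state scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .crf_engine import (
    DELTAS,
    FIVE_STATES,
    FIVE_STATE_ALLOWED,
    NEG,
    REDUCE_5_TO_3,
    THREE_STATES,
    AlignmentPath,
    EdgeScoreTable,
    edge_valid_mask,
    node_valid_mask,
    scheme_states,
)
from .profile_io import (
    SS_INDEX,
    TRANSITION_ORDER,
    ProfileHMM,
    ReferenceAlignment,
    StructuralAnnotation,
)

LN2 = math.log(2.0)

#: default 3x3 secondary-structure pair score (H, E, C order, bits)
DEFAULT_SS_MATRIX = np.array(
    [
        [1.0, -2.0, -0.5],
        [-2.0, 1.0, -0.5],
        [-0.5, -0.5, 1.0],
    ]
)

#: probability floor applied to HMM transition factors inside Str so that a
#: zero transition probability cannot delete lattice edges outright
TRANSITION_PROB_FLOOR = 1e-6

_TR_INDEX = {t: k for k, t in enumerate(TRANSITION_ORDER)}


@dataclass
class PairInput:
    """One alignment problem: two profiles with their structural annotations."""

    template: ProfileHMM
    target: ProfileHMM
    template_ann: StructuralAnnotation
    target_ann: StructuralAnnotation

    def __post_init__(self) -> None:
        if len(self.template) != len(self.template_ann):
            raise ValueError(
                f"template profile length {len(self.template)} != annotation "
                f"length {len(self.template_ann)}"
            )
        if len(self.target) != len(self.target_ann):
            raise ValueError(
                f"target profile length {len(self.target)} != annotation "
                f"length {len(self.target_ann)}"
            )

    @property
    def Ls(self) -> int:
        return len(self.template)

    @property
    def Lt(self) -> int:
        return len(self.target)


@dataclass
class BaseModelConfig:
    """Configuration of the base model T0.

    ``w_ss`` weights the secondary-structure score; ``ss_matrix`` is the 3x3
    class-pair table (H/E/C, bits); ``saa_floor`` bounds the profile column
    score from below (bits).  The five-state transition set is fixed
    (self-loops plus MM <-> gap states); the three-state set defaults to all
    nine ordered pairs.
    """

    scheme: str = "three_state"
    w_ss: float = 0.3
    ss_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_SS_MATRIX.copy())
    saa_floor: float = -10.0
    allowed_three: frozenset = field(
        default_factory=lambda: frozenset(
            (a, b) for a in THREE_STATES for b in THREE_STATES
        )
    )

    def __post_init__(self) -> None:
        self.ss_matrix = np.asarray(self.ss_matrix, dtype=float)
        if self.ss_matrix.shape != (3, 3):
            raise ValueError("ss_matrix must be 3x3")
        if self.scheme not in ("three_state", "five_state"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def allowed(self) -> frozenset:
        if self.scheme == "five_state":
            return FIVE_STATE_ALLOWED
        return self.allowed_three

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "w_ss": self.w_ss,
            "ss_matrix": self.ss_matrix.tolist(),
            "saa_floor": self.saa_floor,
            "allowed_three": sorted(list(t) for t in self.allowed_three),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaseModelConfig":
        return cls(
            scheme=d["scheme"],
            w_ss=float(d["w_ss"]),
            ss_matrix=np.array(d["ss_matrix"], dtype=float),
            saa_floor=float(d["saa_floor"]),
            allowed_three=frozenset(tuple(t) for t in d["allowed_three"]),
        )


# ---------------------------------------------------------------------------
# column scores
# ---------------------------------------------------------------------------


def saa(template: ProfileHMM, i: int, target: ProfileHMM, j: int,
        saa_floor: float = -10.0) -> float:
    """Profile column co-emission log-odds, ``log2 sum_a q_i(a) p_j(a) / f(a)``.

    Floored at ``saa_floor`` bits so disjoint one-hot columns stay finite.
    """
    f = 0.5 * (template.background + target.background)
    s = float(np.dot(template.emissions[i], target.emissions[j] / f))
    if s <= 0.0:
        return saa_floor
    return max(saa_floor, math.log2(s))


def saa_matrix(template: ProfileHMM, target: ProfileHMM,
               saa_floor: float = -10.0) -> np.ndarray:
    """All-pairs Saa, shape (Ls, Lt), bits."""
    f = 0.5 * (template.background + target.background)
    co = template.emissions @ (target.emissions / f).T
    with np.errstate(divide="ignore"):
        return np.maximum(np.log2(np.maximum(co, 0.0)), saa_floor)


def s2(template_ann: StructuralAnnotation, i: int,
       target_ann: StructuralAnnotation, j: int,
       ss_matrix: Optional[np.ndarray] = None, w_ss: float = 0.3) -> float:
    """Confidence-weighted secondary-structure agreement score (bits).

    Uses the template's assigned class against the target's class
    probabilities: ``w_ss * sum_c P_target(c) * ss_matrix[ss_template, c]``.
    """
    M = DEFAULT_SS_MATRIX if ss_matrix is None else np.asarray(ss_matrix)
    row = M[SS_INDEX[template_ann.ss[i]]]
    return float(w_ss * np.dot(target_ann.ss_probs[j], row))


def s2_matrix(template_ann: StructuralAnnotation,
              target_ann: StructuralAnnotation,
              ss_matrix: Optional[np.ndarray] = None,
              w_ss: float = 0.3) -> np.ndarray:
    M = DEFAULT_SS_MATRIX if ss_matrix is None else np.asarray(ss_matrix)
    rows = M[template_ann.ss_indices]  # (Ls, 3)
    return w_ss * (rows @ target_ann.ss_probs.T)


# ---------------------------------------------------------------------------
# transition propensity
# ---------------------------------------------------------------------------


def _letter_log2_factor(profile: ProfileHMM, col0: int, x1: str, x2: str
                        ) -> Optional[float]:
    """log2 of one HMM's transition factor for letter pair ``x1 -> x2``.

    ``col0`` is the number of columns this HMM has consumed at the source
    node; the transition probability of column ``col0`` (1-based) is used.
    ``G`` contributes no factor (0.0); letter pairs outside the seven stored
    transitions (ID, DI) are undefined and return ``None``.
    """
    if "G" in (x1, x2):
        return 0.0
    key = x1 + x2
    if key not in _TR_INDEX:
        return None
    if col0 < 1:
        return 0.0  # no column consumed yet: end transitions are not scored
    p = max(float(profile.transitions[col0 - 1, _TR_INDEX[key]]),
            TRANSITION_PROB_FLOOR)
    return math.log2(p)


def str_score(template: ProfileHMM, target: ProfileHMM,
              from_state: str, to_state: str,
              at: Tuple[int, int],
              allowed: frozenset = FIVE_STATE_ALLOWED) -> float:
    """Five-state transition propensity (bits) for the edge from the node at
    source cell ``at = (i0, j0)`` (consumed counts) into ``to_state``.

    The score factorises over the two HMMs: the target HMM contributes the
    transition between the first letters, the template HMM between the second
    letters; ``G`` contributes factor 1.
    """
    if (from_state, to_state) not in allowed:
        raise ValueError(
            f"transition {from_state}->{to_state} is not in the allowed set"
        )
    i0, j0 = at
    tar_f = _letter_log2_factor(target, j0, from_state[0], to_state[0])
    tpl_f = _letter_log2_factor(template, i0, from_state[1], to_state[1])
    if tar_f is None or tpl_f is None:
        raise ValueError(
            f"transition {from_state}->{to_state} has no defined HMM factor"
        )
    return tar_f + tpl_f


def _letter_log2_vector(profile: ProfileHMM, x1: str, x2: str
                        ) -> Optional[np.ndarray]:
    """Per-source-consumed-count log2 factors, indexed 0..L (0 -> no factor)."""
    L = len(profile)
    if "G" in (x1, x2):
        return np.zeros(L + 1)
    key = x1 + x2
    if key not in _TR_INDEX:
        return None
    out = np.zeros(L + 1)
    p = np.maximum(profile.transitions[:, _TR_INDEX[key]], TRANSITION_PROB_FLOOR)
    out[1:] = np.log2(p)
    return out


def _five_state_str_grid(pair: PairInput, p5: str, s5: str) -> Optional[np.ndarray]:
    """Str (bits) for every dest cell of edge ``p5 -> s5``; None if undefined.

    The returned (Ls+1, Lt+1) grid is indexed by the destination cell; the
    transition factors are evaluated at the source cell.
    """
    tar_v = _letter_log2_vector(pair.target, p5[0], s5[0])
    tpl_v = _letter_log2_vector(pair.template, p5[1], s5[1])
    if tar_v is None or tpl_v is None:
        return None
    di, dj = DELTAS[s5]
    Ls, Lt = pair.Ls, pair.Lt
    grid = np.full((Ls + 1, Lt + 1), NEG)
    # source cell (i - di, j - dj) for dest (i, j)
    ti = tpl_v[: Ls + 1 - di]
    tj = tar_v[: Lt + 1 - dj]
    grid[di:, dj:] = ti[:, None] + tj[None, :]
    return grid


# ---------------------------------------------------------------------------
# lattice construction
# ---------------------------------------------------------------------------


def base_lattice_scores(pair: PairInput, config: BaseModelConfig) -> EdgeScoreTable:
    """Build the base-model edge score table ``T0`` for one pair.

    Saa + S2 attach to every edge entering a match-type node (including the
    BEGIN edge); Str attaches to interior edges only.  Scores are converted
    from bits to natural log.  In the three-state scheme each reduced edge
    takes the largest of its candidate five-state scores.
    """
    Ls, Lt = pair.Ls, pair.Lt
    emis_bits = saa_matrix(pair.template, pair.target, config.saa_floor) \
        + s2_matrix(pair.template_ann, pair.target_ann,
                    config.ss_matrix, config.w_ss)
    emis = np.full((Ls + 1, Lt + 1), NEG)
    emis[1:, 1:] = LN2 * emis_bits

    states = scheme_states(config.scheme)
    S = len(states)
    interior = np.full((S, S, Ls + 1, Lt + 1), NEG)
    entry = np.full((S, Ls + 1, Lt + 1), NEG)
    allowed = config.allowed()

    if config.scheme == "five_state":
        candidates = {(p, s): [(p, s)] for p in FIVE_STATES for s in FIVE_STATES}
    else:
        inv: Dict[str, List[str]] = {"M": ["MM"], "I": ["MI", "DG"], "D": ["IM", "GD"]}
        candidates = {
            (p, s): [(p5, s5) for p5 in inv[p] for s5 in inv[s]]
            for p in THREE_STATES for s in THREE_STATES
        }

    for si, s in enumerate(states):
        nv = node_valid_mask(s, Ls, Lt)
        if DELTAS[s] == (1, 1):
            entry[si] = np.where(nv, emis, NEG)
        else:
            entry[si][nv] = 0.0
        for pi, p in enumerate(states):
            if (p, s) not in allowed:
                continue
            grids = [
                g for g in (
                    _five_state_str_grid(pair, p5, s5)
                    for (p5, s5) in candidates[(p, s)]
                ) if g is not None
            ]
            if not grids:
                continue
            str_grid = grids[0] if len(grids) == 1 else np.maximum.reduce(grids)
            ev = edge_valid_mask(p, s, Ls, Lt)
            sc = LN2 * str_grid
            if DELTAS[s] == (1, 1):
                sc = sc + emis
            interior[pi, si] = np.where(ev, sc, NEG)

    return EdgeScoreTable(scheme=config.scheme, Ls=Ls, Lt=Lt,
                          interior=interior, entry=entry)


# ---------------------------------------------------------------------------
# five-state labeling of reference alignments
# ---------------------------------------------------------------------------

_FIVE_CANDIDATES = {"M": ["MM"], "I": ["MI", "DG"], "D": ["IM", "GD"]}


def label_five_state(ref: ReferenceAlignment, pair: PairInput,
                     config: Optional[BaseModelConfig] = None) -> AlignmentPath:
    """Assign five-state labels along a reference path, maximising T0.

    Match columns are MM; each gap column chooses MI vs DG (insertions) or
    IM vs GD (deletions) by dynamic programming over the fixed path, subject
    to the five-state transition set.  Ties prefer MI over DG and IM over GD.
    """
    five_cfg = BaseModelConfig(
        scheme="five_state",
        w_ss=config.w_ss if config else 0.3,
        ss_matrix=config.ss_matrix if config else DEFAULT_SS_MATRIX,
        saa_floor=config.saa_floor if config else -10.0,
    )
    table = base_lattice_scores(pair, five_cfg)
    idx = {s: k for k, s in enumerate(FIVE_STATES)}
    path3 = ref.path
    if path3 is None or len(path3) == 0:
        raise ValueError("reference alignment carries no path")

    cols = [(s, cell) for s, cell in zip(path3.states, path3.cells)]
    # DP over columns; per column, the candidate five-state labels
    best: Dict[str, float] = {}
    back: List[Dict[str, Optional[str]]] = []
    for k, (s3, (i, j)) in enumerate(cols):
        cand = _FIVE_CANDIDATES[s3]
        new_best: Dict[str, float] = {}
        new_back: Dict[str, Optional[str]] = {}
        for lab in cand:
            li = idx[lab]
            if k == 0:
                v = table.entry[li, i, j]
                if np.isfinite(v):
                    new_best[lab] = float(v)
                    new_back[lab] = None
            else:
                bv, ba = NEG, None
                for prev_lab, pv in best.items():
                    if (prev_lab, lab) not in FIVE_STATE_ALLOWED:
                        continue
                    e = table.interior[idx[prev_lab], li, i, j]
                    if not np.isfinite(e):
                        continue
                    v = pv + float(e)
                    if v > bv:
                        bv, ba = v, prev_lab
                if ba is not None:
                    new_best[lab] = bv
                    new_back[lab] = ba
        if not new_best:
            raise ValueError(
                f"no five-state labeling consistent with the allowed "
                f"transitions at column {k + 1}"
            )
        best, _ = new_best, back.append(new_back)

    # choose the final label: max value, ties by candidate preference order
    last_cand = _FIVE_CANDIDATES[cols[-1][0]]
    final = max(
        (lab for lab in last_cand if lab in best),
        key=lambda lab: (best[lab], -last_cand.index(lab)),
    )
    labels = [final]
    for k in range(len(cols) - 1, 0, -1):
        labels.append(back[k][labels[-1]])
    labels.reverse()
    return AlignmentPath(
        scheme="five_state",
        states=labels,
        cells=[cell for _, cell in cols],
        Ls=path3.Ls,
        Lt=path3.Lt,
    )
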