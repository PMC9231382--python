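"""Fixed-length feature vectors for lattice edges.

Each regression-tree stage scores an edge through a six-dimensional feature
vector: one schema for match-type edges (profile and structural similarity of
the two aligned columns) and one for gap-type edges (properties of the single
consumed residue plus a gap-continuation flag).  The schema is versioned and
serialized with every trained model so that predictions are reproducible.

Scalar extractors implement the defining formulas; the ``PairFeatures`` cache
evaluates the same formulas vectorised over a whole lattice (the two routes
are cross-checked in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .base_scoring import DEFAULT_SS_MATRIX, PairInput, saa, saa_matrix
from .crf_engine import DELTAS, scheme_states
from .profile_io import ProfileHMM, SS_INDEX, StructuralAnnotation

LN20 = float(np.log(20.0))

MATCH_FEATURE_NAMES = (
    "saa_column_score",
    "emission_pearson",
    "ss_agreement",
    "neg_abs_rsa_diff",
    "windowed_ss_agreement",
    "min_neff_scaled",
)
GAP_FEATURE_NAMES = (
    "consumed_ss_class_score",
    "consumed_rsa",
    "emission_entropy",
    "consumed_neff_scaled",
    "terminus_distance",
    "gap_continuation",
)

#: per-class score of a consumed residue's secondary structure (H, E, C)
SS_CLASS_SCORE = {"H": 1.0, "E": -1.0, "C": 0.0}


@dataclass
class FeatureSchema:
    """Ordered feature names per edge type, with a version tag."""

    version: str = "1"
    window: int = 2
    match_names: Tuple[str, ...] = MATCH_FEATURE_NAMES
    gap_names: Tuple[str, ...] = GAP_FEATURE_NAMES

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "window": self.window,
            "match_names": list(self.match_names),
            "gap_names": list(self.gap_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            version=str(d["version"]),
            window=int(d["window"]),
            match_names=tuple(d["match_names"]),
            gap_names=tuple(d["gap_names"]),
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.dot(xc, xc))
    ny = float(np.dot(yc, yc))
    if nx <= 1e-18 or ny <= 1e-18:
        return 0.0  # degenerate variance defined as 0 by contract
    return float(np.dot(xc, yc) / np.sqrt(nx * ny))


def match_features(pair: PairInput, i: int, j: int, window: int = 2,
                   saa_floor: float = -10.0) -> np.ndarray:
    """Six match-edge features for aligned columns (template i, target j).

    (1) Saa column score (bits, floored); (2) Pearson correlation of the two
    emission vectors (0 when a column is degenerate); (3) confidence-weighted
    secondary-structure agreement (unit weight); (4) minus the absolute RSA
    difference; (5) mean secondary-structure agreement over window offsets
    ``-w..+w`` (boundary-truncated); (6) the smaller column diversity, / 20.
    """
    if not (0 <= i < pair.Ls and 0 <= j < pair.Lt):
        raise IndexError(f"columns ({i}, {j}) out of range")
    tpl, tar = pair.template, pair.target
    ta, qa = pair.template_ann, pair.target_ann
    f1 = saa(tpl, i, tar, j, saa_floor)
    f2 = _pearson(tpl.emissions[i], tar.emissions[j])
    f3 = float(np.dot(qa.ss_probs[j], DEFAULT_SS_MATRIX[SS_INDEX[ta.ss[i]]]))
    f4 = -abs(float(ta.rsa[i]) - float(qa.rsa[j]))
    agree = []
    for o in range(-window, window + 1):
        ii, jj = i + o, j + o
        if 0 <= ii < pair.Ls and 0 <= jj < pair.Lt:
            agree.append(float(np.dot(ta.ss_probs[ii], qa.ss_probs[jj])))
    f5 = float(np.mean(agree)) if agree else 0.0
    f6 = min(float(tpl.neff[i]), float(tar.neff[j])) / 20.0
    return np.array([f1, f2, f3, f4, f5, f6])


def gap_features(profile: ProfileHMM, ann: StructuralAnnotation, pos: int,
                 prev_same_state: bool) -> np.ndarray:
    """Six gap-edge features for the residue ``pos`` consumed by the gap.

    (1) secondary-structure class score (H=1, E=-1, C=0); (2) RSA;
    (3) emission-column entropy normalised by ln 20; (4) column diversity
    / 20; (5) normalised distance to the nearer chain terminus, in [0, 0.5];
    (6) 1 if the previous edge had the same state (gap continuation), else 0.
    """
    L = len(profile)
    if not 0 <= pos < L:
        raise IndexError(f"position {pos} out of range")
    p = profile.emissions[pos]
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum()) / LN20
    dist = min(pos, L - 1 - pos) / (L - 1) if L > 1 else 0.0
    return np.array([
        SS_CLASS_SCORE[ann.ss[pos]],
        float(ann.rsa[pos]),
        entropy,
        float(profile.neff[pos]) / 20.0,
        dist,
        1.0 if prev_same_state else 0.0,
    ])


# ---------------------------------------------------------------------------
# vectorised per-pair cache
# ---------------------------------------------------------------------------


def _match_feature_grid(pair: PairInput, window: int, saa_floor: float
                        ) -> np.ndarray:
    """(Ls, Lt, 6) array of match features, same formulas as match_features."""
    tpl, tar = pair.template, pair.target
    ta, qa = pair.template_ann, pair.target_ann
    Ls, Lt = pair.Ls, pair.Lt

    f1 = saa_matrix(tpl, tar, saa_floor)

    E1 = tpl.emissions - tpl.emissions.mean(axis=1, keepdims=True)
    E2 = tar.emissions - tar.emissions.mean(axis=1, keepdims=True)
    n1 = np.sqrt((E1 ** 2).sum(axis=1))
    n2 = np.sqrt((E2 ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        f2 = (E1 @ E2.T) / np.outer(n1, n2)
    f2 = np.where(np.outer(n1 > 1e-9, n2 > 1e-9), np.nan_to_num(f2), 0.0)

    f3 = DEFAULT_SS_MATRIX[ta.ss_indices] @ qa.ss_probs.T
    f4 = -np.abs(ta.rsa[:, None] - qa.rsa[None, :])

    agree = ta.ss_probs @ qa.ss_probs.T  # (Ls, Lt) per-offset agreement
    total = np.zeros((Ls, Lt))
    count = np.zeros((Ls, Lt))
    for o in range(-window, window + 1):
        if o >= 0:
            sub = agree[o:, o:]
            total[: Ls - o, : Lt - o] += sub
            count[: Ls - o, : Lt - o] += 1
        else:
            k = -o
            sub = agree[: Ls - k, : Lt - k]
            total[k:, k:] += sub
            count[k:, k:] += 1
    f5 = total / np.maximum(count, 1)

    f6 = np.minimum(tpl.neff[:, None], tar.neff[None, :]) / 20.0
    return np.stack([f1, f2, f3, f4, f5, f6], axis=-1)


def _gap_feature_rows(profile: ProfileHMM, ann: StructuralAnnotation
                      ) -> np.ndarray:
    """(L, 2, 6): gap features per consumed position, continuation 0 and 1."""
    L = len(profile)
    p = profile.emissions
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=1) / LN20
    pos = np.arange(L)
    dist = np.minimum(pos, L - 1 - pos) / (L - 1) if L > 1 else np.zeros(L)
    ss_score = np.array([SS_CLASS_SCORE[c] for c in ann.ss])
    base = np.stack(
        [ss_score, ann.rsa, entropy, profile.neff / 20.0, dist,
         np.zeros(L)], axis=-1
    )
    out = np.stack([base, base.copy()], axis=1)
    out[:, 1, 5] = 1.0
    return out


@dataclass
class PairFeatures:
    """Cached feature arrays for one pair's lattice.

    ``match[i, j]`` (0-based residue indices) is the match-edge vector;
    ``template_gap[i, c]`` / ``target_gap[j, c]`` are gap-edge vectors for
    the consumed position with continuation flag ``c`` in {0, 1}.
    """

    schema: FeatureSchema
    match: np.ndarray
    template_gap: np.ndarray
    target_gap: np.ndarray

    @classmethod
    def build(cls, pair: PairInput, schema: Optional[FeatureSchema] = None,
              saa_floor: float = -10.0) -> "PairFeatures":
        schema = schema or FeatureSchema()
        return cls(
            schema=schema,
            match=_match_feature_grid(pair, schema.window, saa_floor),
            template_gap=_gap_feature_rows(pair.template, pair.template_ann),
            target_gap=_gap_feature_rows(pair.target, pair.target_ann),
        )

    def edge_vector(self, scheme: str, p_idx: int, s_idx: int,
                    i: int, j: int) -> np.ndarray:
        """Feature vector of the edge (p -> s) into cell (i, j).

        ``p_idx`` may be ``len(states)`` for the BEGIN edge (continuation 0).
        """
        states = scheme_states(scheme)
        s = states[s_idx]
        if DELTAS[s] == (1, 1):
            return self.match[i - 1, j - 1]
        cont = 1 if (p_idx < len(states) and p_idx == s_idx) else 0
        if DELTAS[s] == (1, 0):
            return self.template_gap[i - 1, cont]
        return self.target_gap[j - 1, cont]
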