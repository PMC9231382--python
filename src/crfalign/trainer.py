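"""Stage-wise CRF training with boosted-regression-tree corrections.

Each training step evaluates edge posteriors for every training pair under
the current model ``F = T0 + sum_k mu_k T_k``, samples positive transitions
(the reference-path edges, labelled ``1 - P(edge)``) and ``Nf * La``
uniformly drawn off-path negatives (labelled ``-P(edge)``), pools the samples
over all pairs per alignment state, fits one six-tree ensemble per state to
those functional-gradient labels, and appends the stage with weight ``mu``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .base_scoring import BaseModelConfig, PairInput, base_lattice_scores, label_five_state
from .crf_engine import (
    DELTAS,
    NEG,
    AlignmentPath,
    EdgeScoreTable,
    PosteriorTables,
    forward_backward,
    iter_path_edges,
    map_align,
    path_log_probability,
    scheme_states,
    viterbi,
)
from .features import FeatureSchema, PairFeatures
from .gbrt import StageEnsemble, fit_stage, predict_stages
from .profile_io import ReferenceAlignment

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "crfalign-model/1"

#: fixed order used to hand out the negative-sample remainder
NEGATIVE_SPLIT_ORDER = {
    "three_state": ("M", "I", "D"),
    "five_state": ("MM", "MI", "IM", "GD", "DG"),
}


@dataclass
class TrainConfig:
    """Knobs of the stage-wise training loop.

    ``n_steps`` boosting stages of weight ``mu`` each; ``neg_factor`` (Nf)
    negatives per reference-alignment column; ``min_leaf`` and ``window``
    are forwarded to the trees and the feature extractor.
    """

    n_steps: int = 10
    mu: float = 0.2
    neg_factor: int = 16
    scheme: str = "three_state"
    seed: int = 0
    min_leaf: int = 20
    window: int = 2
    null_base: bool = False
    compute_metrics: bool = True
    mth: float = 0.3

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.neg_factor < 1:
            raise ValueError("neg_factor must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


@dataclass
class ScoringModel:
    """The full alignment scoring function ``F = T0 + sum_k mu_k T_k``.

    ``base`` configures the HHalign-style T0; with ``null_base`` the base is
    the trivial model (score 0 on every allowed edge).  ``stages`` is the
    ordered list of ``(mu, {state: StageEnsemble})``.
    """

    base: BaseModelConfig
    schema: FeatureSchema = field(default_factory=FeatureSchema)
    stages: List[Tuple[float, Dict[str, StageEnsemble]]] = field(default_factory=list)
    null_base: bool = False
    version: str = MODEL_FORMAT_VERSION

    @property
    def scheme(self) -> str:
        return self.base.scheme

    def features_for(self, pair: PairInput) -> PairFeatures:
        return PairFeatures.build(pair, self.schema, self.base.saa_floor)

    def edge_scores(self, pair: PairInput,
                    feats: Optional[PairFeatures] = None) -> EdgeScoreTable:
        """Total edge-score table (base plus all stage corrections)."""
        if self.null_base:
            table = EdgeScoreTable.zeros(self.scheme, pair.Ls, pair.Lt,
                                         self.base.allowed())
        else:
            table = base_lattice_scores(pair, self.base)
        if not self.stages:
            return table
        if feats is None:
            feats = self.features_for(pair)
        self._add_stage_scores(table, feats)
        return table

    def _add_stage_scores(self, table: EdgeScoreTable,
                          feats: PairFeatures) -> None:
        states = table.states
        Ls, Lt = table.Ls, table.Lt
        for si, s in enumerate(states):
            di, dj = DELTAS[s]
            if (di, dj) == (1, 1):
                X = feats.match.reshape(-1, feats.match.shape[-1])
                pred = predict_stages(self.stages, s, X).reshape(Ls, Lt)
                grid = np.zeros((Ls + 1, Lt + 1))
                grid[1:, 1:] = pred
                contribs = {0: grid, 1: grid}
            elif (di, dj) == (1, 0):
                pred = np.stack([
                    predict_stages(self.stages, s, feats.template_gap[:, c])
                    for c in (0, 1)
                ], axis=1)  # (Ls, 2)
                g0 = np.zeros((Ls + 1, Lt + 1))
                g1 = np.zeros((Ls + 1, Lt + 1))
                g0[1:, :] = pred[:, 0][:, None]
                g1[1:, :] = pred[:, 1][:, None]
                contribs = {0: g0, 1: g1}
            else:
                pred = np.stack([
                    predict_stages(self.stages, s, feats.target_gap[:, c])
                    for c in (0, 1)
                ], axis=1)  # (Lt, 2)
                g0 = np.zeros((Ls + 1, Lt + 1))
                g1 = np.zeros((Ls + 1, Lt + 1))
                g0[:, 1:] = pred[:, 0][None, :]
                g1[:, 1:] = pred[:, 1][None, :]
                contribs = {0: g0, 1: g1}
            ent = table.entry[si]
            table.entry[si] = np.where(np.isfinite(ent), ent + contribs[0], NEG)
            for pi in range(len(states)):
                cont = 1 if pi == si else 0
                cur = table.interior[pi, si]
                table.interior[pi, si] = np.where(
                    np.isfinite(cur), cur + contribs[cont], NEG
                )

    def align(self, pair: PairInput, decode: str = "map", mode: str = "global",
              mth: float = 0.3,
              feats: Optional[PairFeatures] = None) -> Tuple[AlignmentPath, dict]:
        """Decode one pair; returns the path and a summary dict."""
        table = self.edge_scores(pair, feats)
        post = forward_backward(table)
        if decode == "viterbi":
            path, score = viterbi(table, mode=mode)
        elif decode == "map":
            path = map_align(post, mode=mode, mth=mth if mode != "global" else 0.0)
            score = float(sum(post.match_posteriors[i, j] for i, j in path.pairs))
        else:
            raise ValueError(f"unknown decode method {decode!r}")
        info = {"log_Z": post.log_Z, "score": score, "n_matches": len(path.pairs)}
        return path, info


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def reference_path(ref: ReferenceAlignment, pair: PairInput,
                   scheme: str, base: Optional[BaseModelConfig] = None
                   ) -> AlignmentPath:
    """The reference path in the training scheme.

    Five-state training first resolves the MI/DG and IM/GD ambiguity by the
    max-score labeling of the reference alignment.
    """
    if ref.path is None:
        raise ValueError("reference alignment has no path")
    if scheme == "three_state":
        return ref.path
    return label_five_state(ref, pair, base)


def sample_transitions(path: AlignmentPath, post: PosteriorTables,
                       scores: EdgeScoreTable, feats: PairFeatures,
                       neg_factor: int, rng: np.random.Generator
                       ) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Positive and negative training samples for one pair.

    Positives are the ``La`` reference-path edges with label ``1 - P(edge)``;
    negatives are ``Nf * La`` off-path edges drawn uniformly without
    replacement, allocated evenly across the alignment states (remainder in
    fixed state order), with label ``-P(edge)``.
    """
    states = scheme_states(path.scheme)
    S = len(states)
    Ls, Lt = post.Ls, post.Lt
    X: Dict[str, List[np.ndarray]] = {s: [] for s in states}
    y: Dict[str, List[float]] = {s: [] for s in states}

    on_path = set(iter_path_edges(path))
    for p, s, i, j in on_path:
        prob = (post.begin_posteriors[s, i, j] if p == S
                else post.edge_posteriors[p, s, i, j])
        X[states[s]].append(feats.edge_vector(path.scheme, p, s, i, j))
        y[states[s]].append(1.0 - float(prob))

    La = len(path)
    n_neg = neg_factor * La
    order = NEGATIVE_SPLIT_ORDER[path.scheme]
    quotas = {s: n_neg // S for s in order}
    for k in range(n_neg % S):
        quotas[order[k]] += 1

    for sname in order:
        si = states.index(sname)
        pool: List[Tuple[int, int, int, int]] = []
        finite = np.isfinite(scores.interior[:, si])
        for pi, i, j in zip(*np.nonzero(finite)):
            e = (int(pi), si, int(i), int(j))
            if e not in on_path:
                pool.append(e)
        di, dj = DELTAS[sname]
        if np.isfinite(scores.entry[si, di, dj]):
            e = (S, si, di, dj)
            if e not in on_path:
                pool.append(e)
        k = quotas[sname]
        if len(pool) < k:
            logger.warning(
                "state %s: only %d off-path edges available for %d requested",
                sname, len(pool), k,
            )
            chosen = pool
        else:
            idx = rng.choice(len(pool), size=k, replace=False)
            chosen = [pool[t] for t in sorted(idx)]
        for p, s, i, j in chosen:
            prob = (post.begin_posteriors[s, i, j] if p == S
                    else post.edge_posteriors[p, s, i, j])
            X[sname].append(feats.edge_vector(path.scheme, p, s, i, j))
            y[sname].append(-float(prob))

    return {
        s: (np.array(X[s]) if X[s] else np.zeros((0, 6)),
            np.array(y[s]))
        for s in states
    }


# ---------------------------------------------------------------------------
# metrics and the training loop
# ---------------------------------------------------------------------------


def alignment_accuracy(pred, ref: ReferenceAlignment) -> float:
    """Fraction of the reference's aligned pairs recovered by the prediction."""
    ref_pairs = set(ref.pairs)
    if not ref_pairs:
        raise ValueError("reference alignment has zero aligned pairs")
    pred_pairs = set(pred.pairs if isinstance(pred, AlignmentPath) else pred)
    return len(pred_pairs & ref_pairs) / len(ref_pairs)


def train(pairs: Sequence[Tuple[PairInput, ReferenceAlignment]],
          config: TrainConfig) -> Tuple[ScoringModel, List[dict]]:
    """Run the stage-wise residual training loop.

    Returns the trained model and one metrics row per step (step 0 is the
    base model), each with the mean reference-path log-probability and the
    Viterbi/MAP training accuracies.
    """
    if not pairs:
        raise ValueError("empty training pair list")
    base = BaseModelConfig(scheme=config.scheme)
    schema = FeatureSchema(window=config.window)
    model = ScoringModel(base=base, schema=schema, null_base=config.null_base)

    prepared = []
    for pair, ref in pairs:
        try:
            feats = model.features_for(pair)
            ref_p = reference_path(ref, pair, config.scheme, base)
        except Exception as exc:  # noqa: BLE001 - skip unreadable pairs, named
            logger.warning("skipping pair %s-%s: %s",
                           ref.template_name, ref.target_name, exc)
            continue
        prepared.append((pair, ref, feats, ref_p))
    if not prepared:
        raise ValueError("no usable training pairs")

    metrics: List[dict] = []
    for step in range(config.n_steps + 1):
        posts = []
        for pair, ref, feats, ref_p in prepared:
            table = model.edge_scores(pair, feats)
            post = forward_backward(table)
            posts.append((table, post))
        if config.compute_metrics:
            row = {"step": step}
            logps, vit_accs, map_accs = [], [], []
            for (pair, ref, feats, ref_p), (table, post) in zip(prepared, posts):
                logps.append(path_log_probability(ref_p, table, post))
                vpath, _ = viterbi(table)
                vit_accs.append(alignment_accuracy(vpath.reduced(), ref))
                map_accs.append(alignment_accuracy(map_align(post), ref))
            row.update(
                mean_ref_logprob=float(np.mean(logps)),
                viterbi_accuracy=float(np.mean(vit_accs)),
                map_accuracy=float(np.mean(map_accs)),
            )
            metrics.append(row)
        else:
            metrics.append({"step": step})
        if step == config.n_steps:
            break

        pooled: Dict[str, Tuple[List[np.ndarray], List[np.ndarray]]] = {
            s: ([], []) for s in scheme_states(config.scheme)
        }
        for k, ((pair, ref, feats, ref_p), (table, post)) in enumerate(
                zip(prepared, posts)):
            rng = np.random.default_rng([config.seed, step, k])
            samples = sample_transitions(
                ref_p, post, table, feats, config.neg_factor, rng
            )
            for s, (Xs, ys) in samples.items():
                if len(Xs):
                    pooled[s][0].append(Xs)
                    pooled[s][1].append(ys)
        stacked = {
            s: (np.vstack(Xs) if Xs else np.zeros((0, 6)), np.concatenate(ys)
                if ys else np.zeros(0))
            for s, (Xs, ys) in pooled.items()
        }
        ensembles = fit_stage(stacked, min_leaf=config.min_leaf)
        model.stages.append((config.mu, ensembles))
        logger.info("appended stage %d (mu=%.3f)", step + 1, config.mu)

    return model, metrics


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: ScoringModel, path: str) -> None:
    """Serialize a model to versioned JSON."""
    doc = {
        "format": model.version,
        "null_base": model.null_base,
        "base": model.base.to_dict(),
        "schema": model.schema.to_dict(),
        "stages": [
            {"mu": mu, "ensembles": {s: e.to_dict() for s, e in ens.items()}}
            for mu, ens in model.stages
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_model(path: str) -> ScoringModel:
    """Load and validate a serialized model."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed model file {path}: {exc}") from exc
    if doc.get("format") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format {doc.get('format')!r} != {MODEL_FORMAT_VERSION!r}"
        )
    base = BaseModelConfig.from_dict(doc["base"])
    schema = FeatureSchema.from_dict(doc["schema"])
    stages = [
        (float(st["mu"]),
         {s: StageEnsemble.from_dict(e) for s, e in st["ensembles"].items()})
        for st in doc["stages"]
    ]
    model = ScoringModel(base=base, schema=schema, stages=stages,
                         null_base=bool(doc["null_base"]))
    states = set(scheme_states(model.scheme))
    for mu, ens in model.stages:
        if set(ens) != states:
            raise ValueError("stage does not cover every alignment state")
    return model


def evaluate(model: ScoringModel,
             pairs: Sequence[Tuple[PairInput, ReferenceAlignment]],
             decode: str = "map", mode: str = "global", mth: float = 0.3
             ) -> dict:
    """Mean alignment accuracy and true-match count over a pair set."""
    accs, true_matches = [], []
    for pair, ref in pairs:
        path, _ = model.align(pair, decode=decode, mode=mode, mth=mth)
        accs.append(alignment_accuracy(path.reduced(), ref))
        true_matches.append(len(set(path.reduced().pairs) & set(ref.pairs)))
    return {
        "mean_accuracy": float(np.mean(accs)),
        "mean_true_matches": float(np.mean(true_matches)),
        "n_pairs": len(accs),
    }
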