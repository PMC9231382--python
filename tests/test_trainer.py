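"""Sampling contract, training loop behavior, model persistence."""

import json

import numpy as np
import pytest

from crfalign.base_scoring import BaseModelConfig
from crfalign.crf_engine import EdgeScoreTable, forward_backward
from crfalign.features import PairFeatures
from crfalign.synthetic_fixtures import SimConfig, simulate_set
from crfalign.trainer import (
    ScoringModel,
    TrainConfig,
    alignment_accuracy,
    evaluate,
    load_model,
    reference_path,
    sample_transitions,
    save_model,
    train,
)

from conftest import make_pair, path_from_states, reference_from_states


def _sampling_setup(states, seed=0):
    """Zero-score lattice + features for a hand-built reference path."""
    path = path_from_states(states)
    pair = make_pair(path.Ls, path.Lt, seed=seed)
    table = EdgeScoreTable.zeros("three_state", path.Ls, path.Lt)
    post = forward_backward(table)
    feats = PairFeatures.build(pair)
    return path, post, table, feats


class TestSampling:
    def test_counts_and_even_split(self):
        # La = 10, Nf = 16: 10 positives, 160 negatives split 54/53/53 (M, I, D)
        path, post, table, feats = _sampling_setup("MMMMIIDDMM")
        assert len(path) == 10
        rng = np.random.default_rng(1)
        samples = sample_transitions(path, post, table, feats, 16, rng)
        n_pos = {s: sum(1 for v in y if v > 0) for s, (X, y) in samples.items()}
        n_neg = {s: sum(1 for v in y if v <= 0) for s, (X, y) in samples.items()}
        assert sum(n_pos.values()) == 10
        assert n_pos == {"M": 6, "I": 2, "D": 2}
        assert sum(n_neg.values()) == 160
        assert n_neg == {"M": 54, "I": 53, "D": 53}

    def test_labels_are_functional_gradients(self):
        path, post, table, feats = _sampling_setup("MMIM")
        rng = np.random.default_rng(2)
        samples = sample_transitions(path, post, table, feats, 2, rng)
        for s, (X, y) in samples.items():
            assert np.all(y <= 1.0) and np.all(y >= -1.0)
        # positives of a diffuse lattice have labels close to (but below) 1
        assert all(0 < v < 1 for v in samples["I"][1][:1])

    def test_deterministic_under_fixed_seed(self):
        path, post, table, feats = _sampling_setup("MMMMIIDDMM")
        a = sample_transitions(path, post, table, feats, 16,
                               np.random.default_rng(7))
        b = sample_transitions(path, post, table, feats, 16,
                               np.random.default_rng(7))
        for s in a:
            assert np.array_equal(a[s][0], b[s][0])
            assert np.array_equal(a[s][1], b[s][1])

    def test_degenerate_single_path_lattice(self):
        # only M->M allowed and only the M entry edge: one path, certainty
        path = path_from_states("MMM")
        pair = make_pair(3, 3, seed=3)
        table = EdgeScoreTable.zeros("three_state", 3, 3,
                                     allowed=frozenset({("M", "M")}))
        table.entry[1:] = -np.inf  # kill D and I begin edges
        post = forward_backward(table)
        feats = PairFeatures.build(pair)
        samples = sample_transitions(path, post, table, feats, 16,
                                     np.random.default_rng(0))
        ys = np.concatenate([y for _, y in samples.values()])
        pos = ys[ys >= 0]
        assert np.allclose(pos[np.abs(ys[ys >= 0]) < 0.5], 0.0, atol=1e-12)
        # every positive is labelled 0 (posterior 1 on the single path)
        assert np.allclose(
            [v for v in ys if v > -1e-12], 0.0, atol=1e-12)


@pytest.fixture(scope="module")
def small_set():
    return simulate_set(SimConfig(n_pairs=10, length_min=20,
                                  length_max=30, seed=21))


class TestTrainLoop:
    def test_zero_steps_returns_base_model(self, small_set):
        model, metrics = train(small_set[:4],
                               TrainConfig(n_steps=0, compute_metrics=False))
        assert model.stages == []
        assert len(metrics) == 1

    def test_reference_logprob_ascends(self, small_set):
        cfg = TrainConfig(n_steps=3, seed=5, null_base=True, min_leaf=10)
        model, metrics = train(small_set[:8], cfg)
        assert len(model.stages) == 3
        assert metrics[3]["mean_ref_logprob"] > metrics[0]["mean_ref_logprob"]
        assert metrics[3]["map_accuracy"] >= metrics[0]["map_accuracy"]

    def test_training_reproducible_bit_for_bit(self, small_set, tmp_path):
        cfg = TrainConfig(n_steps=2, seed=9, null_base=True,
                          compute_metrics=False, min_leaf=10)
        m1, _ = train(small_set[:5], cfg)
        m2, _ = train(small_set[:5], cfg)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_model(m1, p1)
        save_model(m2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_vanishing_mu_reproduces_base_alignments(self, small_set):
        cfg = TrainConfig(n_steps=2, mu=1e-12, seed=5,
                          compute_metrics=False, min_leaf=10)
        model, _ = train(small_set[:4], cfg)
        base = ScoringModel(base=BaseModelConfig())
        for pair, ref in small_set[4:7]:
            p_model, _ = model.align(pair, decode="viterbi")
            p_base, _ = base.align(pair, decode="viterbi")
            assert p_model.pairs == p_base.pairs

    def test_five_state_training_improves_reference_logprob(self):
        pairs = simulate_set(SimConfig(n_pairs=4, length_min=15,
                                       length_max=20, seed=77))
        cfg = TrainConfig(n_steps=2, seed=2, scheme="five_state", min_leaf=5)
        model, metrics = train(pairs, cfg)
        assert sorted(model.stages[0][1]) == ["DG", "GD", "IM", "MI", "MM"]
        assert metrics[2]["mean_ref_logprob"] > metrics[0]["mean_ref_logprob"]

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig())


class TestAccuracy:
    def test_definitional_cases(self):
        ref = reference_from_states("MMMMMMMMMM")  # 10 pairs
        assert alignment_accuracy(ref.path, ref) == 1.0
        assert alignment_accuracy([], ref) == 0.0
        seven = ref.pairs[:7] + [(90, 91), (95, 97), (98, 99)]
        assert alignment_accuracy(seven, ref) == pytest.approx(0.7)

    def test_reference_without_pairs_rejected(self):
        ref = reference_from_states("MID")
        ref.pairs.clear()
        with pytest.raises(ValueError):
            alignment_accuracy([], ref)


class TestPersistence:
    def _model(self):
        pairs = simulate_set(SimConfig(n_pairs=3, length_min=15,
                                       length_max=20, seed=31))
        cfg = TrainConfig(n_steps=2, seed=1, compute_metrics=False, min_leaf=5)
        model, _ = train(pairs, cfg)
        return model, pairs

    def test_round_trip_predicts_identically(self, tmp_path):
        model, pairs = self._model()
        path = tmp_path / "m.json"
        save_model(model, path)
        back = load_model(path)
        assert back.scheme == model.scheme
        assert len(back.stages) == len(model.stages)
        for pair, _ in pairs:
            t1 = model.edge_scores(pair)
            t2 = back.edge_scores(pair)
            assert np.array_equal(t1.interior, t2.interior)

    def test_truncated_file_rejected(self, tmp_path):
        model, _ = self._model()
        path = tmp_path / "m.json"
        save_model(model, path)
        path.write_text(path.read_text()[:100])
        with pytest.raises(ValueError, match="malformed"):
            load_model(path)

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(json.dumps({"format": "other/9"}))
        with pytest.raises(ValueError, match="format"):
            load_model(path)

    def test_stage_blocks_cover_every_state(self, tmp_path):
        model, _ = self._model()
        path = tmp_path / "m.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        assert len(doc["stages"]) == 2
        for st in doc["stages"]:
            assert set(st["ensembles"]) == {"M", "I", "D"}
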