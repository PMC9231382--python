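"""Forward/backward, decoding and gradient checks against enumeration."""

import math

import numpy as np
import pytest

from crfalign import bruteforce as bf
from crfalign.crf_engine import (
    AlignmentPath,
    EdgeScoreTable,
    forward_backward,
    functional_gradient,
    iter_path_edges,
    map_align,
    path_log_probability,
    viterbi,
)

from conftest import path_from_states


def single_path_table(states):
    """A lattice admitting exactly one global path (all other edges -inf)."""
    path = path_from_states(states)
    table = EdgeScoreTable.zeros("three_state", path.Ls, path.Lt)
    keep_interior = np.zeros_like(table.interior, dtype=bool)
    keep_entry = np.zeros_like(table.entry, dtype=bool)
    S = 3
    for p, s, i, j in iter_path_edges(path):
        if p == S:
            keep_entry[s, i, j] = True
        else:
            keep_interior[p, s, i, j] = True
    table.interior[~keep_interior] = -np.inf
    table.entry[~keep_entry] = -np.inf
    return path, table


class TestForwardBackward:
    def test_1x1_zero_lattice(self):
        # three paths: {M}, {I,D}, {D,I}
        post = forward_backward(EdgeScoreTable.zeros("three_state", 1, 1))
        assert post.log_Z == pytest.approx(math.log(3), abs=1e-12)
        assert post.match_posteriors[0, 0] == pytest.approx(1 / 3)

    def test_2x2_zero_lattice_counts_13_paths(self):
        post = forward_backward(EdgeScoreTable.zeros("three_state", 2, 2))
        assert post.log_Z == pytest.approx(math.log(13), abs=1e-12)

    def test_single_path_lattice_is_certain(self):
        path, table = single_path_table("MIMD")
        rng = np.random.default_rng(0)
        n_int = int(np.isfinite(table.interior).sum())
        table.interior[np.isfinite(table.interior)] = rng.normal(size=n_int)
        table.entry[np.isfinite(table.entry)] = rng.normal(size=1)
        post = forward_backward(table)
        expected = sum(table.interior[np.isfinite(table.interior)]) \
            + table.entry[np.isfinite(table.entry)].sum()
        assert post.log_Z == pytest.approx(float(expected))
        on = post.edge_posteriors[np.isfinite(table.interior)]
        assert np.allclose(on, 1.0)

    @pytest.mark.parametrize("scheme", ["three_state", "five_state"])
    def test_matches_enumeration_on_random_lattices(self, scheme):
        rng = np.random.default_rng(11)
        for _ in range(20):
            Ls, Lt = (int(v) for v in rng.integers(1, 5, 2))
            table = bf.random_edge_table(scheme, Ls, Lt, rng)
            post = forward_backward(table)
            lz, interior, begin, match = bf.enum_posteriors(table)
            assert post.log_Z == pytest.approx(lz, abs=1e-10)
            assert np.abs(post.edge_posteriors - interior).max() < 1e-10
            assert np.abs(post.begin_posteriors - begin).max() < 1e-10
            assert np.abs(post.match_posteriors - match).max() < 1e-10

    def test_normalization_over_all_paths(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            table = bf.random_edge_table("three_state", 3, 3, rng)
            post = forward_backward(table)
            total = sum(
                math.exp(path_log_probability(p, table, post))
                for p in bf.enumerate_paths("three_state", 3, 3)
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_residue_consumption_conservation(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            table = bf.random_edge_table("three_state", 6, 6, rng)
            post = forward_backward(table)
            row = post.match_posteriors.sum(axis=1) + post.template_gap_posteriors()
            col = post.match_posteriors.sum(axis=0) + post.target_gap_posteriors()
            assert np.abs(row - 1).max() < 1e-8
            assert np.abs(col - 1).max() < 1e-8

    def test_nan_scores_rejected(self):
        table = EdgeScoreTable.zeros("three_state", 2, 2)
        table.interior[0, 0, 1, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            forward_backward(table)

    def test_posteriors_invariant_under_constant_shift(self):
        # gap-only lattice: every global path has length Ls + Lt
        rng = np.random.default_rng(5)
        allowed = frozenset((a, b) for a in "ID" for b in "ID")
        table = bf.random_edge_table("three_state", 3, 2, rng)
        mask3 = ~np.isfinite(EdgeScoreTable.zeros("three_state", 3, 2, allowed).interior)
        table.interior[mask3] = -np.inf
        mi = 0  # M state index; remove match entries entirely
        table.entry[mi] = -np.inf
        post = forward_backward(table)
        shifted = EdgeScoreTable("three_state", 3, 2,
                                 table.interior + 1.7, table.entry + 1.7)
        post2 = forward_backward(shifted)
        assert post2.log_Z == pytest.approx(post.log_Z + 1.7 * (3 + 2))
        assert np.abs(post2.edge_posteriors - post.edge_posteriors).max() < 1e-10


class TestViterbi:
    def test_tie_break_prefers_match_diagonal(self):
        table = EdgeScoreTable.zeros("three_state", 3, 3)
        path, score = viterbi(table)
        assert score == 0.0
        assert path.states == ["M", "M", "M"]

    def test_planted_pairs_recovered(self):
        rng = np.random.default_rng(6)
        table = EdgeScoreTable.zeros("three_state", 6, 6)
        planted = [(1, 2), (3, 3), (5, 4)]
        for i, j in planted:
            table.interior[:, 0, i + 1, j + 1] += 10.0
            table.entry[0, i + 1, j + 1] += 10.0
        path, _ = viterbi(table)
        assert set(planted) <= set(path.pairs)

    @pytest.mark.parametrize("scheme", ["three_state", "five_state"])
    def test_global_matches_enumeration(self, scheme):
        rng = np.random.default_rng(7)
        for _ in range(25):
            Ls, Lt = (int(v) for v in rng.integers(1, 5, 2))
            table = bf.random_edge_table(scheme, Ls, Lt, rng)
            path, score = viterbi(table)
            _, best = bf.enum_viterbi(table)
            assert score == pytest.approx(best, abs=1e-10)
            assert bf.path_score_by_lookup(path, table) == pytest.approx(score)

    @pytest.mark.parametrize("mode", ["glocal", "local"])
    def test_free_end_modes_match_enumeration(self, mode):
        rng = np.random.default_rng(8)
        for _ in range(10):
            Ls, Lt = (int(v) for v in rng.integers(1, 4, 2))
            table = bf.random_edge_table("three_state", Ls, Lt, rng)
            _, score = viterbi(table, mode=mode)
            assert score == pytest.approx(bf.enum_viterbi_mode(table, mode),
                                          abs=1e-10)

    def test_glocal_path_touches_opposite_boundaries(self):
        rng = np.random.default_rng(9)
        table = bf.random_edge_table("three_state", 4, 4, rng)
        path, _ = viterbi(table, mode="glocal")
        i0, j0 = path.start_cell
        i1, j1 = path.end_cell
        assert i0 == 0 or j0 == 0
        assert i1 == 4 or j1 == 4


class TestMapAlign:
    def _post(self, P):
        Ls, Lt = P.shape
        table = EdgeScoreTable.zeros("three_state", Ls, Lt)
        post = forward_backward(table)
        post.match_posteriors = P
        return post

    def test_single_strong_cell_global(self):
        P = np.zeros((3, 3))
        P[1, 2] = 0.9
        path = map_align(self._post(P))
        assert path.pairs == [(1, 2)] or (1, 2) in path.pairs

    def test_local_with_full_threshold_is_empty(self):
        rng = np.random.default_rng(10)
        table = bf.random_edge_table("three_state", 3, 3, rng, scale=0.5)
        post = forward_backward(table)
        path = map_align(post, mode="local", mth=1.0)
        assert path.states == [] and path.pairs == []

    def test_mth_out_of_range_rejected(self):
        post = self._post(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="mth"):
            map_align(post, mode="local", mth=1.5)

    def test_global_matches_subset_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            table = bf.random_edge_table("three_state", 4, 4, rng)
            post = forward_backward(table)
            path = map_align(post)
            got = sum(post.match_posteriors[i, j] for i, j in path.pairs)
            assert got == pytest.approx(
                bf.enum_best_colinear_total(post.match_posteriors), abs=1e-10)

    def test_map_maximises_expected_true_matches(self):
        # the defining property: over paths, MAP's posterior total >= Viterbi's
        rng = np.random.default_rng(12)
        for _ in range(10):
            table = bf.random_edge_table("three_state", 5, 5, rng)
            post = forward_backward(table)
            mpath = map_align(post)
            vpath, _ = viterbi(table)
            m_tot = sum(post.match_posteriors[i, j] for i, j in mpath.pairs)
            v_tot = sum(post.match_posteriors[i, j] for i, j in vpath.pairs)
            assert m_tot >= v_tot - 1e-12


class TestPathProbabilityAndGradient:
    def test_single_path_probability_one(self):
        path, table = single_path_table("MIMD")
        post = forward_backward(table)
        assert path_log_probability(path, table, post) == pytest.approx(0.0)
        gi, gb = functional_gradient(path, post)
        assert np.abs(gi).max() < 1e-12 and np.abs(gb).max() < 1e-12

    def test_1x1_match_path(self):
        table = EdgeScoreTable.zeros("three_state", 1, 1)
        post = forward_backward(table)
        path = path_from_states("M")
        assert path_log_probability(path, table, post) == pytest.approx(
            math.log(1 / 3))
        gi, gb = functional_gradient(path, post)
        assert gb[0, 1, 1] == pytest.approx(2 / 3)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(13)
        eps = 1e-5
        for _ in range(20):
            Ls, Lt = (int(v) for v in rng.integers(1, 4, 2))
            table = bf.random_edge_table("three_state", Ls, Lt, rng)
            paths = list(bf.enumerate_paths("three_state", Ls, Lt))
            ref = paths[rng.integers(len(paths))]
            post = forward_backward(table)
            gi, gb = functional_gradient(ref, post)
            idxs = np.argwhere(np.isfinite(table.interior))
            p, s, i, j = idxs[rng.integers(len(idxs))]

            def lp(delta):
                t2 = EdgeScoreTable(table.scheme, Ls, Lt,
                                    table.interior.copy(), table.entry.copy())
                t2.interior[p, s, i, j] += delta
                return path_log_probability(ref, t2, forward_backward(t2))

            fd = (lp(eps) - lp(-eps)) / (2 * eps)
            assert fd == pytest.approx(gi[p, s, i, j], abs=1e-4)

    def test_off_lattice_path_rejected(self):
        table = EdgeScoreTable.zeros("three_state", 2, 2)
        post = forward_backward(table)
        bad = path_from_states("MMM")  # ends at (3,3), outside a 2x2 lattice
        with pytest.raises(ValueError):
            path_log_probability(bad, table, post)
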