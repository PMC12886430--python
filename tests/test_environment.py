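"""Synthetic environments: generation, emission, stepping, transforms."""

import numpy as np
import pytest
from pydantic import ValidationError
from scipy import stats

import sameness as sn
from sameness.environment import ConstraintInfeasibleError, _sample_separated
from sameness.therapy import _teach
from sameness import memory as mem


def pairwise_min_dist(env):
    P = env.prototype_matrix()
    d = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return d.min()


class TestSpecValidation:
    def test_branch_arity_one_rejected(self):
        with pytest.raises(ValidationError):
            sn.EnvSpec(branch_arity=1)

    def test_branch_position_out_of_range(self):
        with pytest.raises(ValidationError):
            sn.EnvSpec(seq_length=4, branch_positions=[3])

    def test_branch_probs_must_normalize(self):
        with pytest.raises(ValidationError):
            sn.EnvSpec(branch_positions=[1], branch_probs=[0.7, 0.7])

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError):
            sn.EnvSpec(nonsense=3)


class TestGeneration:
    def test_single_chain(self):
        env = sn.generate_environment(sn.EnvSpec(n_sequences=1, seq_length=5, seed=1))
        assert len(env.states) == 5
        assert env.paths == [[0, 1, 2, 3, 4]]
        assert all(env.out_degree(s) <= 1 for s in env.states)

    def test_three_way_branch_topology(self):
        env = sn.generate_environment(
            sn.EnvSpec(seq_length=4, branch_positions=[1], branch_arity=3,
                       prototype_dim=10, seed=2)
        )
        degs = [env.out_degree(s) for s in env.states]
        assert degs.count(3) == 1
        assert len(env.paths) == 3

    def test_determinism(self):
        spec = sn.EnvSpec(n_sequences=2, seq_length=6, branch_positions=[2], seed=42)
        a = sn.generate_environment(spec)
        b = sn.generate_environment(spec)
        assert np.array_equal(a.prototype_matrix(), b.prototype_matrix())
        assert a.paths == b.paths

    def test_separation_invariant(self):
        spec = sn.EnvSpec(n_sequences=3, seq_length=6, prototype_min_separation=2.5, seed=3)
        env = sn.generate_environment(spec)
        assert pairwise_min_dist(env) >= 2.5

    def test_separation_unattainable_errors(self):
        class DegenerateRng:
            def normal(self, loc, scale, size):
                return np.zeros(size)

        with pytest.raises(RuntimeError, match="separated prototype"):
            _sample_separated(DegenerateRng(), [np.zeros(2)], 2, 10.0, max_tries=50)


class TestEmit:
    def test_zero_noise_exact_prototype(self, chain_env):
        rng = np.random.default_rng(0)
        s = chain_env.paths[0][0]
        assert np.array_equal(sn.emit(chain_env, s, rng), chain_env.states[s])

    def test_seeded_reproducibility(self):
        spec = sn.EnvSpec(seq_length=3, noise_sd=0.3, seed=5)
        env = sn.generate_environment(spec)
        a = sn.emit(env, 0, np.random.default_rng(9))
        b = sn.emit(env, 0, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_emission_mean_near_prototype(self):
        spec = sn.EnvSpec(seq_length=2, noise_sd=0.5, prototype_dim=4, seed=6)
        env = sn.generate_environment(spec)
        rng = np.random.default_rng(7)
        sims = np.vstack([sn.emit(env, 0, rng) for _ in range(1000)])
        err = np.abs(sims.mean(axis=0) - env.states[0])
        assert np.all(err < 3 * 0.5 / np.sqrt(1000))

    def test_noise_clip_bounds_norm(self):
        spec = sn.EnvSpec(seq_length=2, noise_sd=5.0, noise_clip=0.7, seed=8)
        env = sn.generate_environment(spec)
        rng = np.random.default_rng(1)
        for _ in range(50):
            dev = sn.emit(env, 0, rng) - env.states[0]
            assert np.linalg.norm(dev) <= 0.7 + 1e-12


class TestStep:
    def test_chain_successor(self, chain_env):
        rng = np.random.default_rng(0)
        s0 = chain_env.paths[0][0]
        nxt, stim = sn.step_environment(chain_env.copy(), s0, rng)
        assert nxt == chain_env.paths[0][1]

    def test_always_novel_at_rate_one(self):
        spec = sn.EnvSpec(seq_length=4, novelty_rate=1.0, seed=4)
        env = sn.generate_environment(spec)
        base_states = set(env.states)
        rng = np.random.default_rng(2)
        work = env.copy()
        cur = None
        for _ in range(5):
            cur, stim = sn.step_environment(work, cur, rng)
            assert cur not in base_states  # every step injects a new state

    def test_branch_frequencies_match_probs(self):
        spec = sn.EnvSpec(seq_length=3, branch_positions=[0], branch_arity=2, seed=10)
        env = sn.generate_environment(spec)
        root = env.paths[0][0]
        rng = np.random.default_rng(11)
        first = env.successors[root][0][0]
        hits = sum(
            sn.step_environment(env.copy(), root, rng)[0] == first
            for _ in range(10000)
        )
        assert abs(hits / 10000 - 0.5) < 0.02

    def test_constrained_redraw_and_infeasibility(self, branching_env):
        env = branching_env.copy()
        branch = next(s for s in env.states if env.out_degree(s) > 1)
        succ = [t for t, _ in env.successors[branch]]
        rng = np.random.default_rng(3)
        nxt, _ = sn.step_environment(env, branch, rng, constrain_to={succ[0]})
        assert nxt == succ[0]
        with pytest.raises(ConstraintInfeasibleError):
            sn.step_environment(env, branch, rng, constrain_to={-1})

    def test_novelty_suppressed_under_constraint(self):
        spec = sn.EnvSpec(seq_length=4, novelty_rate=1.0, seed=12)
        env = sn.generate_environment(spec)
        rng = np.random.default_rng(13)
        nxt, _ = sn.step_environment(env, 0, rng, constrain_to=set(env.states))
        assert nxt in {t for t, _ in env.successors[0]}


class TestDeprivation:
    def test_every_emission_is_new(self):
        env = sn.deprivation_environment(8, 1.0, seed=1)
        g = mem.MemoryGraph(8)
        mem.insert_observation(g, None, np.full(8, 50.0), 0.5)
        rng = np.random.default_rng(2)
        for _ in range(20):
            _, stim = sn.step_environment(env, 0, rng)
            assert mem.classify(g, stim, 0.5).is_new

    def test_norm_tail_matches_chi_distribution(self):
        d, sd, eps = 8, 1.0, 2.5
        env = sn.deprivation_environment(d, sd, seed=3)
        rng = np.random.default_rng(4)
        norms = np.array(
            [np.linalg.norm(sn.step_environment(env, 0, rng)[1]) for _ in range(3000)]
        )
        frac = (norms > eps).mean()
        expected = stats.chi(df=d, scale=sd).sf(eps)
        se = np.sqrt(expected * (1 - expected) / 3000)
        assert abs(frac - expected) < 4 * se

    def test_requires_positive_noise(self):
        with pytest.raises(ValueError):
            sn.deprivation_environment(4, 0.0)


class TestTransforms:
    def test_amulet_separates_shared_states(self, branching_env):
        env2 = sn.transform_amulets(branching_env)
        assert env2.dim == branching_env.dim + len(branching_env.paths)
        # former shared prefixes are duplicated: one chain per path
        assert len(env2.states) == sum(len(p) for p in env2.paths)
        assert all(env2.out_degree(s) <= 1 for s in env2.states)
        assert pairwise_min_dist(env2) >= branching_env.prototype_min_separation

    def test_amulet_zeroes_memorized_branch_uncertainty(self, branching_env):
        eps = 0.5
        env2 = sn.transform_amulets(branching_env)
        g_before, g_after = mem.MemoryGraph(), mem.MemoryGraph()
        for p in branching_env.paths:
            _teach(g_before, branching_env, p, eps)
        for p in env2.paths:
            _teach(g_after, env2, p, eps)
        # uncertainty at the former branch point (original index 2)
        ctx_before = branching_env.paths[0][:3]
        ids_before = [mem.classify(g_before, branching_env.states[s], eps).item_id
                      for s in ctx_before]
        cls_b = mem.classify(g_before, branching_env.states[ctx_before[-1]], eps)
        assert mem.predictive_uncertainty(g_before, cls_b, ids_before) == pytest.approx(1.0)
        ctx_after = env2.paths[0][:3]
        ids_after = [mem.classify(g_after, env2.states[s], eps).item_id
                     for s in ctx_after]
        cls_a = mem.classify(g_after, env2.states[ctx_after[-1]], eps)
        assert mem.predictive_uncertainty(g_after, cls_a, ids_after) == 0.0

    def test_amulet_identity_topology_on_chain(self, chain_env):
        env2 = sn.transform_amulets(chain_env)
        assert len(env2.paths) == 1 and len(env2.states) == len(chain_env.states)

    def test_branch_to_start_moves_choice_to_index_zero(self):
        spec = sn.EnvSpec(seq_length=6, branch_positions=[3], branch_arity=2,
                          prototype_dim=8, seed=21)
        env = sn.generate_environment(spec)
        env2 = sn.transform_branch_to_start(env)
        heads = {p[0] for p in env2.paths}
        assert len(heads) == len(env2.paths)  # perceptually distinct from step 0
        assert all(env2.out_degree(s) <= 1 for s in env2.states)
        assert sorted(s for p in env2.paths for s in p) == sorted(
            s for p in env.paths for s in p
        )

    def test_branch_to_start_identity_on_branchless(self, chain_env):
        env2 = sn.transform_branch_to_start(chain_env)
        assert env2.paths == chain_env.paths

    def test_branch_to_start_shifts_uncertainty_peak(self):
        """After memorization, per-step uncertainty peaks at step 0, not mid-sequence."""
        eps = 0.5
        spec = sn.EnvSpec(seq_length=6, branch_positions=[3], branch_arity=2,
                          prototype_dim=8, seed=22)
        env = sn.generate_environment(spec)

        def uncertainty_profile(e):
            g = mem.MemoryGraph()
            for p in e.paths:
                _teach(g, e, p, eps)
            prof = []
            path = e.paths[0]
            ids = [mem.classify(g, e.states[s], eps).item_id for s in path]
            for k in range(1, len(path)):
                cls = mem.classify(g, e.states[path[k - 1]], eps)
                prof.append(mem.predictive_uncertainty(g, cls, ids[:k]))
            return prof

        before = uncertainty_profile(env)
        after = uncertainty_profile(sn.transform_branch_to_start(env))
        assert int(np.argmax(before)) > 0
        assert max(after) == 0.0  # within-sequence prediction fully deterministic

    @pytest.mark.parametrize("nu,nu_max", [(4, 2), (8, 2)])
    def test_limit_options_prunes_to_nu_max(self, nu, nu_max):
        spec = sn.EnvSpec(seq_length=4, branch_positions=[1], branch_arity=nu,
                          prototype_dim=16, seed=23)
        env = sn.generate_environment(spec)
        env2 = sn.transform_limit_options(env, nu_max)
        assert max(env2.out_degree(s) for s in env2.states) == nu_max
        assert len(env2.paths) == nu_max
        assert pairwise_min_dist(env2) >= env.prototype_min_separation

    def test_limit_options_identity_when_wide(self, branching_env):
        env2 = sn.transform_limit_options(branching_env, 10)
        assert env2.paths == branching_env.paths
        assert env2.successors == branching_env.successors


class TestPresets:
    @pytest.mark.parametrize("name", ["chain", "branching", "nonstationary", "deprivation"])
    def test_presets_generate(self, name):
        env = sn.generate_environment(sn.preset_spec(name))
        assert env.dim > 0

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            sn.preset_spec("nope")
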