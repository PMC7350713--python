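import math

import numpy as np
import pandas as pd
import pytest

from archorisk import bodysize as bs
from archorisk.simulate import simulate_levy_trait
from archorisk.trees import TreeArrays, parse_newick, to_arrays

from conftest import random_bd_tree, tree_with_tips
from oracles import conditional_normal_mean, dense_bm_loglik


def _bm_data(tree, seed, sigma2=1.0):
    y, _ = simulate_levy_trait(tree, sigma2, 0.0, 1.0, seed=seed)
    return y


class TestBMLikelihood:
    def test_matches_dense_mvn_oracle(self):
        for seed in range(6):
            tree = random_bd_tree(seed, lam=0.3, mu=0.05, crown_age=8.0)
            arr = to_arrays(tree)
            y = _bm_data(tree, seed)
            C = bs.vcv_matrix(arr)
            for sigma2 in (0.4, 1.0, 2.5):
                got = bs.bm_loglik(tree, y, sigma2)
                want = dense_bm_loglik(C, y.reindex(arr.labels).to_numpy(), sigma2)
                assert got == pytest.approx(want, abs=1e-10)

    def test_cherry_identical_traits_max_contrast(self):
        tree = parse_newick("(A:1,B:1);")
        same = bs.bm_loglik(tree, pd.Series({"A": 1.3, "B": 1.3}), 1.0)
        diff = bs.bm_loglik(tree, pd.Series({"A": 1.3, "B": 2.3}), 1.0)
        assert same > diff

    def test_scale_invariance_identity(self, eight_tip_tree):
        y = _bm_data(eight_tip_tree, 3)
        arr = to_arrays(eight_tip_tree)
        c = 3.7
        scaled = TreeArrays(parent=arr.parent.copy(), blen=arr.blen * c,
                            age=arr.age * c, children=[list(x) for x in arr.children],
                            postorder=arr.postorder.copy(), labels=list(arr.labels))
        assert bs.bm_loglik(eight_tip_tree, y, 1.0) == pytest.approx(
            bs.bm_loglik(scaled, y, 1.0 / c), abs=1e-10)

    def test_missing_values_rejected(self, eight_tip_tree):
        arr = to_arrays(eight_tip_tree)
        y = pd.Series(np.nan, index=arr.labels)
        y.iloc[0] = 1.0
        with pytest.raises(ValueError, match="missing"):
            bs.bm_loglik(eight_tip_tree, y, 1.0)


class TestLevyGivenJumps:
    def test_zero_counts_reduce_to_bm(self):
        for seed in range(20):
            tree = random_bd_tree(100 + seed, lam=0.3, mu=0.05, crown_age=8.0)
            arr = to_arrays(tree)
            y = _bm_data(tree, seed)
            c = np.zeros(arr.n_nodes, dtype=int)
            assert bs.levy_loglik_given_jumps(tree, y, 0.8, 5.0, c) == \
                pytest.approx(bs.bm_loglik(tree, y, 0.8), abs=1e-12)

    def test_terminal_jump_equals_stretched_tree(self, eight_tip_tree):
        arr = to_arrays(eight_tip_tree)
        y = _bm_data(eight_tip_tree, 5)
        alpha = 4.2
        c = np.zeros(arr.n_nodes, dtype=int)
        c[0] = 1  # terminal branch of first tip
        stretched = TreeArrays(parent=arr.parent.copy(), blen=arr.blen.copy(),
                               age=arr.age.copy(),
                               children=[list(x) for x in arr.children],
                               postorder=arr.postorder.copy(),
                               labels=list(arr.labels))
        stretched.blen[0] += alpha
        assert bs.levy_loglik_given_jumps(eight_tip_tree, y, 1.1, alpha, c) == \
            pytest.approx(bs.bm_loglik(stretched, y, 1.1), abs=1e-10)

    def test_arbitrary_counts_match_dense_oracle(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            tree = random_bd_tree(200 + seed, lam=0.3, mu=0.05, crown_age=8.0)
            arr = to_arrays(tree)
            y = _bm_data(tree, seed)
            counts = rng.poisson(0.3, arr.n_nodes)
            counts[arr.root] = 0
            alpha, sigma2 = 2.5, 0.9
            M = arr.clade_matrix().astype(float)
            C = (M.T * (arr.blen + counts * alpha)) @ M
            got = bs.levy_loglik_given_jumps(tree, y, sigma2, alpha, counts)
            want = dense_bm_loglik(C, y.reindex(arr.labels).to_numpy(), sigma2)
            assert got == pytest.approx(want, abs=1e-10)

    def test_negative_counts_rejected(self, eight_tip_tree):
        arr = to_arrays(eight_tip_tree)
        y = _bm_data(eight_tip_tree, 1)
        c = np.zeros(arr.n_nodes, dtype=int)
        c[1] = -1
        with pytest.raises(ValueError, match="non-negative"):
            bs.levy_loglik_given_jumps(eight_tip_tree, y, 1.0, 1.0, c)


class TestCallJumps:
    def test_strict_threshold_boundary(self):
        pp = pd.Series({"a": 0.9, "b": 0.85, "c": 0.2})
        post = bs.JumpPosterior(pp=pp, mean_counts=pp, sigma2_mean=1.0,
                                jump_rate_mean=0.0, sigma2_samples=np.array([]),
                                jump_rate_samples=np.array([]), alpha=1.0)
        assert bs.call_jumps(post, 0.85) == {"a"}

    def test_zero_threshold_returns_all_positive(self):
        pp = pd.Series({"a": 0.9, "b": 0.0, "c": 0.2})
        post = bs.JumpPosterior(pp=pp, mean_counts=pp, sigma2_mean=1.0,
                                jump_rate_mean=0.0, sigma2_samples=np.array([]),
                                jump_rate_samples=np.array([]), alpha=1.0)
        assert bs.call_jumps(post, 0.0) == {"a", "c"}

    def test_invalid_threshold_rejected(self):
        pp = pd.Series({"a": 0.9})
        post = bs.JumpPosterior(pp=pp, mean_counts=pp, sigma2_mean=1.0,
                                jump_rate_mean=0.0, sigma2_samples=np.array([]),
                                jump_rate_samples=np.array([]), alpha=1.0)
        with pytest.raises(ValueError):
            bs.call_jumps(post, 1.5)


def _plant_jump(tree, arr, rep, mult=100.0, sigma2=1.0):
    mean_len = arr.blen[arr.parent >= 0].mean()
    alpha = mult * mean_len
    candidates = [i for i in range(arr.n_nodes)
                  if arr.parent[i] >= 0 and arr.blen[i] > mean_len]
    rng = np.random.default_rng(rep)
    planted = candidates[rng.integers(len(candidates))]
    clade = arr.clade_matrix()[planted][: arr.n_tips]
    y, _ = simulate_levy_trait(tree, sigma2, 0.0, alpha, seed=4000 + rep)
    disp = math.sqrt(alpha * sigma2) * (1 if rng.random() < 0.5 else -1)
    return y + disp * clade, planted, alpha


class TestJumpSampler:
    def test_planted_jump_recovery(self):
        hits = max_ok = 0
        n_rep = 5
        for rep in range(n_rep):
            tree, arr, _ = tree_with_tips(40, 70, 100 + rep * 17)
            y, planted, alpha = _plant_jump(tree, arr, rep)
            jp = bs.sample_jump_vectors(tree, y, alpha=alpha, n_vectors=600,
                                        burnin=200, thin=2, seed=rep)
            hits += jp.pp.iloc[planted] > 0.85
            max_ok += jp.pp.idxmax() == jp.pp.index[planted]
        assert hits >= 4
        assert max_ok >= 4

    def test_no_false_calls_on_bm_data(self):
        clean = 0
        n_rep = 5
        for rep in range(n_rep):
            tree, arr, _ = tree_with_tips(40, 70, 900 + rep * 13)
            mean_len = arr.blen[arr.parent >= 0].mean()
            y = _bm_data(tree, 7000 + rep)
            jp = bs.sample_jump_vectors(tree, y, alpha=100 * mean_len,
                                        n_vectors=600, burnin=200, thin=2,
                                        seed=rep)
            clean += not (jp.pp > 0.85).any()
        assert clean >= 4

    def test_seed_determinism(self):
        tree, arr, _ = tree_with_tips(20, 40, 77)
        y = _bm_data(tree, 1)
        kw = dict(alpha=5.0, n_vectors=100, burnin=50, thin=1, seed=9)
        jp1 = bs.sample_jump_vectors(tree, y, **kw)
        jp2 = bs.sample_jump_vectors(tree, y, **kw)
        assert jp1.pp.equals(jp2.pp)

    def test_constant_trait_rejected(self, eight_tip_tree):
        arr = to_arrays(eight_tip_tree)
        y = pd.Series(2.0, index=arr.labels)
        with pytest.raises(ValueError, match="constant"):
            bs.sample_jump_vectors(eight_tip_tree, y, alpha=1.0, n_vectors=10,
                                   burnin=5, seed=0)


class TestAlphaSearchAndLRT:
    def test_grid_spacing_and_budget(self):
        tree, arr, _ = tree_with_tips(25, 45, 55)
        y, planted, alpha = _plant_jump(tree, arr, 3)
        res = bs.alpha_peak_search(tree, y, start=0.5, step=0.5, max_evals=14)
        lg = np.sort(res.profile["log10_alpha"].to_numpy())
        steps = np.diff(lg)
        assert np.allclose(steps, 0.5, atol=1e-9)
        assert res.n_evaluated <= 14

    def test_alpha_recovery_with_planted_jumps(self):
        close = 0
        n_rep = 5
        for rep in range(n_rep):
            tree, arr, _ = tree_with_tips(40, 70, 300 + rep * 31)
            mean_len = arr.blen[arr.parent >= 0].mean()
            alpha_true = 100 * mean_len
            rng = np.random.default_rng(rep)
            # three planted jumps so the jump rate is identifiable
            cands = [i for i in range(arr.n_nodes)
                     if arr.parent[i] >= 0 and arr.blen[i] > mean_len]
            chosen = rng.choice(cands, size=3, replace=False)
            y, _ = simulate_levy_trait(tree, 1.0, 0.0, alpha_true, seed=600 + rep)
            for b in chosen:
                clade = arr.clade_matrix()[b][: arr.n_tips]
                y = y + math.sqrt(alpha_true) * (1 if rng.random() < 0.5 else -1) * clade
            res = bs.alpha_peak_search(tree, y, max_evals=14)
            close += abs(math.log10(res.alpha_hat) - math.log10(alpha_true)) <= 0.75
        assert close >= 3

    def test_flat_profile_sets_warning(self):
        tree, arr, _ = tree_with_tips(25, 45, 66)
        y = _bm_data(tree, 2)
        res = bs.alpha_peak_search(tree, y, max_evals=10)
        # BM data: either flat (no jumps anywhere) or weakly multimodal
        assert res.warning or res.fit["counts"].sum() == 0

    def test_lrt_pinned_rate_gives_zero(self):
        tree, arr, _ = tree_with_tips(25, 45, 88)
        y = _bm_data(tree, 4)
        out = bs.lrt_jump_vs_bm(tree, y, alpha=5.0, max_count=0)
        assert out["D"] == 0.0

    def test_lrt_nonnegative_and_conservative_under_null(self):
        pvals, Ds = [], []
        for rep in range(12):
            tree, arr, _ = tree_with_tips(25, 45, 700 + rep * 3)
            y = _bm_data(tree, 40 + rep)
            out = bs.lrt_jump_vs_bm(tree, y, alpha=10.0)
            Ds.append(out["D"])
            pvals.append(out["p_value"])
        assert all(d >= 0 for d in Ds)
        # boundary case makes the chi2(2) p-value conservative
        assert np.mean(np.array(pvals) < 0.05) <= 0.25

    def test_lrt_power_with_planted_jumps(self):
        sig = 0
        for rep in range(5):
            tree, arr, _ = tree_with_tips(40, 70, 500 + rep * 11)
            mean_len = arr.blen[arr.parent >= 0].mean()
            alpha = 100 * mean_len
            rng = np.random.default_rng(rep)
            cands = [i for i in range(arr.n_nodes)
                     if arr.parent[i] >= 0 and arr.blen[i] > mean_len]
            chosen = rng.choice(cands, size=3, replace=False)
            y, _ = simulate_levy_trait(tree, 1.0, 0.0, alpha, seed=4000 + rep)
            for b in chosen:
                clade = arr.clade_matrix()[b][: arr.n_tips]
                y = y + math.sqrt(alpha) * (1 if rng.random() < 0.5 else -1) * clade
            out = bs.lrt_jump_vs_bm(tree, y, alpha=alpha)
            sig += out["p_value"] < 0.001
        assert sig >= 4


class TestImputeTipsBM:
    def test_matches_conditional_normal_oracle(self):
        tree = random_bd_tree(9, lam=0.3, mu=0.0, crown_age=8.0)
        arr = to_arrays(tree)
        y = _bm_data(tree, 11)
        miss = arr.labels[2]
        part = y.copy()
        part[miss] = np.nan
        filled, se = bs.impute_tips_bm(tree, part)
        # oracle: conditional mean with the same (observed-data) estimates
        C = bs.vcv_matrix(arr)
        obs = np.array([l != miss for l in arr.labels])
        yv = y.reindex(arr.labels).to_numpy()
        Coo = C[np.ix_(obs, obs)]
        Loo = np.linalg.inv(Coo)
        one = np.ones(obs.sum())
        mu = float(one @ Loo @ yv[obs]) / float(one @ Loo @ one)
        want = conditional_normal_mean(C, yv, obs, 1.0, mu)
        assert filled[miss] == pytest.approx(float(want[0]), abs=1e-8)
        assert se[miss] > 0

    def test_short_sister_branch_limit(self):
        tree = parse_newick("((A:0.000001,B:0.000001):1.999999,(C:1,D:1):1);")
        part = pd.Series({"A": np.nan, "B": 3.0, "C": 0.0, "D": 0.5})
        filled, se = bs.impute_tips_bm(tree, part)
        assert filled["A"] == pytest.approx(3.0, abs=1e-3)

    def test_no_missing_returns_unchanged(self, eight_tip_tree):
        y = _bm_data(eight_tip_tree, 12)
        filled, se = bs.impute_tips_bm(eight_tip_tree, y)
        assert filled.reindex(y.index).equals(y.astype(float))
        assert (se == 0).all()

    def test_all_missing_rejected(self, eight_tip_tree):
        arr = to_arrays(eight_tip_tree)
        with pytest.raises(ValueError, match="2 observed"):
            bs.impute_tips_bm(eight_tip_tree, pd.Series(np.nan, index=arr.labels))
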