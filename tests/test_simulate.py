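import math

import numpy as np
import pytest
from scipy import stats

from archorisk.simulate import (SimConfig, StatusGenConfig, TotalExtinctionError,
                                simulate_bd_tree, simulate_levy_trait,
                                simulate_posterior_set, simulate_ranges,
                                simulate_species_table)
from archorisk.trees import to_arrays, validate_ultrametric


class TestBirthDeathTrees:
    def test_yule_mean_tip_count_matches_closed_form(self):
        lam, T = 0.07, 30.0
        rng = np.random.default_rng(77)
        cfg = SimConfig(lambda0=lam, mu0=0.0, crown_age=T)
        tips = [simulate_bd_tree(cfg, rng=rng)[1]["n_tips"] for _ in range(1000)]
        expect = 2.0 * math.exp(lam * T)
        se = np.std(tips, ddof=1) / math.sqrt(len(tips))
        assert abs(np.mean(tips) - expect) < 3 * se

    def test_survival_one_me_is_noop_in_distribution(self):
        # crossing a survival-1 event only restarts the exponential waits
        # (memoryless), so the tip-count distribution is unchanged
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        base = SimConfig(lambda0=0.1, mu0=0.02, crown_age=40.0)
        withme = SimConfig(lambda0=0.1, mu0=0.02, crown_age=40.0,
                           mass_extinctions=[(20.0, 1.0)])
        n1 = [simulate_bd_tree(base, rng=rng1)[1]["n_tips"] for _ in range(400)]
        n2 = [simulate_bd_tree(withme, rng=rng2)[1]["n_tips"] for _ in range(400)]
        assert stats.mannwhitneyu(n1, n2).pvalue > 0.01

    def test_me_survival_kills_expected_fraction(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig(lambda0=0.12, mu0=0.0, crown_age=60.0,
                        mass_extinctions=[(25.0, 0.05)])
        alive = killed = 0
        for _ in range(60):
            _, log = simulate_bd_tree(cfg, rng=rng)
            me = log["mass_extinctions"][0]
            alive += me["n_alive"]
            killed += me["n_killed"]
        res = stats.binomtest(killed, alive, 0.95)
        assert res.pvalue > 0.001
        assert killed / alive == pytest.approx(0.95, abs=0.03)

    def test_total_extinction_error_names_cap(self):
        cfg = SimConfig(lambda0=0.011, mu0=0.01, crown_age=500.0,
                        mass_extinctions=[(1.0, 0.001), (2.0, 0.001)],
                        max_retries=5)
        with pytest.raises(TotalExtinctionError, match="5 attempts"):
            simulate_bd_tree(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="lambda0 > mu0"):
            SimConfig(lambda0=0.02, mu0=0.05).validate()
        with pytest.raises(ValueError, match="survival"):
            SimConfig(mass_extinctions=[(10.0, 1.5)]).validate()
        with pytest.raises(ValueError, match="time"):
            SimConfig(mass_extinctions=[(200.0, 0.5)]).validate()

    def test_bit_reproducible(self):
        cfg = SimConfig(lambda0=0.1, mu0=0.03, crown_age=40.0, seed=11)
        a1 = to_arrays(simulate_bd_tree(cfg)[0])
        a2 = to_arrays(simulate_bd_tree(cfg)[0])
        assert a1.labels == a2.labels
        np.testing.assert_array_equal(a1.blen, a2.blen)


class TestPosteriorSet:
    def test_zero_jitter_identity(self, eight_tip_tree):
        out = simulate_posterior_set(eight_tip_tree, 1, 0.0, seed=1)
        a, b = to_arrays(out[0]), to_arrays(eight_tip_tree)
        da = dict(zip(a.labels, a.blen[: a.n_tips]))
        db = dict(zip(b.labels, b.blen[: b.n_tips]))
        assert da == pytest.approx(db)
        assert a.total_length() == pytest.approx(b.total_length())
        assert a.root_age == pytest.approx(b.root_age)

    def test_all_jittered_trees_ultrametric(self, eight_tip_tree):
        out = simulate_posterior_set(eight_tip_tree, 100, 0.05, seed=2)
        assert all(validate_ultrametric(t, tol=1e-8).ok for t in out)

    def test_median_age_close_to_input(self, eight_tip_tree):
        base = to_arrays(eight_tip_tree)
        out = simulate_posterior_set(eight_tip_tree, 4000, 0.05, seed=3)
        root_ages = [to_arrays(t).root_age for t in out]
        assert np.median(root_ages) == pytest.approx(base.root_age, rel=0.01)


class TestLevyTrait:
    def test_bm_tip_covariance(self, three_tip_tree):
        # cherry (A,B) with t=1 shared: Var(A-B) = 2 sigma2 * 1
        sigma2 = 0.7
        diffs = []
        for seed in range(2000):
            y, _ = simulate_levy_trait(three_tip_tree, sigma2, 0.0, 1.0, seed=seed)
            diffs.append(y["A"] - y["B"])
        assert np.var(diffs, ddof=1) == pytest.approx(2 * sigma2, rel=0.15)

    def test_forced_jump_detectable_offset(self, eight_tip_tree):
        arr = to_arrays(eight_tip_tree)
        sigma2 = 1.0
        # force one jump with alpha=100 on an internal branch
        internal = [i for i in range(arr.n_nodes)
                    if arr.parent[i] >= 0 and arr.children[i]]
        branch = internal[0]
        clade = arr.clade_matrix()[branch][: arr.n_tips]
        hits = 0
        for seed in range(40):
            y, c = simulate_levy_trait(eight_tip_tree, sigma2, 0.0, 100.0,
                                       seed=seed, forced_jumps={branch: 1})
            assert c[branch] == 1
            y0, _ = simulate_levy_trait(eight_tip_tree, sigma2, 0.0, 100.0,
                                        seed=seed)
            offset = (y[clade].mean() - y[~clade].mean()) - \
                     (y0[clade].mean() - y0[~clade].mean())
            hits += abs(offset) > 3 * math.sqrt(sigma2 * arr.blen[branch])
        assert hits >= 20  # |N(0,100)| > 3*sqrt(len) in most draws

    def test_non_ultrametric_rejected(self):
        from archorisk.trees import parse_newick
        bad = parse_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            simulate_levy_trait(bad, 1.0, 0.0, 1.0, seed=1)

    def test_seed_reproducible(self, eight_tip_tree):
        y1, c1 = simulate_levy_trait(eight_tip_tree, 1.0, 0.05, 10.0, seed=4)
        y2, c2 = simulate_levy_trait(eight_tip_tree, 1.0, 0.05, 10.0, seed=4)
        assert (y1 == y2).all() and (c1 == c2).all()


class TestRanges:
    def test_blob_contiguity_4neighbour(self):
        occ, cent, areas = simulate_ranges(30, grid_dims=(20, 30), mean_cells=25,
                                           seed=8)
        for s in range(30):
            cells = set(map(tuple, np.argwhere(occ[s])))
            start = next(iter(cells))
            seen = {start}
            stack = [start]
            while stack:
                r, c = stack.pop()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nb = (r + dr, c + dc)
                    if nb in cells and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            assert seen == cells

    def test_single_cell_species(self):
        occ, cent, areas = simulate_ranges(200, grid_dims=(10, 10), mean_cells=1.0,
                                           cell_area=7.5, seed=1)
        one_cell = areas == 7.5
        assert one_cell.any()
        s = int(np.flatnonzero(one_cell)[0])
        r, c = map(int, np.argwhere(occ[s])[0])
        assert cent[s][0] == pytest.approx(c + 0.5)
        assert cent[s][1] == pytest.approx(r + 0.5)

    def test_mean_cells_larger_than_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_ranges(5, grid_dims=(3, 3), mean_cells=100, seed=1)


def _table_setup(cfg, seed=21):
    from conftest import tree_with_tips

    tree, arr, _ = tree_with_tips(150, 260, 404, lam=0.09, crown_age=60.0)
    occ, cent, areas = simulate_ranges(arr.n_tips, grid_dims=(30, 50),
                                       mean_cells=30, seed=seed)
    tab = simulate_species_table(tree, cent, areas, cfg, seed=seed)
    return tree, arr, tab


class TestStatusGenerator:
    def test_uniform_categories_without_effects(self):
        sd = 0.5
        th = tuple(sd * stats.norm.ppf(np.arange(1, 6) / 6.0))
        cfg = StatusGenConfig(beta_area=0.0, beta_other=(), phylo_signal_sd=0.0,
                              spatial_signal_sd=0.0, noise_sd=sd,
                              thresholds=th, mask_fraction=0.0)
        _, arr, tab = _table_setup(cfg)
        counts = tab["true_status"].value_counts().reindex(
            ["LC", "NT", "VU", "EN", "CR", "EX"]).fillna(0).to_numpy()
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_area_effect_gives_negative_spearman(self):
        cfg = StatusGenConfig(mask_fraction=0.0)
        _, arr, tab = _table_setup(cfg)
        code = tab["true_status"].map(
            {"LC": 1, "NT": 2, "VU": 3, "EN": 4, "CR": 5, "EX": 6})
        rho, _ = stats.spearmanr(np.log(tab["range_area"]), code)
        assert rho < -0.5

    def test_mask_fraction_exact_count(self):
        cfg = StatusGenConfig(mask_fraction=0.3)
        _, arr, tab = _table_setup(cfg)
        n = len(tab)
        assert tab["status"].isin(("DD", "UA")).sum() == round(0.3 * n)

    def test_phylo_signal_sister_similarity(self):
        cfg = StatusGenConfig(beta_area=0.0, beta_other=(), phylo_signal_sd=1.5,
                              spatial_signal_sd=0.0, noise_sd=0.3,
                              mask_fraction=0.0)
        tree, arr, tab = _table_setup(cfg)
        code = tab["true_status"].map(
            {"LC": 1, "NT": 2, "VU": 3, "EN": 4, "CR": 5, "EX": 6})
        code = code.reindex(arr.labels).to_numpy()
        sisters = []
        for i in range(arr.n_nodes):
            ch = arr.children[i]
            if len(ch) == 2 and all(c < arr.n_tips for c in ch):
                sisters.append(abs(code[ch[0]] - code[ch[1]]))
        obs = np.mean(sisters)
        rng = np.random.default_rng(0)
        perm = []
        for _ in range(999):
            pc = rng.permutation(code)
            perm.append(np.mean([abs(pc[2 * k] - pc[2 * k + 1])
                                 for k in range(len(sisters))]))
        p = (1 + sum(1 for v in perm if v <= obs)) / 1000.0
        assert p < 0.05

    def test_small_area_biased_masking(self):
        cfg = StatusGenConfig(mask_fraction=0.3, mask_small_area_bias=2.0)
        _, arr, tab = _table_setup(cfg)
        masked = tab["status"].isin(("DD", "UA"))
        assert (tab.loc[masked, "range_area"].median()
                < tab.loc[~masked, "range_area"].median())

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            StatusGenConfig(thresholds=(0, 1, 1, 2, 3)).validate()
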