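"""Canonical recovery experiments on synthetic data with known truth.

These define the study conditions used by the validation suite and the
reproduction script: the simulation settings are fixed here, in one place.

* Mass-extinction recovery: pure-birth background (lambda = 0.085/Myr,
  crown age 100 Myr) with one mass extinction at 25 Ma and survival 0.05,
  tree size conditioned to 200-450 tips.  With background extinction the
  event is likelihood-confounded with constant turnover, so the pure-birth
  background isolates the instantaneous-kill signature.
* Planted-jump recovery: ~50-tip pure-birth trees; one jump of variance
  100 * sigma2 * (mean branch length) — about six local-contrast standard
  deviations, i.e. unambiguously saltational — planted on a random branch
  longer than the mean, displacement of fixed magnitude and random sign.
* Imputation recovery: the default species-table generator (dominant
  negative log-area effect) at n ~ 400 with 30% of statuses masked.
"""

from __future__ import annotations

import math

import numpy as np

from . import bodysize, diversification as dv, threat_models as tm
from .simulate import (SimConfig, StatusGenConfig, simulate_bd_tree,
                       simulate_levy_trait, simulate_ranges,
                       simulate_species_table)
from .trees import TreeArrays, to_arrays

__all__ = ["sized_bd_tree", "me_recovery_replicate", "constant_rate_replicate",
           "planted_jump_replicate", "null_jump_replicate",
           "imputation_recovery"]


def sized_bd_tree(lo: int, hi: int, seed: int, **cfg_kwargs):
    """First tree (re-seeded rejection) whose tip count lands in [lo, hi]."""
    s = int(seed)
    while True:
        tree, log = simulate_bd_tree(SimConfig(seed=s, **cfg_kwargs))
        arr = to_arrays(tree)
        if lo <= arr.n_tips <= hi:
            return tree, arr, log
        s = (s + 1009) % (2 ** 31)


def me_recovery_replicate(seed: int, n_gen: int = 40_000) -> dict:
    """One planted-mass-extinction detection run; returns the model-level BF.

    40k generations (10k of them tempered burn-in) are needed for the chain
    to reliably cross from the constant-turnover mode into the
    mass-extinction mode; shorter chains under-estimate the posterior
    probability of the planted event.
    """
    tree, arr, log = sized_bd_tree(250, 400, seed, lambda0=0.085, mu0=0.0,
                                   crown_age=100.0,
                                   mass_extinctions=[(25.0, 0.05)])
    fit = dv.fit_constant_bd(tree, seed=seed, n_mcmc=1200)
    post = dv.comet_mcmc(tree, fit.hyperpriors,
                         dv.CometConfig(n_gen=n_gen, seed=seed))
    bf = dv.me_presence_bayes_factor(post)
    me_times = [t for ev in post.events for t, _ in ev["me"]]
    return {"n_tips": arr.n_tips, "two_ln_bf": bf["two_ln_bf"],
            "posterior_p": bf["posterior_p"],
            "me_time_median": float(np.median(me_times)) if me_times else None,
            "converged": post.converged}


def constant_rate_replicate(seed: int, n_gen: int = 8000) -> dict:
    """One no-event run: the posterior mode of the ME count should be 0."""
    tree, arr, _ = sized_bd_tree(150, 400, seed, lambda0=0.07, mu0=0.02,
                                 crown_age=80.0)
    fit = dv.fit_constant_bd(tree, seed=seed, n_mcmc=1000)
    post = dv.comet_mcmc(tree, fit.hyperpriors,
                         dv.CometConfig(n_gen=n_gen, seed=seed))
    return {"n_tips": arr.n_tips,
            "k_me_mode": int(post.samples["k_me"].mode()[0]),
            "p_me_ge1": float((post.samples["k_me"] >= 1).mean()),
            "lambda_hat": fit.lambda_hat, "mu_hat": fit.mu_hat}


def _jump_tree(seed: int):
    return sized_bd_tree(40, 70, seed, lambda0=0.13, mu0=0.0, crown_age=25.0)


def planted_jump_replicate(seed: int, n_vectors: int = 600,
                           burnin: int = 200) -> dict:
    """Plant one large jump and ask the sampler to call it at PP > 0.85."""
    tree, arr, _ = _jump_tree(seed)
    mean_len = float(arr.blen[arr.parent >= 0].mean())
    alpha = 100.0 * mean_len
    rng = np.random.default_rng(seed)
    cands = [i for i in range(arr.n_nodes)
             if arr.parent[i] >= 0 and arr.blen[i] > mean_len]
    planted = int(cands[rng.integers(len(cands))])
    clade = arr.clade_matrix()[planted][: arr.n_tips]
    y, _ = simulate_levy_trait(tree, 1.0, 0.0, alpha, seed=seed + 2 ** 20)
    disp = math.sqrt(alpha) * (1.0 if rng.random() < 0.5 else -1.0)
    y = y + disp * clade
    jp = bodysize.sample_jump_vectors(tree, y, alpha=alpha,
                                      n_vectors=n_vectors, burnin=burnin,
                                      thin=2, seed=seed)
    pp = float(jp.pp.iloc[planted])
    return {"n_tips": arr.n_tips, "pp_planted": pp,
            "called": pp > 0.85,
            "planted_is_argmax": jp.pp.idxmax() == jp.pp.index[planted]}


def null_jump_replicate(seed: int, n_vectors: int = 600,
                        burnin: int = 200) -> dict:
    """Pure-BM data: any branch above PP 0.85 is a false call."""
    tree, arr, _ = _jump_tree(seed)
    mean_len = float(arr.blen[arr.parent >= 0].mean())
    y, _ = simulate_levy_trait(tree, 1.0, 0.0, 100.0 * mean_len,
                               seed=seed + 2 ** 21)
    jp = bodysize.sample_jump_vectors(tree, y, alpha=100.0 * mean_len,
                                      n_vectors=n_vectors, burnin=burnin,
                                      thin=2, seed=seed)
    return {"n_tips": arr.n_tips, "max_pp": float(jp.pp.max()),
            "false_call": bool((jp.pp > 0.85).any())}


def imputation_recovery(seed: int, n_species: int = 400,
                        mask_fraction: float = 0.3) -> dict:
    """End-to-end threat-imputation recovery on default synthetic data."""
    tree, arr, _ = sized_bd_tree(int(0.95 * n_species), int(1.1 * n_species),
                                 seed, lambda0=0.08, mu0=0.02, crown_age=90.0)
    occ, cent, areas = simulate_ranges(arr.n_tips, grid_dims=(40, 80),
                                       mean_cells=40, seed=seed + 1)
    tab = simulate_species_table(tree, cent, areas,
                                 StatusGenConfig(mask_fraction=mask_fraction),
                                 seed=seed + 2)
    res = tm.impute_ensemble(tab, tree, seed=seed + 3)
    truth = tab.loc[res.pooled_codes.index, "true_status"].map(tm.STATUS_CODES)
    acc = float((res.pooled_codes == truth).mean())
    mae = float((res.pooled_codes - truth).abs().mean())
    area_first = {m: res.importances[m].idxmax() == "range_area"
                  for m in ("pglm", "rf", "ann")}
    return {"n_masked": len(truth), "n_species": arr.n_tips,
            "accuracy": acc, "mae": mae, "area_first": area_first,
            "concordance": res.concordance, "result": res, "table": tab,
            "tree": tree}
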