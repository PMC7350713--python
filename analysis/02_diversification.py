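#!/usr/bin/env python
"""Episodic birth-death analysis of the simulated tree: constant-rate fit
with empirical hyperpriors, CoMET-style rjMCMC over rate shifts and mass
extinctions, rates-through-time summaries, and per-interval Bayes factors.

The data were simulated at constant rates, so the expected outcome is
support for zero events and rate medians near the simulation truth
(lambda 0.07, mu 0.03 per Myr).
"""

import json
from pathlib import Path

import numpy as np

from archorisk import diversification as dv
from archorisk import trees

SEED = 7_021
DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    tree = trees.read_trees(DATA / "tree.nwk")[0]
    arr = trees.to_arrays(tree)

    fit = dv.fit_constant_bd(tree, seed=SEED, n_mcmc=2000)
    print(f"constant-rate ML: lambda={fit.lambda_hat:.4f}, "
          f"mu={fit.mu_hat:.4f} per Myr "
          f"(turnover {fit.mu_hat / fit.lambda_hat:.2f})")

    post = dv.comet_mcmc(tree, fit.hyperpriors,
                         dv.CometConfig(n_gen=10_000, seed=SEED))
    me_bf = dv.me_presence_bayes_factor(post)
    print(f"P(>=1 mass extinction) = {me_bf['posterior_p']:.3f}, "
          f"2lnBF = {me_bf['two_ln_bf']:.2f} "
          f"(constant-rate data: no support expected)")
    print(f"diagnostics: ESS {post.diagnostics['ess']}, "
          f"converged={post.converged}")

    grid = np.linspace(0.0, arr.root_age, 25)
    rtt = dv.rates_through_time(post, grid[:-1])
    bf = dv.bayes_factors(post, grid)
    rtt.to_csv(OUT / "rates_through_time.tsv", sep="\t", index=False)
    bf.to_csv(OUT / "bayes_factors.tsv", sep="\t", index=False)
    (OUT / "diversification.json").write_text(json.dumps({
        "lambda_hat": fit.lambda_hat, "mu_hat": fit.mu_hat,
        "turnover": fit.mu_hat / fit.lambda_hat,
        "me_presence": me_bf, "converged": bool(post.converged),
        "k_me_mode": int(post.samples["k_me"].mode()[0]),
        "k_shift_mode": int(post.samples["k_shift"].mode()[0]),
    }, indent=2))
    print(f"wrote rates_through_time.tsv, bayes_factors.tsv, "
          f"diversification.json under {OUT}")


if __name__ == "__main__":
    main()
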