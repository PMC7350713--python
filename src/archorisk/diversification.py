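"""Episodic birth-death diversification with mass-extinction detection.

The reconstructed-process likelihood uses the standard survival/flow
formulation.  Writing ``u(t)`` for the probability that a lineage alive at
age ``t`` (Myr before present) leaves at least one sampled descendant, and
``D(t)`` for the per-lineage density flow, piecewise-constant rates give the
closed forms (r = lambda - mu)::

    du/dt   = u (r - lambda u),          u(0) = rho        (logistic)
    ln Phi  = 2 (ln u2 - ln u1) - r dt                     (branch flow)

An instantaneous mass extinction at age ``t`` with survival probability ``s``
multiplies ``u`` and ``D`` by ``s`` for every lineage crossing it.  The tree
likelihood conditions on the root (crown) age and on both crown lineages
surviving to the present.

Rate shifts and mass extinctions are inferred by a reversible-jump MCMC with
compound-Poisson priors on the event counts (CoMET-style), and summarized by
Bayes factors at the conventional 2lnBF thresholds of 6 and 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import TreeArrays, to_arrays, validate_ultrametric

__all__ = [
    "EpisodicBDModel",
    "CometConfig",
    "CometPosterior",
    "constant_bd_loglik",
    "episodic_bd_loglik",
    "fit_constant_bd",
    "comet_mcmc",
    "bayes_factors",
    "me_presence_bayes_factor",
    "rates_through_time",
]


@dataclass
class EpisodicBDModel:
    """Piecewise-constant birth-death model with mass-extinction events.

    ``boundaries`` are increasing ages strictly inside (0, root age);
    ``lambdas[i]``/``mus[i]`` apply on the i-th interval counted from the
    present, so ``lambdas[0]`` governs [0, boundaries[0]).  ``me_events`` is a
    list of (age, survival probability in (0, 1]).
    """

    lambdas: np.ndarray
    mus: np.ndarray
    boundaries: np.ndarray = field(default_factory=lambda: np.array([]))
    rho: float = 1.0
    me_events: list = field(default_factory=list)

    def __post_init__(self):
        self.lambdas = np.atleast_1d(np.asarray(self.lambdas, dtype=float))
        self.mus = np.atleast_1d(np.asarray(self.mus, dtype=float))
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if len(self.lambdas) != len(self.boundaries) + 1:
            raise ValueError("need one rate per interval: len(lambdas) == len(boundaries)+1")
        if len(self.mus) != len(self.lambdas):
            raise ValueError("lambdas and mus must have equal length")
        if np.any(self.lambdas < 0) or np.any(self.mus < 0):
            raise ValueError("rates must be non-negative")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must be in (0, 1]")
        for t, s in self.me_events:
            if not (0.0 < s <= 1.0):
                raise ValueError("mass-extinction survival must be in (0, 1]")
            if t <= 0:
                raise ValueError("mass-extinction age must be positive")


class _Propagator:
    """Evaluates u(t) and the cumulative log flow g(t) for an episodic model."""

    def __init__(self, model: EpisodicBDModel, root_age: float):
        me = sorted(model.me_events)  # ascending age
        cuts = sorted(set(model.boundaries.tolist())
                      | {t for t, _ in me if t < root_age + 1e-9})
        self.seg_lo = np.array([0.0] + cuts)                  # segment lower edges
        self.me_at = {t: s for t, s in me}
        # rates per segment: from the model's interval containing the segment
        mid = self.seg_lo + 1e-12
        idx = np.searchsorted(model.boundaries, mid, side="right")
        self.lam = model.lambdas[idx]
        self.mu = model.mus[idx]
        self.r = self.lam - self.mu
        # propagate u, g across segment lower edges
        K = len(self.seg_lo)
        self.u_lo = np.empty(K)
        self.g_lo = np.empty(K)
        u, g = model.rho, 0.0
        self.u_lo[0], self.g_lo[0] = u, g
        for k in range(1, K):
            dt = self.seg_lo[k] - self.seg_lo[k - 1]
            u2, dg = _flow(u, dt, self.lam[k - 1], self.r[k - 1])
            u, g = u2, g + dg
            # crossing the cut at seg_lo[k]: apply ME factor if one sits there
            s = self.me_at.get(self.seg_lo[k])
            if s is not None:
                u *= s
                g += math.log(s)
            self.u_lo[k], self.g_lo[k] = u, g
        self._model = model

    def seg_index(self, t):
        return np.clip(np.searchsorted(self.seg_lo, t, side="right") - 1,
                       0, len(self.seg_lo) - 1)

    def u_g(self, t):
        t = np.asarray(t, dtype=float)
        k = self.seg_index(t)
        dt = t - self.seg_lo[k]
        u2, dg = _flow(self.u_lo[k], dt, self.lam[k], self.r[k])
        return u2, self.g_lo[k] + dg

    def lam_at(self, t):
        return self.lam[self.seg_index(np.asarray(t, dtype=float))]


def _flow(u0, dt, lam, r):
    """Propagate survival u and log flow g over dt with constant rates."""
    u0 = np.asarray(u0, dtype=float)
    dt = np.asarray(dt, dtype=float)
    lam = np.asarray(lam, dtype=float)
    r = np.asarray(r, dtype=float)
    near0 = np.abs(r) < 1e-12
    with np.errstate(over="ignore"):
        erdt = np.exp(np.where(near0, 0.0, r) * dt)
        denom = np.where(near0, 1.0 + lam * u0 * dt,
                         1.0 + lam * u0 * (erdt - 1.0) / np.where(near0, 1.0, r))
    u2 = u0 * erdt / denom
    # ln Phi = 2(ln u2 - ln u0) - r dt
    dg = 2.0 * (np.log(u2) - np.log(u0)) - r * dt
    return u2, dg


def _checked_arrays(tree) -> TreeArrays:
    arr = tree if isinstance(tree, TreeArrays) else to_arrays(tree)
    if not arr.is_binary():
        raise ValueError("likelihood requires a fully binary tree (polytomy found)")
    rep = validate_ultrametric(arr)
    if not rep.ok:
        raise ValueError(
            f"likelihood requires an ultrametric tree (max tip-depth deviation "
            f"{rep.max_deviation:.3g} > tol {rep.tol:.3g})")
    return arr


def episodic_bd_loglik(tree, model: EpisodicBDModel) -> float:
    """Log-likelihood of a dated tree under the episodic birth-death model.

    Conditions on the crown age and on survival of both crown lineages.
    """
    arr = _checked_arrays(tree)
    return _loglik_arrays(arr, model)


def _loglik_arrays(arr: TreeArrays, model: EpisodicBDModel) -> float:
    n = arr.n_tips
    root = arr.root
    root_age = arr.age[root]
    prop = _Propagator(model, root_age)
    internal = np.array([i for i in range(arr.n_nodes)
                         if arr.children[i] and i != root], dtype=int)
    t_int = arr.age[internal]
    _, g_int = prop.u_g(t_int)
    u_root, g_root = prop.u_g(np.array([root_age]))
    lam_int = prop.lam_at(t_int)
    if np.any(lam_int <= 0):
        return -np.inf
    ll = (n * math.log(model.rho)
          + 2.0 * float(g_root[0])
          + float(np.sum(g_int + np.log(lam_int)))
          - 2.0 * math.log(float(u_root[0])))
    return ll


def constant_bd_loglik(tree, lam: float, mu: float, rho: float = 1.0) -> float:
    """Constant-rate birth-death log-likelihood (same conditioning)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    model = EpisodicBDModel(lambdas=[lam], mus=[mu], rho=rho)
    return episodic_bd_loglik(tree, model)


# ---------------------------------------------------------------------------
# constant-rate fit and empirical hyperpriors


@dataclass
class ConstantBDFit:
    lambda_hat: float
    mu_hat: float
    loglik: float
    samples: pd.DataFrame
    hyperpriors: dict      # {"lambda": (meanlog, sdlog), "mu": (meanlog, sdlog)}
    intervals: dict        # 95% credible intervals per rate


def fit_constant_bd(tree, rho: float = 1.0, n_mcmc: int = 4000, seed=None) -> ConstantBDFit:
    """ML rates plus a short MCMC giving empirical lognormal hyperpriors.

    The MCMC uses flat priors on (lambda, mu) over [0, inf) with reflecting
    random-walk proposals; the posterior of each rate is moment-matched to a
    lognormal which downstream analyses use as a hyperprior.
    """
    arr = _checked_arrays(tree)
    if arr.n_tips < 3:
        raise ValueError("constant-rate fit needs at least 3 tips")

    def nll(x):
        lam = math.exp(x[0])
        mu = math.exp(x[1])
        try:
            return -_loglik_arrays(arr, EpisodicBDModel(lambdas=[lam], mus=[mu], rho=rho))
        except (ValueError, FloatingPointError):
            return np.inf

    # crude initial guess from tip count
    r0 = max(math.log(arr.n_tips / 2.0) / max(arr.root_age, 1e-6), 1e-4)
    best = None
    for mu_frac in (0.01, 0.5):
        x0 = [math.log(r0 / max(1 - mu_frac, 1e-3)), math.log(max(r0 * mu_frac, 1e-6))]
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    lam_hat, mu_hat = math.exp(best.x[0]), math.exp(best.x[1])

    rng = np.random.default_rng(seed)
    lam, mu = lam_hat, max(mu_hat, 1e-6)
    ll = -nll([math.log(lam), math.log(mu)])
    step = np.array([0.15 * lam, max(0.3 * mu, 0.1 * lam)])
    draws = np.empty((n_mcmc, 2))
    for i in range(n_mcmc):
        for j in range(2):
            cand = np.array([lam, mu])
            cand[j] = abs(cand[j] + step[j] * rng.standard_normal())  # reflect at 0
            if cand[0] <= 0:
                continue
            try:
                cand_ll = _loglik_arrays(
                    arr, EpisodicBDModel(lambdas=[cand[0]], mus=[cand[1]], rho=rho))
            except ValueError:
                continue
            if math.log(rng.random()) < cand_ll - ll:
                lam, mu, ll = cand[0], cand[1], cand_ll
        draws[i] = (lam, mu)
    keep = draws[n_mcmc // 4:]
    samples = pd.DataFrame(keep, columns=["lambda", "mu"])

    def ln_match(x):
        # moment-matched lognormal, but never narrower than half a log unit:
        # the hyperprior sets the scale of plausible rates, not their
        # precision — a tight hyperprior from the no-event fit would pin the
        # rates to the wrong mode once events enter the model
        m, s = float(np.mean(x)), float(np.std(x))
        m = max(m, 1e-10)
        sig2 = math.log1p((s / m) ** 2)
        return (math.log(m) - 0.5 * sig2, max(math.sqrt(sig2), 0.5))

    hyper = {"lambda": ln_match(keep[:, 0]), "mu": ln_match(keep[:, 1])}
    ci = {c: tuple(np.quantile(samples[c], [0.025, 0.975])) for c in samples}
    return ConstantBDFit(lambda_hat=lam_hat, mu_hat=mu_hat, loglik=-best.fun,
                         samples=samples, hyperpriors=hyper, intervals=ci)


# ---------------------------------------------------------------------------
# CoMET-style reversible-jump MCMC


@dataclass
class CometConfig:
    n_gen: int = 10_000
    burnin: float = 0.25          # fraction of n_gen discarded
    thin: int = 2
    max_shifts: int = 2
    max_me: int = 2
    me_prior_shape: float = 100.0     # Beta second shape parameter
    expected_me_survival: float = 0.05
    event_rate: float = 0.5           # Poisson prior mean per event type
    rho: float = 1.0
    seed: int | None = None
    likelihood_on: bool = True        # False: sample the prior (diagnostics)
    # proposal mix: birth/death/move/scale
    move_weights: tuple = (0.2, 0.2, 0.3, 0.3)
    # likelihood tempering during burn-in: beta ramps anneal_start -> 1 over
    # the discarded generations, letting the chain cross between the
    # "rate-shift/turnover" and "mass-extinction" explanations before
    # sampling begins.  Set to 1.0 to disable.
    anneal_start: float = 0.3
    # birth moves for mass-extinction times draw from a profile-likelihood
    # weighted grid (an independence proposal whose density enters the
    # Hastings ratio, so the target is unchanged); "uniform" disables it
    me_time_proposal: str = "data"
    me_proposal_grid: int = 60
    # mass-extinction births propose a paired drop of ln(mu0) (deaths the
    # mirrored raise); the normal proposal densities cancel in the Hastings
    # ratio, so only the mu0 prior ratio remains.  This lets the chain cross
    # between the "high turnover" and "instantaneous kill" explanations in
    # one move.  (mean, sd) of the log-rate shift; (0, 0) disables.
    me_mu_pairing: tuple = (1.5, 0.75)

    @property
    def me_beta(self):
        p = self.expected_me_survival
        b = self.me_prior_shape
        return (b * p / (1.0 - p), b)


@dataclass
class CometPosterior:
    samples: pd.DataFrame      # per kept generation: k_shift, k_me, lambda0, mu0, loglik
    events: list               # per kept generation: {"shifts": [...], "me": [...]}
    diagnostics: dict
    config: CometConfig
    root_age: float
    n_tips: int

    @property
    def converged(self) -> bool:
        return self.diagnostics.get("converged", False)


def _trunc_pois_pmf(k: int, nu: float, cap: int) -> float:
    ks = np.arange(cap + 1)
    w = np.exp(-nu) * nu ** ks / np.array([math.factorial(int(j)) for j in ks])
    return float(w[k] / w.sum())


def _build_model(state, cfg: CometConfig) -> EpisodicBDModel:
    shifts = sorted(state["shifts"], key=lambda e: e[0])  # ascending age
    boundaries = [e[0] for e in shifts]
    # base rates govern the oldest interval; each shift sets the rates on the
    # interval younger than its age (most-recent shift nearest the present)
    lams = [math.exp(e[1]) for e in shifts] + [math.exp(state["lnlam0"])]
    mus = [math.exp(e[2]) for e in shifts] + [math.exp(state["lnmu0"])]
    return EpisodicBDModel(lambdas=lams, mus=mus, boundaries=np.array(boundaries),
                           rho=cfg.rho, me_events=[tuple(e) for e in state["me"]])


def comet_mcmc(tree, priors: dict, config: CometConfig | None = None) -> CometPosterior:
    """Reversible-jump MCMC over rate-shift and mass-extinction events.

    ``priors`` holds lognormal hyperpriors for the rates as
    ``{"lambda": (meanlog, sdlog), "mu": (meanlog, sdlog)}`` (typically from
    :func:`fit_constant_bd`).  Event counts follow independent Poisson priors
    (mean ``event_rate``) truncated at the configured caps, event ages are
    uniform on (0, root age), and mass-extinction survival follows a Beta
    prior with mean ``expected_me_survival`` and second shape
    ``me_prior_shape``.  Runs are deterministic given ``config.seed``; an ESS
    below 200 or a large Geweke z flags the run as non-converged in
    ``diagnostics`` (never silently).
    """
    cfg = config or CometConfig()
    arr = _checked_arrays(tree)
    root_age = arr.root_age
    rng = np.random.default_rng(cfg.seed)
    lam_hyper = priors["lambda"]
    mu_hyper = priors["mu"]
    a_beta, b_beta = cfg.me_beta

    def log_prior(state):
        lp = stats.norm.logpdf(state["lnlam0"], *lam_hyper)
        lp += stats.norm.logpdf(state["lnmu0"], *mu_hyper)
        k_s, k_m = len(state["shifts"]), len(state["me"])
        lp += math.log(_trunc_pois_pmf(k_s, cfg.event_rate, cfg.max_shifts))
        lp += math.log(_trunc_pois_pmf(k_m, cfg.event_rate, cfg.max_me))
        for t, lnl, lnm in state["shifts"]:
            lp += -math.log(root_age)
            lp += stats.norm.logpdf(lnl, *lam_hyper) + stats.norm.logpdf(lnm, *mu_hyper)
        for t, s in state["me"]:
            lp += -math.log(root_age) + stats.beta.logpdf(s, a_beta, b_beta)
        return float(lp)

    def loglik(state):
        if not cfg.likelihood_on:
            return 0.0
        try:
            return _loglik_arrays(arr, _build_model(state, cfg))
        except (ValueError, FloatingPointError, OverflowError):
            return -np.inf

    state = {"lnlam0": lam_hyper[0], "lnmu0": mu_hyper[0], "shifts": [], "me": []}
    ll = loglik(state)

    # data-driven ME-time proposal: profile the gain of one ME event (at the
    # prior-mean survival and hyperprior-mean rates) on a time grid, and mix
    # the resulting weights half-and-half with the uniform density
    if cfg.me_time_proposal == "data" and cfg.likelihood_on:
        G = cfg.me_proposal_grid
        edges = np.linspace(0.0, root_age, G + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        base = EpisodicBDModel(lambdas=[math.exp(lam_hyper[0])],
                               mus=[math.exp(mu_hyper[0])], rho=cfg.rho)
        ll_base = _loglik_arrays(arr, base)
        gains = np.empty(G)
        for k, t_mid in enumerate(mids):
            m = EpisodicBDModel(lambdas=[math.exp(lam_hyper[0])],
                                mus=[math.exp(mu_hyper[0])], rho=cfg.rho,
                                me_events=[(float(t_mid),
                                            cfg.expected_me_survival)])
            gains[k] = _loglik_arrays(arr, m) - ll_base
        w_grid = np.exp(np.clip(gains - gains.max(), -30.0, 0.0))
        w_grid /= w_grid.sum()
        cell = root_age / G

        def draw_me_time():
            if rng.random() < 0.5:
                return rng.uniform(0.0, root_age)
            k = rng.choice(G, p=w_grid)
            return float(edges[k] + cell * rng.random())

        def log_q_me_time(t):
            k = min(int(t / cell), G - 1)
            return math.log(0.5 / root_age + 0.5 * w_grid[k] / cell)
    else:
        def draw_me_time():
            return rng.uniform(0.0, root_age)

        def log_q_me_time(t):
            return -math.log(root_age)

    log_p_time = -math.log(root_age)  # uniform prior density on event ages
    w = np.asarray(cfg.move_weights, dtype=float)
    w = w / w.sum()
    burn = int(cfg.burnin * cfg.n_gen)
    kept_rows, kept_events = [], []
    ll_trace = np.empty(cfg.n_gen)
    n_accept = 0

    for gen in range(cfg.n_gen):
        if cfg.likelihood_on and burn > 0 and gen < burn:
            beta = cfg.anneal_start + (1.0 - cfg.anneal_start) * gen / burn
        else:
            beta = 1.0
        kind = rng.choice(4, p=w)
        accepted = False
        if kind == 0:   # birth
            is_me = rng.random() < 0.5
            key, cap = ("me", cfg.max_me) if is_me else ("shifts", cfg.max_shifts)
            k = len(state[key])
            if k < cap:
                old_lnmu0 = state["lnmu0"]
                if is_me:
                    t_new = draw_me_time()
                    ev = (t_new, float(stats.beta.rvs(a_beta, b_beta, random_state=rng)))
                    hastings = log_p_time - log_q_me_time(t_new)
                    m_pair, s_pair = cfg.me_mu_pairing
                    if s_pair > 0:
                        state["lnmu0"] = old_lnmu0 - rng.normal(m_pair, s_pair)
                        hastings += stats.norm.logpdf(state["lnmu0"], *mu_hyper) \
                            - stats.norm.logpdf(old_lnmu0, *mu_hyper)
                else:
                    t_new = rng.uniform(0.0, root_age)
                    ev = (t_new, rng.normal(*lam_hyper), rng.normal(*mu_hyper))
                    hastings = 0.0
                state[key].append(ev)
                new_ll = loglik(state)
                # unordered event set: prior-draw birth has acceptance
                # nu/(k+1) against uniform-choice death
                log_acc = beta * (new_ll - ll) + math.log(cfg.event_rate) \
                    - math.log(k + 1) + hastings
                if math.log(rng.random() + 1e-300) < log_acc:
                    ll, accepted = new_ll, True
                else:
                    state[key].pop()
                    state["lnmu0"] = old_lnmu0
        elif kind == 1:  # death
            is_me = rng.random() < 0.5
            key = "me" if is_me else "shifts"
            k = len(state[key])
            if k > 0:
                j = int(rng.integers(k))
                ev = state[key].pop(j)
                old_lnmu0 = state["lnmu0"]
                hastings = 0.0
                if is_me:
                    hastings = log_q_me_time(ev[0]) - log_p_time
                    m_pair, s_pair = cfg.me_mu_pairing
                    if s_pair > 0:
                        state["lnmu0"] = old_lnmu0 + rng.normal(m_pair, s_pair)
                        hastings += stats.norm.logpdf(state["lnmu0"], *mu_hyper) \
                            - stats.norm.logpdf(old_lnmu0, *mu_hyper)
                new_ll = loglik(state)
                log_acc = beta * (new_ll - ll) - math.log(cfg.event_rate) \
                    + math.log(k) + hastings
                if math.log(rng.random() + 1e-300) < log_acc:
                    ll, accepted = new_ll, True
                else:
                    state[key].insert(j, ev)
                    state["lnmu0"] = old_lnmu0
        elif kind == 2:  # move an event time (fresh uniform draw; Hastings 1)
            evs = [("shifts", i) for i in range(len(state["shifts"]))] + \
                  [("me", i) for i in range(len(state["me"]))]
            if evs:
                key, j = evs[int(rng.integers(len(evs)))]
                old = state[key][j]
                if key == "me":
                    t_new = draw_me_time()
                    hastings = log_q_me_time(old[0]) - log_q_me_time(t_new)
                else:
                    t_new = rng.uniform(0.0, root_age)
                    hastings = 0.0
                state[key][j] = (t_new,) + tuple(old[1:])
                new_ll = loglik(state)
                if math.log(rng.random() + 1e-300) < beta * (new_ll - ll) + hastings:
                    ll, accepted = new_ll, True
                else:
                    state[key][j] = old
        else:            # scale a rate or survival parameter
            targets = [("base", 0), ("base", 1)]
            targets += [("shift", (i, c)) for i in range(len(state["shifts"]))
                        for c in (1, 2)]
            targets += [("mes", i) for i in range(len(state["me"]))]
            what, idx = targets[int(rng.integers(len(targets)))]
            if what == "base":
                keyname = "lnlam0" if idx == 0 else "lnmu0"
                old = state[keyname]
                hyper = lam_hyper if idx == 0 else mu_hyper
                state[keyname] = old + 0.2 * rng.standard_normal()
                new_ll = loglik(state)
                log_acc = beta * (new_ll - ll) + stats.norm.logpdf(state[keyname], *hyper) \
                    - stats.norm.logpdf(old, *hyper)
                if math.log(rng.random() + 1e-300) < log_acc:
                    ll, accepted = new_ll, True
                else:
                    state[keyname] = old
            elif what == "shift":
                i, c = idx
                old = state["shifts"][i]
                hyper = lam_hyper if c == 1 else mu_hyper
                new = list(old)
                new[c] = old[c] + 0.2 * rng.standard_normal()
                state["shifts"][i] = tuple(new)
                new_ll = loglik(state)
                log_acc = beta * (new_ll - ll) + stats.norm.logpdf(new[c], *hyper) \
                    - stats.norm.logpdf(old[c], *hyper)
                if math.log(rng.random() + 1e-300) < log_acc:
                    ll, accepted = new_ll, True
                else:
                    state["shifts"][i] = old
            else:
                i = idx
                t_old, s_old = state["me"][i]
                y = math.log(s_old / (1 - s_old)) + 0.5 * rng.standard_normal()
                s_new = 1.0 / (1.0 + math.exp(-y))
                state["me"][i] = (t_old, s_new)
                new_ll = loglik(state)
                log_acc = (beta * (new_ll - ll)
                           + stats.beta.logpdf(s_new, a_beta, b_beta)
                           - stats.beta.logpdf(s_old, a_beta, b_beta)
                           + math.log(s_new * (1 - s_new))
                           - math.log(s_old * (1 - s_old)))
                if math.log(rng.random() + 1e-300) < log_acc:
                    ll, accepted = new_ll, True
                else:
                    state["me"][i] = (t_old, s_old)
        n_accept += accepted
        ll_trace[gen] = ll
        if gen >= burn and (gen - burn) % cfg.thin == 0:
            kept_rows.append((len(state["shifts"]), len(state["me"]),
                              math.exp(state["lnlam0"]), math.exp(state["lnmu0"]), ll))
            kept_events.append({"shifts": list(state["shifts"]),
                                "me": list(state["me"])})

    samples = pd.DataFrame(kept_rows,
                           columns=["k_shift", "k_me", "lambda0", "mu0", "loglik"])
    diag = _diagnostics(samples, ll_trace[burn:])
    diag["acceptance_rate"] = n_accept / cfg.n_gen
    return CometPosterior(samples=samples, events=kept_events, diagnostics=diag,
                          config=cfg, root_age=root_age, n_tips=arr.n_tips)


def _ess(x: np.ndarray) -> float:
    """Autocorrelation-time effective sample size (initial positive sequence)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] < 0.05:
            break
        tau += 2.0 * acf[k]
    return float(n / max(tau, 1.0))


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: int(first * n)]
    b = x[int((1 - last) * n):]
    va = np.var(a) / max(_ess(a), 1.0)
    vb = np.var(b) / max(_ess(b), 1.0)
    denom = math.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def _diagnostics(samples: pd.DataFrame, ll_trace: np.ndarray) -> dict:
    ess = {c: _ess(samples[c].to_numpy()) for c in ("lambda0", "mu0", "loglik")}
    geweke = {c: _geweke_z(samples[c].to_numpy()) for c in ("lambda0", "mu0", "loglik")}
    converged = all(v > 200 for v in ess.values()) and \
        all(abs(z) < 3.0 for z in geweke.values())
    return {"ess": ess, "geweke_z": geweke, "converged": converged}


# ---------------------------------------------------------------------------
# Bayes factors and summaries


def _prior_p_any_event(nu: float, cap: int, frac: float) -> float:
    """Prior P(>=1 event lands in a window covering ``frac`` of (0, root age))."""
    p = 0.0
    for k in range(cap + 1):
        p += _trunc_pois_pmf(k, nu, cap) * (1.0 - (1.0 - frac) ** k)
    return p


def _odds(p: float) -> float:
    return p / (1.0 - p)


def me_presence_bayes_factor(posterior: CometPosterior) -> dict:
    """Model-level Bayes factor for >= 1 mass-extinction event anywhere."""
    cfg = posterior.config
    post_p = float((posterior.samples["k_me"] >= 1).mean())
    prior_p = 1.0 - _trunc_pois_pmf(0, cfg.event_rate, cfg.max_me)
    return _bf_entry(post_p, prior_p)


def _bf_entry(post_p: float, prior_p: float) -> dict:
    if prior_p <= 0.0 or prior_p >= 1.0:
        return {"posterior_p": post_p, "prior_p": prior_p, "bf": None,
                "two_ln_bf": None, "support": "undefined"}
    eps = 1e-12
    post_p_c = min(max(post_p, eps), 1.0 - eps)
    bf = _odds(post_p_c) / _odds(prior_p)
    two_ln = 2.0 * math.log(bf)
    if two_ln > 10:
        support = "strong"
    elif two_ln > 6:
        support = "mention"
    else:
        support = "none"
    return {"posterior_p": post_p, "prior_p": prior_p, "bf": bf,
            "two_ln_bf": two_ln, "support": support}


def bayes_factors(posterior: CometPosterior, time_grid) -> pd.DataFrame:
    """Per-interval 2lnBF for mass-extinction and rate-shift presence.

    ``time_grid`` is an increasing array of ages partitioning (part of)
    (0, root age).  For each interval the posterior probability that >= 1
    event of each type falls inside is compared with the prior probability
    under the truncated-Poisson/uniform prior; both BF and 2lnBF are
    reported with support labels at 2lnBF > 6 ("mention") and > 10
    ("strong").  Intervals with prior probability 0 report BF as undefined.
    """
    cfg = posterior.config
    grid = np.asarray(time_grid, dtype=float)
    rows = []
    n_samp = len(posterior.events)
    for lo, hi in zip(grid[:-1], grid[1:]):
        frac = max(min(hi, posterior.root_age) - max(lo, 0.0), 0.0) / posterior.root_age
        hit_me = sum(any(lo <= t < hi for t, *_ in ev["me"]) for ev in posterior.events)
        hit_sh = sum(any(lo <= t < hi for t, *_ in ev["shifts"]) for ev in posterior.events)
        me = _bf_entry(hit_me / n_samp, _prior_p_any_event(cfg.event_rate, cfg.max_me, frac))
        sh = _bf_entry(hit_sh / n_samp, _prior_p_any_event(cfg.event_rate, cfg.max_shifts, frac))
        rows.append({"t_lo": lo, "t_hi": hi,
                     "me_posterior_p": me["posterior_p"], "me_2lnbf": me["two_ln_bf"],
                     "me_support": me["support"],
                     "shift_posterior_p": sh["posterior_p"],
                     "shift_2lnbf": sh["two_ln_bf"], "shift_support": sh["support"]})
    return pd.DataFrame(rows)


def rates_through_time(posterior: CometPosterior, grid, level: float = 0.95) -> pd.DataFrame:
    """Posterior median and credible band for lambda(t), mu(t), r(t), turnover.

    Turnover mu/lambda is reported as a probability; r = lambda - mu.
    """
    if len(posterior.samples) == 0:
        raise ValueError("empty posterior")
    grid = np.asarray(grid, dtype=float)
    lam_draws = np.empty((len(posterior.events), len(grid)))
    mu_draws = np.empty_like(lam_draws)
    cfg = posterior.config
    for i, (ev, row) in enumerate(zip(posterior.events,
                                      posterior.samples.itertuples())):
        shifts = sorted(ev["shifts"], key=lambda e: e[0])
        model = EpisodicBDModel(
            lambdas=[math.exp(e[1]) for e in shifts] + [row.lambda0],
            mus=[math.exp(e[2]) for e in shifts] + [row.mu0],
            boundaries=np.array([e[0] for e in shifts]),
            rho=cfg.rho, me_events=[tuple(e) for e in ev["me"]])
        idx = np.searchsorted(model.boundaries, grid, side="right")
        lam_draws[i] = model.lambdas[idx]
        mu_draws[i] = model.mus[idx]
    q = [(1 - level) / 2, 0.5, 1 - (1 - level) / 2]
    lam_q = np.quantile(lam_draws, q, axis=0)
    mu_q = np.quantile(mu_draws, q, axis=0)
    r_q = np.quantile(lam_draws - mu_draws, q, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        to = np.where(lam_draws > 0, mu_draws / lam_draws, 0.0)
    to_q = np.quantile(to, q, axis=0)
    return pd.DataFrame({
        "time": grid,
        "lambda_lo": lam_q[0], "lambda_med": lam_q[1], "lambda_hi": lam_q[2],
        "mu_lo": mu_q[0], "mu_med": mu_q[1], "mu_hi": mu_q[2],
        "r_lo": r_q[0], "r_med": r_q[1], "r_hi": r_q[2],
        "turnover_lo": to_q[0], "turnover_med": to_q[1], "turnover_hi": to_q[2],
    })
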