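"""Independent reference implementations used only to check the package.

Each oracle is written from the underlying mathematics directly (numeric ODE
integration, dense matrix algebra, closed forms) and shares no code with the
implementation it validates.
"""

import math

import numpy as np
from scipy.integrate import solve_ivp


def yule_loglik(arr, lam):
    """Closed-form pure-birth log-likelihood conditioned on the crown age."""
    n = arr.n_tips
    return (n - 2) * math.log(lam) - lam * arr.total_length()


def ode_bd_loglik(arr, model):
    """Episodic birth-death log-likelihood via numeric integration.

    Integrates the extinction-probability and flow ODEs segmentwise
    (du/dt = u(r - lam*u), dg/dt = (lam-mu) - 2*lam*u) with mass-extinction
    jumps applied at their event ages.
    """
    me = sorted(model.me_events)
    bnd = list(np.asarray(model.boundaries))

    def rates(t):
        i = int(np.searchsorted(bnd, t, side="right"))
        return float(model.lambdas[i]), float(model.mus[i])

    def u_g_at(t_target):
        u, g = model.rho, 0.0
        if t_target <= 0:
            return u, g
        cuts = sorted({c for c in set(bnd) | {t for t, _ in me}
                       if 0.0 < c < t_target})
        pts = [0.0] + cuts + [t_target]
        for a, b in zip(pts[:-1], pts[1:]):
            lam, mu = rates((a + b) / 2)

            def f(_t, yv, lam=lam, mu=mu):
                return [yv[0] * ((lam - mu) - lam * yv[0]),
                        (lam - mu) - 2 * lam * yv[0]]

            sol = solve_ivp(f, (a, b), [u, g], rtol=1e-11, atol=1e-13)
            u, g = float(sol.y[0, -1]), float(sol.y[1, -1])
            for tt, s in me:
                if abs(tt - b) < 1e-12:
                    u *= s
                    g += math.log(s)
        return u, g

    root = arr.root
    root_age = float(arr.age[root])
    n = arr.n_tips
    ur, gr = u_g_at(root_age)
    ll = n * math.log(model.rho) + 2 * gr - 2 * math.log(ur)
    for i in range(arr.n_nodes):
        if arr.children[i] and i != root:
            t = float(arr.age[i])
            _, g = u_g_at(t)
            lam, _ = rates(t + 1e-12)
            ll += g + math.log(lam)
    return ll


def dense_bm_loglik(C, y, sigma2):
    """Dense MVN density at the GLS mean under covariance sigma2*C."""
    n = len(y)
    S = sigma2 * np.asarray(C)
    Sinv = np.linalg.inv(S)
    one = np.ones(n)
    mu = float(one @ Sinv @ y) / float(one @ Sinv @ one)
    r = y - mu
    return float(-0.5 * (n * math.log(2 * math.pi)
                         + np.linalg.slogdet(S)[1] + r @ Sinv @ r))


def welch_t(x, y):
    """Hand-computed Welch two-sample t statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    return float((x.mean() - y.mean()) / math.sqrt(vx + vy))


def conditional_normal_mean(C, y, obs_mask, sigma2, mu):
    """Conditional mean of the missing block of a MVN(mu*1, sigma2*C)."""
    obs = np.asarray(obs_mask, bool)
    Coo = C[np.ix_(obs, obs)]
    Cmo = C[np.ix_(~obs, obs)]
    return mu + Cmo @ np.linalg.solve(Coo, y[obs] - mu)
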