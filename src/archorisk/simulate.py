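"""Synthetic data with known ground truth for every pipeline stage.

Generators emulate the statistical structure the downstream analyses assume:
birth-death trees (optionally with rate shifts and instantaneous mass
extinctions), a node-age-jittered tree "posterior", Brownian-plus-jumps trait
evolution, gridded geographic ranges, and an ordinal threat status driven by a
dominant (negative) range-area effect plus phylogenetic and spatially
autocorrelated signal, with a fraction of statuses masked as DD/UA.

Time is measured in Myr before present; tips sit at age 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .trees import TreeArrays, to_arrays, from_arrays

__all__ = [
    "SimConfig",
    "StatusGenConfig",
    "TotalExtinctionError",
    "simulate_bd_tree",
    "simulate_posterior_set",
    "simulate_levy_trait",
    "simulate_ranges",
    "simulate_species_table",
]

#: categories used for masked (hidden) statuses
MASK_LABELS = ("DD", "UA")

STATUS_ORDER = ("LC", "NT", "VU", "EN", "CR", "EX")


class TotalExtinctionError(RuntimeError):
    """All replicate simulations went extinct before the retry cap."""


@dataclass
class SimConfig:
    """Birth-death simulation settings (rates per lineage per Myr)."""

    n_species: int = 200
    lambda0: float = 0.07   # turtle-like speciation rate
    mu0: float = 0.03       # turtle-like extinction rate
    crown_age: float = 100.0
    rate_shifts: list = field(default_factory=list)   # (time, new_lambda, new_mu)
    mass_extinctions: list = field(default_factory=list)  # (time, survival prob)
    seed: int | None = None
    max_retries: int = 1000

    def validate(self):
        if self.lambda0 <= self.mu0 or self.mu0 < 0:
            raise ValueError("require lambda0 > mu0 >= 0")
        for t, s in self.mass_extinctions:
            if not (0.0 < t < self.crown_age):
                raise ValueError("mass-extinction time outside (0, crown_age)")
            if not (0.0 < s <= 1.0):
                raise ValueError("mass-extinction survival must be in (0, 1]")
        for t, lam, mu in self.rate_shifts:
            if not (0.0 < t < self.crown_age):
                raise ValueError("rate-shift time outside (0, crown_age)")
            if lam < 0 or mu < 0:
                raise ValueError("rates must be non-negative")


@dataclass
class StatusGenConfig:
    """Latent-score model for ordinal threat status.

    latent = beta_area * z(log area) + X_minor @ beta_other + BM(tree) +
    spatial GP + iid noise; the five ``thresholds`` cut the latent score into
    the six ordered categories LC..EX.  ``mask_fraction`` of species have
    their status hidden (reported as DD/UA).
    """

    beta_area: float = -1.5
    beta_other: tuple = (0.4, -0.3, 0.3)
    phylo_signal_sd: float = 0.5
    spatial_signal_sd: float = 0.5
    noise_sd: float = 0.5
    thresholds: tuple = (-1.6, -0.6, 0.45, 1.5, 2.6)
    mask_fraction: float = 0.3
    mask_small_area_bias: float = 0.0  # >0 weights masking toward small ranges
    spatial_range: float | None = None  # kernel length scale; default: median distance

    def validate(self):
        th = np.asarray(self.thresholds, dtype=float)
        if th.size != 5 or np.any(np.diff(th) <= 0):
            raise ValueError("thresholds must be 5 strictly increasing cutpoints")
        if not (0.0 <= self.mask_fraction < 1.0):
            raise ValueError("mask_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# birth-death trees


def _piecewise_rates(cfg: SimConfig):
    """Return (change_times_desc, lambdas, mus) forward in time.

    Base rates apply from the crown; each shift (time before present) switches
    the rates from that moment toward the present.
    """
    shifts = sorted(cfg.rate_shifts, key=lambda x: -x[0])  # oldest first
    times = [cfg.crown_age] + [s[0] for s in shifts]
    lams = [cfg.lambda0] + [s[1] for s in shifts]
    mus = [cfg.mu0] + [s[2] for s in shifts]
    return times, lams, mus


def simulate_bd_tree(config: SimConfig, rng=None):
    """Simulate one dated tree under the episodic birth-death process.

    Runs the process forward from two crown lineages at ``crown_age``,
    applying rate shifts and mass extinctions at their configured times, and
    conditions (by rejection, up to ``max_retries``) on both crown lineages
    having extant descendants — which keeps the pruned tree's root age equal
    to the crown age.  Extinct lineages are pruned.

    Returns ``(tree, event_log)`` where ``event_log`` records realized shift
    times and, per mass extinction, how many lineages were alive and killed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for attempt in range(config.max_retries):
        result = _simulate_once(config, rng)
        if result is not None:
            tree, log = result
            log["attempts"] = attempt + 1
            return tree, log
    raise TotalExtinctionError(
        f"no surviving tree in {config.max_retries} attempts "
        f"(lambda0={config.lambda0}, mu0={config.mu0})")


def _simulate_once(config: SimConfig, rng):
    times, lams, mus = _piecewise_rates(config)
    me = sorted(config.mass_extinctions, key=lambda x: -x[0])  # oldest first
    # breakpoints forward in time (decreasing age)
    breaks = sorted({t for t, *_ in config.rate_shifts} | {t for t, _ in me},
                    reverse=True)
    # nodes: list of dicts; alive = list of node ids; record birth age per lineage
    parent = [-1, -1]  # two crown lineages; a virtual root joins them later
    birth_age = [config.crown_age, config.crown_age]
    death_age = [None, None]
    children: list = [[], []]
    crown_of = [0, 1]
    alive = [0, 1]
    event_log = {"shifts": [], "mass_extinctions": [], "n_extinct": 0}

    def rates_at(age):
        lam, mu = lams[0], mus[0]
        for t, l, m in zip(times, lams, mus):
            if age <= t:
                lam, mu = l, m
        return lam, mu

    t = config.crown_age  # current age, decreasing to 0
    seg_ends = breaks + [0.0]
    me_at = dict((tt, s) for tt, s in me)
    shift_at = {tt for tt, *_ in config.rate_shifts}
    for seg_end in seg_ends:
        lam, mu = rates_at(t - 1e-12)  # rates just after current boundary
        while alive and t > seg_end:
            total = len(alive) * (lam + mu)
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if t - wait <= seg_end:
                break
            t -= wait
            i = alive[rng.integers(len(alive))]
            if rng.random() < lam / (lam + mu):
                for _ in range(2):
                    parent.append(i)
                    birth_age.append(t)
                    death_age.append(None)
                    children.append([])
                    crown_of.append(crown_of[i])
                    children[i].append(len(parent) - 1)
                death_age[i] = t
                alive.remove(i)
                alive.extend([len(parent) - 2, len(parent) - 1])
            else:
                death_age[i] = t
                alive.remove(i)
                event_log["n_extinct"] += 1
        t = seg_end
        if not alive:
            return None
        if seg_end in me_at:
            s = me_at[seg_end]
            # survival 1 is an exact no-op: no RNG draws, stream unchanged
            survivors = alive if s >= 1.0 else [i for i in alive if rng.random() < s]
            killed = [i for i in alive if i not in survivors]
            for i in killed:
                death_age[i] = seg_end
            event_log["mass_extinctions"].append(
                {"time": seg_end, "survival": s,
                 "n_alive": len(alive), "n_killed": len(killed)})
            event_log["n_extinct"] += len(killed)
            alive = survivors
            if not alive:
                return None
        if seg_end in shift_at:
            event_log["shifts"].append({"time": seg_end})
    if not alive:
        return None
    if {crown_of[i] for i in alive} != {0, 1}:
        return None  # one whole crown lineage died: reject
    # build dendropy tree of survivors only
    tree = _build_pruned_tree(parent, birth_age, death_age, children, alive,
                              config.crown_age)
    event_log["n_tips"] = len(alive)
    return tree, event_log


def _build_pruned_tree(parent, birth_age, death_age, children, alive, crown_age):
    alive_set = set(alive)
    # survivor count below each lineage
    n_lin = len(parent)
    surv = [0] * n_lin

    def count_surv(i):
        stack, out = [i], []
        while stack:
            j = stack.pop()
            out.append(j)
            stack.extend(children[j])
        for j in reversed(out):
            surv[j] = (1 if j in alive_set else 0) + sum(surv[c] for c in children[j])
    count_surv(0)
    count_surv(1)

    tns = dendropy.TaxonNamespace()
    counter = [0]

    def build(i, top_age):
        """Return dendropy node for the pruned subtree of lineage i.

        ``top_age`` is the age at which lineage i began (its branch top).
        """
        j = i
        # follow the chain of single-surviving-child speciations
        while True:
            live_kids = [c for c in children[j] if surv[c] > 0]
            if j in alive_set and not children[j]:
                nd = dendropy.Node()
                counter[0] += 1
                nd.taxon = tns.require_taxon(label=f"t{counter[0]}")
                nd.edge.length = top_age - 0.0
                return nd
            if j in alive_set and children[j]:
                raise AssertionError("alive lineage with children")
            if len(live_kids) == 2:
                nd = dendropy.Node()
                split_age = birth_age[live_kids[0]]
                nd.edge.length = top_age - split_age
                for c in live_kids:
                    nd.add_child(build(c, split_age))
                return nd
            j = live_kids[0]

    root = dendropy.Node()
    for i in (0, 1):
        root.add_child(build(i, crown_age))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def simulate_posterior_set(tree: dendropy.Tree, n_trees: int,
                           age_jitter_cv: float, seed=None) -> list:
    """Emulate a dated-tree posterior by jittering node ages.

    Topology is fixed; each internal node age is perturbed multiplicatively by
    Normal(1, cv), resampled (never clamped) whenever the draw would invert the
    parent-older-than-child ordering.  Tips stay at age 0, so every output tree
    is ultrametric by construction.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    arr = to_arrays(tree)
    out = []
    pre = arr.postorder[::-1]
    for _ in range(n_trees):
        age = arr.age.copy()
        if age_jitter_cv > 0:
            from scipy.stats import truncnorm
            for i in pre:  # root first: parent age fixed before children
                if arr.children[i]:
                    hi = age[arr.parent[i]] if arr.parent[i] >= 0 else np.inf
                    lo = max((age[c] for c in arr.children[i]
                              if not arr.children[c]), default=0.0)
                    if hi <= lo:
                        raise RuntimeError(
                            f"no valid age window for node {i}: ({lo}, {hi})")
                    m = arr.age[i]
                    s = age_jitter_cv * m
                    # draw from the exact order-respecting conditional
                    # (equivalent to resampling inversions, never clamping)
                    age[i] = float(truncnorm.rvs((lo - m) / s,
                                                 (hi - m) / s if np.isfinite(hi) else np.inf,
                                                 loc=m, scale=s,
                                                 random_state=rng))
        jit = TreeArrays(parent=arr.parent.copy(), blen=arr.blen.copy(),
                         age=age, children=[list(c) for c in arr.children],
                         postorder=arr.postorder.copy(), labels=list(arr.labels))
        for i in range(jit.n_nodes):
            p = jit.parent[i]
            if p >= 0:
                jit.blen[i] = age[p] - age[i]
        out.append(from_arrays(jit))
    return out


def simulate_levy_trait(tree, sigma2: float, jump_rate: float, alpha: float,
                        root_state: float = 0.0, seed=None,
                        forced_jumps: dict | None = None):
    """Simulate one continuous trait under BM plus compound-Poisson jumps.

    Along each branch of length L the trait accrues Normal(0, sigma2*L) drift
    plus ``c`` jumps, c ~ Poisson(jump_rate*L), each jump Normal(0,
    alpha*sigma2).  ``forced_jumps`` maps node index (child end of the branch,
    in :func:`to_arrays` indexing) to a fixed jump count, overriding the
    Poisson draw on that branch.

    Returns ``(tip_values: pd.Series by label, jump_counts: np.ndarray per node)``.
    """
    if sigma2 <= 0 or jump_rate < 0 or alpha <= 0:
        raise ValueError("require sigma2>0, jump_rate>=0, alpha>0")
    arr = tree if isinstance(tree, TreeArrays) else to_arrays(tree)
    from .trees import validate_ultrametric
    if not validate_ultrametric(arr).ok:
        raise ValueError("levy trait simulation requires an ultrametric tree")
    rng = np.random.default_rng(seed)
    x = np.zeros(arr.n_nodes)
    counts = np.zeros(arr.n_nodes, dtype=int)
    for i in arr.postorder[::-1]:
        p = arr.parent[i]
        if p < 0:
            x[i] = root_state
            continue
        L = arr.blen[i]
        c = rng.poisson(jump_rate * L)
        if forced_jumps and i in forced_jumps:
            c = int(forced_jumps[i])
        counts[i] = c
        incr = rng.normal(0.0, np.sqrt(sigma2 * L)) if L > 0 else 0.0
        if c > 0:
            incr += rng.normal(0.0, np.sqrt(alpha * sigma2), size=c).sum()
        x[i] = x[p] + incr
    tips = pd.Series(x[: arr.n_tips], index=arr.labels, name="trait")
    return tips, counts


# ---------------------------------------------------------------------------
# geographic ranges


def simulate_ranges(n_species: int, grid_dims=(40, 80), mean_cells: float = 40.0,
                    cell_area: float = 1.0, seed=None, labels=None):
    """Simulate contiguous gridded ranges.

    Each species occupies one 4-connected blob grown by random accretion from
    a random seed cell; target blob size is lognormal with the given mean
    (clipped to the grid size).  Returns ``(occupancy, centroids, areas)``:
    a boolean (n_species, rows, cols) array, an (n_species, 2) array of
    occupied-cell centroids (x=col+0.5, y=row+0.5), and areas in cell-area
    units.
    """
    rows, cols = grid_dims
    if mean_cells > rows * cols:
        raise ValueError("mean_cells exceeds the number of grid cells")
    rng = np.random.default_rng(seed)
    occ = np.zeros((n_species, rows, cols), dtype=bool)
    centroids = np.zeros((n_species, 2))
    areas = np.zeros(n_species)
    # lognormal sizes with E[size]=mean_cells, sd of log = 1
    sig = 1.0
    mu_log = np.log(mean_cells) - 0.5 * sig ** 2
    for s in range(n_species):
        target = int(np.clip(np.round(np.exp(rng.normal(mu_log, sig))), 1, rows * cols))
        r0, c0 = rng.integers(rows), rng.integers(cols)
        cells = {(int(r0), int(c0))}
        frontier = [(int(r0), int(c0))]
        while len(cells) < target and frontier:
            idx = rng.integers(len(frontier))
            r, c = frontier[idx]
            nbrs = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                    if 0 <= r + dr < rows and 0 <= c + dc < cols
                    and (r + dr, c + dc) not in cells]
            if not nbrs:
                frontier.pop(idx)
                continue
            new = nbrs[rng.integers(len(nbrs))]
            cells.add(new)
            frontier.append(new)
        rr = np.array([c[0] for c in cells])
        cc = np.array([c[1] for c in cells])
        occ[s, rr, cc] = True
        centroids[s] = (cc.mean() + 0.5, rr.mean() + 0.5)
        areas[s] = len(cells) * cell_area
    return occ, centroids, areas


# ---------------------------------------------------------------------------
# species table with ordinal threat status


def _bm_latent(arr: TreeArrays, sd: float, rng) -> np.ndarray:
    """BM realization at the tips, scaled to marginal sd ``sd`` at the root-to-tip depth."""
    if sd == 0:
        return np.zeros(arr.n_tips)
    depth = arr.root_age if arr.root_age > 0 else 1.0
    x = np.zeros(arr.n_nodes)
    for i in arr.postorder[::-1]:
        p = arr.parent[i]
        if p >= 0:
            x[i] = x[p] + rng.normal(0.0, np.sqrt(arr.blen[i] / depth)) * sd
    return x[: arr.n_tips]


def _spatial_latent(centroids: np.ndarray, sd: float, length_scale, rng) -> np.ndarray:
    if sd == 0:
        return np.zeros(len(centroids))
    from scipy.spatial.distance import squareform, pdist
    d = squareform(pdist(centroids))
    if length_scale is None:
        off = d[np.triu_indices_from(d, k=1)]
        length_scale = np.median(off) if off.size else 1.0
    K = np.exp(-d / max(length_scale, 1e-9))
    K[np.diag_indices_from(K)] += 1e-8
    L = np.linalg.cholesky(K)
    return sd * (L @ rng.standard_normal(len(centroids)))


def simulate_species_table(tree, centroids, areas, cfg: StatusGenConfig,
                           seed=None) -> pd.DataFrame:
    """Generate per-species predictors and ordinal threat status.

    Predictors mirror the field's usual inventory: log body length and mass,
    microhabitat (3 levels), endemicity (2), ecoregion (12 levels),
    human-encroachment index, five climate components, AET, NPP, range area
    and centroid.  The latent threat score is dominated by a negative effect
    of log range area, with minor effects of HEI, AET and climate, a Brownian
    (phylogenetic) component, a spatially autocorrelated component, and iid
    noise; five thresholds cut it into the six ordered categories.

    A ``mask_fraction`` of species (exactly ``round(frac*n)``) have status
    hidden: the ``status`` column holds DD/UA while ``true_status`` keeps the
    generated category.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    arr = tree if isinstance(tree, TreeArrays) else to_arrays(tree)
    n = arr.n_tips
    centroids = np.asarray(centroids, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if len(areas) != n or len(centroids) != n:
        raise ValueError("areas/centroids must align with the tree's tips")

    log_area = np.log(areas)
    z_area = (log_area - log_area.mean()) / (log_area.std() or 1.0)

    body_length = np.exp(rng.normal(3.0, 0.8, n))           # cm
    body_mass = np.exp(1.1 * np.log(body_length) + rng.normal(2.0, 0.6, n))  # g
    hei = rng.beta(2, 5, n)                                  # human encroachment
    clim = rng.standard_normal((n, 5))
    aet = np.exp(rng.normal(6.5, 0.5, n))
    npp = np.exp(rng.normal(6.0, 0.5, n))
    microhabitat = rng.choice(["freshwater", "terrestrial", "marine"], n,
                              p=[0.6, 0.3, 0.1])
    endemicity = rng.choice(["mainland", "island"], n, p=[0.8, 0.2])
    ecoregion = rng.choice([f"eco{k:02d}" for k in range(1, 13)], n)

    minors = np.column_stack([
        (hei - hei.mean()) / (hei.std() or 1.0),
        (np.log(aet) - np.log(aet).mean()) / (np.log(aet).std() or 1.0),
        clim[:, 0],
    ])
    beta_other = np.asarray(cfg.beta_other, dtype=float)
    latent = (cfg.beta_area * z_area
              + minors[:, : len(beta_other)] @ beta_other
              + _bm_latent(arr, cfg.phylo_signal_sd, rng)
              + _spatial_latent(centroids, cfg.spatial_signal_sd,
                                cfg.spatial_range, rng)
              + rng.normal(0.0, cfg.noise_sd, n))
    codes = np.searchsorted(np.asarray(cfg.thresholds, dtype=float), latent) + 1
    true_status = np.array([STATUS_ORDER[c - 1] for c in codes])

    n_mask = int(round(cfg.mask_fraction * n))
    if n_mask > 0:
        if cfg.mask_small_area_bias > 0:
            w = np.exp(-cfg.mask_small_area_bias * z_area)
            w /= w.sum()
            masked = rng.choice(n, size=n_mask, replace=False, p=w)
        else:
            masked = rng.choice(n, size=n_mask, replace=False)
    else:
        masked = np.array([], dtype=int)
    status = true_status.astype(object).copy()
    status[masked] = rng.choice(MASK_LABELS, size=n_mask)

    df = pd.DataFrame({
        "species": arr.labels,
        "body_length_cm": body_length,
        "body_mass_g": body_mass,
        "microhabitat": microhabitat,
        "endemicity": endemicity,
        "ecoregion": ecoregion,
        "range_area": areas,
        "hei": hei,
        "clim1": clim[:, 0], "clim2": clim[:, 1], "clim3": clim[:, 2],
        "clim4": clim[:, 3], "clim5": clim[:, 4],
        "aet": aet,
        "npp": npp,
        "centroid_x": centroids[:, 0],
        "centroid_y": centroids[:, 1],
        "latent_score": latent,
        "true_status": true_status,
        "status": status,
    }).set_index("species")
    return df
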