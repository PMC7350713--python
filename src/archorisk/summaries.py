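"""Headline summaries: status breakdowns, ED-vs-threat tests, ED modes.

These are the final-table computations of the pipeline: category counts and
threatened fractions, the Welch t-test of ED between threatened and
non-threatened species, the boxplot notch-overlap check across categories,
and kernel-density mode finding for the ED distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geography import THREATENED, NONTHREATENED

__all__ = ["StatusSummary", "status_summary", "ed_threat_ttest",
           "notch_test", "ed_distribution"]

_VALID = ("LC", "NT", "VU", "EN", "CR", "EX")


@dataclass
class StatusSummary:
    counts: pd.DataFrame          # per group: one column per category + totals
    fractions: pd.DataFrame       # assessed fraction, threatened fractions
    display: pd.DataFrame         # percentages rounded for display


def status_summary(statuses: pd.Series, assessed: pd.Series | None = None,
                   group_labels: pd.Series | None = None) -> StatusSummary:
    """Category counts and threatened fractions, overall and per group.

    ``statuses`` holds the final LC..EX category per species; ``assessed``
    (optional boolean) separates originally assessed species from imputed
    ones.  "threatened" counts VU+EN+CR; "threatened_or_extinct" adds EX.
    Display percentages are rounded to integers; raw fractions are retained.
    """
    bad = set(statuses.dropna()) - set(_VALID)
    if bad:
        raise ValueError(f"unknown status categories: {sorted(bad)}")
    if statuses.isna().any():
        raise ValueError("all species need a final status (impute first)")
    groups = pd.Series("all", index=statuses.index) if group_labels is None \
        else group_labels.reindex(statuses.index)
    rows_c, rows_f = [], []
    group_names = ["all"] + ([] if group_labels is None
                             else sorted(groups.unique()))
    for g in dict.fromkeys(group_names):
        sel = statuses if g == "all" else statuses[groups == g]
        n = len(sel)
        counts = {c: int((sel == c).sum()) for c in _VALID}
        thr = sum(counts[c] for c in THREATENED)
        thr_ex = thr + counts["EX"]
        row_c = {"group": g, **counts, "n": n, "threatened": thr,
                 "threatened_or_extinct": thr_ex}
        row_f = {"group": g,
                 "frac_threatened": thr / n if n else float("nan"),
                 "frac_threatened_or_extinct": thr_ex / n if n else float("nan")}
        if assessed is not None:
            a = assessed.reindex(sel.index)
            n_assessed = int(a.sum())
            row_c["n_assessed"] = n_assessed
            row_f["frac_assessed"] = n_assessed / n if n else float("nan")
            known = sel[a.astype(bool)]
            thr_a = int(known.isin(THREATENED).sum())
            row_c["assessed_threatened"] = thr_a
            row_f["frac_assessed_threatened"] = (thr_a / n_assessed
                                                 if n_assessed else float("nan"))
        rows_c.append(row_c)
        rows_f.append(row_f)
    counts = pd.DataFrame(rows_c).set_index("group")
    fractions = pd.DataFrame(rows_f).set_index("group")
    display = (100.0 * fractions).round(0)
    return StatusSummary(counts=counts, fractions=fractions, display=display)


def ed_threat_ttest(ed: pd.Series, statuses: pd.Series,
                    exclude_ex: bool = True, equal_var: bool = False) -> dict:
    """Two-sample t-test of ED: non-threatened (LC/NT) minus threatened
    (VU/EN/CR).

    Welch by default; with the non-threatened group first, lower ED in
    non-threatened species gives a negative t.  Extinct
    species are excluded by default (they carry no extant risk).  Group
    medians are reported.
    """
    statuses = statuses.reindex(ed.index)
    non = ed[statuses.isin(NONTHREATENED)]
    thr = ed[statuses.isin(THREATENED)]
    if exclude_ex is False:
        thr = pd.concat([thr, ed[statuses == "EX"]])
    if len(non) < 2 or len(thr) < 2:
        raise ValueError("each group needs at least 2 species")
    t, p = stats.ttest_ind(non, thr, equal_var=equal_var)
    return {"t": float(t), "p_value": float(p),
            "median_nonthreatened": float(non.median()),
            "median_threatened": float(thr.median()),
            "n_nonthreatened": int(len(non)), "n_threatened": int(len(thr))}


def notch_test(ed: pd.Series, statuses: pd.Series) -> pd.DataFrame:
    """Boxplot notch-overlap check between every pair of categories.

    Notches span median +/- 1.58*IQR/sqrt(n); non-overlapping notches are the
    conventional visual criterion for differing medians.
    """
    rows = []
    cats = [c for c in _VALID if (statuses == c).sum() > 0]
    notches = {}
    for c in cats:
        x = ed[statuses == c].dropna()
        iqr = float(x.quantile(0.75) - x.quantile(0.25))
        half = 1.58 * iqr / math.sqrt(len(x)) if len(x) else float("nan")
        notches[c] = (float(x.median()) - half, float(x.median()) + half)
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            lo = max(notches[a][0], notches[b][0])
            hi = min(notches[a][1], notches[b][1])
            rows.append({"cat_a": a, "cat_b": b, "overlap": lo <= hi})
    return pd.DataFrame(rows)


def ed_distribution(ed: pd.Series, bin_width: float = 2.0) -> dict:
    """Histogram plus kernel-density mode locations, ordered by height.

    A constant sample reports a single degenerate mode.
    """
    x = np.asarray(ed.dropna(), dtype=float)
    if x.size == 0:
        raise ValueError("empty ED input")
    if np.ptp(x) == 0:
        edges = np.array([x[0] - bin_width / 2, x[0] + bin_width / 2])
        return {"hist": (np.array([x.size]), edges),
                "modes": [float(x[0])], "degenerate": True}
    edges = np.arange(x.min(), x.max() + bin_width, bin_width)
    hist = np.histogram(x, bins=edges)
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    peaks = [i for i in range(1, len(grid) - 1)
             if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]]
    if dens[0] > dens[1]:
        peaks.insert(0, 0)
    if dens[-1] > dens[-2]:
        peaks.append(len(grid) - 1)
    peaks.sort(key=lambda i: -dens[i])
    return {"hist": hist, "modes": [float(grid[i]) for i in peaks],
            "degenerate": False}
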