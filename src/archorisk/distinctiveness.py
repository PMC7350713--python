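"""Fair-proportion evolutionary distinctiveness (ED) and EDGE scores.

Fair proportion divides each branch's length equally among the tips it
subtends; a tip's ED is the sum of its shares along the root-to-tip path, so
ED summed over tips equals total tree length.  The EDGE score combines ED
with the IUCN category weight GE (LC=0 .. CR=4):

    EDGE = ln(1 + ED) + GE * ln 2

so with every species Least Concern, EDGE reduces to the log-transformed ED.
Extinct (EX) species carry no GE weight and are excluded from EDGE ranking;
median ED over a tree posterior is taken before the log transform.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .trees import TreeArrays, to_arrays

__all__ = ["fair_proportion", "median_ed", "ge_weight", "edge_score",
           "edge_table", "rank_edge", "GE_WEIGHTS"]

GE_WEIGHTS = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}


def fair_proportion(tree) -> pd.Series:
    """Per-tip ED (Myr) under the fair-proportion apportionment."""
    arr = tree if isinstance(tree, TreeArrays) else to_arrays(tree)
    if np.any(arr.blen < 0):
        raise ValueError("branch lengths must be non-negative")
    ntips = arr.n_subtended_tips()
    share = np.where(arr.parent >= 0, arr.blen / ntips, 0.0)
    ed = np.zeros(arr.n_nodes)
    for i in arr.postorder[::-1]:  # preorder: parents before children
        p = arr.parent[i]
        ed[i] = share[i] + (ed[p] if p >= 0 else 0.0)
    return pd.Series(ed[: arr.n_tips], index=arr.labels, name="ED")


def median_ed(posterior) -> pd.DataFrame:
    """Per-species median ED across a posterior set of trees.

    All trees must share one tip set.  Returns a table with the median and
    the number of trees it summarizes.
    """
    if not posterior:
        raise ValueError("empty posterior tree set")
    eds = []
    tip_set = None
    for tree in posterior:
        ed = fair_proportion(tree)
        if tip_set is None:
            tip_set = set(ed.index)
        elif set(ed.index) != tip_set:
            raise ValueError("trees in the posterior have differing tip sets")
        eds.append(ed)
    mat = pd.concat(eds, axis=1)
    out = pd.DataFrame({"ED": mat.median(axis=1)})
    out.attrs["n_trees"] = len(eds)
    return out


def ge_weight(status: str) -> int:
    """IUCN category weight: LC=0, NT=1, VU=2, EN=3, CR=4.

    EX and unknown/missing categories have no defined weight and raise.
    """
    try:
        return GE_WEIGHTS[status]
    except (KeyError, TypeError):
        raise ValueError(f"no GE weight defined for status {status!r}") from None


def edge_score(ed: float, ge: int) -> float:
    """EDGE = ln(1 + ED) + GE * ln 2."""
    if ed < 0:
        raise ValueError("ED must be non-negative")
    if ge not in (0, 1, 2, 3, 4):
        raise ValueError("GE must be an integer in 0..4")
    return math.log1p(ed) + ge * math.log(2.0)


def edge_table(ed: pd.Series | pd.DataFrame, statuses: pd.Series) -> pd.DataFrame:
    """EDGE scores for every non-extinct species with a known category.

    ``ed`` may be a Series or the output of :func:`median_ed`.  EX species
    are retained in ED tables upstream but dropped here (they cannot be
    prioritized); missing statuses raise.
    """
    if isinstance(ed, pd.DataFrame):
        ed = ed["ED"]
    statuses = statuses.reindex(ed.index)
    if statuses.isna().any():
        missing = statuses.index[statuses.isna()].tolist()
        raise ValueError(f"species without status: {missing[:5]}")
    keep = statuses != "EX"
    rows = []
    for sp in ed.index[keep]:
        ge = ge_weight(statuses[sp])
        rows.append((sp, float(ed[sp]), ge, edge_score(float(ed[sp]), ge)))
    out = pd.DataFrame(rows, columns=["species", "ED", "GE", "EDGE"]).set_index("species")
    return out


def rank_edge(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-``n`` species by EDGE; ties break by higher ED, then label."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = table.iloc[
        np.lexsort((table.index.to_numpy(),
                    -table["ED"].to_numpy(),
                    -table["EDGE"].to_numpy()))]
    out = ordered.head(n).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out
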