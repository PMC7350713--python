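"""Gridded richness summaries and centroid geometry.

Ranges live on an abstract equal-area planar grid (no projections): a
species-by-cell boolean occupancy array, a centroid per species, and cell
areas in arbitrary km^2-like units.  "Threatened" maps count VU/EN/CR,
"non-threatened" LC/NT; extinct species are excluded from both (they have no
extant range to map).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["richness_map", "edge_weighted_richness", "centroid_distance_matrix",
           "THREATENED", "NONTHREATENED"]

THREATENED = frozenset({"VU", "EN", "CR"})
NONTHREATENED = frozenset({"LC", "NT"})


def _as_occ(grid) -> np.ndarray:
    occ = np.asarray(grid, dtype=bool)
    if occ.ndim != 3:
        raise ValueError("occupancy must be (n_species, rows, cols)")
    return occ


def richness_map(grid, species: list, statuses: pd.Series,
                 which: str = "threatened") -> np.ndarray:
    """Per-cell species counts for one threat class.

    ``which`` is "threatened" (VU/EN/CR), "nonthreatened" (LC/NT), "ex"
    (extinct only) or "total" (all non-extinct).  Species present in the grid
    but lacking a final status raise.
    """
    occ = _as_occ(grid)
    if len(species) != occ.shape[0]:
        raise ValueError("species list must match occupancy rows")
    sel = {"threatened": THREATENED, "nonthreatened": NONTHREATENED,
           "ex": frozenset({"EX"}),
           "total": THREATENED | NONTHREATENED | {"EX"}}.get(which)
    if sel is None:
        raise ValueError(f"unknown richness class {which!r}")
    out = np.zeros(occ.shape[1:], dtype=int)
    for i, sp in enumerate(species):
        st = statuses.get(sp)
        if st is None or (isinstance(st, float) and np.isnan(st)):
            raise ValueError(f"species {sp!r} has no final status")
        if st not in THREATENED | NONTHREATENED | {"EX"}:
            raise ValueError(f"species {sp!r} has unresolved status {st!r}")
        if st in sel:
            out += occ[i]
    return out


def edge_weighted_richness(grid, species: list, edge_scores: pd.Series):
    """Per-cell sum of EDGE scores over occupying species.

    Species without an EDGE score (e.g. extinct ones) are skipped; the count
    of skipped species is returned alongside the map.
    """
    occ = _as_occ(grid)
    out = np.zeros(occ.shape[1:], dtype=float)
    skipped = 0
    for i, sp in enumerate(species):
        v = edge_scores.get(sp)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            skipped += 1
            continue
        out += float(v) * occ[i]
    return out, skipped


def centroid_distance_matrix(centroids) -> np.ndarray:
    """Pairwise Euclidean distances between range centroids (planar grid)."""
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError("centroids must be (n, 2)")
    if np.any(~np.isfinite(c)):
        raise ValueError("missing centroid coordinates")
    return squareform(pdist(c))
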