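#!/usr/bin/env python
"""Spatial summaries on the equal-area grid: richness of threatened
(VU/EN/CR) and non-threatened (LC/NT) species per cell, and richness
weighted by EDGE score.  Uses the final (assessed + imputed) statuses.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from archorisk import distinctiveness as di
from archorisk import geography as geo

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    species = pd.read_csv(DATA / "species.tsv", sep="\t", index_col=0)
    final = pd.read_csv(OUT / "final_statuses.tsv", sep="\t",
                        index_col=0)["final_status"]
    ed = pd.read_csv(OUT / "ed.tsv", sep="\t", index_col=0)["ED"]
    man = json.loads((DATA / "manifest.json").read_text())
    rows, cols = man["grid_dims"]

    trip = pd.read_csv(DATA / "occupancy.tsv", sep="\t")
    occ = np.zeros((len(species), rows, cols), dtype=bool)
    pos = {sp: i for i, sp in enumerate(species.index)}
    occ[trip["species"].map(pos), trip["row"], trip["col"]] = True

    names = list(species.index)
    thr = geo.richness_map(occ, names, final, "threatened")
    non = geo.richness_map(occ, names, final, "nonthreatened")
    print(f"threatened richness: max {thr.max()} species/cell; "
          f"non-threatened: max {non.max()}")

    edge = di.edge_table(ed, final)
    wmap, skipped = geo.edge_weighted_richness(occ, names, edge["EDGE"])
    print(f"EDGE-weighted richness: max {wmap.max():.1f} "
          f"({skipped} species without EDGE skipped)")

    np.savetxt(OUT / "richness_threatened.tsv", thr, fmt="%d", delimiter="\t")
    np.savetxt(OUT / "richness_nonthreatened.tsv", non, fmt="%d", delimiter="\t")
    np.savetxt(OUT / "richness_edge_weighted.tsv", wmap, fmt="%.3f", delimiter="\t")
    print("wrote richness_threatened.tsv, richness_nonthreatened.tsv, "
          "richness_edge_weighted.tsv")


if __name__ == "__main__":
    main()
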