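#!/usr/bin/env python
"""Headline tables: status breakdown (assessed + imputed), EDGE ranking of
the top-10 species, the ED-vs-threat Welch t-test and notch test, and the
ED distribution modes.
"""

import json
from pathlib import Path

import pandas as pd

from archorisk import distinctiveness as di
from archorisk import summaries as sm

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    final = pd.read_csv(OUT / "final_statuses.tsv", sep="\t", index_col=0)
    statuses, imputed = final["final_status"], final["imputed"]
    ed = pd.read_csv(OUT / "ed.tsv", sep="\t", index_col=0)["ED"]

    summ = sm.status_summary(statuses, assessed=~imputed)
    pct = summ.display.loc["all", "frac_threatened_or_extinct"]
    print(f"{int(pct)}% of species threatened or extinct "
          f"({int(summ.counts.loc['all', 'threatened_or_extinct'])}"
          f"/{int(summ.counts.loc['all', 'n'])})")

    edge = di.edge_table(ed, statuses)
    top = di.rank_edge(edge, 10)
    print("top-10 EDGE species:")
    for sp, row in top.iterrows():
        print(f"  {int(row['rank']):>2}. {sp}: ED={row['ED']:.1f} Myr, "
              f"GE={int(row['GE'])}, EDGE={row['EDGE']:.2f}")

    tt = sm.ed_threat_ttest(ed, statuses)
    print(f"ED, non-threatened vs threatened: medians "
          f"{tt['median_nonthreatened']:.1f} vs {tt['median_threatened']:.1f} "
          f"Myr; Welch t={tt['t']:.2f}, p={tt['p_value']:.3f}")
    notch = sm.notch_test(ed, statuses)

    summ.counts.to_csv(OUT / "status_summary.tsv", sep="\t")
    top.to_csv(OUT / "edge_top10.tsv", sep="\t")
    edge.to_csv(OUT / "edge.tsv", sep="\t")
    notch.to_csv(OUT / "notch_test.tsv", sep="\t", index=False)
    (OUT / "headline.json").write_text(json.dumps({
        "pct_threatened_or_extinct": float(pct), "ed_ttest": tt,
        "top10": list(top.index)}, indent=2))
    print("wrote status_summary.tsv, edge_top10.tsv, edge.tsv, "
          "notch_test.tsv, headline.json")


if __name__ == "__main__":
    main()
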