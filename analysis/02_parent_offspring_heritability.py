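#!/usr/bin/env python
"""Parent-offspring regression heritabilities on the simulated population.

Builds brood-level midparent, father- and mother-offspring datasets (full
sibs averaged), estimates mate correlations from the measured breeding pairs,
and reports h2 per method and habitat with the (1 + r) assortative-mating
correction applied to the single-parent slopes.
"""

import owlfid as o
from owlfid import io as fio

SYN = "results/synthetic"


def main() -> None:
    ped = fio.read_pedigree_file(f"{SYN}/pedigree.tsv")
    phen = fio.read_phenotypes(f"{SYN}/phenotypes.csv")

    pairs = o.mate_pairs_from_pedigree(ped, phen)
    mate_r = {}
    for hab in ("rural", "urban", "all"):
        sub = pairs if hab == "all" else pairs[pairs["habitat"] == hab]
        mate_r[hab] = o.mate_correlation(list(zip(sub["female_value"], sub["male_value"])))
    print("mate correlations used for the (1+r) correction:",
          {k: round(v, 2) for k, v in mate_r.items()})

    table = o.heritability_table(ped, phen, mate_r)
    fio.write_table(table, "results/estimates.tsv")
    print(table.round(3).to_string(index=False))
    mid_all = table.query("method == 'midparent' and habitat == 'all'").iloc[0]
    print(f"\nmidparent h2 (all birds): {mid_all['h2']:.2f} +/- {mid_all['se']:.2f} "
          f"from {int(mid_all['n'])} broods (simulated truth: 0.43 in the founders; "
          "later generations run slightly higher under assortative mating)")
    print("wrote results/estimates.tsv")


if __name__ == "__main__":
    main()
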