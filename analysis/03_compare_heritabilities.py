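#!/usr/bin/env python
"""z comparisons of heritability estimates, habitat by habitat and method by
method, on the simulated estimates table; none of the pairwise differences is
expected to be significant when all strata share one true h2."""

import pandas as pd

import owlfid as o
from owlfid import io as fio


def main() -> None:
    est = pd.read_csv("results/estimates.tsv", sep="\t")
    table = o.comparison_table(est)
    fio.write_table(table, "results/comparisons.tsv")
    print(table.round(4).to_string(index=False))
    n_sig = (table["p"] < 0.05).sum()
    print(f"\n{n_sig} of {len(table)} pairwise comparisons significant at 0.05")
    print("wrote results/comparisons.tsv")


if __name__ == "__main__":
    main()
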