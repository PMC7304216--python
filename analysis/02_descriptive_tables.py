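"""Descriptive statistics: published tables and the synthetic replica.

Recomputes Pearson chi-square tests from the published 2016 EDHS
cross-tabulations (the tables themselves are the data here), then builds the
same table from the synthetic dataset of step 01.
"""

from pathlib import Path

import pandas as pd

from comorbmap.data_model import read_dataset
from comorbmap.reporting import (PUBLISHED_CROSSTABS, crosstab_from_counts,
                                 descriptive_table)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for cov, tab in PUBLISHED_CROSSTABS.items():
        ct = crosstab_from_counts(cov, list(tab), list(tab.values()))
        rows.append({"covariate": cov, "chi2": round(ct.chi2, 3),
                     "df": ct.df, "p": round(ct.p_value, 3)})
    pub = pd.DataFrame(rows)
    pub.to_csv(OUT / "published_chisq.csv", index=False)
    print("chi-square tests on the published tables:")
    print(pub.to_string(index=False))

    data = OUT / "dataset.csv"
    if data.exists():
        ds = read_dataset(data)
        descriptive_table(ds).to_csv(OUT / "table1_synthetic.csv", index=False)
        print(f"\nsynthetic descriptive table written ({ds.n} children)")
    else:
        print("\nrun 01_simulate.py first for the synthetic table")


if __name__ == "__main__":
    main()
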