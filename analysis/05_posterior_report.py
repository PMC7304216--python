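"""Fit the fixed+smooth+structured model and write the posterior reports.

Produces the odds-ratio table (posterior mean exp(beta) with 95% credible
intervals), the three-class spatial significance map, and the age curve with
nested 80%/95% bands; prints where the recovered curve peaks.
"""

from pathlib import Path

import numpy as np

from comorbmap.data_model import read_dataset
from comorbmap.inference import MCMCOptions, diagnostics, fit
from comorbmap.model_selection import model_spec
from comorbmap.reporting import or_summary, smooth_bands, spatial_significance
from comorbmap.synthetic import lattice11_graph

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    ds = read_dataset(OUT / "dataset.csv")
    g = lattice11_graph()
    s = fit(ds, g, model_spec("M5"),
            options=MCMCOptions(iterations=2000, burnin=600, thin=7,
                                seed=seed))
    s.save(OUT / "samples_m5")
    or_summary(s).to_csv(OUT / "table4_synthetic.csv", index=False)
    spatial_significance(s).to_csv(OUT / "spatial_classes.csv", index=False)
    curve = smooth_bands(s)
    curve.to_frame().to_csv(OUT / "smooth_curves.csv", index=False)
    peak = curve.grid[np.argmax(curve.mean[:, 0])]
    print(f"recovered age-curve peak (one illness): {peak:.1f} months "
          f"(truth: 12)")
    d = diagnostics(s)
    print(f"{int(d['flag'].sum())}/{len(d)} parameters flagged (R-hat > 1.1)")


if __name__ == "__main__":
    main()
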