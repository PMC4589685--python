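#!/usr/bin/env python
"""Cross-correlate matrix microstructure with cell motility across the
simulated conditions.

Condition means of each metric are min-max normalized to [0, 1] and each
pair is summarized by OLS slope, r^2 and the slope p-value, mirroring
how matrix descriptors are tested as predictors of motility.  Writes
results/correlations.csv (plots to scratch/plots).  Requires
analysis/02 and 03.
"""

from pathlib import Path

import pandas as pd

from ecmkit import correlation_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

PAIRS = [
    ("alpha", "speed_um_per_min"),
    ("alpha", "net_invasion_um"),
    ("alpha", "protrusions_per_90min"),
    ("alpha", "polarization_index"),
    ("pore_diameter_um", "speed_um_per_min"),
    ("pore_diameter_um", "alpha"),
]


def main() -> None:
    matrix = pd.read_csv(RESULTS / "matrix_metrics.csv", index_col="condition")
    motility = pd.read_csv(RESULTS / "motility_metrics.csv", index_col="condition")
    table = matrix.join(motility, how="inner")

    results = correlation_report(table, PAIRS, out_dir=str(ROOT / "scratch" / "plots"))
    out = RESULTS / "correlations.csv"
    results.to_csv(out, index=False, float_format="%.6g")

    for _, r in results.iterrows():
        flag = "*" if r["p_slope"] < 0.05 else " "
        print(f"{r['x_metric']:>18} vs {r['y_metric']:<22} "
              f"slope={r['slope']:+.2f}  r2={r['r_squared']:.2f}  p={r['p_slope']:.4f} {flag}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
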