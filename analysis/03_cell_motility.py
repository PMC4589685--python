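#!/usr/bin/env python
"""Summarize cell motility per simulated condition: speed, net invasion
distance, protrusion rate and polarization index, averaged over cells.

Writes results/motility_metrics.csv.  Requires analysis/01_simulate.py.
"""

from pathlib import Path

import pandas as pd

from ecmkit import condition_means, read_protrusions, read_tracks, summarize_cell

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    labels = sorted(p.stem.replace("tracks_", "") for p in SCRATCH.glob("tracks_*.csv"))
    rows = []
    for label in labels:
        tracks = {t.cell_id: t for t in read_tracks(SCRATCH / f"tracks_{label}.csv")}
        records = {r.cell_id: r for r in read_protrusions(SCRATCH / f"protrusions_{label}.csv")}
        summaries = [
            summarize_cell(tracks.get(cid), records.get(cid))
            for cid in sorted(set(tracks) | set(records))
        ]
        means = condition_means(summaries)
        row = {"condition": label, "n_cells": len(summaries)}
        for metric in means.index:
            row[metric] = means.loc[metric, "mean"]
            row[f"{metric}_sem"] = means.loc[metric, "sem"]
        rows.append(row)
        print(f"{label}: speed = {row['speed_um_per_min']:.3f} um/min, "
              f"invasion = {row['net_invasion_um']:.1f} um, "
              f"rate = {row['protrusions_per_90min']:.2f}/90min, "
              f"polarization = {row['polarization_index']:.2f}")

    out = RESULTS / "motility_metrics.csv"
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.6g")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
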