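#!/usr/bin/env python
"""Simulate a six-condition synthetic study emulating collagen gels of
increasing density.

Each condition gets reflection-style fiber images (fiber count rising
with density; orientation concentration following the biphasic
alignment trend the matrix conditions are meant to emulate: high at the
lowest density, lowest at intermediate density, partially recovering at
high density), plus cell trajectories and protrusion streams whose
ground-truth speed, persistence and axial bias track the alignment of
their condition.  Images (binary-heavy TIFFs) go to scratch/; the
ground-truth condition table and the motility CSVs for the downstream
steps are written alongside.

Run from the repository root:  python analysis/01_simulate.py
"""

import json
from pathlib import Path

import pandas as pd

from ecmkit import (
    BackgroundParams,
    FiberFieldParams,
    ProtrusionStreamParams,
    WalkParams,
    generate_fiber_image,
    generate_protrusion_stream,
    generate_trajectory,
    write_image,
    write_protrusions,
    write_tracks,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

#: Ground truth per condition: label -> (n_fibers, kappa, speed um/min,
#: persistence, protrusion rate per 90 min, axial bias).  Alignment and
#: motility follow the biphasic density response being emulated.
CONDITIONS = {
    "1.0mg": (110, 10.0, 0.55, 0.85, 4.5, 0.85),
    "1.5mg": (150, 3.0, 0.40, 0.70, 3.5, 0.55),
    "2.0mg": (200, 2.0, 0.30, 0.55, 2.5, 0.40),
    "2.5mg": (250, 1.0, 0.25, 0.45, 2.0, 0.30),
    "4.0mg": (340, 4.0, 0.35, 0.60, 3.0, 0.55),
    "6.0mg": (450, 6.0, 0.45, 0.70, 3.8, 0.70),
}

N_IMAGES = 3      # replicate fields per condition
N_CELLS = 20      # tracked cells per condition
N_STEPS = 120     # 2-min steps per track (4 h)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    image_index = {}
    for ci, (label, (n_fib, kappa, speed, pers, rate, bias)) in enumerate(CONDITIONS.items()):
        paths = []
        for rep in range(N_IMAGES):
            seed = 1000 * ci + rep
            params = FiberFieldParams(
                image_size_px=(256, 256), n_fibers=n_fib,
                orientation_kappa=kappa, seed=seed,
            )
            bg = BackgroundParams(center_intensity=0.4, speckle_sd=0.05, seed=seed)
            img, _ = generate_fiber_image(params, bg)
            paths.append(str(write_image(img, SCRATCH / f"{label}_rep{rep}.tif")))
        image_index[label] = paths

        tracks = [
            generate_trajectory(
                WalkParams(n_steps=N_STEPS, speed_um_per_min=speed,
                           persistence=pers, seed=2000 * ci + c),
                cell_id=f"{label}_c{c:02d}",
            )
            for c in range(N_CELLS)
        ]
        write_tracks(tracks, SCRATCH / f"tracks_{label}.csv")

        streams = [
            generate_protrusion_stream(
                ProtrusionStreamParams(rate_per_90min=rate, axial_bias=bias,
                                       seed=3000 * ci + c),
                cell_id=f"{label}_c{c:02d}",
            )
            for c in range(N_CELLS)
        ]
        write_protrusions(streams, SCRATCH / f"protrusions_{label}.csv")
        print(f"{label}: {N_IMAGES} fields, {N_CELLS} tracks, "
              f"{sum(len(s.events) for s in streams)} protrusion events")

    (SCRATCH / "image_index.json").write_text(json.dumps(image_index, indent=2))
    truth = pd.DataFrame(
        [
            {"condition": k, "n_fibers": v[0], "kappa": v[1], "true_speed": v[2],
             "persistence": v[3], "true_rate": v[4], "axial_bias": v[5]}
            for k, v in CONDITIONS.items()
        ]
    )
    truth.to_csv(RESULTS / "simulated_ground_truth.csv", index=False)
    print(f"wrote ground truth for {len(CONDITIONS)} conditions -> "
          f"{RESULTS / 'simulated_ground_truth.csv'}")


if __name__ == "__main__":
    main()
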