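"""Top-level pipeline: chain preprocessing, microstructure, motility and
correlation over declared inputs, writing a manifest that enables exact
reruns.

Inputs are files on disk (images, track/protrusion CSVs, an optional
condition table); every numeric output is a CSV/JSON file under the
output directory, and the manifest records inputs, the full parameter
set, package version and seed so that rerunning from the manifest
reproduces all CSV/JSON outputs bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .errors import EcmkitError
from .io import read_image, read_protrusions, read_tracks
from .microstructure import MicrostructureConfig, analyze_microstructure
from .motility import condition_means, summarize_cell
from .stats import correlation_report

log = logging.getLogger("ecmkit.pipeline")

INPUT_KEYS = {"images", "tracks", "protrusions", "condition_table"}


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _microstructure_config(cfg: PipelineConfig) -> MicrostructureConfig:
    return MicrostructureConfig(
        mask_size=cfg.preprocess.mask_size,
        n_orientations=cfg.preprocess.n_orientations,
        gaussian_sd=cfg.preprocess.gaussian_sd,
        threshold_method=cfg.preprocess.threshold_method,
        threshold_value=cfg.preprocess.threshold_value,
        max_radius_px=cfg.microstructure.max_radius_px,
        n_thetas=cfg.microstructure.n_thetas,
        dc_remove=cfg.microstructure.dc_remove,
        radon_interpolation=cfg.microstructure.radon_interpolation,
        crop_um=cfg.microstructure.crop_um,
        alignment_source=cfg.microstructure.alignment_source,
    )


def run_pipeline(config: PipelineConfig, inputs: dict, out_dir: str | Path) -> dict:
    """Execute the requested stages and write outputs plus a manifest.

    ``inputs`` may contain:

    * ``images`` — mapping of condition label to image path (microstructure
      is measured per image);
    * ``tracks`` / ``protrusions`` — CSV paths (motility summary);
    * ``condition_table`` — CSV of per-condition metric means for the
      correlation stage (uses ``config.stats.pairs``).

    Returns the manifest dict (also written to ``manifest.json``).
    """
    unknown = sorted(set(inputs) - INPUT_KEYS)
    if unknown:
        raise EcmkitError(f"unknown input keys: {unknown}; expected subset of {sorted(INPUT_KEYS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    timings: dict[str, float] = {}

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    log.error("stage %s: FAILED: %s", name, exc)
                else:
                    log.info("stage %s: done in %.2fs", name, timings[name])
                return False

        return _T()

    if "images" in inputs:
        with _stage("microstructure"):
            mcfg = _microstructure_config(config)
            summaries = {}
            for label, path in sorted(inputs["images"].items()):
                img = read_image(path, pixel_size_um=config.pixel_size_um)
                report = analyze_microstructure(img, mcfg)
                summaries[label] = report.summary()
                spec = report.pore
                spectrum = pd.DataFrame(
                    {"radius_px": spec.radii_px, "I_r": spec.retained_area, "f_r": spec.freq}
                )
                spath = out_dir / f"pore_spectrum_{label}.csv"
                spectrum.to_csv(spath, index=False, float_format="%.9g")
                outputs.append(spath.name)
                if spec.near_resolution_limit:
                    log.warning("condition %s: mean pore size below the resolution limit", label)
            jpath = out_dir / "microstructure_summary.json"
            _json_dump(summaries, jpath)
            outputs.append(jpath.name)

    if "tracks" in inputs or "protrusions" in inputs:
        with _stage("motility"):
            trajectories = read_tracks(inputs["tracks"]) if "tracks" in inputs else []
            records = (
                read_protrusions(
                    inputs["protrusions"],
                    min_length_um=config.motility.min_protrusion_um,
                )
                if "protrusions" in inputs
                else []
            )
            by_cell = {t.cell_id: {"traj": t} for t in trajectories}
            for r in records:
                by_cell.setdefault(r.cell_id, {})["rec"] = r
            rows = []
            for cell_id in sorted(by_cell):
                s = summarize_cell(
                    by_cell[cell_id].get("traj"), by_cell[cell_id].get("rec"),
                    window_min=config.motility.window_min,
                )
                rows.append(
                    {"cell_id": s.cell_id, "speed_um_per_min": s.speed_um_per_min,
                     "net_invasion_um": s.net_invasion_um,
                     "protrusions_per_90min": s.protrusions_per_90min,
                     "polarization_index": s.polarization_index, "C1": s.C1, "C2": s.C2}
                )
            mpath = out_dir / "motility_summary.csv"
            pd.DataFrame(rows).to_csv(mpath, index=False, float_format="%.9g")
            outputs.append(mpath.name)
            cpath = out_dir / "motility_condition_means.csv"
            condition_means(
                [summarize_cell(by_cell[c].get("traj"), by_cell[c].get("rec"),
                                window_min=config.motility.window_min)
                 for c in sorted(by_cell)]
            ).to_csv(cpath, float_format="%.9g")
            outputs.append(cpath.name)

    if "condition_table" in inputs:
        with _stage("correlate"):
            table = pd.read_csv(inputs["condition_table"], index_col=0)
            pairs = [tuple(p) for p in config.stats.pairs]
            exclude = {
                tuple(k.split(":")): v for k, v in config.stats.exclusions.items()
            }
            results = correlation_report(table, pairs, exclude=exclude,
                                         out_dir=str(out_dir / "plots"))
            rpath = out_dir / "correlations.csv"
            results.to_csv(rpath, index=False, float_format="%.9g")
            outputs.append(rpath.name)

    manifest = {
        "ecmkit_version": __version__,
        "config": config.to_dict(),
        "inputs": {k: (dict(v) if isinstance(v, dict) else str(v)) for k, v in inputs.items()},
        "outputs": sorted(outputs),
        "seed": config.seed,
        "stage_timings_s": timings,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _json_dump(manifest, out_dir / "manifest.json")
    return manifest


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Re-execute a pipeline run exactly as recorded in its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    config = PipelineConfig.from_dict(manifest["config"])
    return run_pipeline(config, manifest["inputs"], out_dir)


def manifests_equivalent(a: dict, b: dict) -> bool:
    """Equality of two manifests ignoring timestamps and stage timings."""
    strip = lambda m: {k: v for k, v in m.items() if k not in ("timestamp", "stage_timings_s")}
    return strip(a) == strip(b)
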