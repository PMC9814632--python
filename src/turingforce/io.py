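"""Persistence: HDF5 snapshot series, CSV reports, PNG renders, and the
run manifest."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, config_hash
from .pde import FieldState, RunResult

__all__ = ["save_snapshots", "load_snapshots", "save_run", "write_manifest",
           "render_field_png", "stage_table", "RunManifest"]


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record of one simulation run."""

    config_hash: str
    seed: int
    version: str
    stage_summaries: list[dict]
    outputs: list[str]

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stage_summaries": self.stage_summaries,
            "outputs": self.outputs,
        }


def save_snapshots(snapshots: list[FieldState], path) -> None:
    """Write a snapshot series to HDF5: groups snap_0000, snap_0001, ...
    each with datasets u, v and a time attribute."""
    with h5py.File(path, "w") as fh:
        for i, s in enumerate(snapshots):
            g = fh.create_group(f"snap_{i:04d}")
            g.create_dataset("u", data=s.u)
            g.create_dataset("v", data=s.v)
            g.attrs["t"] = s.t


def load_snapshots(path) -> list[FieldState]:
    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh.keys()):
            g = fh[name]
            out.append(FieldState(u=g["u"][...], v=g["v"][...],
                                  t=float(g.attrs["t"])))
    return out


def stage_table(result: RunResult) -> pd.DataFrame:
    """Per-stage summary (forcing, times, classification) as a table."""
    rows = []
    for s in result.stage_summaries:
        r = s.report
        rows.append({
            "stage": s.index,
            "A": s.forcing.A,
            "T": s.forcing.T,
            "t_start": s.t_start,
            "t_end": s.t_end,
            "label": r.label if r is not None else "",
            "dominant_k": r.dominant_k if r is not None else np.nan,
            "spatial_sd": r.spatial_sd if r is not None else np.nan,
            "temporal_sd": r.temporal_sd if r is not None else np.nan,
        })
    return pd.DataFrame(rows)


def render_field_png(field: np.ndarray, path, vmin=None, vmax=None) -> None:
    """Grayscale PNG of a field with fixed contrast limits, matching the
    convention of plotting the activator concentration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo = float(np.min(field)) if vmin is None else vmin
    hi = float(np.max(field)) if vmax is None else vmax
    if hi <= lo:
        hi = lo + 1.0
    plt.imsave(path, field, cmap="gray", vmin=lo, vmax=hi, origin="lower")


def save_run(result: RunResult, out_dir) -> RunManifest:
    """Persist a run: snapshots (HDF5), stage table (CSV), final-frame
    PNG, and a JSON manifest listing everything."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5_path = out / "snapshots.h5"
    save_snapshots(result.snapshots, h5_path)
    csv_path = out / "stages.csv"
    stage_table(result).to_csv(csv_path, index=False)
    png_path = out / "final_u.png"
    render_field_png(result.snapshots[-1].u, png_path)
    outputs = [h5_path.name, csv_path.name, png_path.name]
    manifest = write_manifest(result.config, result, out, outputs)
    return manifest


def write_manifest(config: SimulationConfig, result: RunResult, out_dir,
                   outputs: list[str]) -> RunManifest:
    out = Path(out_dir)
    summaries = stage_table(result).to_dict(orient="records")
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=config.seed,
        version=__version__,
        stage_summaries=summaries,
        outputs=outputs,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
    missing = [o for o in outputs if not (out / o).exists()]
    if missing:
        raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
    return manifest
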