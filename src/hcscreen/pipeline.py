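"""End-to-end orchestration: fields -> masks -> cells -> wells -> screen outputs.

``run_pipeline`` chains segmentation, per-cell measurement, optional EdU
classification, well aggregation, control normalization, dose-response
fitting (per compound arm with >= 4 distinct doses), relative cell counts
and — when several cell lines are present — profile-matrix assembly,
hierarchical clustering and a heatmap. Every tabular artifact is written
atomically as CSV with a provenance sidecar, and the run is deterministic
for a fixed input, so re-running a config yields byte-identical CSVs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .features import classify_edu, measure_cells
from .screen import (
    aggregate_plate,
    build_profile_matrix,
    cluster_profiles,
    compare_cell_counts,
    fit_dose_response,
    normalize_plate,
)
from .segment import SegmentationParams, segment_field

log = logging.getLogger("hcscreen")

__all__ = ["PlateInput", "RunConfig", "RunResult", "run_pipeline"]


@dataclass
class PlateInput:
    path: str
    cell_line: str = "cells"
    plate: str = "plate01"


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    plates: list[PlateInput]
    out_dir: str
    marker_channel: str = "receptor"
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    measure_background_radius: int | None = 25
    normalize_scale: str = "fold_vehicle"
    vehicle: str = "vehicle"
    agonist: str = "DHT"
    cluster_transform: str = "log2"
    write_masks: bool = False
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "plates": [
                {"path": p.path, "cell_line": p.cell_line, "plate": p.plate}
                for p in self.plates
            ],
            "out_dir": self.out_dir,
            "marker_channel": self.marker_channel,
            "segmentation": self.segmentation.as_dict(),
            "measure_background_radius": self.measure_background_radius,
            "normalize_scale": self.normalize_scale,
            "vehicle": self.vehicle,
            "agonist": self.agonist,
            "cluster_transform": self.cluster_transform,
            "write_masks": self.write_masks,
            "seed": self.seed,
        }


@dataclass
class RunResult:
    artifacts: dict[str, Path]
    complete: bool
    n_fields: int
    n_skipped: int


def _fit_doses_for_plate(norm: pd.DataFrame, agonist: str) -> pd.DataFrame:
    rows = []
    for (compound, combo), grp in norm.groupby(["compound", "with_agonist"], sort=True):
        if compound in ("vehicle",):
            continue
        doses = grp["dose"].to_numpy(dtype=float)
        if len(np.unique(doses[doses > 0])) < 4:
            continue
        resp = grp["nuclear_level_median"].to_numpy(dtype=float)
        fit = fit_dose_response(doses, resp, direction="down")
        row = {"compound": compound, "with_agonist": combo}
        row.update(fit.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run the full analysis for one or more plates; returns artifact paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"seed": cfg.seed, "config_hash": hio.config_hash(cfg.as_dict())}
    artifacts: dict[str, Path] = {}
    all_norm = []
    all_counts = []
    n_fields = 0
    n_skipped = 0
    complete = True

    for plate_in in cfg.plates:
        pdir = Path(plate_in.path)
        layout = pd.read_csv(pdir / "layout.csv")
        fields = hio.read_fields(pdir, plate=plate_in.plate)
        expected = len(layout) if len(fields) == 0 else None
        if expected:
            log.warning("plate %s: no readable fields", plate_in.path)
        cell_parts = []
        for fimg in fields:
            try:
                seg = segment_field(fimg, cfg.segmentation)
            except Exception as exc:
                log.warning("segmentation failed for %s f%02d: %s",
                            fimg.well, fimg.field, exc)
                n_skipped += 1
                complete = False
                continue
            n_fields += 1
            if cfg.write_masks:
                hio.write_masks(seg, out / plate_in.cell_line / "masks",
                                fimg.well, fimg.field)
            cells = measure_cells(
                seg,
                fimg,
                marker_channel=cfg.marker_channel,
                background_radius=cfg.measure_background_radius,
            )
            cell_parts.append(cells)
        cells = (
            pd.concat(cell_parts, ignore_index=True)
            if cell_parts
            else pd.DataFrame()
        )
        pout = out / plate_in.cell_line
        has_edu = len(cells) and f"edu_nuc_mean" in cells.columns
        if has_edu:
            vehicle_wells = layout.loc[
                (layout["compound"] == cfg.vehicle)
                & (~layout["combo_agonist"].astype(bool)),
                "well",
            ]
            edu = classify_edu(cells, vehicle_wells)
            cells = edu.cells
        artifacts[f"{plate_in.cell_line}/cells"] = hio.write_csv(
            cells, pout / "cells.csv", **prov
        )
        wells = aggregate_plate(cells, layout, marker_channel=cfg.marker_channel)
        wells["cell_line"] = plate_in.cell_line
        artifacts[f"{plate_in.cell_line}/wells"] = hio.write_csv(
            wells, pout / "wells.csv", **prov
        )
        try:
            norm = normalize_plate(
                wells,
                scale=cfg.normalize_scale,
                vehicle=cfg.vehicle,
                agonist=cfg.agonist,
            )
        except ValueError as exc:
            log.warning("normalization skipped for %s: %s", plate_in.cell_line, exc)
            complete = False
            continue
        artifacts[f"{plate_in.cell_line}/wells_normalized"] = hio.write_csv(
            norm, pout / "wells_normalized.csv", **prov
        )
        fits = _fit_doses_for_plate(norm, cfg.agonist)
        if len(fits):
            fits.insert(0, "cell_line", plate_in.cell_line)
            artifacts[f"{plate_in.cell_line}/fits"] = hio.write_csv(
                fits, pout / "dose_response_fits.csv", **prov
            )
        counts = compare_cell_counts(norm, vehicle=cfg.vehicle)
        artifacts[f"{plate_in.cell_line}/cell_counts"] = hio.write_csv(
            counts, pout / "cell_counts.csv", **prov
        )
        all_norm.append(norm)
        all_counts.append(counts)

    if len(all_norm) >= 2:
        combined = pd.concat(all_norm, ignore_index=True)
        pm = build_profile_matrix(
            combined,
            value_col="nuclear_level_median",
            agonist=cfg.agonist,
            transform=cfg.cluster_transform
            if cfg.cluster_transform in ("log2",)
            else None,
        )
        mat_out = pm.values.reset_index()
        artifacts["profile_matrix"] = hio.write_csv(
            mat_out, out / "profile_matrix.csv", **prov
        )
        clusterable = pm.values.dropna(axis=0, how="any")
        if clusterable.shape[0] >= 2:
            dend = cluster_profiles(
                type(pm)(values=clusterable, transform=pm.transform)
            )
            nwk = out / "dendrogram.newick"
            tmp = nwk.with_suffix(".tmp")
            tmp.write_text(dend.to_newick() + "\n")
            tmp.replace(nwk)
            hio.write_provenance(nwk, **prov)
            artifacts["dendrogram"] = nwk
            artifacts["heatmap"] = _write_heatmap(pm.values, out / "heatmap.png")

    import yaml

    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.as_dict(), fh, sort_keys=True)
    hio.write_provenance(out / "run_config.yaml", **prov)
    artifacts["run_config"] = out / "run_config.yaml"
    return RunResult(
        artifacts=artifacts, complete=complete, n_fields=n_fields, n_skipped=n_skipped
    )


def _write_heatmap(values: pd.DataFrame, path: Path) -> Path:
    """Yellow-high / blue-low heatmap of the profile matrix."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * values.shape[1], 1 + 0.3 * values.shape[0])
    )
    im = ax.imshow(values.to_numpy(dtype=float), aspect="auto", cmap="cividis")
    ax.set_xticks(range(values.shape[1]), values.columns, rotation=45, ha="right")
    ax.set_yticks(range(values.shape[0]), values.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="normalized nuclear level")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
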