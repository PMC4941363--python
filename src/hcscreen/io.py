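"""File formats: TIFF fields, layout/truth CSVs, YAML configs, provenance.

Naming convention (owned by this module): one grayscale 16-bit TIFF per
channel per field, ``r{row:02d}c{col:02d}f{field:02d}_{channel}.tif``; the
plate layout as ``layout.csv`` with columns
``well,compound,dose,unit,combo_agonist,replicate``; ground truth as
``truth.csv``; the resolved simulation config as ``config.yaml``. An
explicit manifest CSV (``file,well,field,channel``) is the escape hatch
for arbitrary layouts. Every tabular output gets a small JSON provenance
sidecar (config hash, seed, package version).
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .field import FieldImage
from .simulate import SimulatedPlate, config_to_dict

__all__ = [
    "field_filename",
    "quantize_u16",
    "write_plate",
    "read_fields",
    "write_masks",
    "write_csv",
    "write_provenance",
]

log = logging.getLogger("hcscreen")

_FIELD_RE = re.compile(r"^(r\d+c\d+)f(\d+)_(.+)\.tif{1,2}$")


def field_filename(well: str, field: int, channel: str) -> str:
    return f"{well}f{field:02d}_{channel}.tif"


def quantize_u16(image: np.ndarray) -> tuple[np.ndarray, int]:
    """Round to the 16-bit unsigned output range; count clipped pixels."""
    arr = np.asarray(image, dtype=float)
    clipped = int(np.count_nonzero((arr < 0) | (arr > 65535)))
    return np.round(np.clip(arr, 0, 65535)).astype(np.uint16), clipped


def write_plate(sim: SimulatedPlate, outdir: str | Path) -> Path:
    """Write a simulated plate: images/, layout.csv, truth.csv, config.yaml."""
    outdir = Path(outdir)
    imgdir = outdir / "images"
    imgdir.mkdir(parents=True, exist_ok=True)
    clip_events = 0
    for fimg in sim.fields:
        for ch, arr in fimg.channels.items():
            q, clipped = quantize_u16(arr)
            clip_events += clipped
            tifffile.imwrite(imgdir / field_filename(fimg.well, fimg.field, ch), q)
    if clip_events:
        log.warning("quantization clipped %d pixels to the 16-bit range", clip_events)
    write_csv(sim.layout, outdir / "layout.csv", seed=sim.seed)
    write_csv(sim.truth, outdir / "truth.csv", seed=sim.seed)
    cfg = config_to_dict(sim.config)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    write_provenance(outdir / "config.yaml", seed=sim.seed)
    return outdir


def _manifest_groups(manifest: pd.DataFrame, root: Path):
    for (well, field), grp in manifest.groupby(["well", "field"], sort=True):
        files = {row["channel"]: root / row["file"] for _, row in grp.iterrows()}
        yield well, int(field), files


def read_fields(
    path: str | Path, manifest: str | Path | None = None, plate: str = "plate01"
) -> list[FieldImage]:
    """Load fields from a directory of per-channel TIFFs.

    Files are grouped into fields either by the naming convention or by a
    manifest CSV with columns ``file,well,field,channel``. Fields with
    unreadable files or mismatched channel dimensions are skipped with a
    logged warning rather than aborting the run.
    """
    path = Path(path)
    root = path / "images" if (path / "images").is_dir() else path
    groups: dict[tuple[str, int], dict[str, Path]] = {}
    if manifest is not None:
        mdf = pd.read_csv(manifest)
        for well, field, files in _manifest_groups(mdf, root):
            groups[(well, field)] = files
    else:
        for fn in sorted(os.listdir(root)):
            m = _FIELD_RE.match(fn)
            if not m:
                continue
            well, field, channel = m.group(1), int(m.group(2)), m.group(3)
            groups.setdefault((well, field), {})[channel] = root / fn
    fields: list[FieldImage] = []
    for (well, field), files in sorted(groups.items()):
        channels = {}
        ok = True
        for ch, fp in sorted(files.items()):
            try:
                channels[ch] = np.asarray(tifffile.imread(fp), dtype=float)
            except Exception as exc:  # corrupt/unreadable file
                log.warning("skipping field %s f%02d: cannot read %s (%s)",
                            well, field, fp.name, exc)
                ok = False
                break
        if ok and len({a.shape for a in channels.values()}) > 1:
            log.warning("skipping field %s f%02d: channel dimension mismatch",
                        well, field)
            ok = False
        if ok and channels:
            fields.append(
                FieldImage(channels=channels, well=well, field=field, plate=plate)
            )
    return fields


def write_masks(seg, outdir: str | Path, well: str, field: int) -> None:
    """Write nuclear and cell label masks as 16-bit TIFFs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for kind, mask in (("nuclei", seg.nuclear_mask), ("cells", seg.cell_mask)):
        tifffile.imwrite(
            outdir / f"{well}f{field:02d}_mask_{kind}.tif",
            mask.astype(np.uint16),
        )


def write_csv(df: pd.DataFrame, path: str | Path, **prov) -> Path:
    """Write a CSV atomically (tmp + rename) with a provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)
    write_provenance(path, **prov)
    return path


def config_hash(obj) -> str:
    payload = yaml.safe_dump(obj, sort_keys=True) if not isinstance(obj, str) else obj
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_provenance(path: str | Path, **meta) -> None:
    path = Path(path)
    prov = {"package": "hcscreen", "version": __version__}
    prov.update(meta)
    side = path.with_suffix(path.suffix + ".provenance.json")
    tmp = side.with_suffix(".tmp")
    with open(tmp, "w") as fh:
        json.dump(prov, fh, sort_keys=True, indent=1)
    os.replace(tmp, side)
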