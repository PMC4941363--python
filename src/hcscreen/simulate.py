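"""Synthetic screening plates with per-cell ground truth.

This module generates the known-answer test bed for the whole pipeline:
multi-channel fluorescence fields (DAPI nuclei, a receptor channel whose
nuclear level and nuclear/cytoplasmic partition respond to dose through a
four-parameter logistic effect curve, a bimodal EdU channel with a
controllable S-phase fraction, punctate mitochondria, and two-channel
JC-1 fields), together with a plate layout and a ground-truth table that
joins 1:1 with rendered cells.

Geometry is deliberately simple — nuclei are discs and the cytoplasm is a
concentric annulus — because every downstream measurement uses only areas,
containment and mean intensities, never shape. Touching nuclei are placed
as explicit pairs with a centre distance of 1.4-1.8 nuclear radii so the
dumbbell has two distance-transform maxima and watershed splitting is
well-posed.

The noise model is additive Gaussian read noise plus an
intensity-proportional ("shot") Gaussian term, applied after a constant
background with an optional linear gradient. At zero noise every rendered
pixel equals its analytic value, so integrated intensities and
nuclear/cytoplasmic ratios are exact — the basis of the measurement
recovery tests.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .field import FieldImage

__all__ = [
    "EffectModel",
    "hill_response",
    "Condition",
    "CellSpec",
    "PlateSimConfig",
    "SimulatedPlate",
    "sample_field_cells",
    "render_field",
    "truth_masks",
    "simulate_plate",
    "simulate_cell_records",
    "BiologConfig",
    "BiologPlate",
    "simulate_biolog",
    "well_name",
]


# --------------------------------------------------------------------------
# dose-effect model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectModel:
    """Four-parameter logistic (Hill) dose-effect curve.

    ``direction="down"``: response falls from ``top`` at zero dose to
    ``bottom`` at saturation, with midpoint ``ec50`` and steepness
    ``hill_slope``. ``direction="up"`` is the mirrored curve rising from
    ``bottom`` to ``top``.
    """

    top: float
    bottom: float
    ec50: float
    hill_slope: float = 1.0
    direction: str = "down"

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")
        if self.direction not in ("down", "up"):
            raise ValueError("direction must be 'down' or 'up'")


def hill_response(dose, model: EffectModel):
    """Evaluate the 4PL effect curve at one or more doses.

    For ``direction="down"`` returns
    ``bottom + (top - bottom) / (1 + (dose/ec50)**hill_slope)``;
    the "up" direction is mirrored (zero dose gives ``bottom``).
    Negative doses are rejected.
    """
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ValueError("dose must be non-negative")
    with np.errstate(over="ignore"):
        x = (dose_arr / model.ec50) ** model.hill_slope
    frac = 1.0 / (1.0 + x)  # weight of the zero-dose plateau
    if model.direction == "down":
        out = model.bottom + (model.top - model.bottom) * frac
    else:
        out = model.top + (model.bottom - model.top) * frac
    if np.isscalar(dose):
        return float(out)
    return out


# --------------------------------------------------------------------------
# plate configuration
# --------------------------------------------------------------------------

@dataclass
class Condition:
    """One treatment condition and the true effects it exerts.

    ``effect`` drives the receptor nuclear level, ``ratio_effect`` the true
    nuclear/cytoplasmic ratio, ``s_phase_effect`` the S-phase fraction and
    ``density_effect`` the relative cell density; each falls back to the
    corresponding constant when no curve is given.
    """

    compound: str
    dose: float = 0.0
    dose_unit: str = "uM"
    with_agonist: bool = False
    effect: EffectModel | None = None
    baseline_level: float | None = None
    ratio: float = 2.0
    ratio_effect: EffectModel | None = None
    s_phase_fraction: float = 0.27
    s_phase_effect: EffectModel | None = None
    density_factor: float = 1.0
    density_effect: EffectModel | None = None
    mito_intensity: float = 500.0
    mito_radius: float = 2.0
    jc1_ratio: float = 2.0
    timepoint: str = "24h"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not 0.0 <= self.s_phase_fraction <= 1.0:
            raise ValueError("s_phase_fraction must be in [0, 1]")
        if self.density_factor < 0:
            raise ValueError("density_factor must be non-negative")

    def nuclear_level(self, baseline: float) -> float:
        if self.effect is not None:
            return hill_response(self.dose, self.effect)
        if self.baseline_level is not None:
            return self.baseline_level
        return baseline

    def true_ratio(self) -> float:
        if self.ratio_effect is None:
            return self.ratio
        return hill_response(self.dose, self.ratio_effect)

    def s_fraction(self) -> float:
        if self.s_phase_effect is None:
            return self.s_phase_fraction
        return float(np.clip(hill_response(self.dose, self.s_phase_effect), 0, 1))

    def density(self) -> float:
        if self.density_effect is None:
            return self.density_factor
        return hill_response(self.dose, self.density_effect)

    def label(self, agonist: str = "DHT") -> str:
        return f"{self.compound}+{agonist}" if self.with_agonist else self.compound


@dataclass
class PlateSimConfig:
    """Everything needed to render one simulated plate deterministically.

    Defaults describe the study conditions used throughout the tests:
    quadruplicate wells per condition with vehicle (and, where relevant, a
    1 nM DHT agonist control) on every plate, ~50 cells per 400x400 px
    field, 10% of cells placed as touching nuclear pairs, and a modest
    noise level (read noise of 2% of the foreground receptor level plus a
    shot term) so segmentation tests probe the operators, not denoising.
    """

    conditions: dict[str, Condition]
    n_replicates: int = 4
    fields_per_well: int = 1
    field_shape: tuple[int, int] = (400, 400)
    cells_per_field: int = 50
    touching_fraction: float = 0.1
    nuclear_radius: float = 9.0
    nuclear_radius_sd: float = 0.5
    cyto_extra: float = 7.0
    edge_margin: float = 26.0
    channels: tuple[str, ...] = ("dapi", "receptor")
    dapi_level: float = 1500.0
    receptor_level: float = 1000.0
    intensity_cv: float = 0.15
    ratio_cv: float = 0.10
    edu_negative_level: float = 150.0
    edu_positive_level: float = 2000.0
    edu_cv: float = 0.25
    mito_count_mean: float = 6.0
    mito_intensity_cv: float = 0.15
    jc1_green_level: float = 500.0
    read_noise_sd: float = 20.0
    shot_noise_scale: float = 1.0
    background_level: float = 100.0
    background_gradient: float = 0.1
    plate_rows: int = 16
    plate_cols: int = 24
    agonist: str = "DHT"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if min(self.field_shape) <= 0 or self.fields_per_well <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if not 0.0 <= self.touching_fraction <= 1.0:
            raise ValueError("touching_fraction must be in [0, 1]")
        if self.nuclear_radius <= 0 or self.cyto_extra <= 0:
            raise ValueError("radii must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")

    @property
    def cyto_radius(self) -> float:
        return self.nuclear_radius + self.cyto_extra


@dataclass
class CellSpec:
    """Ground truth for one simulated cell.

    ``nuclear_intensity`` / ``cyto_intensity`` map channel name to the true
    (noise-free) mean intensity over the nuclear disc and cytoplasmic
    annulus. ``mito_objects`` is a list of ``(center, radius, intensity)``
    puncta rendered additively into the mitochondria channel.
    """

    center: tuple[float, float]
    nuclear_radius: float
    cyto_radius: float
    nuclear_intensity: dict[str, float]
    cyto_intensity: dict[str, float]
    s_phase: bool = False
    mito_objects: list = dc_field(default_factory=list)
    pair_id: int = -1
    edge_ok: bool = False

    def __post_init__(self) -> None:
        if not (self.cyto_radius > self.nuclear_radius > 0):
            raise ValueError("need cyto_radius > nuclear_radius > 0")
        for d in (self.nuclear_intensity, self.cyto_intensity):
            for ch, v in d.items():
                if v < 0:
                    raise ValueError(f"negative intensity for channel {ch!r}")


def well_name(row: int, col: int) -> str:
    """0-based plate coordinates -> well id like ``r01c01``."""
    return f"r{row + 1:02d}c{col + 1:02d}"


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


# --------------------------------------------------------------------------
# cell placement
# --------------------------------------------------------------------------

def sample_field_cells(
    config: PlateSimConfig,
    condition: Condition,
    rng: np.random.Generator,
) -> list[CellSpec]:
    """Draw the cells of one field for one treatment condition.

    Cells are placed by rejection sampling with a minimum centre-to-centre
    separation of twice the cytoplasmic radius, except for the configured
    fraction of touching pairs whose two nuclei are 1.4-1.8 nuclear radii
    apart. True intensities are drawn around the condition's dose-effect
    values with lognormal cell-to-cell variability; S-phase flags are
    Bernoulli at the condition's S fraction.
    """
    n = int(round(config.cells_per_field * condition.density()))
    if n == 0:
        return []
    h, w = config.field_shape
    # keep cells clear of the border (cytoplasm + downstream cell-mask
    # dilation) so edge removal is exercised only by dedicated tests
    margin = max(config.edge_margin, config.cyto_radius + 2.0)
    min_sep = 2.0 * config.cyto_radius + 1.0
    if n * min_sep * min_sep > 0.45 * h * w:
        raise ValueError(
            f"density infeasible: {n} cells with separation {min_sep:.0f}px "
            f"will not pack into a {h}x{w} field"
        )
    n_pairs = int(round(config.touching_fraction * n / 2.0))
    n_singles = n - 2 * n_pairs

    centers: list[tuple[float, float]] = []

    def _try_place(min_dist: float, tries: int = 4000):
        for _ in range(tries):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist**2 for pr, pc in centers):
                return (r, c)
        raise ValueError("density infeasible: could not place cell after rejection sampling")

    placements: list[tuple[tuple[float, float], int]] = []  # (center, pair_id)
    pair_radius: dict[int, float] = {}
    for pid in range(n_pairs):
        mid = _try_place(min_sep + 2 * config.nuclear_radius)
        # both nuclei of a pair share one radius so the dumbbell geometry
        # (and its two distance maxima) is controlled
        pair_radius[pid] = float(
            np.clip(
                rng.normal(config.nuclear_radius, config.nuclear_radius_sd),
                config.nuclear_radius - 2,
                config.nuclear_radius + 2,
            )
        )
        theta = rng.uniform(0, 2 * math.pi)
        sep = rng.uniform(1.4, 1.8) * pair_radius[pid]
        dr, dc = 0.5 * sep * math.sin(theta), 0.5 * sep * math.cos(theta)
        a = (mid[0] + dr, mid[1] + dc)
        b = (mid[0] - dr, mid[1] - dc)
        centers.extend([a, b])
        placements.extend([(a, pid), (b, pid)])
    for _ in range(n_singles):
        p = _try_place(min_sep)
        centers.append(p)
        placements.append((p, -1))

    level = condition.nuclear_level(config.receptor_level)
    ratio = condition.true_ratio()
    s_frac = condition.s_fraction()

    cells: list[CellSpec] = []
    for center, pid in placements:
        if pid >= 0:
            nr = pair_radius[pid]
        else:
            nr = float(
                np.clip(
                    rng.normal(config.nuclear_radius, config.nuclear_radius_sd),
                    config.nuclear_radius - 2,
                    config.nuclear_radius + 2,
                )
            )
        nuc_level = level * float(_lognormal_factor(rng, config.intensity_cv))
        cell_ratio = ratio * float(_lognormal_factor(rng, config.ratio_cv))
        s_phase = bool(rng.random() < s_frac)
        nuclear_int = {}
        cyto_int = {}
        for ch in config.channels:
            if ch == "dapi":
                nuclear_int[ch] = config.dapi_level * float(
                    _lognormal_factor(rng, config.intensity_cv)
                )
                cyto_int[ch] = 0.0
            elif ch == "receptor":
                nuclear_int[ch] = nuc_level
                cyto_int[ch] = nuc_level / cell_ratio
            elif ch == "edu":
                lev = (
                    config.edu_positive_level if s_phase else config.edu_negative_level
                )
                nuclear_int[ch] = lev * float(_lognormal_factor(rng, config.edu_cv))
                cyto_int[ch] = 0.0
            elif ch == "mito":
                nuclear_int[ch] = 0.0
                cyto_int[ch] = 0.0
            elif ch == "jc1_green":
                g = config.jc1_green_level * float(
                    _lognormal_factor(rng, config.intensity_cv)
                )
                nuclear_int[ch] = g
                cyto_int[ch] = g
            elif ch == "jc1_red":
                pass  # filled below, needs the green level
            else:
                nuclear_int[ch] = 0.0
                cyto_int[ch] = 0.0
        if "jc1_red" in config.channels:
            g = nuclear_int.get("jc1_green", config.jc1_green_level)
            r_level = g * condition.jc1_ratio * float(
                _lognormal_factor(rng, config.ratio_cv)
            )
            nuclear_int["jc1_red"] = r_level
            cyto_int["jc1_red"] = r_level
        mito_objects = []
        if "mito" in config.channels:
            n_mito = int(rng.poisson(config.mito_count_mean))
            min_gap = 2.0 * condition.mito_radius + 2.0
            placed: list[tuple[float, float]] = []
            for _ in range(n_mito):
                # puncta of one cell must not touch each other, so each
                # rendered object is an isolated analytic disc
                for _try in range(50):
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = rng.uniform(
                        nr + condition.mito_radius,
                        config.cyto_radius - condition.mito_radius,
                    )
                    mcenter = (
                        center[0] + rad * math.sin(ang),
                        center[1] + rad * math.cos(ang),
                    )
                    if all(
                        (mcenter[0] - pr) ** 2 + (mcenter[1] - pc) ** 2
                        >= min_gap**2
                        for pr, pc in placed
                    ):
                        placed.append(mcenter)
                        inten = condition.mito_intensity * float(
                            _lognormal_factor(rng, config.mito_intensity_cv)
                        )
                        mito_objects.append((mcenter, condition.mito_radius, inten))
                        break
        cells.append(
            CellSpec(
                center=center,
                nuclear_radius=nr,
                cyto_radius=nr + config.cyto_extra,
                nuclear_intensity=nuclear_int,
                cyto_intensity=cyto_int,
                s_phase=s_phase,
                mito_objects=mito_objects,
                pair_id=pid,
            )
        )
    return cells


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def truth_masks(cells: list[CellSpec], shape: tuple[int, int]):
    """Ground-truth nuclear and cell label masks for a list of cells.

    Labels are ``1..len(cells)`` in list order. Where nuclear discs of a
    touching pair overlap, the pixel goes to the nearer centre (ties to the
    lower label); the cell mask agrees with the nuclear mask wherever a
    nucleus is present, so nucleus-within-cell containment holds exactly.
    """
    h, w = shape
    nuc = np.zeros(shape, dtype=np.int32)
    cell = np.zeros(shape, dtype=np.int32)
    best_nuc = np.full(shape, np.inf)
    best_cell = np.full(shape, np.inf)
    for i, spec in enumerate(cells, start=1):
        cr, cc = spec.center
        rad = spec.cyto_radius
        r0, r1 = max(0, int(cr - rad) - 1), min(h, int(cr + rad) + 2)
        c0, c1 = max(0, int(cc - rad) - 1), min(w, int(cc + rad) + 2)
        rr, ccol = np.ogrid[r0:r1, c0:c1]
        d2 = (rr - cr) ** 2 + (ccol - cc) ** 2
        in_nuc = d2 <= spec.nuclear_radius**2
        in_cell = d2 <= rad**2
        sub_bn = best_nuc[r0:r1, c0:c1]
        upd = in_nuc & (d2 < sub_bn)
        nuc[r0:r1, c0:c1][upd] = i
        sub_bn[upd] = d2[upd]
        sub_bc = best_cell[r0:r1, c0:c1]
        updc = in_cell & (d2 < sub_bc)
        cell[r0:r1, c0:c1][updc] = i
        sub_bc[updc] = d2[updc]
    # cell ownership defers to nuclear ownership so nucleus subset-of cell
    has_nuc = nuc > 0
    cell[has_nuc] = nuc[has_nuc]
    return nuc, cell


def render_field(
    cells: list[CellSpec],
    config: PlateSimConfig,
    rng: np.random.Generator,
    *,
    well: str = "r01c01",
    field_index: int = 1,
    plate: str = "plate01",
    condition: Condition | None = None,
) -> tuple[FieldImage, pd.DataFrame]:
    """Render one field and emit its ground-truth rows.

    The DAPI channel is the filled nuclear discs; the receptor channel is
    the true cytoplasmic intensity over the annulus and the true nuclear
    intensity over the nucleus; EdU is nuclear-only and bimodal; the
    mitochondria channel is additive puncta; JC-1 channels cover the whole
    cell. Background and noise are applied last, after the analytic signal.
    """
    shape = config.field_shape
    nuc_owner, cell_owner = truth_masks(cells, shape)
    n = len(cells)
    arrays = {ch: np.zeros(shape, dtype=float) for ch in config.channels}
    if n:
        for ch in config.channels:
            if ch == "mito":
                continue
            lut_n = np.zeros(n + 1)
            lut_c = np.zeros(n + 1)
            for i, spec in enumerate(cells, start=1):
                lut_n[i] = spec.nuclear_intensity.get(ch, 0.0)
                lut_c[i] = spec.cyto_intensity.get(ch, 0.0)
            img = lut_c[cell_owner]
            in_nuc = nuc_owner > 0
            img[in_nuc] = lut_n[nuc_owner[in_nuc]]
            arrays[ch] = img
        if "mito" in arrays:
            img = arrays["mito"]
            h, w = shape
            for spec in cells:
                for (mr, mc), rad, inten in spec.mito_objects:
                    r0, r1 = max(0, int(mr - rad) - 1), min(h, int(mr + rad) + 2)
                    c0, c1 = max(0, int(mc - rad) - 1), min(w, int(mc + rad) + 2)
                    if r0 >= r1 or c0 >= c1:
                        continue
                    rr, ccol = np.ogrid[r0:r1, c0:c1]
                    disc = (rr - mr) ** 2 + (ccol - mc) ** 2 <= rad * rad
                    img[r0:r1, c0:c1][disc] += inten

    # background with linear left-to-right gradient, then noise, channel by
    # channel in declared order for determinism
    h, w = shape
    if config.background_level > 0:
        ramp = (np.arange(w) / max(w - 1, 1)) - 0.5
        bg = config.background_level * (1.0 + config.background_gradient * ramp)
        for ch in config.channels:
            arrays[ch] = arrays[ch] + bg[None, :]
    if config.read_noise_sd > 0 or config.shot_noise_scale > 0:
        for ch in config.channels:
            img = arrays[ch]
            noise = np.zeros(shape)
            if config.read_noise_sd > 0:
                noise += rng.normal(0.0, config.read_noise_sd, size=shape)
            if config.shot_noise_scale > 0:
                noise += rng.standard_normal(shape) * (
                    config.shot_noise_scale * np.sqrt(np.clip(img, 0, None))
                )
            arrays[ch] = np.clip(img + noise, 0.0, None)

    rows = []
    for i, spec in enumerate(cells, start=1):
        row = {
            "well": well,
            "field": field_index,
            "cell": i,
            "row": spec.center[0],
            "col": spec.center[1],
            "nuclear_radius": spec.nuclear_radius,
            "cyto_radius": spec.cyto_radius,
            "s_phase": spec.s_phase,
            "pair_id": spec.pair_id,
            "n_mito": len(spec.mito_objects),
        }
        for ch in config.channels:
            row[f"{ch}_nuclear"] = spec.nuclear_intensity.get(ch, 0.0)
            row[f"{ch}_cyto"] = spec.cyto_intensity.get(ch, 0.0)
        if "receptor" in config.channels:
            cyt = spec.cyto_intensity.get("receptor", 0.0)
            row["true_ratio"] = (
                spec.nuclear_intensity.get("receptor", 0.0) / cyt if cyt > 0 else np.nan
            )
        if condition is not None:
            row["compound"] = condition.compound
            row["dose"] = condition.dose
            row["dose_unit"] = condition.dose_unit
            row["with_agonist"] = condition.with_agonist
            row["timepoint"] = condition.timepoint
        rows.append(row)
    truth = pd.DataFrame(rows)
    fimg = FieldImage(channels=arrays, well=well, field=field_index, plate=plate)
    return fimg, truth


# --------------------------------------------------------------------------
# whole plates
# --------------------------------------------------------------------------

@dataclass
class SimulatedPlate:
    fields: list[FieldImage]
    layout: pd.DataFrame
    truth: pd.DataFrame
    config: PlateSimConfig
    cells: dict[tuple[str, int], list[CellSpec]]

    @property
    def seed(self) -> int:
        return self.config.seed


def simulate_plate(config: PlateSimConfig, plate: str = "plate01") -> SimulatedPlate:
    """Simulate every well/field of a plate deterministically from its seed.

    Conditions are laid out row-major, each occupying ``n_replicates``
    wells; a vehicle control condition must be present (plates are always
    normalizable). Per-field RNG streams are derived hierarchically from
    the plate seed so re-rendering a single field reproduces it exactly.
    """
    conds = list(config.conditions.items())
    if not any(c.compound == "vehicle" for _, c in conds):
        raise ValueError("plate must contain a vehicle control condition")
    n_wells_needed = len(conds) * config.n_replicates
    if n_wells_needed > config.plate_rows * config.plate_cols:
        raise ValueError("conditions x replicates exceed plate capacity")

    layout_rows = []
    fields: list[FieldImage] = []
    truth_parts = []
    cells_by_field: dict[tuple[str, int], list[CellSpec]] = {}
    widx = 0
    for cond_name, cond in conds:
        for rep in range(1, config.n_replicates + 1):
            wr, wc = divmod(widx, config.plate_cols)
            wname = well_name(wr, wc)
            layout_rows.append(
                {
                    "well": wname,
                    "compound": cond.compound,
                    "dose": cond.dose,
                    "unit": cond.dose_unit,
                    "combo_agonist": cond.with_agonist,
                    "replicate": rep,
                    "condition": cond_name,
                    "timepoint": cond.timepoint,
                }
            )
            for fidx in range(1, config.fields_per_well + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=int(config.seed) & 0x7FFFFFFF,
                        spawn_key=(widx, fidx),
                    )
                )
                cells = sample_field_cells(config, cond, rng)
                fimg, truth = render_field(
                    cells,
                    config,
                    rng,
                    well=wname,
                    field_index=fidx,
                    plate=plate,
                    condition=cond,
                )
                fields.append(fimg)
                if len(truth):
                    truth_parts.append(truth)
                cells_by_field[(wname, fidx)] = cells
            widx += 1
    layout = pd.DataFrame(layout_rows)
    truth = (
        pd.concat(truth_parts, ignore_index=True)
        if truth_parts
        else pd.DataFrame()
    )
    return SimulatedPlate(
        fields=fields, layout=layout, truth=truth, config=config, cells=cells_by_field
    )


def simulate_cell_records(
    n_cells: int,
    condition: Condition,
    config: PlateSimConfig,
    rng: np.random.Generator,
    *,
    well: str = "r01c01",
    measurement_cv: float = 0.02,
) -> pd.DataFrame:
    """Draw per-cell measurement records directly from the generative model.

    Bypasses rasterisation: intensities are the true per-cell values times
    a small lognormal measurement error. Used for estimator studies (EdU
    fraction recovery at thousands of cells per well) where rendering and
    re-segmenting images would only add the noise already tested elsewhere.
    """
    level = condition.nuclear_level(config.receptor_level)
    ratio = condition.true_ratio()
    s_frac = condition.s_fraction()
    s_phase = rng.random(n_cells) < s_frac
    nuc = level * _lognormal_factor(rng, config.intensity_cv, n_cells)
    cell_ratio = ratio * _lognormal_factor(rng, config.ratio_cv, n_cells)
    edu_level = np.where(
        s_phase, config.edu_positive_level, config.edu_negative_level
    ) * _lognormal_factor(rng, config.edu_cv, n_cells)
    meas = lambda x: x * _lognormal_factor(rng, measurement_cv, n_cells)  # noqa: E731
    area = np.round(math.pi * config.nuclear_radius**2 * np.ones(n_cells)).astype(int)
    nuc_mean = meas(nuc)
    df = pd.DataFrame(
        {
            "plate": "sim",
            "well": well,
            "field": 1,
            "label": np.arange(1, n_cells + 1),
            "nuc_area": area,
            "receptor_nuc_mean": nuc_mean,
            "receptor_nuc_integrated": nuc_mean * area,
            "receptor_cyto_mean": meas(nuc / cell_ratio),
            "edu_nuc_mean": meas(edu_level),
            "s_phase_true": s_phase,
        }
    )
    df["ratio_receptor"] = df["receptor_nuc_mean"] / df["receptor_cyto_mean"]
    df["edu_positive"] = pd.NA
    df["qc_flags"] = ""
    return df


# --------------------------------------------------------------------------
# Biolog-style phenotype plates
# --------------------------------------------------------------------------

@dataclass
class BiologConfig:
    """Generative model for a 96-well carbon-source utilization plate.

    90 source wells plus 6 empty negative-control wells; dye-reduction
    signal is a shared baseline plus a per-source utilization increment,
    scaled in the treated arm by per-source effect multipliers.
    """

    n_replicates: int = 3
    negative_control_wells: tuple[int, ...] = (0, 12, 24, 36, 48, 60)
    baseline: float = 100.0
    utilization_mean: float = 150.0
    utilization_cv: float = 0.5
    noise_sd: float = 5.0
    effect_multipliers: object = 1.0  # scalar or array over source wells
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.negative_control_wells) < 1:
            raise ValueError("at least one negative-control well is required")
        if len(set(self.negative_control_wells)) != len(self.negative_control_wells):
            raise ValueError("duplicate negative-control wells")

    @property
    def source_wells(self) -> np.ndarray:
        return np.array(
            [i for i in range(96) if i not in set(self.negative_control_wells)]
        )


@dataclass
class BiologPlate:
    """One 96-well phenotype-array readout."""

    values: np.ndarray
    negative_control_wells: tuple[int, ...]
    condition: str
    replicate: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (96,):
            raise ValueError("a Biolog plate has exactly 96 wells")
        if len(self.negative_control_wells) < 1:
            raise ValueError("at least one negative-control well is required")

    @property
    def source_wells(self) -> np.ndarray:
        return np.array(
            [i for i in range(96) if i not in set(self.negative_control_wells)]
        )

    @property
    def source_names(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(len(self.source_wells))]


def simulate_biolog(
    config: BiologConfig, rng: np.random.Generator | None = None
) -> tuple[list[BiologPlate], list[BiologPlate]]:
    """Simulate paired vehicle/treated replicate phenotype plates.

    Per-source utilization increments are drawn once and shared by every
    replicate of both arms, so the treated/vehicle contrast is exactly the
    configured effect multipliers (plus measurement noise).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    src = config.source_wells
    n_src = len(src)
    util = config.utilization_mean * _lognormal_factor(
        rng, config.utilization_cv, n_src
    )
    mult = np.broadcast_to(
        np.asarray(config.effect_multipliers, dtype=float), (n_src,)
    )
    vehicle, treated = [], []
    for arm, plates, m in (("vehicle", vehicle, np.ones(n_src)), ("treated", treated, mult)):
        for rep in range(1, config.n_replicates + 1):
            vals = np.full(96, config.baseline)
            vals[src] += m * util
            if config.noise_sd > 0:
                vals = vals + rng.normal(0.0, config.noise_sd, size=96)
            plates.append(
                BiologPlate(
                    values=vals,
                    negative_control_wells=config.negative_control_wells,
                    condition=arm,
                    replicate=rep,
                )
            )
    return vehicle, treated


def with_seed(config: PlateSimConfig, seed: int) -> PlateSimConfig:
    """Copy of a plate config with a different seed."""
    return replace(config, seed=seed)


def config_to_dict(config) -> dict:
    """Dataclass config -> plain nested dict (for YAML serialization)."""
    return asdict(config)
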