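"""Well aggregation, plate normalization, dose-response, clustering, Biolog.

Wells are summarised by robust statistics (median, MAD) of the per-cell
features; plates are normalized to their on-plate controls, either as fold
change over the vehicle median or as percent-of-agonist
``100 * (x - vehicle) / (agonist - vehicle)``.

Dose-response curves are four-parameter logistic (Hill) fits

    f(d) = r_inf + (r_0 - r_inf) / (1 + (d / ic50)**slope)

estimated by bounded nonlinear least squares with multi-start
initialization; the reported IC50 is the fitted midpoint (relative IC50,
half-way between the fitted plateaus). "No activity" is declared when an
extra-sum-of-squares F-test cannot reject the flat (constant) model at
alpha = 0.05.

Profile clustering is agglomerative with Euclidean distances (average
linkage by default); Biolog phenotype plates are corrected by subtracting
the per-plate negative-control mean, then Z-scored per carbon source
across all corrected replicate values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy

from .simulate import BiologPlate

__all__ = [
    "aggregate_well",
    "aggregate_plate",
    "normalize_plate",
    "DoseResponseFit",
    "fit_dose_response",
    "ProfileMatrix",
    "build_profile_matrix",
    "Dendrogram",
    "cluster_profiles",
    "BiologResult",
    "biolog_analyze",
    "compare_cell_counts",
]


# --------------------------------------------------------------------------
# well aggregation
# --------------------------------------------------------------------------

def _mad(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        return float("nan")
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def aggregate_well(
    records: pd.DataFrame,
    layout_entry: dict | pd.Series,
    marker_channel: str = "receptor",
    stat: str = "mean",
) -> dict:
    """Summarise the cells of one well into a WellSummary row.

    ``stat`` selects the per-cell nuclear-level statistic ("mean" or
    "integrated" intensity of the marker channel). An empty well yields a
    flagged summary rather than an exception.
    """
    entry = dict(layout_entry)
    level_col = f"{marker_channel}_nuc_{'integrated' if stat == 'integrated' else 'mean'}"
    ratio_col = f"ratio_{marker_channel}"
    n = len(records)
    out = {
        "well": entry.get("well", records["well"].iloc[0] if n else ""),
        "compound": entry.get("compound", ""),
        "dose": entry.get("dose", 0.0),
        "dose_unit": entry.get("unit", entry.get("dose_unit", "")),
        "with_agonist": bool(entry.get("combo_agonist", entry.get("with_agonist", False))),
        "replicate": entry.get("replicate", 1),
        "timepoint": entry.get("timepoint", ""),
        "n_cells": n,
        "empty": n == 0,
    }
    if n == 0:
        out.update(
            nuclear_level_mean=np.nan,
            nuclear_level_median=np.nan,
            nuclear_level_mad=np.nan,
            ratio_median=np.nan,
            pct_edu=np.nan,
        )
        return out
    levels = records[level_col].to_numpy(dtype=float)
    out["nuclear_level_mean"] = float(np.nanmean(levels))
    out["nuclear_level_median"] = float(np.nanmedian(levels))
    out["nuclear_level_mad"] = _mad(levels)
    if ratio_col in records.columns:
        out["ratio_median"] = float(np.nanmedian(records[ratio_col].to_numpy(dtype=float)))
    else:
        out["ratio_median"] = np.nan
    edu = records["edu_positive"] if "edu_positive" in records.columns else None
    if edu is not None and edu.notna().all() and n:
        out["pct_edu"] = float(100.0 * edu.astype(bool).mean())
    else:
        out["pct_edu"] = np.nan
    return out


def aggregate_plate(
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    marker_channel: str = "receptor",
    stat: str = "mean",
) -> pd.DataFrame:
    """Aggregate a per-cell table to one WellSummary row per layout well."""
    rows = []
    grouped = dict(tuple(cells.groupby("well", sort=False))) if len(cells) else {}
    for _, entry in layout.iterrows():
        recs = grouped.get(entry["well"], cells.iloc[0:0])
        rows.append(aggregate_well(recs, entry, marker_channel, stat))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# plate normalization
# --------------------------------------------------------------------------

_DEFAULT_VALUE_COLS = ("nuclear_level_mean", "nuclear_level_median", "ratio_median")


def normalize_plate(
    summaries: pd.DataFrame,
    scale: str = "fold_vehicle",
    vehicle: str = "vehicle",
    agonist: str = "DHT",
    value_cols=_DEFAULT_VALUE_COLS,
) -> pd.DataFrame:
    """Normalize well summaries to the on-plate controls.

    ``scale="fold_vehicle"``: value / median over vehicle wells.
    ``scale="percent_agonist"``: ``100 * (value - vehicle) / (agonist -
    vehicle)`` with medians over the respective control wells (requires
    agonist wells). The scale used is recorded in a ``norm_scale`` column.
    """
    if scale not in ("fold_vehicle", "percent_agonist"):
        raise ValueError("scale must be 'fold_vehicle' or 'percent_agonist'")
    veh = summaries[(summaries["compound"] == vehicle) & ~summaries["with_agonist"]]
    if len(veh) == 0:
        raise ValueError("no vehicle wells on the plate")
    out = summaries.copy()
    if scale == "fold_vehicle":
        for col in value_cols:
            ref = float(veh[col].median())
            out[col] = summaries[col] / ref
    else:
        ago = summaries[(summaries["compound"] == agonist) & ~summaries["with_agonist"]]
        if len(ago) == 0:
            raise ValueError("percent-of-agonist scale requested but no agonist wells")
        for col in value_cols:
            v = float(veh[col].median())
            a = float(ago[col].median())
            out[col] = 100.0 * (summaries[col] - v) / (a - v)
    out["norm_scale"] = scale
    return out


# --------------------------------------------------------------------------
# four-parameter logistic dose-response
# --------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """4PL fit result; ``flat=True`` means no dose-dependent activity."""

    top: float
    bottom: float
    hill_slope: float
    ic50: float
    rss: float
    converged: bool
    flat: bool
    ic50_in_range: bool
    n: int
    direction: str = "down"

    def as_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "hill_slope": self.hill_slope,
            "ic50": self.ic50,
            "rss": self.rss,
            "converged": self.converged,
            "flat": self.flat,
            "ic50_in_range": self.ic50_in_range,
            "n": self.n,
            "direction": self.direction,
        }


def _four_pl(d, r0, rinf, log_ic50, slope):
    """4PL over raw dose; defined at d = 0 (returns the r0 plateau)."""
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        x = np.where(d > 0, (d / 10.0**log_ic50) ** slope, 0.0)
    return rinf + (r0 - rinf) / (1.0 + x)


def fit_dose_response(
    doses,
    responses,
    direction: str = "down",
    alpha: float = 0.05,
) -> DoseResponseFit:
    """Fit a 4PL curve and decide activity vs a flat model.

    Requires >= 4 distinct doses. Zero doses are allowed as baseline
    anchors (they pin the zero-dose plateau); negative doses are rejected.
    Multi-start bounded least squares: plateaus from the response extrema,
    IC50 started at the dose bracketing half-max and at the geometric
    centre of the grid, slope in {0.5, 1, 2}. The fit is declared flat
    when the extra-sum-of-squares F-test cannot reject the constant model
    at ``alpha``; then ``converged=False`` and no IC50 is reported.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have the same length")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    n = len(doses)
    pos = doses[doses > 0]
    dmin, dmax = float(pos.min()), float(pos.max())
    rmean = float(responses.mean())
    rss_flat = float(np.sum((responses - rmean) ** 2))
    scale = max(1.0, float(np.max(np.abs(responses))))
    if rss_flat <= (1e-10 * scale) ** 2 * n:
        return DoseResponseFit(
            top=rmean, bottom=rmean, hill_slope=np.nan, ic50=np.nan,
            rss=rss_flat, converged=False, flat=True, ic50_in_range=False,
            n=n, direction=direction,
        )

    order = np.argsort(doses)
    d_sorted, r_sorted = doses[order], responses[order]
    r_lo = float(np.mean(r_sorted[d_sorted == d_sorted.min()]))
    r_hi = float(np.mean(r_sorted[d_sorted == d_sorted.max()]))
    rmin, rmax = float(responses.min()), float(responses.max())
    span = max(rmax - rmin, 1e-12)
    lo_b = rmin - 2 * span
    hi_b = rmax + 2 * span
    l_lo, l_hi = np.log10(dmin) - 2.0, np.log10(dmax) + 2.0

    # dose bracketing half-max: first sorted dose whose response crosses it
    half = 0.5 * (r_lo + r_hi)
    cross = dmin * np.sqrt(dmax / dmin)
    for i in range(1, len(d_sorted)):
        lo, hi = sorted((r_sorted[i - 1], r_sorted[i]))
        if lo <= half <= hi and d_sorted[i] > 0 and d_sorted[i - 1] > 0:
            cross = float(np.sqrt(d_sorted[i - 1] * d_sorted[i]))
            break
    ic50_starts = {cross, float(np.sqrt(dmin * dmax))}

    best = None
    bounds = ([lo_b, lo_b, l_lo, 0.05], [hi_b, hi_b, l_hi, 10.0])
    for slope0 in (0.5, 1.0, 2.0):
        for ic0 in ic50_starts:
            x0 = np.array([r_lo, r_hi, np.log10(ic0), slope0])
            try:
                res = optimize.least_squares(
                    lambda th: _four_pl(doses, *th) - responses,
                    x0,
                    bounds=bounds,
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=2000,
                )
            except Exception:  # pragma: no cover - optimizer hiccup
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0]:
                best = (rss, res.x, res.success)
    if best is None:  # pragma: no cover
        return DoseResponseFit(
            top=np.nan, bottom=np.nan, hill_slope=np.nan, ic50=np.nan,
            rss=np.nan, converged=False, flat=False, ic50_in_range=False,
            n=n, direction=direction,
        )
    rss, theta, success = best
    r0, rinf, log_ic50, slope = theta

    # extra-sum-of-squares F-test vs the constant model
    flat = False
    dof = n - 4
    if rss >= rss_flat:
        flat = True
    elif dof >= 1:
        if rss <= (1e-10 * scale) ** 2 * n:
            flat = False  # essentially perfect 4PL fit
        else:
            f_stat = ((rss_flat - rss) / 3.0) / (rss / dof)
            p = stats.f.sf(f_stat, 3, dof)
            flat = bool(p > alpha)
    if flat:
        return DoseResponseFit(
            top=rmean, bottom=rmean, hill_slope=np.nan, ic50=np.nan,
            rss=rss_flat, converged=False, flat=True, ic50_in_range=False,
            n=n, direction=direction,
        )
    ic50 = float(10**log_ic50)
    if direction == "down":
        top, bottom = float(r0), float(rinf)
    else:
        top, bottom = float(rinf), float(r0)
    return DoseResponseFit(
        top=top,
        bottom=bottom,
        hill_slope=float(slope),
        ic50=ic50,
        rss=rss,
        converged=bool(success),
        flat=False,
        ic50_in_range=bool(dmin <= ic50 <= dmax),
        n=n,
        direction=direction,
    )


# --------------------------------------------------------------------------
# condition x cell-line profiles and clustering
# --------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    """Treatment-condition x cell-line matrix of normalized responses."""

    values: pd.DataFrame  # rows = conditions, cols = cell lines; NaN = masked
    transform: str = "none"

    @property
    def mask(self) -> pd.DataFrame:
        return self.values.isna()


def build_profile_matrix(
    summaries: pd.DataFrame,
    value_col: str = "nuclear_level_median",
    agonist: str = "DHT",
    transform: str | None = None,
) -> ProfileMatrix:
    """Assemble the condition x cell-line profile matrix.

    ``summaries`` must carry ``cell_line``, ``compound``, ``with_agonist``,
    ``well`` and the value column; compound alone and compound+agonist form
    distinct rows, values are averaged over replicate wells and missing
    combinations stay masked (NaN). ``transform="log2"`` takes log2 of the
    (fold-change) values, the scale on which profiles are clustered.
    """
    req = {"cell_line", "compound", "with_agonist", "well", value_col}
    missing = req - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries lack columns: {sorted(missing)}")
    df = summaries.copy()
    dup = df.duplicated(subset=["cell_line", "well"], keep=False)
    if dup.any():
        conflicting = df.loc[dup].groupby(["cell_line", "well"])[value_col].nunique()
        if (conflicting > 1).any():
            raise ValueError("conflicting duplicate condition/cell-line entries")
        df = df.drop_duplicates(subset=["cell_line", "well"])
    df["condition"] = np.where(
        df["with_agonist"], df["compound"] + "+" + agonist, df["compound"]
    )
    mat = df.pivot_table(
        index="condition", columns="cell_line", values=value_col, aggfunc="mean"
    )
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    if transform == "log2":
        mat = np.log2(mat)
    elif transform not in (None, "none"):
        raise ValueError("transform must be None or 'log2'")
    return ProfileMatrix(values=mat, transform=transform or "none")


@dataclass
class Dendrogram:
    """Agglomerative clustering result (scipy linkage encoding).

    ``merges`` is the (n-1, 4) linkage matrix: each row joins two nodes at
    a merge height with the resulting cluster size; ``labels`` are the leaf
    names in input order and ``leaf_order`` the dendrogram traversal order.
    """

    merges: np.ndarray
    labels: list[str]
    method: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    def to_newick(self) -> str:
        """Newick with branch lengths = parent height - child height."""
        tree = hierarchy.to_tree(self.merges)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                name = self.labels[node.id].replace(" ", "_")
                return f"{name}:{parent_height:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


def cluster_profiles(
    matrix: ProfileMatrix | pd.DataFrame,
    axis: str = "rows",
    method: str = "average",
) -> Dendrogram:
    """Hierarchically cluster profile rows (or columns).

    Pairwise Euclidean distances, agglomerative merging with the chosen
    linkage (average/UPGMA by default). Masked (NaN) values on the
    clustered axis are rejected — imputation or row dropping must be an
    explicit upstream step.
    """
    values = matrix.values if isinstance(matrix, ProfileMatrix) else matrix
    if axis == "cols":
        values = values.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("masked values on the clustered axis; impute or drop first")
    merges = hierarchy.linkage(arr, method=method, metric="euclidean")
    return Dendrogram(merges=merges, labels=[str(i) for i in values.index], method=method)


# --------------------------------------------------------------------------
# Biolog phenotype arrays
# --------------------------------------------------------------------------

@dataclass
class BiologResult:
    """Negative-control-corrected and Z-scored phenotype-array matrices."""

    corrected: pd.DataFrame  # rows = carbon sources, cols = arm_replicate
    zscores: pd.DataFrame
    zero_variance_sources: list[str] = dc_field(default_factory=list)


def biolog_analyze(
    vehicle_plates: list[BiologPlate], treated_plates: list[BiologPlate]
) -> BiologResult:
    """Correct and Z-score paired vehicle/treated phenotype plates.

    Each plate is corrected by subtracting the mean of its own
    negative-control wells; Z-scores are computed per carbon source across
    all corrected replicate values (population SD), so every emitted row
    has mean 0 and SD 1 unless the row is constant, in which case it is
    zeroed and flagged.
    """
    if not vehicle_plates or not treated_plates:
        raise ValueError("need at least one plate per arm")
    cols = {}
    source_names = None
    for plate in list(vehicle_plates) + list(treated_plates):
        nc = np.asarray(plate.negative_control_wells, dtype=int)
        corrected = plate.values - plate.values[nc].mean()
        names = plate.source_names
        if source_names is None:
            source_names = names
        elif names != source_names:
            raise ValueError("plates disagree on carbon-source layout")
        cols[f"{plate.condition}_{plate.replicate}"] = corrected[plate.source_wells]
    corrected_df = pd.DataFrame(cols, index=source_names)
    arr = corrected_df.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    zero_var = sd.ravel() == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (arr - mu) / safe_sd
    z[zero_var, :] = 0.0
    flagged = [source_names[i] for i in np.flatnonzero(zero_var)]
    if flagged:
        warnings.warn(
            f"{len(flagged)} zero-variance carbon sources; Z rows set to 0",
            stacklevel=2,
        )
    z_df = pd.DataFrame(z, index=source_names, columns=corrected_df.columns)
    return BiologResult(
        corrected=corrected_df, zscores=z_df, zero_variance_sources=flagged
    )


# --------------------------------------------------------------------------
# relative cell numbers
# --------------------------------------------------------------------------

def compare_cell_counts(
    summaries: pd.DataFrame, vehicle: str = "vehicle"
) -> pd.DataFrame:
    """Relative cell number per well vs the vehicle median at the same timepoint.

    Adds ``relative_count`` (n_cells over the timepoint's vehicle median)
    and a ``zero_cells`` flag. Requires vehicle wells at every timepoint.
    """
    df = summaries.copy()
    if "timepoint" not in df.columns:
        df["timepoint"] = ""
    out = []
    for tp, grp in df.groupby("timepoint", sort=False):
        veh = grp[(grp["compound"] == vehicle) & ~grp["with_agonist"]]
        if len(veh) == 0:
            raise ValueError(f"no vehicle wells at timepoint {tp!r}")
        ref = float(veh["n_cells"].median())
        g = grp.copy()
        g["relative_count"] = g["n_cells"] / ref if ref > 0 else np.nan
        g["zero_cells"] = g["n_cells"] == 0
        out.append(g)
    return pd.concat(out, ignore_index=True)
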