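"""Bacterial-positive cell calling and niche annotation for spatial transcript data.

Operates on transcript-level output of spatial molecular imaging: one row per
detected transcript with a target name, a probe class (host transcript,
bacterial 16S, or negative probe), µm-scale x/y/z coordinates, the field of
view (FOV) and the segmented cell id (null for extracellular transcripts).

The calling chain:

* per-cell background from negative probes (a dataset-wide negative-probe
  rate times the cell's total counts, floored at the 5th percentile of
  non-zero backgrounds);
* bacterial counts normalized to that background;
* a positivity threshold selected by ROC on confident pseudo-labels
  (zero-count cells as negatives, normalized counts > 20 as positives);
* a geometric intracellularity check: high-confidence cells require the
  median bacterial position to sit within the central 50% of all the cell's
  transcript positions on every axis;
* per-FOV intracellular/extracellular transcript densities;
* 30 µm / 100 µm neighborhood labels around tumor cells and a
  dissimilar-cell-type neighbor-expression covariate for downstream models.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GeometryError, ThresholdError

BACTERIAL_CLASSES = frozenset({"bacterial"})
NEGPROBE_CLASSES = frozenset({"negprobe_host", "negprobe_bact"})

#: Cells below this total-transcript count are dropped before any computation.
MIN_TOTAL_TRANSCRIPTS = 20

#: Normalized-count cutoff defining robust pseudo-positive cells for the ROC.
PSEUDO_POSITIVE_CUTOFF = 20.0


@dataclass(frozen=True)
class FovGeometry:
    """Fixed FOV pixel geometry; area in µm² derives from it."""

    edge_pixels: int = 4256
    pixel_size_um: float = 0.12

    @property
    def edge_um(self) -> float:
        return self.edge_pixels * self.pixel_size_um

    @property
    def area_um2(self) -> float:
        return self.edge_um**2


def qc_cells(cells: pd.DataFrame, min_total: int = MIN_TOTAL_TRANSCRIPTS) -> pd.DataFrame:
    """Drop cells with fewer than ``min_total`` total transcripts."""
    return cells[cells["total_counts"] >= min_total].copy()


def cell_centroids(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell centroid (mean transcript position) for tables lacking x_um/y_um."""
    intra = transcripts[transcripts["cell_id"].notna()]
    return intra.groupby("cell_id")[["x_um", "y_um"]].mean()


def _per_cell_class_counts(transcripts: pd.DataFrame, classes: frozenset) -> pd.Series:
    t = transcripts[transcripts["probe_class"].isin(classes) & transcripts["cell_id"].notna()]
    return t.groupby("cell_id").size()


def estimate_background(
    cells: pd.DataFrame, transcripts: pd.DataFrame, per_probe_mean: bool = False
) -> pd.Series:
    """Per-cell negative-probe background level.

    The dataset-wide background rate is the total intracellular negative-probe
    count divided by the total transcript count over all (QC-passing) cells;
    each cell's background is that rate times its total counts, floored at the
    5th percentile of the non-zero backgrounds so low-RNA cells cannot inflate
    the normalized values. ``per_probe_mean`` switches to a variant rate
    computed as the mean negative-probe count per probe per cell, scaled by
    relative cell totals.
    """
    neg = _per_cell_class_counts(transcripts, NEGPROBE_CLASSES)
    neg_total = float(neg.reindex(cells["cell_id"], fill_value=0).sum())
    grand_total = float(cells["total_counts"].sum())
    if grand_total <= 0:
        raise ValueError("cells carry no transcripts")
    if per_probe_mean:
        # variant: average the per-cell negprobe fraction instead of pooling
        per_cell_neg = neg.reindex(cells["cell_id"], fill_value=0).to_numpy(float)
        totals = cells["total_counts"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(totals > 0, per_cell_neg / totals, 0.0)
        p = float(ratios.mean())
    else:
        p = neg_total / grand_total
    if p == 0:
        warnings.warn("no negative-probe counts dataset-wide; backgrounds all floored")
    b = p * cells["total_counts"].astype(float)
    nonzero = b[b > 0]
    if len(nonzero):
        q05 = float(np.percentile(nonzero, 5))
        b = b.clip(lower=q05)
    b.index = cells["cell_id"].values
    return b


def normalize_bacterial(raw_bact: pd.Series, background: pd.Series) -> pd.Series:
    """Raw bacterial counts divided by the cell-specific background."""
    bg = background.reindex(raw_bact.index)
    if (bg <= 0).all():
        raise ValueError("all backgrounds are zero; cannot normalize")
    return raw_bact.astype(float) / bg


def roc_threshold(
    norm_bact: pd.Series,
    raw_bact: pd.Series,
    pseudo_positive_cutoff: float = PSEUDO_POSITIVE_CUTOFF,
) -> float:
    """Positivity threshold maximizing Youden's J on confident pseudo-labels.

    Pseudo-negatives are cells with zero raw bacterial counts; pseudo-positives
    have normalized counts above ``pseudo_positive_cutoff``. Candidate
    thresholds are midpoints between consecutive sorted unique normalized
    values of the labelled subset; ties on J resolve to the smallest candidate.
    """
    neg = norm_bact[raw_bact.reindex(norm_bact.index) == 0]
    pos = norm_bact[norm_bact > pseudo_positive_cutoff]
    if len(neg) == 0:
        raise ThresholdError("no pseudo-negative cells (zero bacterial counts)")
    if len(pos) == 0:
        raise ThresholdError(
            f"no pseudo-positive cells (normalized counts > {pseudo_positive_cutoff})"
        )
    labelled = np.concatenate([neg.to_numpy(float), pos.to_numpy(float)])
    labels = np.concatenate([np.zeros(len(neg)), np.ones(len(pos))])
    uniq = np.unique(labelled)
    if uniq.size < 2:
        raise ThresholdError("pseudo-labelled values are degenerate")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_j = -np.inf
    best_t = candidates[0]
    for t in candidates:
        called = labelled > t
        sens = called[labels == 1].mean()
        spec = (~called[labels == 0]).mean()
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j = j
            best_t = t
    return float(best_t)


def call_positive(norm_bact: pd.Series, threshold: float) -> pd.Series:
    """Strictly-greater-than positivity call on normalized bacterial counts."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return norm_bact > threshold


def central50_intracellular(cell_transcripts: pd.DataFrame) -> tuple[bool, str]:
    """Geometric high-confidence check for one cell's transcripts.

    On each axis independently, the median of the cell's bacterial transcript
    coordinates must lie within [Q1, Q3] (inclusive, linear interpolation) of
    the coordinates of *all* the cell's transcripts. Returns the flag and a
    reason code for audit trails.
    """
    bact = cell_transcripts[cell_transcripts["probe_class"].isin(BACTERIAL_CLASSES)]
    if len(cell_transcripts) < 4:
        return False, "fewer than 4 transcripts"
    if len(bact) < 1:
        return False, "no bacterial transcripts"
    for axis in ("x_um", "y_um", "z_um"):
        med = float(np.median(bact[axis]))
        q1, q3 = np.percentile(cell_transcripts[axis].to_numpy(float), [25, 75])
        if not (q1 <= med <= q3):
            return False, f"median outside central 50% on {axis}"
    return True, "ok"


def annotate_high_confidence(
    cells: pd.DataFrame, transcripts: pd.DataFrame, positive: pd.Series
) -> pd.Series:
    """Apply the central-50% criterion to every positive cell."""
    intra = transcripts[transcripts["cell_id"].notna()]
    grouped = dict(tuple(intra.groupby("cell_id")))
    flags = {}
    for cid in cells["cell_id"]:
        if not bool(positive.get(cid, False)):
            flags[cid] = False
            continue
        grp = grouped.get(cid)
        flags[cid] = central50_intracellular(grp)[0] if grp is not None else False
    return pd.Series(flags)


def fov_density(
    transcripts: pd.DataFrame, cells: pd.DataFrame, geom: FovGeometry = FovGeometry()
) -> pd.DataFrame:
    """Per-FOV intracellular and extracellular bacterial transcript densities.

    Intracellular density divides the FOV's cell-assigned bacterial transcript
    count by the summed segmented cell area; extracellular density divides the
    unassigned count by the FOV area minus the summed cell area. Units are
    transcripts per µm².
    """
    bact = transcripts[transcripts["probe_class"].isin(BACTERIAL_CLASSES)]
    rows = []
    for fov, cell_grp in cells.groupby("fov"):
        cell_area = float(cell_grp["area_um2"].sum())
        if cell_area >= geom.area_um2:
            raise GeometryError(
                f"FOV {fov}: summed cell area {cell_area} µm² >= FOV area {geom.area_um2} µm²"
            )
        fb = bact[bact["fov"] == fov]
        n_intra = int(fb["cell_id"].notna().sum())
        n_extra = int(fb["cell_id"].isna().sum())
        rows.append(
            {
                "fov": fov,
                "n_intracellular": n_intra,
                "n_extracellular": n_extra,
                "intracellular_density": n_intra / cell_area if cell_area > 0 else np.nan,
                "extracellular_density": n_extra / (geom.area_um2 - cell_area),
            }
        )
    return pd.DataFrame(rows).set_index("fov")


def summarize_density(density: pd.DataFrame) -> dict:
    """Median / min / max of the per-FOV densities."""
    out = {}
    for col in ("intracellular_density", "extracellular_density"):
        v = density[col].dropna()
        out[col] = {
            "median": float(v.median()) if len(v) else np.nan,
            "min": float(v.min()) if len(v) else np.nan,
            "max": float(v.max()) if len(v) else np.nan,
        }
    return out


def annotate_neighborhoods(
    cells: pd.DataFrame,
    positive: pd.Series,
    radius_um: float = 30.0,
    exclusion_um: float = 100.0,
) -> pd.Series:
    """Label each cell's niche relative to 16S-positive and -negative tumor cells.

    Positive neighborhoods: cells within ``radius_um`` (2-D Euclidean,
    centroid to centroid) of any 16S-positive tumor cell. Candidate negative
    neighborhoods: within ``radius_um`` of a 16S-negative tumor cell. Cells
    farther than ``radius_um`` from every tumor cell are excluded, as are
    candidate negatives within ``exclusion_um`` of the closest 16S-positive
    cell. Positive labels take precedence. Neighborhoods are evaluated within
    each FOV separately (coordinates are FOV-local).
    """
    labels = pd.Series("excluded", index=cells["cell_id"].values, dtype=object)
    for _, grp in cells.groupby("fov"):
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        ids = grp["cell_id"].to_numpy()
        is_tumor = grp["is_tumor"].astype(bool).to_numpy()
        pos = positive.reindex(ids).fillna(False).astype(bool).to_numpy()
        if not is_tumor.any():
            warnings.warn("no tumor cells in an FOV; all its cells excluded")
            continue
        tree = cKDTree(xy)
        pos_tumor_idx = np.where(is_tumor & pos)[0]
        neg_tumor_idx = np.where(is_tumor & ~pos)[0]
        pos_any_idx = np.where(pos)[0]

        near_pos_tumor = _within(tree, xy, pos_tumor_idx, radius_um)
        near_neg_tumor = _within(tree, xy, neg_tumor_idx, radius_um)
        near_pos_any = _within(tree, xy, pos_any_idx, exclusion_um)

        lab = np.full(len(grp), "excluded", dtype=object)
        cand_neg = near_neg_tumor & ~near_pos_any
        lab[cand_neg] = "negative_nh"
        lab[near_pos_tumor] = "positive_nh"
        labels.loc[ids] = lab
    return labels


def _within(tree: cKDTree, xy: np.ndarray, anchor_idx: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of points within ``radius`` of any anchor point."""
    mask = np.zeros(len(xy), dtype=bool)
    if len(anchor_idx) == 0:
        return mask
    anchor_tree = cKDTree(xy[anchor_idx])
    for i, neighbors in enumerate(anchor_tree.query_ball_point(xy, r=radius)):
        if neighbors:
            mask[i] = True
    return mask


def neighbor_expression_covariate(
    cells: pd.DataFrame, panel_totals: pd.Series, radius_um: float = 30.0
) -> pd.Series:
    """Summed panel expression of dissimilar-cell-type neighbors, per cell.

    For each cell, sums ``panel_totals`` (per-cell total counts over the
    analyzed gene panel) across the cells within ``radius_um`` (2-D, same FOV)
    whose cell type differs from the cell's own. Used as a fixed-effect
    covariate guarding differential expression against segmentation spillover.
    """
    out = pd.Series(0.0, index=cells["cell_id"].values)
    for _, grp in cells.groupby("fov"):
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        ids = grp["cell_id"].to_numpy()
        ctype = grp["cell_type"].to_numpy()
        totals = panel_totals.reindex(ids).fillna(0.0).to_numpy(float)
        tree = cKDTree(xy)
        for i, neighbors in enumerate(tree.query_ball_point(xy, r=radius_um)):
            s = 0.0
            for j in neighbors:
                if j != i and ctype[j] != ctype[i]:
                    s += totals[j]
            out.loc[ids[i]] = s
    return out


def positivity_percent(n_positive: int, n_cells: int, ndigits: int = 2) -> float:
    """Percentage of analyzed cells called positive, at report precision."""
    if n_cells <= 0:
        return float("nan")
    return round(100.0 * n_positive / n_cells, ndigits)


def run_spatial_calling(
    transcripts: pd.DataFrame,
    cells: pd.DataFrame,
    pseudo_positive_cutoff: float = PSEUDO_POSITIVE_CUTOFF,
    nh_radius_um: float = 30.0,
    excl_radius_um: float = 100.0,
    geom: FovGeometry = FovGeometry(),
) -> tuple[pd.DataFrame, dict]:
    """Full calling chain; returns the augmented cell table and a summary dict."""
    cells = qc_cells(cells)
    cells = cells.reset_index(drop=True)
    raw = _per_cell_class_counts(transcripts, BACTERIAL_CLASSES)
    raw_bact = raw.reindex(cells["cell_id"], fill_value=0).astype(int)
    raw_bact.index = cells["cell_id"].values
    background = estimate_background(cells, transcripts)
    norm_bact = normalize_bacterial(raw_bact, background)
    threshold = roc_threshold(norm_bact, raw_bact, pseudo_positive_cutoff)
    positive = call_positive(norm_bact, threshold)
    high_conf = annotate_high_confidence(cells, transcripts, positive)
    nh = annotate_neighborhoods(cells, positive, nh_radius_um, excl_radius_um)

    out = cells.copy()
    out["raw_bact"] = raw_bact.values
    out["norm_bact"] = norm_bact.values
    out["background"] = background.reindex(out["cell_id"]).values
    out["positive"] = positive.reindex(out["cell_id"]).values
    out["high_confidence"] = high_conf.reindex(out["cell_id"]).values
    out["nh_label"] = nh.reindex(out["cell_id"]).values

    density = fov_density(transcripts, cells, geom)
    summary = {
        "threshold": threshold,
        "n_cells": int(len(out)),
        "n_positive": int(out["positive"].sum()),
        "n_high_confidence": int(out["high_confidence"].sum()),
        "high_confidence_percent": positivity_percent(
            int(out["high_confidence"].sum()), int(len(out))
        ),
        "density": summarize_density(density),
    }
    return out, summary
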