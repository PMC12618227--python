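"""Numeric procedures for digital spatial profiling (DSP) ROI count matrices.

A DSP run yields a targets × ROIs count matrix in which some rows are
negative probes (no biological target; they estimate background), some are
bacterial 16S probes, and — in protein mode — some are IgG isotype controls.
This module implements the standard processing chain for such matrices:

* ROI sequencing QC (aligned-read fraction, saturation, total reads);
* the per-ROI limit of quantification, LOQ = geomean(negprobes) · geoSD(negprobes)^n;
* the two-pass 10% detection filter (ROIs first, then targets);
* background subtraction plus Q3 normalization for whole-transcriptome counts
  and background division for the 16S probe set;
* quartile annotation of ROIs into low/mid/high 16S regions;
* log2 pre-thresholding (values < 1 raised to the largest sub-1 value);
* the protein-mode signal-to-noise filter against the IgG background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnnotationError, EmptyResultError

#: Pseudo-count replacing zeros before log-domain statistics.
ZERO_PSEUDOCOUNT = 0.5


@dataclass
class RoiMatrix:
    """Counts matrix (targets × ROIs) with probe classes and per-ROI QC fields.

    ``probe_class`` maps each target to one of {analyte, negprobe, bact16s,
    igg}; ``roi_qc`` has one row per ROI with columns ``aligned_frac``,
    ``saturation`` and ``total_reads``.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    roi_qc: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.probe_class = self.probe_class.reindex(self.counts.index)
        if self.probe_class.isna().any():
            raise ValueError("every target needs a probe_class")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def rows(self, cls: str) -> pd.Index:
        return self.probe_class.index[self.probe_class == cls]

    @property
    def analyte_rows(self) -> pd.Index:
        return self.rows("analyte")

    @property
    def negprobe_rows(self) -> pd.Index:
        return self.rows("negprobe")

    @property
    def bact16s_rows(self) -> pd.Index:
        return self.rows("bact16s")

    @property
    def igg_rows(self) -> pd.Index:
        return self.rows("igg")

    def subset(self, targets=None, rois=None) -> "RoiMatrix":
        counts = self.counts
        if targets is not None:
            counts = counts.loc[targets]
        if rois is not None:
            counts = counts[rois]
        qc = self.roi_qc.loc[counts.columns] if len(self.roi_qc) else self.roi_qc
        return RoiMatrix(counts.copy(), self.probe_class.reindex(counts.index), qc.copy())


def geomean(values: np.ndarray, pseudocount: float = ZERO_PSEUDOCOUNT) -> float:
    v = np.asarray(values, dtype=float)
    v = np.where(v <= 0, pseudocount, v)
    return float(np.exp(np.mean(np.log(v))))


def geosd(values: np.ndarray, pseudocount: float = ZERO_PSEUDOCOUNT) -> float:
    """Geometric standard deviation; defined as 1 for a single value."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 1.0
    v = np.where(v <= 0, pseudocount, v)
    return float(np.exp(np.std(np.log(v), ddof=1)))


def roi_qc_filter(
    m: RoiMatrix,
    min_aligned: float = 0.80,
    min_saturation: float = 0.50,
    min_reads: int = 1000,
) -> RoiMatrix:
    """Keep ROIs with aligned fraction >= 80%, saturation > 50% and >= 1,000 reads."""
    qc = m.roi_qc
    keep = (
        (qc["aligned_frac"] >= min_aligned)
        & (qc["saturation"] > min_saturation)
        & (qc["total_reads"] >= min_reads)
    )
    kept = qc.index[keep]
    if len(kept) == 0:
        raise EmptyResultError("no ROI passes sequencing QC")
    return m.subset(rois=kept)


def compute_loq(m: RoiMatrix, n_sd: float = 2.0) -> pd.Series:
    """Per-ROI limit of quantification from the negative probes.

    LOQ = geomean(negprobe values) · geoSD(negprobe values)^n_sd, computed in
    log space with zeros replaced by the pseudo-count. With a single negative
    probe the geometric SD is 1 by convention and the LOQ equals that value.
    """
    neg = m.counts.loc[m.negprobe_rows]
    if len(neg) == 0:
        raise ValueError("matrix has no negative-probe rows")
    return pd.Series(
        {roi: geomean(neg[roi]) * geosd(neg[roi]) ** n_sd for roi in neg.columns},
        name="loq",
    )


def detection_filter(
    m: RoiMatrix, loq: pd.Series, min_roi_rate: float = 0.10, min_target_rate: float = 0.10
) -> RoiMatrix:
    """Two-pass detection filter against the per-ROI LOQ.

    A target is detected in an ROI when its count strictly exceeds the ROI's
    LOQ. ROIs detecting fewer than ``min_roi_rate`` of the analyte targets are
    dropped first; then analyte targets detected in fewer than
    ``min_target_rate`` of the surviving ROIs are dropped. Non-analyte rows
    (negative probes, 16S, IgG) ride along untouched.
    """
    analytes = m.analyte_rows
    detected = m.counts.loc[analytes].gt(loq[m.counts.columns], axis=1)
    roi_rate = detected.mean(axis=0)
    keep_rois = roi_rate.index[roi_rate >= min_roi_rate]
    if len(keep_rois) == 0:
        raise EmptyResultError("detection filter removed every ROI")
    target_rate = detected[keep_rois].mean(axis=1)
    keep_targets = target_rate.index[target_rate >= min_target_rate]
    if len(keep_targets) == 0:
        raise EmptyResultError("detection filter removed every target")
    keep_all = keep_targets.union(m.counts.index.difference(analytes), sort=False)
    keep_all = m.counts.index[m.counts.index.isin(keep_all)]  # preserve row order
    return m.subset(targets=keep_all, rois=keep_rois)


def normalize_wta(m: RoiMatrix) -> pd.DataFrame:
    """Background subtraction followed by Q3 normalization of the analyte rows.

    Per ROI, the negative-probe geometric mean is subtracted (floored at 0);
    each ROI is then scaled so its 75th-percentile analyte value equals the
    geometric mean of the per-ROI Q3 values — the fixed point of the
    transform. ROIs whose Q3 is 0 are dropped with a warning.
    """
    import warnings

    neg = m.counts.loc[m.negprobe_rows]
    analytes = m.counts.loc[m.analyte_rows].astype(float)
    bg = pd.Series({roi: geomean(neg[roi]) for roi in m.counts.columns})
    sub = analytes.sub(bg, axis=1).clip(lower=0.0)
    q3 = sub.quantile(0.75, axis=0)
    good = q3.index[q3 > 0]
    if len(good) < len(q3):
        warnings.warn(f"dropping {len(q3) - len(good)} ROI(s) with zero Q3")
        sub = sub[good]
        q3 = q3[good]
    target = float(np.exp(np.mean(np.log(q3))))
    return sub.mul(target / q3, axis=1)


def normalize_16s(m: RoiMatrix) -> pd.DataFrame:
    """Background normalization of the 16S probe rows (division by negprobe geomean)."""
    neg = m.counts.loc[m.negprobe_rows]
    bg = pd.Series({roi: geomean(neg[roi]) for roi in m.counts.columns})
    return m.counts.loc[m.bact16s_rows].astype(float).div(bg, axis=1)


def annotate_16s_status(m: RoiMatrix) -> pd.DataFrame:
    """Quartile-based low/mid/high 16S annotation of ROIs.

    Per ROI, the geometric mean of the background-normalized 16S probe values;
    ROIs at or below the 25th percentile of these geomeans are ``low``, at or
    above the 75th percentile ``high``, otherwise ``mid``. A degenerate
    all-equal vector resolves every ROI to ``mid``.
    """
    norm16s = normalize_16s(m)
    if norm16s.shape[1] < 4:
        raise AnnotationError("need >= 4 ROIs for quartile annotation")
    gm = pd.Series({roi: geomean(norm16s[roi]) for roi in norm16s.columns}, name="geomean_16s")
    q1, q3 = np.percentile(gm.to_numpy(float), [25, 75])
    if np.isclose(q1, q3):
        status = pd.Series("mid", index=gm.index)
    else:
        status = pd.Series("mid", index=gm.index, dtype=object)
        status[gm <= q1] = "low"
        status[gm >= q3] = "high"
    return pd.DataFrame({"geomean_16s": gm, "status": status})


def log2_threshold(values: pd.DataFrame) -> pd.DataFrame:
    """Raise values below 1 to the largest value below 1 (log2 pre-threshold)."""
    arr = values.to_numpy(float)
    below = arr[arr < 1.0]
    if below.size == 0:
        return values.copy()
    floor = float(below.max())
    out = values.copy()
    out[out < 1.0] = floor
    return out


def protein_snr_filter(
    m: RoiMatrix, min_snr: float = 2.0, min_roi_fraction: float = 0.10
) -> pd.DataFrame:
    """IgG-based selection and normalization of protein targets.

    Per ROI the noise floor is the geometric mean of the IgG rows; a protein
    is kept when its signal-to-noise ratio exceeds ``min_snr`` in at least
    ``min_roi_fraction`` of the ROIs. Kept counts are divided by the per-ROI
    IgG geometric mean (background normalization).
    """
    import warnings

    igg = m.counts.loc[m.igg_rows]
    if len(igg) == 0:
        raise ValueError("protein mode needs IgG rows")
    noise = pd.Series({roi: geomean(igg[roi]) for roi in m.counts.columns})
    if (noise <= 0).any():
        warnings.warn("zero IgG geomean; pseudo-count applied")
        noise = noise.clip(lower=ZERO_PSEUDOCOUNT)
    proteins = m.counts.loc[m.analyte_rows].astype(float)
    snr = proteins.div(noise, axis=1)
    keep = (snr > min_snr).mean(axis=1) >= min_roi_fraction
    return proteins.loc[keep.index[keep]].div(noise, axis=1)
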