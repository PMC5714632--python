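"""Image-quality and CBCT-number consistency metrics.

ROI statistics, contrast-to-noise ratio, bolus/no-bolus consistency
summaries and piecewise-linear CBCT-number -> relative-electron-density
conversion curves — the quantitative layer that turns reconstructions
into the tables a physicist would report.

CNR is defined as |mean_fg - mean_bg| / std_bg. Summary standard
deviations use the sample (n-1) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantoms import ROISpec


def roi_mask(shape, voxel_size, origin, roi: ROISpec) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside a circular ROI."""
    ny, nx = shape
    dy, dx = voxel_size
    y = origin[0] + (np.arange(ny) + 0.5) * dy
    x = origin[1] + (np.arange(nx) + 0.5) * dx
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return (yy - roi.center[0]) ** 2 + (xx - roi.center[1]) ** 2 <= roi.radius**2


def roi_stats(image: np.ndarray, roi: ROISpec, voxel_size, origin):
    """(mean, sample std, n_voxels) of the image values inside the ROI."""
    mask = roi_mask(image.shape, voxel_size, origin, roi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"ROI {roi.label!r} contains no voxels")
    vals = image[mask]
    std = float(vals.std(ddof=1)) if n > 1 else 0.0
    return float(vals.mean()), std, n


def cnr(image: np.ndarray, roi_fg: ROISpec, roi_bg: ROISpec,
        voxel_size, origin) -> float:
    """Contrast-to-noise ratio |mean_fg - mean_bg| / std_bg."""
    m_fg, _, _ = roi_stats(image, roi_fg, voxel_size, origin)
    m_bg, s_bg, _ = roi_stats(image, roi_bg, voxel_size, origin)
    if s_bg == 0:
        raise ValueError("background std is zero: CNR undefined")
    return abs(m_fg - m_bg) / s_bg


@dataclass
class ConsistencyReport:
    """Per-insert values under two conditions and their |difference|,
    with mean/min/max/sample-std of the differences."""

    per_insert: pd.DataFrame  # label, value_a, value_b, abs_difference
    mean: float
    min: float
    max: float
    std: float

    def summary_rounded(self) -> tuple[int, int, int, int]:
        r = lambda v: int(round(v))
        return r(self.mean), r(self.min), r(self.max), r(self.std)

    def to_frame(self) -> pd.DataFrame:
        return self.per_insert.copy()


def consistency_summary(pairs) -> ConsistencyReport:
    """Summarize absolute per-insert differences between two conditions.

    ``pairs``: iterable of (label, value_a, value_b); labels must be
    unique and at least two pairs are required.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least two insert pairs")
    labels = [p[0] for p in pairs]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate insert labels: {dupes}")
    df = pd.DataFrame(pairs, columns=["label", "value_a", "value_b"])
    df["abs_difference"] = (df["value_a"] - df["value_b"]).abs()
    d = df["abs_difference"].to_numpy(float)
    return ConsistencyReport(
        per_insert=df, mean=float(d.mean()), min=float(d.min()),
        max=float(d.max()), std=float(d.std(ddof=1)))


@dataclass
class CalibrationCurve:
    """Piecewise-linear map from CBCT number to relative electron density."""

    knots_cbct: np.ndarray
    knots_ed: np.ndarray
    interpolation: str = "piecewise_linear"

    def __call__(self, cbct_number):
        return np.interp(cbct_number, self.knots_cbct, self.knots_ed)


def fit_calibration_curve(measurements) -> CalibrationCurve:
    """Build a CBCT-number -> ED lookup from (cbct_number, ED) points.

    Points are ordered by CBCT number; exact CBCT-number ties are merged
    by averaging their electron densities. Evaluating the curve at a knot
    returns that knot's ED exactly; outside the knot range the end values
    are held (clamped extrapolation).
    """
    pts = sorted((float(c), float(e)) for c, e in measurements)
    if len(pts) < 2:
        raise ValueError("need at least two calibration points")
    if any(e <= 0 for _, e in pts):
        raise ValueError("electron densities must be strictly positive")
    cbct, ed = [], []
    i = 0
    while i < len(pts):
        j = i
        while j < len(pts) and pts[j][0] == pts[i][0]:
            j += 1
        cbct.append(pts[i][0])
        ed.append(float(np.mean([pts[k][1] for k in range(i, j)])))
        i = j
    if len(cbct) < 2:
        raise ValueError("calibration points degenerate after tie-averaging: "
                         f"all share CBCT number {cbct[0]}")
    return CalibrationCurve(np.array(cbct), np.array(ed))


def table2_summary(report_original: ConsistencyReport,
                   report_processed: ConsistencyReport,
                   report_bowtie: ConsistencyReport | None = None) -> pd.DataFrame:
    """Max/mean/min difference rows per condition, table-style."""
    reports = {"original": report_original, "processed": report_processed}
    if report_bowtie is not None:
        reports["bowtie"] = report_bowtie
    ref = set(report_original.per_insert["label"])
    for name, rep in reports.items():
        if set(rep.per_insert["label"]) != ref:
            raise ValueError(f"insert labels of report {name!r} do not match")
    data = {name: [rep.max, rep.mean, rep.min] for name, rep in reports.items()}
    return pd.DataFrame(data, index=["maximum", "mean", "minimum"])
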