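"""ROI dosimetry reporting: histograms, summary statistics, comparisons.

Descriptive only -- voxels inside an ROI are not independent samples,
so no inferential statistics are attached to ROI contrasts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Default exposure binning: 50 uniform bins on [0, 1] V/m.
DEFAULT_BIN_EDGES = np.linspace(0.0, 1.0, 51)


@dataclass
class HistogramRecord:
    """Binned ROI exposure distribution with out-of-range bookkeeping."""

    bin_edges: np.ndarray
    counts: np.ndarray
    omitted_above: int            # values > clip_max, not binned
    below_range: int              # values below the first edge
    n_voxels: int


@dataclass
class StatsRecord:
    """mean / sd (n-1) / median / 99th percentile over ROI voxels, V/m."""

    mean: float
    sd: float
    median: float
    p99: float
    n_voxels: int


@dataclass
class ROIReport:
    name: str
    stats: StatsRecord
    histogram: HistogramRecord
    metadata: dict = field(default_factory=dict)


def roi_histogram(map_values: np.ndarray, roi_mask: np.ndarray,
                  bin_edges: np.ndarray | None = None,
                  clip_max: float = 1.0) -> HistogramRecord:
    """Histogram of exposure values inside an ROI.

    Bins are left-closed right-open with a right-closed final bin
    (numpy convention); values above ``clip_max`` (or above the last
    edge) are counted as omitted, values below the first edge as
    below-range, so counts always conserve the ROI voxel total.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("ROI mask is empty")
    edges = np.asarray(DEFAULT_BIN_EDGES if bin_edges is None else bin_edges,
                       dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigurationError("bin edges must be strictly increasing")
    v = np.asarray(map_values)[mask]
    cut = min(clip_max, edges[-1])
    above = int(np.count_nonzero(v > cut))
    below = int(np.count_nonzero(v < edges[0]))
    counts, _ = np.histogram(v[(v <= cut) & (v >= edges[0])], bins=edges)
    return HistogramRecord(bin_edges=edges, counts=counts,
                           omitted_above=above, below_range=below,
                           n_voxels=int(mask.sum()))


def roi_summary(map_values: np.ndarray, roi_mask: np.ndarray) -> StatsRecord:
    """Summary statistics over ROI voxels (sd with n-1 denominator,
    percentiles by linear interpolation)."""
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("ROI mask is empty")
    v = np.asarray(map_values, dtype=float)[mask]
    return StatsRecord(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        median=float(np.median(v)),
        p99=float(np.percentile(v, 99)),
        n_voxels=int(v.size),
    )


def build_reports(map_values: np.ndarray, roi_masks: dict,
                  bin_edges: np.ndarray | None = None, clip_max: float = 1.0,
                  metadata: dict | None = None) -> dict:
    """One :class:`ROIReport` per named ROI mask."""
    return {
        name: ROIReport(
            name=name,
            stats=roi_summary(map_values, mask),
            histogram=roi_histogram(map_values, mask, bin_edges, clip_max),
            metadata=dict(metadata or {}),
        )
        for name, mask in roi_masks.items()
    }


def compare_conditions(reports_a: dict, reports_b: dict,
                       label_a: str = "a", label_b: str = "b") -> pd.DataFrame:
    """Side-by-side ROI statistics and mean/median differences (a - b)."""
    names_a, names_b = set(reports_a), set(reports_b)
    if names_a != names_b:
        only_a = sorted(names_a - names_b)
        only_b = sorted(names_b - names_a)
        raise ConfigurationError(
            f"ROI name mismatch: only in {label_a}: {only_a}; "
            f"only in {label_b}: {only_b}")
    rows = []
    for name in sorted(names_a):
        sa, sb = reports_a[name].stats, reports_b[name].stats
        rows.append({
            "roi": name,
            f"mean_{label_a}": sa.mean, f"mean_{label_b}": sb.mean,
            f"sd_{label_a}": sa.sd, f"sd_{label_b}": sb.sd,
            f"median_{label_a}": sa.median, f"median_{label_b}": sb.median,
            f"p99_{label_a}": sa.p99, f"p99_{label_b}": sb.p99,
            "mean_diff": sa.mean - sb.mean,
            "median_diff": sa.median - sb.median,
        })
    return pd.DataFrame(rows)


def report_to_json(reports: dict, path) -> None:
    """Serialize ROI reports deterministically (sorted keys, fixed floats)."""
    payload = {}
    for name in sorted(reports):
        r = reports[name]
        payload[name] = {
            "stats": {k: round(float(v), 9) if isinstance(v, float) else v
                      for k, v in vars(r.stats).items()},
            "histogram": {
                "bin_edges": [round(float(e), 9) for e in r.histogram.bin_edges],
                "counts": [int(c) for c in r.histogram.counts],
                "omitted_above": r.histogram.omitted_above,
                "below_range": r.histogram.below_range,
                "n_voxels": r.histogram.n_voxels,
            },
            "metadata": r.metadata,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
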