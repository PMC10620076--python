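"""Montage enumeration, exposure metrics and pareto selection.

A montage is two electrode pairs (one per channel) drawn from
mirror-symmetric electrode quadruples.  Each montage is scored against
the 98% volumetric iso-percentile threshold of its TI exposure map with
three maximized objectives:

* target exposure strength -- median TI exposure inside the target mask
  (the mean is reported alongside; the median is robust to the skewed
  exposure distributions seen in deep targets),
* focality ratio -- % of suprathreshold brain volume inside the target,
* activation ratio -- % of the target volume that is suprathreshold,

and the pareto-optimal front is the set of montages not dominated on
all three at once.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SolverError
from .phantom import ElectrodeSpec, HeadPhantom, ROISet
from .solver import ChannelPair, normalize_current, solve_channel
from .ti import TIExposureMap, ti_envelope_map

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Montage:
    """Two channel pairs and the geometry class of their current paths."""

    pair1: ChannelPair
    pair2: ChannelPair
    geometry_class: str  # parallel-sagittal | parallel-coronal | crossing

    def __post_init__(self):
        labels = self.electrode_labels
        if len(set(labels)) != 4:
            raise ConfigurationError(
                f"montage electrodes must be distinct, got {labels}")

    @property
    def electrode_labels(self) -> tuple:
        return (self.pair1.anode.label, self.pair1.cathode.label,
                self.pair2.anode.label, self.pair2.cathode.label)

    @property
    def name(self) -> str:
        return f"{self.pair1.label}+{self.pair2.label}"


@dataclass
class ExposureMetrics:
    """Threshold-based exposure metrics for one montage."""

    threshold_V_per_m: float
    target_mean: float
    target_sd: float
    target_median: float
    target_p99: float
    focality_pct: float          # NaN when no voxel is suprathreshold
    activation_pct: float
    suprathreshold_brain_voxels: int


def iso_percentile_threshold(map_values: np.ndarray, brain_mask: np.ndarray,
                             p: float = 98.0) -> float:
    """p-th percentile of the exposure over brain voxels (linear interpolation).

    The suprathreshold set is defined by strict inequality (> threshold).
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("brain mask is empty")
    if not (0 < p < 100):
        raise ConfigurationError(f"percentile must lie in (0, 100), got {p}")
    return float(np.percentile(np.asarray(map_values)[mask], p))


def exposure_metrics(ti_map: TIExposureMap | np.ndarray, target_mask: np.ndarray,
                     brain_mask: np.ndarray, p: float = 98.0) -> ExposureMetrics:
    """Score one exposure map against the iso-percentile threshold."""
    values = ti_map.values if isinstance(ti_map, TIExposureMap) else np.asarray(ti_map)
    target = np.asarray(target_mask, dtype=bool)
    brain = np.asarray(brain_mask, dtype=bool)
    if not target.any() or not brain.any():
        raise ConfigurationError("target and brain masks must be nonempty")
    if (target & ~brain).any():
        raise ConfigurationError("target mask must be a subset of the brain mask")

    thr = iso_percentile_threshold(values, brain, p)
    supra = (values > thr) & brain
    n_supra = int(supra.sum())
    n_hit = int((supra & target).sum())
    focality = 100.0 * n_hit / n_supra if n_supra > 0 else float("nan")
    activation = 100.0 * n_hit / int(target.sum())

    tv = values[target]
    return ExposureMetrics(
        threshold_V_per_m=thr,
        target_mean=float(tv.mean()),
        target_sd=float(tv.std(ddof=1)) if tv.size > 1 else 0.0,
        target_median=float(np.median(tv)),
        target_p99=float(np.percentile(tv, 99)),
        focality_pct=focality,
        activation_pct=activation,
        suprathreshold_brain_voxels=n_supra,
    )


def homolog_pairs(electrodes: list[ElectrodeSpec],
                  tol: float = 1e-6) -> list[tuple[ElectrodeSpec, ElectrodeSpec]]:
    """Group electrodes into left/right mirror pairs about the mid-sagittal plane.

    An electrode with |x| < tol (midline) has no homolog and is ignored.
    """
    left = [e for e in electrodes if e.direction[0] < -tol]
    right = [e for e in electrodes if e.direction[0] > tol]
    pairs = []
    used = set()
    for l in left:
        mirror = np.array([-l.direction[0], l.direction[1], l.direction[2]])
        for r in right:
            if r.label in used:
                continue
            if np.linalg.norm(r.direction_arr - mirror) < tol:
                pairs.append((l, r))
                used.add(r.label)
                break
    return pairs


def enumerate_montages(electrodes: list[ElectrodeSpec],
                       f1_Hz: float = 2000.0, delta_f_Hz: float = 100.0,
                       current_mA: float = 1.0) -> list[Montage]:
    """All symmetric 4-electrode montages over the homolog pairs.

    For every unordered choice of two homolog pairs {L1,R1}, {L2,R2}
    three montages exist up to channel-swap and polarity-swap symmetry:

    * parallel-sagittal: (L1,L2) and (R1,R2) -- each channel within one
      hemisphere, anterior-posterior current paths;
    * parallel-coronal: (L1,R1) and (L2,R2) -- left-right paths;
    * crossing: (L1,R2) and (L2,R1) -- paths crossing the midline.

    With k homolog pairs the count is exactly 3 * C(k, 2).
    """
    if len(electrodes) < 4:
        raise ConfigurationError("montage enumeration needs >= 4 electrodes")
    pairs = homolog_pairs(electrodes)
    if len(pairs) < 2:
        raise ConfigurationError(
            "need at least two left/right homolog electrode pairs")
    f2 = f1_Hz + delta_f_Hz
    montages = []
    for (l1, r1), (l2, r2) in itertools.combinations(pairs, 2):
        def chan(a, c, f):
            return ChannelPair(anode=a, cathode=c, carrier_frequency_Hz=f,
                               current_mA=current_mA)
        montages.append(Montage(chan(l1, l2, f1_Hz), chan(r1, r2, f2),
                                "parallel-sagittal"))
        montages.append(Montage(chan(l1, r1, f1_Hz), chan(l2, r2, f2),
                                "parallel-coronal"))
        montages.append(Montage(chan(l1, r2, f1_Hz), chan(l2, r1, f2),
                                "crossing"))
    return montages


def pareto_front(objectives: np.ndarray) -> np.ndarray:
    """Non-domination flags over rows of maximized objectives.

    A row is flagged unless some other row is >= in every objective and
    > in at least one; equal rows are all flagged.  NaNs compare as
    -inf (a row with an undefined metric never beats a defined one).
    """
    obj = np.asarray(objectives, dtype=float)
    if obj.ndim != 2 or obj.shape[0] == 0:
        raise ConfigurationError("pareto_front needs a nonempty 2-D array")
    obj = np.where(np.isnan(obj), -np.inf, obj)
    n = obj.shape[0]
    flags = np.ones(n, dtype=bool)
    for i in range(n):
        dominated = np.all(obj >= obj[i], axis=1) & np.any(obj > obj[i], axis=1)
        if dominated.any():
            flags[i] = False
    return flags


def argmax_depth_mm(values: np.ndarray, phantom: HeadPhantom,
                    erode_voxels: int = 2) -> float:
    """Depth below the scalp surface of the interior-brain arg-max voxel.

    The brain mask is eroded by ``erode_voxels`` before taking the
    arg-max: at the gray/CSF interface the conductivity contrast makes
    the normal field jump, and the finite-difference gradient within two
    voxels of the boundary mixes the two tissues, so raw boundary voxels
    carry spuriously large magnitudes (cf. the edge-of-brain-mask noise
    conventionally omitted from exposure histograms).
    """
    from scipy.ndimage import binary_erosion

    brain = phantom.brain_mask.astype(bool)
    if erode_voxels > 0:
        brain = binary_erosion(brain, iterations=erode_voxels)
    if not brain.any():
        raise ConfigurationError("interior brain mask is empty after erosion")
    v = np.where(brain, values, -np.inf)
    idx = np.unravel_index(int(np.argmax(v)), v.shape)
    r = phantom.radius_volume_mm()[idx]
    return float(phantom.layer_radii_mm["scalp"] - r)


@dataclass
class SweepResult:
    """One scored row per montage plus provenance."""

    table: pd.DataFrame
    maps: dict = field(default_factory=dict)   # montage name -> TIExposureMap (optional)
    provenance: dict = field(default_factory=dict)


def run_sweep(phantom: HeadPhantom, roi_set: ROISet,
              electrodes: list[ElectrodeSpec],
              currents_mA: tuple = (1.0, 1.0), p: float = 98.0,
              tol: float = 1e-8, keep_maps: bool = False) -> SweepResult:
    """Score every enumerated montage; solves are cached per electrode pair.

    A failed solve marks its row ``failed`` and the sweep continues.
    Pareto flags are computed over (target median exposure, focality,
    activation), all maximized.
    """
    montages = enumerate_montages(electrodes, current_mA=currents_mA[0])
    cache: dict = {}

    def field_for(pair: ChannelPair):
        key = frozenset((pair.anode.label, pair.cathode.label))
        if key not in cache:
            pot, fld, injected = solve_channel(phantom, pair, tol=tol)
            _, fld = normalize_current(pot, fld, injected, 1.0)
            cache[key] = fld
        return cache[key]

    brain = roi_set["brain"]
    target = roi_set["target"]
    rows = []
    maps = {}
    for m in montages:
        row = {
            "montage": m.name,
            "geometry_class": m.geometry_class,
            "electrodes": ",".join(m.electrode_labels),
            "failed": False,
        }
        try:
            f1 = field_for(m.pair1)
            f2 = field_for(m.pair2)
            ti_map = ti_envelope_map(f1, f2, currents_mA[0], currents_mA[1])
            metrics = exposure_metrics(ti_map, target, brain, p=p)
        except SolverError as exc:
            log.warning("montage %s failed: %s", m.name, exc)
            row["failed"] = True
            row.update({k: float("nan") for k in
                        ("threshold_V_per_m", "target_mean", "target_sd",
                         "target_median", "target_p99", "focality_pct",
                         "activation_pct", "suprathreshold_brain_voxels")})
            rows.append(row)
            continue
        row.update(vars(metrics))
        rows.append(row)
        if keep_maps:
            maps[m.name] = ti_map

    table = pd.DataFrame(rows)
    ok = ~table["failed"].to_numpy()
    flags = np.zeros(len(table), dtype=bool)
    if ok.any():
        obj = table.loc[ok, ["target_median", "focality_pct",
                             "activation_pct"]].to_numpy(dtype=float)
        flags[np.flatnonzero(ok)] = pareto_front(obj)
    table["pareto"] = flags

    prov = {
        "spacing_mm": phantom.spacing_mm,
        "tol": tol,
        "currents_mA": list(currents_mA),
        "percentile": p,
        "n_montages": len(montages),
    }
    return SweepResult(table=table, maps=maps, provenance=prov)
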