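"""Layered-sphere head phantom, scalp electrodes and ROI masks.

The phantom stands in for a detailed anatomical head model: concentric
spherical shells (scalp, skull, CSF, gray matter, white matter) on a
regular isotropic voxel grid, with a bilateral deep spherical target
embedded in the brain.  All geometry is analytic, so label volumes are
deterministic and mirror-symmetric about the mid-sagittal plane.

Conventions
-----------
* World coordinates are millimetres on RAS axes (+x right, +y anterior,
  +z superior); voxel (i, j, k) maps to ``origin_mm + spacing_mm*(i,j,k)``
  (voxel centers).
* A voxel belongs to the innermost shell whose radius strictly exceeds
  the distance of its center from the head center.
* Masks are uint8 volumes on the phantom grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, InfeasibleROIError, UnknownElectrodeError

log = logging.getLogger(__name__)

# Tissue label codes
AIR = 0
SCALP = 1
SKULL = 2
CSF = 3
GRAY = 4
WHITE = 5
TARGET = 6

TISSUE_NAMES = {
    AIR: "air",
    SCALP: "scalp",
    SKULL: "skull",
    CSF: "csf",
    GRAY: "gray",
    WHITE: "white",
    TARGET: "deep_target",
}

#: Low-frequency conductivities in S/m.  Literature-scale defaults; every
#: value is overridable through :class:`PhantomConfig`.
DEFAULT_CONDUCTIVITY = {
    AIR: 0.0,
    SCALP: 0.4,
    SKULL: 0.01,
    CSF: 1.79,
    GRAY: 0.28,
    WHITE: 0.13,
    TARGET: 0.28,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the layered-sphere phantom.

    Radii are outer radii per shell in mm and must be strictly
    decreasing inward.  ``white_radius_mm`` splits the brain sphere into
    an outer gray shell and an inner white core.
    """

    spacing_mm: float = 2.0
    scalp_radius_mm: float = 92.0
    skull_radius_mm: float = 86.0
    csf_radius_mm: float = 80.0
    brain_radius_mm: float = 78.0
    white_radius_mm: float = 55.0
    target_radius_mm: float = 12.0
    target_lateral_mm: float = 20.0
    target_anterior_mm: float = 5.0
    target_superior_mm: float = 5.0
    conductivity: dict = field(default_factory=lambda: dict(DEFAULT_CONDUCTIVITY))
    margin_voxels: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not (1.0 <= self.spacing_mm <= 4.0):
            raise ConfigurationError(
                f"spacing_mm must lie in [1, 4] mm, got {self.spacing_mm}")
        radii = [self.scalp_radius_mm, self.skull_radius_mm,
                 self.csf_radius_mm, self.brain_radius_mm, self.white_radius_mm]
        if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])):
            raise ConfigurationError(
                "shell radii must be strictly decreasing inward "
                f"(scalp > skull > CSF > brain > white), got {radii}")
        if any(s < 0 for s in self.conductivity.values()):
            raise ConfigurationError("conductivities must be nonnegative")
        if self.conductivity.get(AIR, 0.0) != 0.0:
            raise ConfigurationError("air conductivity must be exactly 0")


@dataclass
class HeadPhantom:
    """Voxelized tissue-label volume plus grid and conductivity metadata."""

    labels: np.ndarray                  # uint8, shape (nx, ny, nz)
    spacing_mm: float
    origin_mm: np.ndarray               # world position of voxel (0,0,0) center
    head_center_mm: np.ndarray
    layer_radii_mm: dict                # tissue name -> outer radius
    conductivity_table: dict            # tissue code -> S/m
    config: PhantomConfig

    @property
    def shape(self) -> tuple:
        return tuple(self.labels.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing_mm ** 3)

    def conductivity_volume(self) -> np.ndarray:
        """Per-voxel conductivity in S/m (float64)."""
        lut = np.zeros(max(self.conductivity_table) + 1)
        for code, sigma in self.conductivity_table.items():
            lut[code] = sigma
        return lut[self.labels]

    def voxel_coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers, one 1-D array per axis."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm * np.arange(self.labels.shape[a])
            for a in range(3)
        )

    def radius_volume_mm(self) -> np.ndarray:
        """Distance of each voxel center from the head center (mm)."""
        x, y, z = self.voxel_coords_mm()
        cx, cy, cz = self.head_center_mm
        return np.sqrt(
            (x - cx)[:, None, None] ** 2
            + (y - cy)[None, :, None] ** 2
            + (z - cz)[None, None, :] ** 2
        )

    @property
    def brain_mask(self) -> np.ndarray:
        return np.isin(self.labels, (GRAY, WHITE, TARGET)).astype(np.uint8)

    @property
    def tissue_mask(self) -> np.ndarray:
        return (self.labels != AIR).astype(np.uint8)

    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass(frozen=True)
class ElectrodeSpec:
    """A circular scalp electrode given by its radial direction."""

    label: str
    direction: tuple          # unit 3-vector from head center to scalp
    radius_mm: float = 7.0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"electrode {self.label!r}: direction must be a unit vector")
        if self.radius_mm <= 0:
            raise ConfigurationError(
                f"electrode {self.label!r}: radius_mm must be positive")
        object.__setattr__(self, "direction", tuple(float(v) for v in d))

    @property
    def direction_arr(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


def _build_1010_table() -> dict[str, tuple[float, float]]:
    """Built-in 10-10 label -> (inclination, azimuth) table, degrees.

    Inclination is measured from the vertex (+z); azimuth from anterior
    (+y), positive toward the right (+x).  Midline and vertex-coronal
    electrodes sit at multiples of 18 deg inclination; the outer ring at
    72 deg inclination carries azimuths in 18 deg steps; interior rows
    interpolate linearly in both angles between their midline electrode
    and their outer-ring terminus.  This is a placement convention of
    the package, versioned with it.
    """
    tbl: dict[str, tuple[float, float]] = {"Cz": (0.0, 0.0)}
    # midline, anterior then posterior
    for name, inc, az in [("FCz", 18, 0), ("Fz", 36, 0), ("AFz", 54, 0),
                          ("Fpz", 72, 0), ("CPz", 18, 180), ("Pz", 36, 180),
                          ("POz", 54, 180), ("Oz", 72, 180)]:
        tbl[name] = (float(inc), float(az))
    # vertex coronal row
    for i, name in enumerate(["C1", "C3", "C5", "T7"], start=1):
        tbl[name] = (18.0 * i, -90.0)
    # outer ring (72 deg), left hemisphere; azimuth steps of 18 deg
    ring_left = ["Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1"]
    for i, name in enumerate(ring_left, start=1):
        tbl[name] = (72.0, -18.0 * i)
    # interior rows: (midline label, ring terminus, members inboard->outboard)
    rows = [
        ("AFz", "AF7", ["AF3"]),          # single interior electrode at 50%
        ("Fz", "F7", ["F1", "F3", "F5"]),
        ("FCz", "FT7", ["FC1", "FC3", "FC5"]),
        ("CPz", "TP7", ["CP1", "CP3", "CP5"]),
        ("Pz", "P7", ["P1", "P3", "P5"]),
        ("POz", "PO7", ["PO3"]),
    ]
    for mid, ring, members in rows:
        inc0, az0 = tbl[mid]
        inc1, az1 = tbl[ring]
        if az0 == 180.0:                  # posterior rows: go 180 -> az1+360? no:
            az0 = -180.0                  # left hemisphere azimuths are negative
        n = len(members) + 1
        for i, name in enumerate(members, start=1):
            f = i / n
            tbl[name] = (inc0 + f * (inc1 - inc0), az0 + f * (az1 - az0))
    # right-hemisphere homologs: mirror azimuth
    homolog = {"1": "2", "3": "4", "5": "6", "7": "8"}
    for name in list(tbl):
        if name[-1] in homolog:
            right = name[:-1] + homolog[name[-1]]
            inc, az = tbl[name]
            tbl[right] = (inc, -az)
    return tbl


TEN_TEN_TABLE = _build_1010_table()


def _direction_from_angles(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    inc = np.deg2rad(inclination_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array([np.sin(inc) * np.sin(az),
                     np.sin(inc) * np.cos(az),
                     np.cos(inc)])


def build_phantom(config: PhantomConfig | None = None) -> HeadPhantom:
    """Voxelize the layered-sphere phantom on a grid containing the scalp.

    The grid is odd-sized and centered on the head center, which makes
    the label volume exactly mirror-symmetric about the mid-sagittal
    plane.  Deterministic given the configuration.
    """
    cfg = config or PhantomConfig()
    cfg.validate()

    h = cfg.spacing_mm
    half = int(np.ceil(cfg.scalp_radius_mm / h)) + cfg.margin_voxels
    n = 2 * half + 1
    if n < 5:
        raise ConfigurationError("grid too small to contain the scalp sphere")
    center = np.zeros(3)
    origin = -half * h * np.ones(3)

    coords = origin[0] + h * np.arange(n)
    r2 = (coords[:, None, None] ** 2
          + coords[None, :, None] ** 2
          + coords[None, None, :] ** 2)

    labels = np.full((n, n, n), AIR, dtype=np.uint8)
    labels[r2 < cfg.scalp_radius_mm ** 2] = SCALP
    labels[r2 < cfg.skull_radius_mm ** 2] = SKULL
    labels[r2 < cfg.csf_radius_mm ** 2] = CSF
    labels[r2 < cfg.brain_radius_mm ** 2] = GRAY
    labels[r2 < cfg.white_radius_mm ** 2] = WHITE

    # bilateral deep target, only where already brain
    for side in (-1.0, +1.0):
        c = np.array([side * cfg.target_lateral_mm,
                      cfg.target_anterior_mm, cfg.target_superior_mm])
        d2 = ((coords - c[0])[:, None, None] ** 2
              + (coords - c[1])[None, :, None] ** 2
              + (coords - c[2])[None, None, :] ** 2)
        inside = (d2 < cfg.target_radius_mm ** 2) & np.isin(labels, (GRAY, WHITE))
        labels[inside] = TARGET

    radii = {
        "scalp": cfg.scalp_radius_mm,
        "skull": cfg.skull_radius_mm,
        "csf": cfg.csf_radius_mm,
        "brain": cfg.brain_radius_mm,
        "white": cfg.white_radius_mm,
    }
    return HeadPhantom(
        labels=labels,
        spacing_mm=h,
        origin_mm=origin,
        head_center_mm=center,
        layer_radii_mm=radii,
        conductivity_table=dict(cfg.conductivity),
        config=cfg,
    )


def electrode_positions(labels: list[str], phantom: HeadPhantom,
                        radius_mm: float = 7.0) -> list[ElectrodeSpec]:
    """Look up 10-10 labels and return electrode specs on the phantom scalp.

    Raises :class:`UnknownElectrodeError` listing the known labels if a
    name is absent from the built-in table.
    """
    specs = []
    for name in labels:
        if name not in TEN_TEN_TABLE:
            known = ", ".join(sorted(TEN_TEN_TABLE))
            raise UnknownElectrodeError(
                f"unknown electrode label {name!r}; known labels: {known}")
        inc, az = TEN_TEN_TABLE[name]
        specs.append(ElectrodeSpec(label=name,
                                   direction=tuple(_direction_from_angles(inc, az)),
                                   radius_mm=radius_mm))
    return specs


def scalp_surface_mask(phantom: HeadPhantom) -> np.ndarray:
    """Outermost scalp voxels: scalp-labeled with at least one air 6-neighbor."""
    lab = phantom.labels
    scalp = lab == SCALP
    air = np.pad(lab == AIR, 1, constant_values=True)
    has_air = np.zeros_like(scalp)
    for axis in range(3):
        for off in (0, 2):
            sl = [slice(1, -1)] * 3
            sl[axis] = slice(off, off + lab.shape[axis])
            has_air |= air[tuple(sl)]
    return (scalp & has_air).astype(np.uint8)


def electrode_patch(phantom: HeadPhantom, electrode: ElectrodeSpec) -> np.ndarray:
    """Scalp-surface voxels within the electrode radius of the ray exit point."""
    surface = scalp_surface_mask(phantom).astype(bool)
    exit_pt = (phantom.head_center_mm
               + electrode.direction_arr * phantom.layer_radii_mm["scalp"])
    x, y, z = phantom.voxel_coords_mm()
    d2 = ((x - exit_pt[0])[:, None, None] ** 2
          + (y - exit_pt[1])[None, :, None] ** 2
          + (z - exit_pt[2])[None, None, :] ** 2)
    patch = surface & (d2 <= electrode.radius_mm ** 2)
    if not patch.any():
        # tolerate coarse grids: take nearest surface voxels within one spacing
        patch = surface & (d2 <= (electrode.radius_mm + phantom.spacing_mm) ** 2)
    if not patch.any():
        raise ConfigurationError(
            f"electrode {electrode.label!r}: empty scalp patch")
    return patch.astype(np.uint8)


@dataclass
class ROISet:
    """Named binary masks on the phantom grid with a role tag per ROI."""

    masks: dict                       # name -> uint8 volume
    roles: dict                       # name -> {"target","control","electrode-sphere","brain"}
    clipped_fraction: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> list[str]:
        return list(self.masks)

    def add(self, name: str, mask: np.ndarray, role: str,
            clipped_fraction: float = 0.0) -> None:
        self.masks[name] = mask.astype(np.uint8)
        self.roles[name] = role
        self.clipped_fraction[name] = float(clipped_fraction)


def _sphere_mask(phantom: HeadPhantom, center_mm: np.ndarray,
                 radius_mm: float) -> np.ndarray:
    x, y, z = phantom.voxel_coords_mm()
    d2 = ((x - center_mm[0])[:, None, None] ** 2
          + (y - center_mm[1])[None, :, None] ** 2
          + (z - center_mm[2])[None, None, :] ** 2)
    return (d2 <= radius_mm ** 2).astype(np.uint8)


def make_roi_set(phantom: HeadPhantom,
                 target_radius_mm: float | None = None,
                 target_centers_mm: list | None = None,
                 control_shell_mm: float = 8.0) -> ROISet:
    """Deep bilateral target spheres, a cortical-shell control, brain mask.

    ROIs extending outside the brain are clipped to it; the clipped
    fraction is logged and recorded on the returned :class:`ROISet`.
    """
    cfg = phantom.config
    if target_radius_mm is None:
        target_radius_mm = cfg.target_radius_mm
    if target_centers_mm is None:
        target_centers_mm = [
            np.array([-cfg.target_lateral_mm, cfg.target_anterior_mm,
                      cfg.target_superior_mm]),
            np.array([+cfg.target_lateral_mm, cfg.target_anterior_mm,
                      cfg.target_superior_mm]),
        ]
    brain = phantom.brain_mask.astype(bool)
    rois = ROISet(masks={}, roles={})
    rois.add("brain", brain, "brain")

    names = ["target_left", "target_right"] + [
        f"target_{i}" for i in range(2, len(target_centers_mm))]
    union = np.zeros_like(brain)
    for name, c in zip(names, target_centers_mm):
        raw = _sphere_mask(phantom, np.asarray(c, float), target_radius_mm).astype(bool)
        if not raw.any():
            raise InfeasibleROIError(f"ROI {name!r}: empty mask")
        clipped = raw & brain
        frac = 1.0 - clipped.sum() / raw.sum()
        if frac > 0:
            log.warning("ROI %s clipped to brain: %.1f%% of voxels removed",
                        name, 100 * frac)
        rois.add(name, clipped, "target", clipped_fraction=frac)
        union |= clipped
    rois.add("target", union, "target")

    radius = phantom.radius_volume_mm()
    shell = (brain
             & (phantom.labels == GRAY)
             & (radius >= cfg.brain_radius_mm - control_shell_mm))
    rois.add("cortical_control", shell, "control")
    return rois


def sphere_under_electrode(phantom: HeadPhantom, electrode: ElectrodeSpec,
                           radius_mm: float = 10.0,
                           depth_step_mm: float = 0.1) -> np.ndarray:
    """Shallowest fully brain-contained sphere on the electrode's inward ray.

    Scans the sphere center along the ray from the scalp toward the head
    center in ``depth_step_mm`` steps and returns the mask of the first
    (shallowest) position at which every voxel of the sphere lies inside
    the brain mask.
    """
    brain_r = phantom.layer_radii_mm["brain"]
    if 2 * radius_mm >= brain_r:
        raise InfeasibleROIError(
            f"sphere radius {radius_mm} mm too large for brain radius {brain_r} mm")
    brain = phantom.brain_mask.astype(bool)
    d = electrode.direction_arr
    scalp_r = phantom.layer_radii_mm["scalp"]
    for depth in np.arange(0.0, scalp_r, depth_step_mm):
        center = phantom.head_center_mm + d * (scalp_r - depth)
        if np.linalg.norm(center - phantom.head_center_mm) + radius_mm > brain_r + phantom.spacing_mm:
            continue  # cannot be contained yet; cheap analytic reject
        mask = _sphere_mask(phantom, center, radius_mm).astype(bool)
        if mask.any() and (mask <= brain).all():
            return mask.astype(np.uint8)
    raise InfeasibleROIError(
        f"no depth admits a fully brain-contained {radius_mm} mm sphere "
        f"under electrode {electrode.label!r}")
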