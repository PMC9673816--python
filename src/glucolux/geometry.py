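"""Parametric barcode-biosensor designs, skin scene, and voxelization.

The tissue model is a three-layer skin block (epidermis / dermis /
hypodermis) of the dorsal wrist, 17 x 17 x 4 mm, discretized into 0.05-mm
cubic voxels.  Coordinates: origin at the tissue surface under the center of
the illumination source, X and Y lateral, Z positive downward; voxels are
half-open intervals with 0-based indices.

Three candidate insertable designs share the constraints: fixed total
length, alternating repeating units of the two sensing assays, and insertion
through a 17-gauge hypodermic needle (the circumscribed cross-section
diameter must not exceed the needle bore):

* ``rect_barcode`` - the current cuboid barcode (0.7 x 0.9 mm cross section)
  with transverse alternating assay slabs;
* ``stacked_cylinder`` - coaxial cylindrical disks, alternating assays; the
  default diameter is the needle-inscribed 1.19 mm, which maximizes sensing
  volume under the insertion constraint;
* ``longitudinal_rods`` - a 2 x 2 bundle of full-length rods, two per assay
  on opposite diagonals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GeometryError",
    "PlacementError",
    "MEDIA",
    "MEDIA_NAMES",
    "Cuboid",
    "Cylinder",
    "RodBundle",
    "SensorDesign",
    "Placement",
    "VoxelScene",
    "tissue_scene",
    "build_design",
    "default_design",
    "needle_fit",
    "rasterize",
    "save_scene",
    "load_scene",
    "NEEDLE_ID_17G_TW",
]


class GeometryError(ValueError):
    """A design violates a geometric constraint (e.g. needle fit)."""


class PlacementError(ValueError):
    """A placed sensor is clipped by the tissue domain boundary."""


#: Medium label codes used in the voxel grid.
MEDIA = {
    "epidermis": 0,
    "dermis": 1,
    "hypodermis": 2,
    "hydrogel": 3,
    "assay1": 4,
    "assay2": 5,
}
MEDIA_NAMES = {v: k for k, v in MEDIA.items()}

#: Inner diameter (mm) of a 17-gauge thin-wall hypodermic needle.
NEEDLE_ID_17G_TW = 1.19


# ---------------------------------------------------------------------------
# cross sections

@dataclass(frozen=True)
class Cuboid:
    """Rectangular cross section, ``width`` (Y) x ``height`` (Z) in mm."""

    width: float = 0.7
    height: float = 0.9

    @property
    def circumscribed_diameter(self) -> float:
        return math.hypot(self.width, self.height)

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class Cylinder:
    """Circular cross section of the given ``diameter`` (mm)."""

    diameter: float = NEEDLE_ID_17G_TW

    @property
    def circumscribed_diameter(self) -> float:
        return self.diameter

    @property
    def area(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2


@dataclass(frozen=True)
class RodBundle:
    """``n_rods`` touching parallel rods (2 x 2 square bundle for 4 rods).

    The default rod diameter inscribes the 4-rod bundle in the 17G needle
    bore: d = ID / (1 + sqrt(2)).
    """

    rod_diameter: float = NEEDLE_ID_17G_TW / (1.0 + math.sqrt(2.0))
    n_rods: int = 4

    def __post_init__(self):
        if self.n_rods not in (2, 4):
            raise GeometryError("rod bundles support 2 or 4 rods")

    @property
    def circumscribed_diameter(self) -> float:
        if self.n_rods == 2:
            return 2.0 * self.rod_diameter
        return self.rod_diameter * (1.0 + math.sqrt(2.0))

    @property
    def area(self) -> float:
        return self.n_rods * math.pi * (self.rod_diameter / 2.0) ** 2

    def rod_centers(self):
        """(dy, dz) offsets of rod axes from the bundle center, mm."""
        r = self.rod_diameter / 2.0
        if self.n_rods == 2:
            return [(-r, 0.0), (r, 0.0)]
        return [(-r, -r), (r, r), (r, -r), (-r, r)]

    def rod_assays(self):
        """Assay label per rod; diagonal pairing keeps both assays visible."""
        if self.n_rods == 2:
            return ["assay1", "assay2"]
        return ["assay1", "assay1", "assay2", "assay2"]


# ---------------------------------------------------------------------------
# designs

@dataclass(frozen=True)
class SensorDesign:
    """A parametric barcode biosensor.

    ``unit_thickness`` is the length of one repeating compartment along the
    long (X) axis for the segmented designs; longitudinal-rod designs span
    the full length and carry one "unit" per rod.
    """

    design_id: str
    total_length: float
    cross_section: object
    unit_thickness: float | None = None
    n_units_total: int = 0
    assay_order: tuple = ("assay1", "assay2")

    @property
    def n_units_per_assay(self) -> int:
        return max(1, self.n_units_total // 2)

    def analytic_volume(self) -> float:
        """Analytic sensor volume in mm^3."""
        return self.cross_section.area * self.total_length

    def compartment_label(self, x_local: np.ndarray) -> np.ndarray:
        """Compartment index for positions along the axis, 0-based from -L/2."""
        n = max(self.n_units_total, 1)
        idx = np.floor((x_local + self.total_length / 2.0) * n / self.total_length)
        return np.clip(idx, 0, n - 1).astype(int)


@dataclass(frozen=True)
class Placement:
    """Sensor center offset (mm) from the source axis origin; X-aligned."""

    x: float = 0.0
    y: float = 0.0
    z: float = 2.0


def needle_fit(design: SensorDesign, needle_inner_diameter: float = NEEDLE_ID_17G_TW) -> bool:
    """True iff the circumscribed cross-section diameter fits the needle bore."""
    if needle_inner_diameter <= 0:
        raise ValueError("needle_inner_diameter must be > 0")
    return design.cross_section.circumscribed_diameter <= needle_inner_diameter + 1e-12


def build_design(
    design_id: str,
    total_length: float = 6.5,
    unit_thickness: float | None = None,
    cross_section=None,
    n_units_per_assay: int | None = None,
    needle_inner_diameter: float = NEEDLE_ID_17G_TW,
    voxel_mm: float = 0.05,
) -> SensorDesign:
    """Construct one of the candidate designs with validated constraints.

    Exactly one of ``unit_thickness`` / ``n_units_per_assay`` sets the
    segmentation for the segmented designs; rod designs ignore both.
    """
    if total_length <= 0:
        raise GeometryError("total_length must be > 0")
    if cross_section is None:
        cross_section = {
            "rect_barcode": Cuboid(),
            "stacked_cylinder": Cylinder(),
            "longitudinal_rods": RodBundle(),
            "custom": Cuboid(),
        }.get(design_id)
        if cross_section is None:
            raise GeometryError(f"unknown design_id {design_id!r}")

    if design_id == "longitudinal_rods" or isinstance(cross_section, RodBundle):
        n_total = cross_section.n_rods
        unit = total_length
    else:
        if n_units_per_assay is not None:
            n_total = 2 * n_units_per_assay
            unit = total_length / n_total
        else:
            if unit_thickness is None or unit_thickness <= 0:
                raise GeometryError("unit_thickness (or n_units_per_assay) required")
            n_total = int(round(total_length / unit_thickness))
            if n_total < 1:
                raise GeometryError("unit_thickness exceeds total_length")
            # the stated unit thickness must tile the length to within a voxel
            if abs(n_total * unit_thickness - total_length) > voxel_mm + 1e-9:
                raise GeometryError(
                    f"unit_thickness {unit_thickness} mm does not divide "
                    f"total_length {total_length} mm to within one voxel"
                )
            unit = total_length / n_total

    design = SensorDesign(
        design_id=design_id,
        total_length=total_length,
        cross_section=cross_section,
        unit_thickness=unit,
        n_units_total=n_total,
    )
    if not needle_fit(design, needle_inner_diameter):
        raise GeometryError(
            f"cross-section circumscribed diameter "
            f"{cross_section.circumscribed_diameter:.4f} mm exceeds needle "
            f"inner diameter {needle_inner_diameter} mm"
        )
    return design


def default_design(design_id: str) -> SensorDesign:
    """The three default candidate designs at 6.5 mm total length."""
    if design_id in ("design1", "rect_barcode"):
        return build_design("rect_barcode", 6.5, unit_thickness=3.25)
    if design_id in ("design2", "stacked_cylinder"):
        return build_design("stacked_cylinder", 6.5, unit_thickness=0.65)
    if design_id in ("design3", "longitudinal_rods"):
        return build_design("longitudinal_rods", 6.5)
    raise GeometryError(f"unknown design {design_id!r}")


# ---------------------------------------------------------------------------
# voxel scene

@dataclass
class VoxelScene:
    """Labeled 3-D voxel grid of the tissue block (optionally with a sensor).

    ``labels[ix, iy, iz]`` holds a :data:`MEDIA` code; voxel ``(i, j, k)``
    covers the half-open box ``[i*h - Lx/2, (i+1)*h - Lx/2) x ... x
    [k*h, (k+1)*h)`` with edge length ``h = voxel_mm``.
    """

    labels: np.ndarray
    voxel_mm: float = 0.05
    layer_depths: tuple = (0.1, 1.6)  # epidermis/dermis and dermis/hypodermis, mm

    @property
    def shape(self):
        return self.labels.shape

    @property
    def extent_mm(self):
        nx, ny, nz = self.labels.shape
        return (nx * self.voxel_mm, ny * self.voxel_mm, nz * self.voxel_mm)

    def axis_centers(self, axis: str) -> np.ndarray:
        """Voxel-center coordinates (mm) along 'x', 'y' (centered) or 'z'."""
        nx, ny, nz = self.labels.shape
        h = self.voxel_mm
        if axis == "x":
            return (np.arange(nx) + 0.5) * h - nx * h / 2.0
        if axis == "y":
            return (np.arange(ny) + 0.5) * h - ny * h / 2.0
        if axis == "z":
            return (np.arange(nz) + 0.5) * h
        raise ValueError(axis)

    def copy(self) -> "VoxelScene":
        return VoxelScene(self.labels.copy(), self.voxel_mm, self.layer_depths)


def tissue_scene(
    extent_mm=(17.0, 17.0, 4.0),
    voxel_mm: float = 0.05,
    layer_depths=(0.1, 1.6),
) -> VoxelScene:
    """Sensor-free three-layer skin scene.

    ``layer_depths`` gives the epidermis/dermis and dermis/hypodermis
    boundary depths in mm (strictly increasing).
    """
    d1, d2 = layer_depths
    if not 0 < d1 < d2 < extent_mm[2]:
        raise GeometryError("layer depths must be strictly increasing within the domain")
    shape = tuple(int(round(e / voxel_mm)) for e in extent_mm)
    labels = np.empty(shape, dtype=np.uint8)
    z = (np.arange(shape[2]) + 0.5) * voxel_mm
    col = np.where(z < d1, MEDIA["epidermis"], np.where(z < d2, MEDIA["dermis"], MEDIA["hypodermis"]))
    labels[:, :, :] = col.astype(np.uint8)[None, None, :]
    return VoxelScene(labels, voxel_mm, layer_depths)


def rasterize(design: SensorDesign, placement: Placement, scene: VoxelScene) -> VoxelScene:
    """Relabel scene voxels inside the placed sensor by voxel-center membership.

    Ties on compartment boundaries resolve toward the sensor (membership
    tests are inclusive), which keeps thin compartments contiguous.  Raises
    :class:`PlacementError` if the sensor would be clipped by the domain.
    """
    out = scene.copy()
    if design.total_length <= 0:
        return out
    h = scene.voxel_mm
    ex, ey, ez = scene.extent_mm
    cs = design.cross_section
    half_l = design.total_length / 2.0
    # bounding box (mm) in centered-x/y, downward-z coordinates
    r = cs.circumscribed_diameter / 2.0
    if isinstance(cs, Cuboid):
        by, bz = cs.width / 2.0, cs.height / 2.0
    else:
        by = bz = r
    if (
        placement.x - half_l < -ex / 2 or placement.x + half_l > ex / 2
        or placement.y - by < -ey / 2 or placement.y + by > ey / 2
        or placement.z - bz < 0 or placement.z + bz > ez
    ):
        raise PlacementError(
            f"sensor at ({placement.x}, {placement.y}, {placement.z}) mm is "
            "clipped by the tissue domain boundary"
        )

    xs = scene.axis_centers("x") - placement.x
    ys = scene.axis_centers("y") - placement.y
    zs = scene.axis_centers("z") - placement.z
    in_x = np.abs(xs) <= half_l
    X = xs[in_x]
    comp = design.compartment_label(X)

    if isinstance(cs, RodBundle):
        ix = np.where(in_x)[0]
        rr = (cs.rod_diameter / 2.0) ** 2
        for (dy, dz), assay in zip(cs.rod_centers(), cs.rod_assays()):
            mask_yz = (ys[:, None] - dy) ** 2 + (zs[None, :] - dz) ** 2 <= rr + 1e-12
            for j, k in zip(*np.where(mask_yz)):
                out.labels[ix, j, k] = MEDIA[assay]
        return out

    if isinstance(cs, Cuboid):
        mask_yz = (np.abs(ys)[:, None] <= cs.width / 2.0 + 1e-12) & (
            np.abs(zs)[None, :] <= cs.height / 2.0 + 1e-12
        )
    else:  # Cylinder
        mask_yz = ys[:, None] ** 2 + zs[None, :] ** 2 <= (cs.diameter / 2.0) ** 2 + 1e-12

    ix = np.where(in_x)[0]
    iy, iz = np.where(mask_yz)
    codes = np.array(
        [MEDIA[design.assay_order[c % 2]] for c in range(design.n_units_total)],
        dtype=np.uint8,
    )
    vox_codes = codes[comp]  # per x-slab
    for j, k in zip(iy, iz):
        out.labels[ix, j, k] = vox_codes
    return out


def save_scene(scene: VoxelScene, path) -> None:
    """Write the label grid as a compressed archive + JSON media sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        labels=scene.labels,
        voxel_mm=scene.voxel_mm,
        layer_depths=np.asarray(scene.layer_depths),
    )
    sidecar = path.with_suffix(".media.json")
    sidecar.write_text(json.dumps({str(v): k for k, v in MEDIA.items()}, indent=1))


def load_scene(path) -> VoxelScene:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as f:
        return VoxelScene(
            f["labels"], float(f["voxel_mm"]), tuple(f["layer_depths"].tolist())
        )
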