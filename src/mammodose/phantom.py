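"""Compressed-breast voxel phantoms with separate glandular and adipose
compartments, plus the printed reference-dose fixture table.

Geometry convention: axes in cm, origin at the chest-wall/support corner.
The compressed breast is a semicircular-footprint slab: x in [-R, R]
across the chest wall, y in [0, R] from chest wall toward the nipple,
z in [0, T] through the compressed thickness.  The beam travels along
-z (enters at z = T).  Voxels are half-open cubes indexed 0-based; a
voxel belongs to the compartment its center falls in.

Two phantom modes:

* ``non-mixture`` -- glandular tissue fills a paraboloid of revolution
  whose apex sits at the nipple and which widens toward the chest wall
  (the qualitative anatomy of the mammary gland); adipose tissue fills
  the remaining interior.  The paraboloid's lateral scale is solved so
  the interior glandular mass fraction hits the requested target.
* ``mixture`` -- the conventional homogeneous phantom: every interior
  voxel holds a single glandular/adipose blend at the requested mass
  fraction (blend density from mass-weighted specific volumes).

Skin is the outermost 1.5 mm on every face except the chest-wall plane.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .materials import Material, blend, builtin_materials

__all__ = [
    "PhantomSpec", "VoxelPhantom", "FixtureTable", "PhantomSizingError",
    "AIR", "SKIN", "GLANDULAR", "ADIPOSE", "INTERIOR_MIX", "LABEL_NAMES",
    "build_phantom", "glandular_mass_fraction", "dosimeter_positions",
    "fixture_table", "export_phantom", "import_phantom",
]

AIR, SKIN, GLANDULAR, ADIPOSE, INTERIOR_MIX = 0, 1, 2, 3, 4
LABEL_NAMES = {AIR: "air", SKIN: "skin", GLANDULAR: "glandular",
               ADIPOSE: "adipose", INTERIOR_MIX: "interior"}


class PhantomSizingError(ValueError):
    """Requested glandular fraction unreachable for this geometry."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one compressed-breast phantom.

    The study grid uses thickness 4 / 4.5 / 5 cm and glandular targets
    0.25 / 0.50 / 0.75; any positive thickness and fraction in (0, 1)
    is accepted.  ``fraction_basis`` selects whether the target is a
    mass (default) or volume fraction of the interior.
    """

    thickness_cm: float = 4.0
    glandular_fraction: float = 0.50
    mode: str = "non-mixture"            # "non-mixture" | "mixture"
    skin_mm: float = 1.5
    footprint_radius_cm: float = 8.0
    voxel_mm: float = 1.0
    fraction_basis: str = "mass"         # "mass" | "volume"

    def __post_init__(self):
        if self.thickness_cm <= 2 * self.skin_mm / 10.0:
            raise ValueError("thickness must exceed twice the skin thickness")
        if not 0.0 < self.glandular_fraction < 1.0:
            raise ValueError("glandular fraction must be in (0, 1)")
        if self.mode not in ("non-mixture", "mixture"):
            raise ValueError("mode must be 'non-mixture' or 'mixture'")
        if self.voxel_mm <= 0 or self.skin_mm <= 0 or self.footprint_radius_cm <= 0:
            raise ValueError("voxel, skin and footprint sizes must be positive")
        if self.fraction_basis not in ("mass", "volume"):
            raise ValueError("fraction_basis must be 'mass' or 'volume'")


@dataclass(frozen=True)
class VoxelPhantom:
    """Realized labeled voxel grid with per-compartment masses."""

    spec: PhantomSpec
    labels: np.ndarray                  # uint8, shape (nx, ny, nz)
    voxel_mm: float
    origin_cm: Tuple[float, float, float]
    materials: Dict[int, Material] = field(repr=False)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.voxel_mm / 10.0) ** 3

    def voxel_centers(self, axis: int) -> np.ndarray:
        h = self.voxel_mm / 10.0
        return self.origin_cm[axis] + h * (np.arange(self.shape[axis]) + 0.5)

    def compartment_masses(self) -> Dict[str, float]:
        """Mass in grams per labeled compartment (air excluded)."""
        out = {}
        for lab, mat in self.materials.items():
            if lab == AIR:
                continue
            n = int(np.count_nonzero(self.labels == lab))
            out[LABEL_NAMES[lab]] = n * self.voxel_volume_cm3 * mat.density
        return out

    def total_mass(self) -> float:
        return float(sum(self.compartment_masses().values()))


def _grid_geometry(spec: PhantomSpec):
    h = spec.voxel_mm / 10.0
    r = spec.footprint_radius_cm
    t = spec.thickness_cm
    nx = int(round(2 * r / h))
    ny = int(round(r / h))
    nz = int(round(t / h))
    origin = (-r, 0.0, 0.0)
    x = origin[0] + h * (np.arange(nx) + 0.5)
    y = origin[1] + h * (np.arange(ny) + 0.5)
    z = origin[2] + h * (np.arange(nz) + 0.5)
    return origin, x, y, z


def _base_labels(spec: PhantomSpec):
    """Air / skin / interior masks on the voxel grid."""
    origin, x, y, z = _grid_geometry(spec)
    r = spec.footprint_radius_cm
    t = spec.thickness_cm
    s = spec.skin_mm / 10.0
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    rad = np.hypot(xx, yy)
    inside = rad <= r
    # skin: within s of the lateral curved face or the top/bottom faces;
    # the chest-wall plane (y = 0) stays open.  Strict inequality keeps
    # the shell one voxel thick at the default 1 mm voxel pitch.
    near_surface = (rad > r - s) | (zz < s) | (zz > t - s)
    labels = np.full(xx.shape, AIR, dtype=np.uint8)
    labels[inside & near_surface] = SKIN
    interior = inside & ~near_surface
    return origin, (x, y, z), labels, interior


def _paraboloid_mask(spec, coords, interior):
    """Return fn(scale) -> glandular mask inside the interior."""
    x, y, z = coords
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    y_apex = float(y[interior.any(axis=(0, 2))].max()) if interior.any() \
        else 0.0
    rad_axis = np.hypot(xx, zz - spec.thickness_cm / 2.0)
    shrink = np.sqrt(np.clip(1.0 - yy / y_apex, 0.0, None))

    def mask(scale: float) -> np.ndarray:
        return interior & (rad_axis <= scale * shrink)

    return mask


def build_phantom(spec: PhantomSpec,
                  registry: Dict[str, Material] | None = None) -> VoxelPhantom:
    """Realize the voxel phantom for ``spec``.

    Non-mixture mode solves the paraboloid lateral scale by bisection so
    the realized interior glandular fraction is within +-0.01 of the
    target; an unreachable target raises :class:`PhantomSizingError`
    naming the achievable range.
    """
    reg = registry or builtin_materials()
    origin, coords, labels, interior = _base_labels(spec)
    rho_g = reg["glandular"].density
    rho_a = reg["adipose"].density

    if spec.mode == "mixture":
        g = spec.glandular_fraction
        if spec.fraction_basis == "volume":
            # convert a volume target to the equivalent mass blend
            g = g * rho_g / (g * rho_g + (1 - g) * rho_a)
        interior_mat = blend("glandular/adipose blend",
                             {"glandular": g, "adipose": 1.0 - g}, reg)
        labels[interior] = INTERIOR_MIX
        mats = {AIR: reg["air"], SKIN: reg["skin"], INTERIOR_MIX: interior_mat}
        return VoxelPhantom(spec, labels, spec.voxel_mm, origin, mats)

    mask_fn = _paraboloid_mask(spec, coords, interior)
    n_int = int(np.count_nonzero(interior))
    if n_int == 0:
        raise PhantomSizingError("no interior voxels at this geometry")

    def realized(scale: float) -> float:
        n_g = np.count_nonzero(mask_fn(scale))
        n_a = n_int - n_g
        if spec.fraction_basis == "mass":
            mg, ma = n_g * rho_g, n_a * rho_a
        else:
            mg, ma = float(n_g), float(n_a)
        return mg / (mg + ma)

    lo, hi = 0.0, 2.0 * np.hypot(spec.footprint_radius_cm,
                                 spec.thickness_cm / 2.0)
    f_hi = realized(hi)
    target = spec.glandular_fraction
    if target > f_hi + 0.01:
        raise PhantomSizingError(
            f"target fraction {target} unreachable; achievable range "
            f"(0, {f_hi:.3f}] at voxel {spec.voxel_mm} mm")
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    scale = hi
    if abs(realized(scale) - target) > 0.01:
        raise PhantomSizingError(
            f"fraction quantization too coarse: reached {realized(scale):.4f} "
            f"for target {target} at voxel {spec.voxel_mm} mm")

    gland = mask_fn(scale)
    labels[interior] = ADIPOSE
    labels[gland] = GLANDULAR
    mats = {AIR: reg["air"], SKIN: reg["skin"],
            GLANDULAR: reg["glandular"], ADIPOSE: reg["adipose"]}
    return VoxelPhantom(spec, labels, spec.voxel_mm, origin, mats)


def glandular_mass_fraction(phantom: VoxelPhantom) -> float:
    """Glandular mass / (glandular + adipose mass), skin excluded.

    For a mixture-mode phantom the interior is a fixed blend, so the
    specified blend fraction is reported.
    """
    if phantom.spec.mode == "mixture":
        return phantom.spec.glandular_fraction
    m = phantom.compartment_masses()
    gl = m.get("glandular", 0.0)
    ad = m.get("adipose", 0.0)
    if gl + ad == 0:
        raise ValueError("phantom has no interior tissue")
    return gl / (gl + ad)


def dosimeter_positions(phantom: VoxelPhantom, n: int = 6
                        ) -> List[Tuple[float, float, float]]:
    """``n`` deterministic points inside glandular voxels.

    Points sit at mid-thickness on the chest-wall -> nipple axis, at
    evenly spaced quantiles of the glandular y-extent (the protocol of
    the six dosimeter holes spanning the whole gland); each is snapped
    to the nearest glandular voxel center.  Results are ordered by
    distance from the chest wall and pairwise distinct.
    """
    if phantom.spec.mode != "non-mixture":
        raise ValueError("dosimeter positions require a non-mixture phantom")
    idx = np.argwhere(phantom.labels == GLANDULAR)
    if idx.shape[0] < n:
        raise ValueError(f"glandular region has only {idx.shape[0]} voxels; "
                         f"cannot place {n} distinct dosimeters")
    h = phantom.voxel_mm / 10.0
    centers = phantom.origin_cm + h * (idx + 0.5)

    if n == 1:
        targets = [centers.mean(axis=0)]
    else:
        y_lo, y_hi = centers[:, 1].min(), centers[:, 1].max()
        z_mid = phantom.spec.thickness_cm / 2.0
        qs = (np.arange(n) + 0.5) / n
        targets = [np.array([0.0, y_lo + q * (y_hi - y_lo), z_mid])
                   for q in qs]

    chosen: List[Tuple[float, float, float]] = []
    taken = np.zeros(centers.shape[0], dtype=bool)
    for tgt in targets:
        d = np.linalg.norm(centers - tgt, axis=1)
        d[taken] = np.inf
        k = int(np.argmin(d))
        taken[k] = True
        chosen.append(tuple(centers[k]))
    chosen.sort(key=lambda p: p[1])
    return chosen


# ---------------------------------------------------------------------------
# Printed reference doses (read-only comparison fixture)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureRow:
    simulated_mgy: float
    measured_mgy: float
    measured_spread_mgy: float


@dataclass(frozen=True)
class FixtureTable:
    """The published per-thickness mean glandular doses (mGy), simulated
    and glass-dosimeter measured, plus the published overall per-filter
    means.  Values are transcribed verbatim and never recomputed."""

    rows: Dict[Tuple[float, str], FixtureRow]
    overall_simulated: Dict[str, float]
    overall_measured: Dict[str, Tuple[float, float]]


def fixture_table() -> FixtureTable:
    rows = {
        (4.0, "Rh"): FixtureRow(0.68, 0.66, 0.02),
        (4.5, "Rh"): FixtureRow(0.64, 0.62, 0.02),
        (5.0, "Rh"): FixtureRow(0.58, 0.59, 0.02),
        (4.0, "Ag"): FixtureRow(0.98, 0.98, 0.03),
        (4.5, "Ag"): FixtureRow(0.88, 0.85, 0.03),
        (5.0, "Ag"): FixtureRow(0.82, 0.83, 0.02),
    }
    return FixtureTable(rows,
                        overall_simulated={"Ag": 1.00, "Rh": 0.72},
                        overall_measured={"Ag": (0.89, 0.03),
                                          "Rh": (0.62, 0.02)})


# ---------------------------------------------------------------------------
# Export / import (raw label volume + text sidecar header)
# ---------------------------------------------------------------------------

def export_phantom(phantom: VoxelPhantom, path: str | Path) -> None:
    """Write ``<path>.raw`` (uint8 labels, C order) and ``<path>.hdr``."""
    path = Path(path)
    raw = path.with_suffix(".raw")
    hdr = path.with_suffix(".hdr")
    raw.write_bytes(phantom.labels.tobytes(order="C"))
    buf = io.StringIO()
    buf.write("# mammodose phantom header\n")
    s = phantom.spec
    buf.write(f"shape: {phantom.shape[0]} {phantom.shape[1]} {phantom.shape[2]}\n")
    buf.write(f"voxel_mm: {phantom.voxel_mm!r}\n")
    buf.write(f"origin_cm: {phantom.origin_cm[0]!r} {phantom.origin_cm[1]!r} "
              f"{phantom.origin_cm[2]!r}\n")
    buf.write(f"spec: thickness_cm={s.thickness_cm!r} "
              f"glandular_fraction={s.glandular_fraction!r} mode={s.mode} "
              f"skin_mm={s.skin_mm!r} footprint_radius_cm={s.footprint_radius_cm!r} "
              f"voxel_mm={s.voxel_mm!r} fraction_basis={s.fraction_basis}\n")
    for lab in sorted(phantom.materials):
        m = phantom.materials[lab]
        buf.write(f"label {lab}: {LABEL_NAMES[lab]} density={m.density!r}\n")
    hdr.write_text(buf.getvalue())


def import_phantom(path: str | Path,
                   registry: Dict[str, Material] | None = None) -> VoxelPhantom:
    """Round-trip load of :func:`export_phantom` output (bit-exact)."""
    path = Path(path)
    hdr = path.with_suffix(".hdr").read_text()
    fields: Dict[str, str] = {}
    for ln in hdr.splitlines():
        if ln.startswith("#") or not ln.strip():
            continue
        key, val = ln.split(":", 1)
        fields[key.strip()] = val.strip()
    shape = tuple(int(v) for v in fields["shape"].split())
    voxel_mm = float(fields["voxel_mm"])
    origin = tuple(float(v) for v in fields["origin_cm"].split())
    sp = dict(kv.split("=") for kv in fields["spec"].split())
    spec = PhantomSpec(thickness_cm=float(sp["thickness_cm"]),
                       glandular_fraction=float(sp["glandular_fraction"]),
                       mode=sp["mode"], skin_mm=float(sp["skin_mm"]),
                       footprint_radius_cm=float(sp["footprint_radius_cm"]),
                       voxel_mm=float(sp["voxel_mm"]),
                       fraction_basis=sp["fraction_basis"])
    labels = np.frombuffer(path.with_suffix(".raw").read_bytes(),
                           dtype=np.uint8).reshape(shape).copy()
    reg = registry or builtin_materials()
    if spec.mode == "mixture":
        g = spec.glandular_fraction
        mats = {AIR: reg["air"], SKIN: reg["skin"],
                INTERIOR_MIX: blend("glandular/adipose blend",
                                    {"glandular": g, "adipose": 1 - g}, reg)}
    else:
        mats = {AIR: reg["air"], SKIN: reg["skin"],
                GLANDULAR: reg["glandular"], ADIPOSE: reg["adipose"]}
    return VoxelPhantom(spec, labels, voxel_mm, origin, mats)
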