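"""Synthetic ankle-joint label bitmaps with parametric subchondral cysts.

The generator draws an idealized ankle cross-section — distal tibia (and
fibula in the frontal projection), talus, calcaneus base, cartilage gaps,
ligaments, a soft-tissue envelope, small synovial fluid pockets and a
medullary cavity — onto a 250x250 grid of tissue-class codes at 0.5 mm per
pixel.  Fluid-filled cysts are inserted into the trabecular interior of the
talus and/or tibia, centrally (on the limb axis) or peripherally (lateral
third of the bone), always subchondral (close to the articular cartilage).

The geometry is deliberately impersonal: it is a parametric stand-in for a
hand-drawn joint contour, not patient anatomy.  Coordinate convention:
pixel (row 0, col 0) is top-left, physical y increases downward, the loaded
edge is the topmost solid row and the restrained edge the bottom-most.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "CLASS_NAMES",
    "CLASS_CODES",
    "DEFAULT_PALETTE",
    "LabelImage",
    "CystSpec",
    "ScenarioSpec",
    "GeometryParams",
    "GeometryError",
    "CystPlacementError",
    "generate_geometry",
    "insert_cysts",
    "render_grayscale",
    "standard_scenarios",
    "solid_mask",
    "check_load_path",
]

# Closed set of tissue classes; codes are positional.
CLASS_NAMES: tuple[str, ...] = (
    "background",
    "cortical",
    "trabecular",
    "cartilage",
    "ligament",
    "soft_tissue",
    "fluid",
    "medullary",
    "cyst",
)
CLASS_CODES: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

# Default grayscale palette (8-bit).  Background is 0 by convention; bone is
# bright, soft structures dark — loosely mimicking a radiographic rendering.
DEFAULT_PALETTE: dict[str, int] = {
    "background": 0,
    "soft_tissue": 60,
    "medullary": 75,
    "fluid": 90,
    "cyst": 105,
    "cartilage": 120,
    "ligament": 150,
    "trabecular": 190,
    "cortical": 255,
}

# Classes that transmit load ("solid"): everything except background and the
# enveloping soft tissue.  Enclosed fluid/medullary spaces count as part of
# the structure for the load-path check.
_SOLID_EXCLUDED = ("background", "soft_tissue")

_FOUR_CONN = ndimage.generate_binary_structure(2, 1)


class GeometryError(ValueError):
    """Raised when parameters produce an invalid (e.g. disconnected) model."""


class CystPlacementError(ValueError):
    """Raised when a cyst cannot be placed inside trabecular bone."""


@dataclass
class LabelImage:
    """A per-pixel tissue-class map with physical pixel size.

    ``labels`` is a ``(height, width)`` uint8 array of class codes from
    :data:`CLASS_CODES`.  ``bone_masks`` optionally records which pixels
    belong to each named bone (needed to resolve cyst placement); it is
    carried through :func:`insert_cysts` but not serialized to bitmaps.
    """

    labels: np.ndarray
    pixel_size: float = 0.5
    projection: str = "frontal"
    bone_masks: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.labels.max(initial=0) >= len(CLASS_NAMES):
            raise ValueError("labels contain codes outside the tissue-class set")
        if self.projection not in ("frontal", "sagittal"):
            raise ValueError(f"unknown projection {self.projection!r}")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def copy(self) -> "LabelImage":
        masks = None
        if self.bone_masks is not None:
            masks = {k: v.copy() for k, v in self.bone_masks.items()}
        return LabelImage(self.labels.copy(), self.pixel_size, self.projection, masks)

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == CLASS_CODES[name]

    def content_hash(self) -> str:
        """SHA-256 of the raw label array (reproducibility fingerprint)."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.labels).tobytes())
        h.update(f"{self.pixel_size}:{self.projection}".encode())
        return h.hexdigest()


@dataclass(frozen=True)
class CystSpec:
    """One fluid-filled cyst: which bone, where, and how big.

    ``center`` is in mm relative to the top-left of the bone's bounding box;
    when ``None`` it is resolved from ``position``: *central* sits on the
    bone's vertical midline, *peripheral* in the lateral third, both tucked
    directly under the subchondral plate.
    """

    bone: str  # "talus" | "tibia"
    position: str  # "central" | "peripheral"
    semi_axes: tuple[float, float] = (4.0, 4.0)  # (x, y) in mm
    center: tuple[float, float] | None = None  # (x, y) mm rel. to bone bbox

    def __post_init__(self) -> None:
        if self.bone not in ("talus", "tibia"):
            raise ValueError(f"cyst bone must be talus or tibia, got {self.bone!r}")
        if self.position not in ("central", "peripheral"):
            raise ValueError(f"cyst position must be central or peripheral, got {self.position!r}")
        if min(self.semi_axes) <= 0:
            raise ValueError("cyst semi-axes must be positive")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named cyst constellation (S1..S7 in the standard set)."""

    id: str
    cysts: tuple[CystSpec, ...] = ()


def standard_scenarios(
    radius_mm: float = 4.0,
) -> dict[str, ScenarioSpec]:
    """The seven standard cyst constellations.

    S1 no cyst; S2 central talus; S3 peripheral talus; S4 central talus +
    central tibia; S5 peripheral talus + peripheral tibia; S6 central +
    peripheral talus; S7 all four.
    """
    ax = (radius_mm, radius_mm)
    tc = CystSpec("talus", "central", ax)
    tp = CystSpec("talus", "peripheral", ax)
    bc = CystSpec("tibia", "central", ax)
    bp = CystSpec("tibia", "peripheral", ax)
    return {
        "S1": ScenarioSpec("S1", ()),
        "S2": ScenarioSpec("S2", (tc,)),
        "S3": ScenarioSpec("S3", (tp,)),
        "S4": ScenarioSpec("S4", (tc, bc)),
        "S5": ScenarioSpec("S5", (tp, bp)),
        "S6": ScenarioSpec("S6", (tc, tp)),
        "S7": ScenarioSpec("S7", (tc, tp, bc, bp)),
    }


@dataclass(frozen=True)
class GeometryParams:
    """Layout of the idealized ankle cross-section (all lengths in mm).

    Defaults follow frontal-plane ankle proportions: a 30 mm tibial shaft
    cut widening to a 36 mm plafond, an 8 mm fibula (so the fibula carries
    about a fifth of the loaded cross-section, the upper end of the
    physiological share it is credited with), a 54 mm talus and a wider
    calcaneus base, with the medullary canal reaching into the metaphysis.
    ``jitter_mm`` adds seed-controlled smooth contour noise (off by
    default: the default geometry is fully deterministic).
    """

    width: int = 250
    height: int = 250
    pixel_size: float = 0.5

    limb_axis_x: float = 55.0  # vertical limb axis (tibia midline)

    tibia_top: float = 5.0
    tibia_plafond: float = 70.0  # distal articular surface of the tibia
    tibia_half_width_top: float = 15.0
    tibia_half_width_bottom: float = 18.0

    fibula_center_x: float = 84.0  # frontal projection only
    fibula_half_width: float = 4.0
    fibula_top: float = 5.0
    fibula_bottom: float = 76.0  # lateral malleolus tip

    cartilage_thickness: float = 2.0

    talus_height: float = 26.0
    talus_half_width: float = 27.0  # frontal; sagittal uses talus_half_length
    talus_half_length: float = 30.0

    subtalar_cartilage_thickness: float = 2.0

    calcaneus_height: float = 18.0
    calcaneus_half_width: float = 30.0  # frontal; sagittal wider
    calcaneus_half_length: float = 35.0

    cortical_thickness: float = 1.5
    medullary_half_width: float = 6.0
    medullary_bottom: float = 55.0

    soft_margin: float = 4.0  # soft-tissue envelope thickness
    subchondral_max_distance: float = 5.0  # cyst-to-cartilage tolerance

    jitter_mm: float = 0.0
    mirror: bool = False

    def px(self, mm: float) -> int:
        return int(round(mm / self.pixel_size))


def _fill_band(mask: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> None:
    """Set a clipped [r0, r1) x [c0, c1) rectangle to True."""
    h, w = mask.shape
    mask[max(r0, 0) : min(r1, h), max(c0, 0) : min(c1, w)] = True


def _jitter(rng: np.random.Generator, n: int, amp_px: float) -> np.ndarray:
    """Smooth low-frequency contour noise, +-amp_px, length n."""
    if amp_px <= 0:
        return np.zeros(n)
    coarse = rng.uniform(-amp_px, amp_px, size=max(4, n // 16))
    x = np.linspace(0, 1, coarse.size)
    return np.interp(np.linspace(0, 1, n), x, coarse)


def generate_geometry(
    projection: str,
    seed: int = 0,
    params: GeometryParams | None = None,
) -> LabelImage:
    """Generate the cyst-free ankle label image for one projection.

    Deterministic for a given ``(projection, seed, params)``; the seed only
    drives optional contour jitter and has no effect when ``jitter_mm`` is 0.
    Raises :class:`GeometryError` if the resulting solid region does not
    connect the loaded top edge to the restrained bottom edge.
    """
    if projection not in ("frontal", "sagittal"):
        raise ValueError(f"unknown projection {projection!r}")
    p = params or GeometryParams()
    rng = np.random.default_rng(seed)
    H, W = p.height, p.width
    labels = np.zeros((H, W), dtype=np.uint8)

    axis_c = p.px(p.limb_axis_x)
    shell = max(1, p.px(p.cortical_thickness))

    # --- bone silhouettes -------------------------------------------------
    tib_top, tib_bot = p.px(p.tibia_top), p.px(p.tibia_plafond)
    rows = np.arange(tib_top, tib_bot)
    t = (rows - tib_top) / max(1, tib_bot - 1 - tib_top)
    half_w = (p.tibia_half_width_top + t * (p.tibia_half_width_bottom - p.tibia_half_width_top)) / p.pixel_size
    half_w = half_w + _jitter(rng, rows.size, p.jitter_mm / p.pixel_size)
    tibia = np.zeros((H, W), dtype=bool)
    for r, hw in zip(rows, half_w):
        tibia[r, max(axis_c - int(round(hw)), 0) : min(axis_c + int(round(hw)), W)] = True

    fibula = np.zeros((H, W), dtype=bool)
    if projection == "frontal":
        fc = p.px(p.fibula_center_x)
        fhw = p.px(p.fibula_half_width)
        _fill_band(fibula, p.px(p.fibula_top), p.px(p.fibula_bottom), fc - fhw, fc + fhw)

    cart_px = max(1, p.px(p.cartilage_thickness))
    talus_top = tib_bot + cart_px
    talus_bot = talus_top + p.px(p.talus_height)
    talus_hw = p.px(p.talus_half_width if projection == "frontal" else p.talus_half_length)
    talus = np.zeros((H, W), dtype=bool)
    _fill_band(talus, talus_top, talus_bot, axis_c - talus_hw, axis_c + talus_hw)
    # round the talus shoulders with quarter-ellipse cuts (cosmetic only;
    # the flat articular interfaces carry the load path)
    sh = p.px(6.0)
    rr, cc = np.mgrid[0:H, 0:W]
    for sgn in (-1, 1):
        corner_c = axis_c + sgn * talus_hw
        cut = (
            ((rr - (talus_top + sh)) / sh) ** 2 + ((cc - (corner_c - sgn * sh)) / sh) ** 2
            > 1.0
        ) & (rr < talus_top + sh) & (sgn * (cc - (corner_c - sgn * sh)) > 0)
        talus &= ~cut

    sub_px = max(1, p.px(p.subtalar_cartilage_thickness))
    calc_top = talus_bot + sub_px
    calc_bot = calc_top + p.px(p.calcaneus_height)
    calc_hw = p.px(p.calcaneus_half_width if projection == "frontal" else p.calcaneus_half_length)
    calc_c = axis_c if projection == "frontal" else axis_c + p.px(6.0)  # heel sits posteriorly
    calcaneus = np.zeros((H, W), dtype=bool)
    _fill_band(calcaneus, calc_top, calc_bot, calc_c - calc_hw, calc_c + calc_hw)

    bones = {"tibia": tibia, "fibula": fibula, "talus": talus, "calcaneus": calcaneus}

    # --- paint trabecular interiors then cortical shells ------------------
    for mask in bones.values():
        labels[mask] = CLASS_CODES["trabecular"]
    for mask in bones.values():
        if mask.any():
            interior = ndimage.binary_erosion(mask, _FOUR_CONN, iterations=shell)
            labels[mask & ~interior] = CLASS_CODES["cortical"]

    # --- articular cartilage bands ---------------------------------------
    # talocrural: between tibia plafond and talus dome, across their overlap
    tib_cols = np.where(tibia[tib_bot - 1])[0]
    tal_cols = np.where(talus[talus_top])[0]
    joint_cols = np.intersect1d(tib_cols, tal_cols)
    labels[tib_bot:talus_top, joint_cols.min() : joint_cols.max() + 1] = CLASS_CODES["cartilage"]
    # subtalar: between talus and calcaneus
    tal_b = np.where(talus[talus_bot - 1])[0]
    cal_t = np.where(calcaneus[calc_top])[0]
    sub_cols = np.intersect1d(tal_b, cal_t)
    labels[talus_bot:calc_top, sub_cols.min() : sub_cols.max() + 1] = CLASS_CODES["cartilage"]

    # --- ligaments --------------------------------------------------------
    lig = np.zeros((H, W), dtype=bool)
    if projection == "frontal":
        # distal tibiofibular syndesmosis
        _fill_band(lig, p.px(60.0), p.px(64.0), axis_c, p.px(p.fibula_center_x))
        # lateral fibulotalar band
        _fill_band(lig, p.px(p.fibula_bottom), p.px(p.fibula_bottom) + p.px(4.0),
                   axis_c + talus_hw - p.px(2.0), p.px(p.fibula_center_x) + p.px(p.fibula_half_width))
    else:
        # anterior/posterior capsule bands bridging the joint line edges
        for sgn in (-1, 1):
            edge = axis_c + sgn * (p.px(p.tibia_half_width_bottom) + p.px(6.0))
            _fill_band(lig, tib_bot - p.px(4.0), talus_top + p.px(4.0), edge - p.px(2.0), edge + p.px(2.0))
    labels[lig & (labels == CLASS_CODES["background"])] = CLASS_CODES["ligament"]

    # --- synovial fluid pockets at the joint-space recesses ----------------
    fl = np.zeros((H, W), dtype=bool)
    for sgn in (-1, 1):
        c0 = joint_cols.min() - p.px(3.0) if sgn < 0 else joint_cols.max() + 1
        _fill_band(fl, tib_bot, talus_top, c0, c0 + p.px(3.0))
    labels[fl & (labels == CLASS_CODES["background"])] = CLASS_CODES["fluid"]

    # --- medullary cavity inside the tibial shaft -------------------------
    med = np.zeros((H, W), dtype=bool)
    _fill_band(
        med,
        tib_top + 2 * shell,
        p.px(p.medullary_bottom),
        axis_c - p.px(p.medullary_half_width),
        axis_c + p.px(p.medullary_half_width),
    )
    labels[med & (labels == CLASS_CODES["trabecular"])] = CLASS_CODES["medullary"]

    # --- soft-tissue envelope ---------------------------------------------
    struct_mask = labels != CLASS_CODES["background"]
    envelope = ndimage.binary_dilation(struct_mask, _FOUR_CONN, iterations=p.px(p.soft_margin))
    solid_rows = np.where(struct_mask.any(axis=1))[0]
    top_row, bottom_row = solid_rows.min(), solid_rows.max()
    envelope[:top_row] = False  # keep the loaded top and restrained bottom
    envelope[bottom_row + 1 :] = False  # edges purely skeletal
    labels[envelope & ~struct_mask] = CLASS_CODES["soft_tissue"]

    img = LabelImage(labels, p.pixel_size, projection, bones)
    if p.mirror:
        img = LabelImage(
            np.fliplr(img.labels).copy(),
            p.pixel_size,
            projection,
            {k: np.fliplr(v).copy() for k, v in bones.items()},
        )
    check_load_path(img)
    return img


def solid_mask(image: LabelImage) -> np.ndarray:
    """Pixels that belong to the load-bearing structure."""
    excluded = [CLASS_CODES[name] for name in _SOLID_EXCLUDED]
    return ~np.isin(image.labels, excluded)


def check_load_path(image: LabelImage) -> None:
    """Verify one 4-connected solid component spans top to bottom.

    Raises :class:`GeometryError` when the load path is broken.
    """
    solid = solid_mask(image)
    if not solid.any():
        raise GeometryError("empty solid region")
    rows = np.where(solid.any(axis=1))[0]
    top, bottom = rows.min(), rows.max()
    comp, _ = ndimage.label(solid, structure=_FOUR_CONN)
    top_ids = set(np.unique(comp[top][comp[top] > 0]))
    bottom_ids = set(np.unique(comp[bottom][comp[bottom] > 0]))
    if not (top_ids & bottom_ids):
        raise GeometryError(
            "disconnected load path: no solid 4-connected component joins the "
            f"loaded top row {top} to the restrained bottom row {bottom}"
        )


def _resolve_cyst_pixels(
    image: LabelImage, spec: CystSpec
) -> tuple[np.ndarray, tuple[int, int]]:
    """Return (boolean ellipse mask, (row, col) center) for one cyst."""
    if image.bone_masks is None or spec.bone not in image.bone_masks:
        raise CystPlacementError(f"bone {spec.bone!r} not recorded in image")
    bone = image.bone_masks[spec.bone]
    if not bone.any():
        raise CystPlacementError(f"bone {spec.bone!r} absent from this projection")
    ps = image.pixel_size
    trab = bone & (image.labels == CLASS_CODES["trabecular"])
    if not trab.any():
        raise CystPlacementError(f"bone {spec.bone!r} has no trabecular interior")
    rows_any = np.where(bone.any(axis=1))[0]
    cols_any = np.where(bone.any(axis=0))[0]
    r0, c0 = rows_any.min(), cols_any.min()
    width_px = cols_any.max() - c0 + 1
    rx = spec.semi_axes[0] / ps
    ry = spec.semi_axes[1] / ps

    if spec.center is not None:
        cc = c0 + int(round(spec.center[0] / ps))
        cr = r0 + int(round(spec.center[1] / ps))
    else:
        frac = 0.5 if spec.position == "central" else 0.78
        cc = c0 + int(round(frac * (width_px - 1)))
        col_rows = np.where(trab[:, cc])[0]
        if col_rows.size == 0:
            raise CystPlacementError(
                f"no trabecular bone at column {cc} for {spec.position} {spec.bone} cyst"
            )
        if spec.bone == "talus":
            # subchondral plate is the bone's top surface
            cr = col_rows.min() + int(np.ceil(ry)) + 1
        else:
            # distal tibia: subchondral plate is the bottom (plafond)
            cr = col_rows.max() - int(np.ceil(ry)) - 1

    rr, cc_grid = np.ogrid[0 : image.height, 0 : image.width]
    ellipse = ((rr - cr) / ry) ** 2 + ((cc_grid - cc) / rx) ** 2 <= 1.0
    if not ellipse.any():
        raise CystPlacementError("cyst ellipse contains no pixels")
    return ellipse, (cr, cc)


def insert_cysts(image: LabelImage, scenario: ScenarioSpec) -> LabelImage:
    """Return a copy of ``image`` with the scenario's cysts relabeled.

    Each cyst must fall entirely inside the trabecular interior of its bone
    (no overlap with cortical shell, cartilage, or a previously placed cyst)
    and lie within the subchondral tolerance of the articular cartilage.
    """
    out = image.copy()
    cart_dist = None
    for spec in scenario.cysts:
        ellipse, (cr, cc) = _resolve_cyst_pixels(out, spec)
        hit = out.labels[ellipse]
        bad = hit != CLASS_CODES["trabecular"]
        if bad.any():
            offenders = sorted({CLASS_NAMES[int(v)] for v in np.unique(hit[bad])})
            raise CystPlacementError(
                f"{spec.position} {spec.bone} cyst at (row {cr}, col {cc}) overlaps "
                f"non-trabecular tissue: {', '.join(offenders)}"
            )
        if not out.bone_masks[spec.bone][ellipse].all():
            raise CystPlacementError(
                f"{spec.position} {spec.bone} cyst extends outside its bone"
            )
        if cart_dist is None:
            cart = out.labels == CLASS_CODES["cartilage"]
            cart_dist = ndimage.distance_transform_edt(~cart, sampling=out.pixel_size)
        max_d = GeometryParams().subchondral_max_distance
        if float(cart_dist[ellipse].min()) > max_d:
            raise CystPlacementError(
                f"{spec.position} {spec.bone} cyst is not subchondral: nearest "
                f"cartilage {cart_dist[ellipse].min():.1f} mm away (limit {max_d} mm)"
            )
        out.labels[ellipse] = CLASS_CODES["cyst"]
    return out


def render_grayscale(
    image: LabelImage, palette: Mapping[str, int] | None = None
) -> np.ndarray:
    """Map class codes to 8-bit gray levels (the CT2FEM input convention).

    The palette must be injective so that
    :func:`cystfem.materials.grayscale_to_labels` can invert it exactly.
    """
    pal = dict(DEFAULT_PALETTE if palette is None else palette)
    missing = [n for n in CLASS_NAMES if n not in pal]
    if missing:
        raise ValueError(f"palette missing classes: {missing}")
    values = list(pal.values())
    if len(set(values)) != len(values):
        dupes = sorted({v for v in values if values.count(v) > 1})
        raise ValueError(f"palette assigns one gray level to several classes: {dupes}")
    lut = np.zeros(len(CLASS_NAMES), dtype=np.uint8)
    for name, code in CLASS_CODES.items():
        lut[code] = pal[name]
    return lut[image.labels]
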