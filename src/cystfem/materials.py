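"""Tissue elastic properties and the grayscale -> material-attribute step.

Bitmap gray shades carry the material information: each of up to 256 shades
is an "attribute" resolving to a Young's modulus E (MPa) and Poisson ratio
nu.  In the homogenized setting used throughout, every tissue class maps to
one attribute, so an image with k classes produces exactly k attributes.
All moduli are kept in MPa (= N/mm^2) so that stresses come out in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

from .geometry import CLASS_CODES, CLASS_NAMES, DEFAULT_PALETTE, LabelImage

__all__ = [
    "MaterialTable",
    "AttributeMap",
    "default_material_table",
    "grayscale_to_labels",
    "build_attribute_map",
    "attribute_lookup_from_anchors",
    "GPA_TO_MPA",
]

GPA_TO_MPA = 1000.0
KPA_TO_MPA = 1.0e-3


@dataclass(frozen=True)
class MaterialTable:
    """Tissue class -> (E in MPa, Poisson ratio)."""

    entries: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (E, nu) in self.entries.items():
            if name not in CLASS_CODES or name == "background":
                raise ValueError(f"unknown or non-meshable tissue class {name!r}")
            if not E > 0:
                raise ValueError(f"{name}: Young's modulus must be positive, got {E}")
            if not 0 < nu < 0.5:
                raise ValueError(f"{name}: Poisson ratio must lie in (0, 0.5), got {nu}")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, float]]) -> "MaterialTable":
        return cls({k: (float(v["E"]), float(v["nu"])) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "MaterialTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc["materials"] if "materials" in doc else doc)

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {k: {"E": E, "nu": nu} for k, (E, nu) in self.entries.items()}


def default_material_table() -> MaterialTable:
    """Homogenized tissue properties (MPa).

    Cortical bone 20 GPa, trabecular bone 10 GPa, articular cartilage 1 MPa,
    ligament 10 MPa; soft tissue, synovial fluid, medullary cavity and cyst
    fluid all 1 kPa.  Poisson ratio 0.3 for every tissue.
    """
    nu = 0.3
    return MaterialTable(
        {
            "cortical": (20.0 * GPA_TO_MPA, nu),
            "trabecular": (10.0 * GPA_TO_MPA, nu),
            "cartilage": (1.0, nu),
            "ligament": (10.0, nu),
            "soft_tissue": (1.0 * KPA_TO_MPA, nu),
            "fluid": (1.0 * KPA_TO_MPA, nu),
            "medullary": (1.0 * KPA_TO_MPA, nu),
            "cyst": (1.0 * KPA_TO_MPA, nu),
        }
    )


@dataclass
class AttributeMap:
    """Per-pixel attribute index plus the attribute -> (E, nu) lookup.

    ``index`` is int16 with -1 marking background (no element is generated
    there); valid indices address rows of ``lookup`` (shape (n_attr, 2)).
    """

    index: np.ndarray
    lookup: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=np.int16)
        self.lookup = np.asarray(self.lookup, dtype=float)
        if self.lookup.ndim != 2 or self.lookup.shape[1] != 2:
            raise ValueError("lookup must have shape (n_attributes, 2)")
        if self.lookup.shape[0] > 256:
            raise ValueError("at most 256 material attributes are supported")
        if self.index.max(initial=-1) >= self.lookup.shape[0]:
            raise ValueError("attribute index exceeds lookup table")

    @property
    def n_attributes(self) -> int:
        return self.lookup.shape[0]


def grayscale_to_labels(
    bitmap: np.ndarray,
    palette: Mapping[str, int] | None = None,
    pixel_size: float = 0.5,
    projection: str = "frontal",
    nearest: bool = False,
) -> LabelImage:
    """Invert a class palette: gray bitmap -> LabelImage.

    Exact inverse of :func:`cystfem.geometry.render_grayscale` for the same
    palette.  With ``nearest=True``, off-palette shades are binned to the
    nearest palette gray instead of raising (the 256-shade pathway for
    bitmaps that were not produced by the renderer).
    """
    pal = dict(DEFAULT_PALETTE if palette is None else palette)
    bitmap = np.asarray(bitmap)
    if bitmap.ndim != 2:
        raise ValueError("bitmap must be a 2-D grayscale array")
    grays = np.array(sorted(pal.values()))
    gray_to_code = {g: CLASS_CODES[n] for n, g in pal.items()}
    present = np.unique(bitmap)
    unmapped = [g for g in present.tolist() if g not in gray_to_code]
    if unmapped and not nearest:
        counts = {g: int((bitmap == g).sum()) for g in unmapped}
        detail = ", ".join(f"gray {g} ({c} px)" for g, c in counts.items())
        raise ValueError(f"bitmap contains gray values absent from the palette: {detail}")
    lut = np.zeros(256, dtype=np.uint8)
    for g in range(256):
        if g in gray_to_code:
            lut[g] = gray_to_code[g]
        elif nearest:
            lut[g] = gray_to_code[int(grays[np.argmin(np.abs(grays - g))])]
    return LabelImage(lut[bitmap], pixel_size=pixel_size, projection=projection)


def build_attribute_map(image: LabelImage, table: MaterialTable) -> AttributeMap:
    """Assign one material attribute per tissue class present in the image.

    Properties are homogenized: every pixel of a class shares one (E, nu).
    Background receives index -1 and produces no finite element.
    """
    present_codes = np.unique(image.labels)
    names: list[str] = []
    for code in present_codes.tolist():
        name = CLASS_NAMES[code]
        if name == "background":
            continue
        if name not in table:
            raise ValueError(f"material table has no entry for tissue class {name!r}")
        names.append(name)
    lookup = np.array([table[n] for n in names], dtype=float)
    code_to_idx = np.full(len(CLASS_NAMES), -1, dtype=np.int16)
    for i, n in enumerate(names):
        code_to_idx[CLASS_CODES[n]] = i
    return AttributeMap(code_to_idx[image.labels], lookup, tuple(names))


def attribute_lookup_from_anchors(
    anchors: Mapping[int, tuple[float, float]]
) -> np.ndarray:
    """Build a full 256-attribute (E, nu) lookup from sparse gray anchors.

    Between anchor shades, E is interpolated log-linearly (moduli span seven
    orders of magnitude, so linear interpolation would be dominated by the
    stiff anchor) and nu linearly; outside the anchored range the nearest
    anchor is held.  This is the generic shade->property transfer for
    bitmaps with more shades than declared tissues.
    """
    if not anchors:
        raise ValueError("at least one anchor attribute is required")
    grays = np.array(sorted(anchors))
    E = np.array([anchors[g][0] for g in grays], dtype=float)
    nu = np.array([anchors[g][1] for g in grays], dtype=float)
    if (E <= 0).any():
        raise ValueError("anchor moduli must be positive")
    x = np.arange(256)
    logE = np.interp(x, grays, np.log(E))
    nu_full = np.interp(x, grays, nu)
    return np.column_stack([np.exp(logE), nu_full])
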