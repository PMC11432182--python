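"""Bitmap, table and field I/O: PNG/PGM, CSV exports, legacy VTK, contours."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

from .geometry import (
    CLASS_CODES,
    CLASS_NAMES,
    DEFAULT_PALETTE,
    LabelImage,
    render_grayscale,
)
from .fem import StressField

__all__ = [
    "save_grayscale_png",
    "save_pgm",
    "load_grayscale",
    "save_label_png",
    "load_label_png",
    "export_field_csv",
    "export_field_vtk",
    "render_contour_png",
]


def save_grayscale_png(image: LabelImage, path, palette: Mapping[str, int] | None = None) -> None:
    """8-bit grayscale PNG using the class palette (CT2FEM-style input)."""
    Image.fromarray(render_grayscale(image, palette), mode="L").save(path, format="PNG")


def save_pgm(image: LabelImage, path, palette: Mapping[str, int] | None = None) -> None:
    """Binary PGM (P5), the other accepted bitmap interchange format."""
    gray = render_grayscale(image, palette)
    h, w = gray.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n255\n".encode())
        fh.write(gray.tobytes())


def load_grayscale(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG or PGM into an array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def save_label_png(image: LabelImage, path) -> None:
    """Label map as an indexed-palette PNG plus a sidecar class table.

    Pixel values are the class codes themselves; the embedded palette only
    provides display colors.  The sidecar ``<path>.classes.json`` records
    code -> class name and the physical pixel size.
    """
    path = Path(path)
    im = Image.fromarray(image.labels, mode="P")
    colors = np.zeros((256, 3), dtype=np.uint8)
    for name, code in CLASS_CODES.items():
        g = DEFAULT_PALETTE[name]
        colors[code] = (g, g, g)
    im.putpalette(colors.ravel().tolist())
    im.save(path, format="PNG")
    sidecar = {
        "classes": {str(code): name for name, code in CLASS_CODES.items()},
        "pixel_size_mm": image.pixel_size,
        "projection": image.projection,
    }
    Path(f"{path}.classes.json").write_text(json.dumps(sidecar, indent=2))


def load_label_png(path) -> LabelImage:
    path = Path(path)
    with Image.open(path) as im:
        labels = np.asarray(im, dtype=np.uint8)
    sidecar = Path(f"{path}.classes.json")
    pixel_size, projection = 0.5, "frontal"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta.get("pixel_size_mm", 0.5))
        projection = meta.get("projection", "frontal")
        classes = meta.get("classes", {})
        for code, name in classes.items():
            if CLASS_NAMES[int(code)] != name:
                raise ValueError(f"sidecar class table disagrees at code {code}")
    return LabelImage(labels, pixel_size=pixel_size, projection=projection)


def export_field_csv(field: StressField, path) -> None:
    """Per-element stresses: id, centroid x/y (mm), sigma_x/y, tau, sigma_z, vm."""
    m = field.model
    cent = m.nodes[m.elements].mean(axis=1)
    data = np.column_stack(
        [np.arange(m.n_elements), cent, field.sigma, field.sigma_z, field.vm]
    )
    header = "element,x_mm,y_mm,sigma_x,sigma_y,tau_xy,sigma_z,von_mises"
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt=["%d"] + ["%.10g"] * 7)


def export_field_vtk(field: StressField, path) -> None:
    """Legacy ASCII VTK unstructured grid with cell stress data."""
    m = field.model
    lines = [
        "# vtk DataFile Version 3.0",
        "cystfem stress field",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {m.n_nodes} float",
    ]
    for x, y in m.nodes:
        lines.append(f"{x:.6g} {y:.6g} 0")
    lines.append(f"CELLS {m.n_elements} {5 * m.n_elements}")
    for quad in m.elements:
        lines.append("4 " + " ".join(str(int(n)) for n in quad))
    lines.append(f"CELL_TYPES {m.n_elements}")
    lines.extend(["9"] * m.n_elements)  # VTK_QUAD
    lines.append(f"CELL_DATA {m.n_elements}")
    lines.append("SCALARS von_mises float 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{v:.6g}" for v in field.vm)
    lines.append(f"POINT_DATA {m.n_nodes}")
    lines.append("VECTORS displacement float")
    for ux, uy in field.displacements:
        lines.append(f"{ux:.6g} {uy:.6g} 0")
    Path(path).write_text("\n".join(lines) + "\n")


def render_contour_png(field: StressField, path, title: str = "") -> None:
    """Von Mises contour map with an SMax annotation (report-figure style)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = field.model
    H = m.element_pixel[:, 0].max() + 1
    W = m.element_pixel[:, 1].max() + 1
    grid = np.full((H, W), np.nan)
    grid[m.element_pixel[:, 0], m.element_pixel[:, 1]] = field.vm
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(grid, cmap="jet", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="von Mises stress (MPa)")
    ax.set_title(f"{title}  SMax = {np.nanmax(grid):.3g} MPa".strip())
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
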