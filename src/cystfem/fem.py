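"""Plane linear-elastic FEM on the pixel mesh, with von Mises recovery.

Every non-background pixel of a label image becomes one square 4-node
bilinear (Q4) element of side ``pixel_size`` (default 0.5 mm); nodes are
shared between adjacent pixels.  The default formulation is plane strain —
the joint cross-section is laterally constrained by surrounding tissue — in
which the out-of-plane stress sigma_z = nu (sigma_x + sigma_y) enters the
von Mises (Huber-Mises-Hencky) equivalent stress.  Boundary conditions
follow the loading archetype of an axially loaded limb segment: the bottom
edge of the solid region is fully restrained, and a uniform pressure acts
downward (along the limb axis) on the top edge as consistent nodal forces.

Assembly is vectorized over elements; since all elements are congruent
squares, one 8x8 stiffness per distinct material attribute suffices.  The
system is reduced by Dirichlet elimination and solved by sparse LU
(SuperLU) with one step of iterative refinement; a dense direct path exists
as an independent oracle for small models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from .geometry import CLASS_CODES, LabelImage, solid_mask
from .materials import AttributeMap

__all__ = [
    "LoadCase",
    "FEModel",
    "StressField",
    "StressSummary",
    "build_model",
    "assemble_stiffness",
    "assemble_and_solve",
    "von_mises",
    "summarize",
    "periarticular_roi",
    "elastic_matrix",
    "REFERENCE_WEIGHT_KG",
    "REFERENCE_PRESSURE_MPA",
]

# Average axial joint load for the 70 kg reference subject, in N/mm^2 (MPa).
REFERENCE_WEIGHT_KG = 70.0
REFERENCE_PRESSURE_MPA = 0.248

Formulation = Literal["plane_strain", "plane_stress"]


@dataclass(frozen=True)
class LoadCase:
    """A body weight and the axial joint pressure it implies.

    Pressure scales linearly from the 70 kg reference: p = 0.248 * W / 70
    MPa, so p(70) = 0.248 and p(0) = 0.  An explicit ``pressure`` overrides
    the weight-derived value (used by unit tests and the unit-load trick).
    """

    body_weight: float = REFERENCE_WEIGHT_KG
    pressure_override: float | None = None

    @property
    def pressure(self) -> float:
        if self.pressure_override is not None:
            return self.pressure_override
        return REFERENCE_PRESSURE_MPA * self.body_weight / REFERENCE_WEIGHT_KG


@dataclass
class FEModel:
    """The assembled discrete problem on the pixel mesh.

    ``nodes`` are (x, y) in mm with y increasing downward; ``elements`` are
    (n_elem, 4) node indices in the Q4 corner order (-1,-1),(1,-1),(1,1),
    (-1,1); ``element_attr`` indexes ``attr_lookup`` rows of (E, nu).
    ``element_pixel`` maps each element back to its (row, col) pixel.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_attr: np.ndarray
    attr_lookup: np.ndarray
    fixed_dofs: np.ndarray
    forces: np.ndarray
    loaded_nodes: np.ndarray
    pressure: float
    pixel_size: float
    element_pixel: np.ndarray
    formulation: Formulation = "plane_strain"
    top_row: int = 0
    bottom_row: int = 0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_dofs(self) -> int:
        return 2 * self.n_nodes

    def with_pressure(self, pressure: float) -> "FEModel":
        """Same mesh and constraints, rescaled load (stiffness unchanged)."""
        scale = pressure / self.pressure
        return FEModel(
            self.nodes, self.elements, self.element_attr, self.attr_lookup,
            self.fixed_dofs, self.forces * scale, self.loaded_nodes, pressure,
            self.pixel_size, self.element_pixel, self.formulation,
            self.top_row, self.bottom_row,
        )


@dataclass
class StressField:
    """Centroid stresses per element plus nodal displacements.

    Components in MPa: sigma (n_elem, 3) = (sigma_x, sigma_y, tau_xy),
    sigma_z the plane-strain out-of-plane by-product (zero in plane stress),
    ``vm`` the von Mises equivalent stress.  ``displacements`` are (n_nodes,
    2) in mm.  ``residual`` is the normwise backward error of the solve.
    """

    sigma: np.ndarray
    sigma_z: np.ndarray
    vm: np.ndarray
    displacements: np.ndarray
    model: FEModel
    residual: float


@dataclass(frozen=True)
class StressSummary:
    smax: float
    mean: float
    n_elements: int
    argmax_pixel: tuple[int, int]


class SingularModelError(RuntimeError):
    """The reduced stiffness is singular (insufficiently constrained)."""


def elastic_matrix(E: float, nu: float, formulation: Formulation = "plane_strain") -> np.ndarray:
    """3x3 constitutive matrix D for an isotropic material."""
    if formulation == "plane_strain":
        c = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
        return c * np.array(
            [[1.0 - nu, nu, 0.0], [nu, 1.0 - nu, 0.0], [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0]]
        )
    if formulation == "plane_stress":
        c = E / (1.0 - nu**2)
        return c * np.array([[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]])
    raise ValueError(f"unknown formulation {formulation!r}")


_GAUSS = (-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0))


def _b_matrix(xi: float, eta: float, h: float) -> np.ndarray:
    """Strain-displacement matrix of the square Q4 element of side h."""
    dN_dxi = np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)]) / 4.0
    dN_deta = np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]) / 4.0
    dN_dx = dN_dxi * (2.0 / h)
    dN_dy = dN_deta * (2.0 / h)
    B = np.zeros((3, 8))
    B[0, 0::2] = dN_dx
    B[1, 1::2] = dN_dy
    B[2, 0::2] = dN_dy
    B[2, 1::2] = dN_dx
    return B


def element_stiffness(E: float, nu: float, h: float, formulation: Formulation) -> np.ndarray:
    """8x8 Q4 stiffness (2x2 Gauss) for a square element of side h."""
    D = elastic_matrix(E, nu, formulation)
    ke = np.zeros((8, 8))
    detJ_w = (h * h) / 4.0  # det J times unit Gauss weight
    for xi in _GAUSS:
        for eta in _GAUSS:
            B = _b_matrix(xi, eta, h)
            ke += B.T @ D @ B * detJ_w
    return 0.5 * (ke + ke.T)


def build_model(
    image: LabelImage,
    attrs: AttributeMap,
    load: LoadCase,
    formulation: Formulation = "plane_strain",
    bottom_bc: Literal["fixed", "roller"] = "fixed",
) -> FEModel:
    """Mesh the image and attach boundary conditions and loads.

    Only the largest 4-connected component of non-background pixels that
    carries the top-to-bottom load path is meshed.  The loaded edge is the
    topmost row of solid (non-soft-tissue) pixels: a uniform pressure acts
    downward there as consistent nodal forces (p*h/2 per edge node).  The
    restrained edge is the bottom-most solid row; ``bottom_bc='fixed'``
    removes both DOFs of its nodes, ``'roller'`` only the vertical one
    (frictionless support, used by patch tests).
    """
    meshable = attrs.index >= 0
    if not meshable.any():
        raise ValueError("empty solid region: nothing to mesh")
    comp, n_comp = ndimage.label(meshable, structure=ndimage.generate_binary_structure(2, 1))
    solid = solid_mask(image) & meshable
    solid_rows = np.where(solid.any(axis=1))[0]
    top_row, bottom_row = int(solid_rows.min()), int(solid_rows.max())
    # component(s) joining the loaded and restrained rows
    top_ids = np.unique(comp[top_row][comp[top_row] > 0])
    bottom_ids = np.unique(comp[bottom_row][comp[bottom_row] > 0])
    path_ids = np.intersect1d(top_ids, bottom_ids)
    if path_ids.size == 0:
        raise ValueError("load path broken: no connected component spans top to bottom")
    sizes = ndimage.sum_labels(meshable, comp, path_ids)
    keep = int(path_ids[np.argmax(sizes)])
    mesh_px = comp == keep

    H, W = image.labels.shape
    h = image.pixel_size
    prow, pcol = np.nonzero(mesh_px)
    n_elem = prow.size

    # grid-node numbering restricted to used nodes
    corner_ids = np.empty((n_elem, 4), dtype=np.int64)
    # grid node id = r * (W+1) + c ; Q4 order (c,r),(c+1,r),(c+1,r+1),(c,r+1)
    corner_ids[:, 0] = prow * (W + 1) + pcol
    corner_ids[:, 1] = prow * (W + 1) + pcol + 1
    corner_ids[:, 2] = (prow + 1) * (W + 1) + pcol + 1
    corner_ids[:, 3] = (prow + 1) * (W + 1) + pcol
    used, elements = np.unique(corner_ids, return_inverse=True)
    elements = elements.reshape(n_elem, 4)
    node_r, node_c = np.divmod(used, W + 1)
    nodes = np.column_stack([node_c * h, node_r * h]).astype(float)

    element_attr = attrs.index[prow, pcol].astype(np.int64)

    # --- restrained bottom edge ------------------------------------------
    bottom_elems = np.nonzero(solid[prow, pcol] & (prow == bottom_row))[0]
    if bottom_elems.size == 0:
        raise ValueError("no solid pixels on the restrained bottom row")
    bottom_nodes = np.unique(elements[bottom_elems][:, [2, 3]])
    if bottom_bc == "fixed":
        fixed_dofs = np.concatenate([2 * bottom_nodes, 2 * bottom_nodes + 1])
    elif bottom_bc == "roller":
        # vertical support everywhere, one pinned node to kill x translation
        fixed_dofs = np.concatenate([2 * bottom_nodes + 1, [2 * bottom_nodes[0]]])
    else:
        raise ValueError(f"unknown bottom_bc {bottom_bc!r}")
    fixed_dofs = np.unique(fixed_dofs)

    # --- loaded top edge: consistent nodal forces for uniform pressure ----
    top_elems = np.nonzero(solid[prow, pcol] & (prow == top_row))[0]
    if top_elems.size == 0:
        raise ValueError("no solid pixels on the loaded top row")
    p = load.pressure
    forces = np.zeros(2 * nodes.shape[0])
    for corner in (0, 1):  # the two top nodes of each loaded element edge
        np.add.at(forces, 2 * elements[top_elems, corner] + 1, p * h / 2.0)
    loaded_nodes = np.unique(elements[top_elems][:, [0, 1]])

    return FEModel(
        nodes=nodes,
        elements=elements,
        element_attr=element_attr,
        attr_lookup=attrs.lookup.copy(),
        fixed_dofs=fixed_dofs,
        forces=forces,
        loaded_nodes=loaded_nodes,
        pressure=p,
        pixel_size=h,
        element_pixel=np.column_stack([prow, pcol]),
        formulation=formulation,
        top_row=top_row,
        bottom_row=bottom_row,
    )


def assemble_stiffness(model: FEModel) -> csr_matrix:
    """Global sparse stiffness matrix (all DOFs, constraints not applied)."""
    h = model.pixel_size
    kes = np.stack(
        [
            element_stiffness(E, nu, h, model.formulation)
            for E, nu in model.attr_lookup
        ]
    )
    edofs = np.empty((model.n_elements, 8), dtype=np.int64)
    edofs[:, 0::2] = 2 * model.elements
    edofs[:, 1::2] = 2 * model.elements + 1
    rows = np.repeat(edofs, 8, axis=1).ravel()
    cols = np.tile(edofs, (1, 8)).ravel()
    data = kes[model.element_attr].reshape(model.n_elements, 64).ravel()
    K = coo_matrix((data, (rows, cols)), shape=(model.n_dofs, model.n_dofs))
    return K.tocsr()


class FactorizedModel:
    """Reusable LU factorization of the constrained stiffness.

    The stiffness depends only on geometry and materials, not on the load
    level, so one factorization serves every body weight of a scenario;
    each weight is then an independent triangular solve + stress recovery.
    """

    def __init__(self, model: FEModel):
        self.model = model
        if model.fixed_dofs.size < 3:
            raise SingularModelError(
                "fewer than 3 constrained DOFs: rigid-body modes remain"
            )
        self.K = assemble_stiffness(model)
        free = np.ones(model.n_dofs, dtype=bool)
        free[model.fixed_dofs] = False
        self.free = np.nonzero(free)[0]
        Kff = self.K[self.free][:, self.free].tocsc()
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # surface SuperLU singularity warnings
            try:
                self.lu = splu(Kff)
            except Warning as w:  # pragma: no cover - defensive
                raise SingularModelError(f"singular stiffness: {w}") from None
        self._Kff = Kff.tocsr()

    def solve(self, forces: np.ndarray) -> tuple[np.ndarray, float]:
        """Solve K u = f for the free DOFs, with one refinement step.

        Returns the full displacement vector and the normwise relative
        backward error ||K u - f|| / (||K|| ||u|| + ||f||).
        """
        ff = forces[self.free]
        uf = self.lu.solve(ff)
        uf = uf + self.lu.solve(ff - self._Kff @ uf)  # iterative refinement
        if not np.all(np.isfinite(uf)):
            raise SingularModelError("solver produced non-finite displacements")
        r = ff - self._Kff @ uf
        knorm = np.abs(self._Kff).sum(axis=1).max()  # inf-norm
        denom = knorm * np.abs(uf).max(initial=0.0) + np.abs(ff).max(initial=0.0)
        residual = float(np.abs(r).max(initial=0.0) / denom) if denom > 0 else 0.0
        u = np.zeros(self.model.n_dofs)
        u[self.free] = uf
        return u, residual

    def stresses(self, forces: np.ndarray | None = None) -> StressField:
        model = self.model
        u, residual = self.solve(model.forces if forces is None else forces)
        return recover_stresses(model, u, residual)


def recover_stresses(model: FEModel, u: np.ndarray, residual: float = 0.0) -> StressField:
    """Centroid stress recovery from the bilinear displacement field."""
    h = model.pixel_size
    Bc = _b_matrix(0.0, 0.0, h)
    edofs = np.empty((model.n_elements, 8), dtype=np.int64)
    edofs[:, 0::2] = 2 * model.elements
    edofs[:, 1::2] = 2 * model.elements + 1
    strains = u[edofs] @ Bc.T  # (n_elem, 3)
    sigma = np.empty_like(strains)
    for a, (E, nu) in enumerate(model.attr_lookup):
        sel = model.element_attr == a
        if sel.any():
            D = elastic_matrix(E, nu, model.formulation)
            sigma[sel] = strains[sel] @ D.T
    if model.formulation == "plane_strain":
        nus = model.attr_lookup[model.element_attr, 1]
        sigma_z = nus * (sigma[:, 0] + sigma[:, 1])
    else:
        sigma_z = np.zeros(model.n_elements)
    vm = von_mises(sigma[:, 0], sigma[:, 1], sigma[:, 2], sigma_z)
    return StressField(
        sigma=sigma,
        sigma_z=sigma_z,
        vm=vm,
        displacements=u.reshape(-1, 2),
        model=model,
        residual=residual,
    )


def assemble_and_solve(
    model: FEModel,
    method: Literal["sparse", "dense"] = "sparse",
    residual_tol: float = 1.0e-10,
) -> StressField:
    """Solve the static problem and recover centroid stresses.

    ``method='dense'`` solves the reduced system with LAPACK on a dense
    matrix — an independent oracle path intended for small models.  Raises
    :class:`SingularModelError` on singular systems or non-finite results,
    and a RuntimeError if the relative backward error exceeds
    ``residual_tol``.
    """
    if method == "dense":
        K = assemble_stiffness(model)
        free = np.ones(model.n_dofs, dtype=bool)
        free[model.fixed_dofs] = False
        if model.fixed_dofs.size < 3:
            raise SingularModelError("fewer than 3 constrained DOFs")
        Kff = K[free][:, free].toarray()
        ff = model.forces[free]
        try:
            uf = np.linalg.solve(Kff, ff)
        except np.linalg.LinAlgError as e:
            raise SingularModelError(str(e)) from None
        if not np.all(np.isfinite(uf)):
            raise SingularModelError("non-finite displacements")
        u = np.zeros(model.n_dofs)
        u[free] = uf
        r = ff - Kff @ uf
        denom = np.abs(Kff).sum(axis=1).max() * np.abs(uf).max(initial=0.0) + np.abs(ff).max(initial=0.0)
        residual = float(np.abs(r).max(initial=0.0) / denom) if denom > 0 else 0.0
        field = recover_stresses(model, u, residual)
    else:
        field = FactorizedModel(model).stresses()
    if field.residual > residual_tol:
        raise RuntimeError(
            f"solver backward error {field.residual:.2e} exceeds {residual_tol:.0e}"
        )
    return field


def von_mises(
    sx: np.ndarray | float,
    sy: np.ndarray | float,
    txy: np.ndarray | float,
    sz: np.ndarray | float = 0.0,
) -> np.ndarray | float:
    """Von Mises (Huber-Mises-Hencky) equivalent stress.

    sqrt(1/2 [(sx-sy)^2 + (sy-sz)^2 + (sz-sx)^2] + 3 txy^2); non-negative,
    zero only for a stress-free state.
    """
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2) + 3.0 * txy**2
    )


def periarticular_roi(
    image: LabelImage,
    model: FEModel,
    distance_mm: float = 12.0,
    axis_half_width_mm: float | None = 5.0,
    bones: tuple[str, ...] = ("tibia", "talus"),
) -> np.ndarray:
    """Element mask for the subchondral limb-axis zone of the ankle joint.

    The study's quantity of interest is the stress carried along the limb
    axis directly above and below the articular surface, so the ROI is
    cortical/trabecular/cyst pixels of the named bones lying within
    ``distance_mm`` vertically of the talocrural cartilage band and within
    ``axis_half_width_mm`` of the band's column center (``None`` widens the
    core to the full band).  This deliberately excludes far-field restraint
    corners, the fibula tip and the medullary-cavity corners at the tibial
    cut, whose pixel-corner stress concentrations are artifacts of the
    idealized outline, not of the joint.  Falls back to the whole cartilage
    band if bone masks are absent.
    """
    labels = image.labels
    cart = labels == CLASS_CODES["cartilage"]
    if not cart.any():
        raise ValueError("image has no cartilage layer to anchor the ROI")
    if image.bone_masks and "tibia" in image.bone_masks:
        # the talocrural band is the cartilage component touching the tibia
        comp, n = ndimage.label(cart, structure=ndimage.generate_binary_structure(2, 1))
        tib = ndimage.binary_dilation(
            image.bone_masks["tibia"], ndimage.generate_binary_structure(2, 1)
        )
        ids = np.unique(comp[tib & cart])
        ids = ids[ids > 0]
        if ids.size:
            cart = np.isin(comp, ids)
    rows = np.where(cart.any(axis=1))[0]
    cols = np.where(cart.any(axis=0))[0]
    d_px = int(round(distance_mm / image.pixel_size))
    if axis_half_width_mm is None:
        c_lo, c_hi = cols.min(), cols.max()
    else:
        center = 0.5 * (cols.min() + cols.max())
        half = axis_half_width_mm / image.pixel_size
        c_lo = max(int(np.floor(center - half)), cols.min())
        c_hi = min(int(np.ceil(center + half)), cols.max())
    window = np.zeros_like(cart)
    window[
        max(rows.min() - d_px, 0) : rows.max() + d_px + 1,
        c_lo : c_hi + 1,
    ] = True
    bone_px = np.isin(
        labels,
        [CLASS_CODES["cortical"], CLASS_CODES["trabecular"], CLASS_CODES["cyst"]],
    )
    if image.bone_masks:
        named = np.zeros_like(cart)
        for b in bones:
            if b in image.bone_masks:
                named |= image.bone_masks[b]
        bone_px &= named
    keep = window & bone_px
    return keep[model.element_pixel[:, 0], model.element_pixel[:, 1]]


def summarize(
    field: StressField,
    roi: np.ndarray | None = None,
    boundary_layer: int = 2,
    exclude_classes: tuple[str, ...] = (),
    image: LabelImage | None = None,
) -> StressSummary:
    """SMax and mean von Mises stress over a region of interest.

    By default the ROI is every meshed element whose pixel row lies more
    than ``boundary_layer`` elements away from the loaded top and fully
    fixed bottom rows — the clamped edge produces artificial concentrations
    that are an artifact of the restraint, not of the joint.  ``roi`` may
    override with an explicit boolean element mask; ``exclude_classes``
    (with ``image``) drops named tissue classes from the ROI.
    """
    model = field.model
    if roi is None:
        rows = model.element_pixel[:, 0]
        roi = (rows > model.top_row + boundary_layer) & (
            rows < model.bottom_row - boundary_layer
        )
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != (model.n_elements,):
            raise ValueError("roi must be a boolean mask over elements")
    if exclude_classes:
        if image is None:
            raise ValueError("exclude_classes requires the label image")
        codes = [CLASS_CODES[c] for c in exclude_classes]
        px = image.labels[model.element_pixel[:, 0], model.element_pixel[:, 1]]
        roi = roi & ~np.isin(px, codes)
    if not roi.any():
        raise ValueError("empty region of interest")
    vm = field.vm[roi]
    idx = np.nonzero(roi)[0][int(np.argmax(vm))]
    return StressSummary(
        smax=float(vm.max()),
        mean=float(vm.mean()),  # equal-area pixels: plain mean is area-weighted
        n_elements=int(roi.sum()),
        argmax_pixel=tuple(int(v) for v in field.model.element_pixel[idx]),
    )
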