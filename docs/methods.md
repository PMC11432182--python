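# Methods

## The model

The package simulates stress in a diseased ankle joint with a 2-D
image-based finite-element idealization. A labeled bitmap of the joint
cross-section (250×250 pixels, 0.5 mm per pixel) is converted one-to-one
into a structured mesh of square 4-node bilinear (Q4) elements: every
non-background pixel is one element; nodes are shared between adjacent
pixels. Tissue classes carry homogenized isotropic elastic properties

| class        | E (MPa) | ν   |
|--------------|--------:|-----|
| cortical     | 20 000  | 0.3 |
| trabecular   | 10 000  | 0.3 |
| cartilage    | 1       | 0.3 |
| ligament     | 10      | 0.3 |
| soft tissue  | 0.001   | 0.3 |
| fluid        | 0.001   | 0.3 |
| medullary    | 0.001   | 0.3 |
| cyst         | 0.001   | 0.3 |

A cyst is mechanically a fluid space (1 kPa): a compliant inclusion inside
trabecular bone. Retaining ν = 0.3 even for fluid-like tissues is a
deliberate simplification of the homogenized model (a true fluid would be
nearly incompressible); it keeps every material in the same constitutive
family and far from the ν → 0.5 locking regime.

**Formulation.** Plane strain by default — a joint cross-section is
laterally constrained by the surrounding tissue, so zero out-of-plane
strain is the appropriate 2-D reduction of a single-layer 3-D model; plane
stress is available as a switch (`formulation`). In plane strain the
out-of-plane stress σz = ν(σx+σy) is carried into the von Mises
(Huber–Mises–Hencky) equivalent stress
σ_vM = √(½[(σx−σy)²+(σy−σz)²+(σz−σx)²]+3τxy²).

**Boundary conditions and load.** All degrees of freedom are removed at
the nodes of the bottom-most solid row (the model's base); a uniform
pressure acts vertically (along the limb axis) on the topmost solid row,
applied as consistent nodal forces p·h/2 per element edge node. For body
weight W the pressure is p = 0.248·W/70 N/mm², i.e. 0.248 MPa for the
70 kg reference subject, rising to ≈0.602 MPa at 170 kg. (The per-weight
pressures are always computed from this ratio rather than tabulated; the
derived values agree with conventional rounded listings to within
0.002 MPa.) A frictionless-roller variant of the base support exists for
verification problems (patch tests need the lateral expansion free).

**Solution and stress recovery.** Because every element is the same
square, one 8×8 stiffness (2×2 Gauss) per distinct material attribute
suffices; assembly is vectorized into a sparse matrix. Dirichlet rows are
eliminated and the reduced system is factorized with SuperLU; one step of
iterative refinement follows each triangular solve. The normwise backward
error ‖Ku−f‖∞/(‖K‖∞‖u‖∞+‖f‖∞) is recorded per solve and must stay below
10⁻¹⁰ (observed: ~10⁻¹⁶). A dense LAPACK path provides an independent
oracle for small systems. Stresses are evaluated once per element at the
centroid from the bilinear displacement field — matching the
constant-per-element rendering of the stress maps and avoiding any nodal
averaging policy. The stiffness does not depend on the load level, so the
experiment grid factorizes once per scenario × projection and performs an
independent triangular solve and stress recovery per body weight; a
`fast` mode instead rescales the 70 kg solution exactly (linear
elasticity), and the default mode doubles as a built-in linearity check.

## The synthetic geometry

The original study's hand-drawn joint contours are not published, so the
generator produces a parametric stand-in with the same design intent: an
impersonal, idealized ankle silhouette rather than patient anatomy.
Frontal-plane proportions follow gross anatomy — a 30 mm tibial shaft cut
widening to a 36 mm plafond, an 8 mm fibula (≈20% of the loaded
cross-section, the upper end of its physiological load share), a 54 mm
talus (60 mm long in the sagittal plane) and a wider calcaneus base — with
1.5 mm cortical shells, 2 mm cartilage gaps bridging every joint space,
syndesmotic/capsular ligament bands, small synovial fluid pockets, a
medullary canal reaching into the distal metaphysis, and a 4 mm soft-tissue
envelope. The load path (tibia → cartilage → talus → cartilage →
calcaneus) is verified by 4-connected flood fill; parameter sets that break
it are rejected.

Cysts default to 4 mm-radius circles (configurable ellipses). "Central"
places the cyst on the bone's vertical midline — the limb axis — and
"peripheral" at 0.78 of the bone's width (the lateral third); both are
tucked directly under the subchondral plate (placement is rejected if the
cyst is farther than 5 mm from articular cartilage, overlaps cortical
bone, cartilage, or another cyst, or leaves its bone). The seven standard
scenarios are: S1 none; S2 talus central; S3 talus peripheral; S4 talus +
tibia central; S5 talus + tibia peripheral; S6 talus central + peripheral;
S7 all four.

The default geometry is fully deterministic; a seed only drives optional
smooth contour jitter (`jitter_mm`, off by default), so identical inputs
give bit-identical bitmaps — a property the reproducibility tests rely on.

**What the phantom does not emulate.** No torsion, no contact mechanics
between articular surfaces, no talocalcaneal-joint kinematics, no
anisotropy or real trabecular microstructure, no patient-specific shape
variation. Consequently, passing tests demonstrate the internal
consistency of the method and the direction and rough magnitude of cyst
effects on an idealized joint — not absolute stresses in any real ankle.

## The summary stress and its region of interest

The quantity tabulated per (scenario, weight) is SMax — the maximum von
Mises stress — inside the subchondral limb-axis core: cortical/trabecular
(and cyst) pixels of the tibia and talus lying within 12 mm vertically of
the talocrural cartilage band and within ±5 mm (cyst radius + 1 mm rim) of
the band's column center. This is the region the study's stress maps
annotate and the one its central-vs-peripheral contrast refers to: a
peripheral cyst raises stress around *itself* but barely shifts the
limb-axis field. The restriction also excludes pixel-corner stress
concentrations at the fully clamped base, the fibula tip and the
medullary-canal corners, which are artifacts of the idealized outline. A
generic `summarize()` with a boundary-layer exclusion (default 2 elements
off the loaded/restrained edges) is available for arbitrary ROIs, and the
ROI mean is reported alongside SMax in the run manifest. Frontal and
sagittal summaries are combined by plain arithmetic mean (no weighting is
justified by the study design).

## Statistical conventions

- **Descriptives**: mean and *population* SD (denominator n). The
  published summary row follows this convention — the control column's
  sample SD would round to 0.39, not the printed 0.35 — so the population
  form is the default and the (n−1) form sits behind a flag.
- **Slopes**: ordinary least squares of stress on body weight, reported
  both raw and rounded to 2 decimals (the headline "0.01/0.02 MPa per kg"
  claim is a rounded figure). Rounding is decimal half-up
  (`round_half_up`), the convention of printed tables; binary-float
  `round()` can disagree exactly at .xx5 boundaries.
- **Friedman test**: within-block (per-weight) average ranks,
  χ² = 12/(nk(k+1))·ΣR² − 3n(k+1), df = k−1, p from the χ² distribution.
  No tie-correction factor is applied (the classic statistic); the
  tie-corrected variant in scipy serves as a cross-check oracle on
  tie-free tables, where the two coincide.
- **Wilcoxon matched pairs**: two-sided; zero differences are dropped with
  a warning (all-zero pairs report p = 1). Default mode enumerates all 2ⁿ
  sign assignments of the (average-tied) ranks — exact even under ties.
  At n = 6 blocks the smallest achievable exact two-sided p is
  2/2⁶ = 0.03125, so a blanket "all p < 0.03" can only arise from the
  normal approximation; the `approx` mode (no continuity correction,
  tie-corrected variance) reproduces that behaviour, and the report
  records which mode satisfies the bound. No multiple-testing correction
  is applied by default (none is part of the original analysis);
  Bonferroni/Holm are available as options.

## Numerical and design choices

- Background pixels produce no element (rather than near-zero stiffness):
  this avoids conditioning problems while the 1 kPa soft-tissue envelope
  already represents the compliant surround. Only the largest 4-connected
  component carrying the top-to-bottom load path is meshed.
- The grayscale pathway mirrors a 256-attribute shade-to-material mapping:
  a class palette renders label images to 8-bit bitmaps and inverts
  exactly; off-palette shades can be binned to the nearest palette entry,
  and a full 256-bin lookup can be built from sparse anchors with
  log-linear interpolation of E (moduli span seven orders of magnitude,
  so linear interpolation would be meaningless) and linear ν.
- Mesh convergence: with the 0.5 mm pixel mesh the cyst-rim maxima are
  mildly mesh-dependent (soft-inclusion corners are stress risers); a
  refinement test (1.0 → 0.5 → 0.25 mm) verifies that probe stresses away
  from singular corners converge with shrinking increments. Scenario
  *comparisons* are made at fixed resolution, so this discretization bias
  largely cancels.
- Degenerate inputs fail loudly: empty ROI, broken load path, missing
  material entries, unmapped gray shades (reported with value and pixel
  count), under-constrained models, non-finite solutions.
- Problem sizes: the default grid solves 14 distinct systems of ≈27 000
  elements / ≈56 000 DOF (84 load cases), a desk-scale budget chosen so
  the full experiment plus its repetition for the reproducibility check
  completes in a few minutes on one CPU.

## Known limitations

- Absolute stress magnitudes depend on the unpublished original contours;
  only ratios and orderings between scenarios are meaningful, and those
  reproduce the expected pattern (central cysts raise the limb-axis SMax
  strongly, adding a tibial central cyst raises it further, peripheral
  cysts leave it within the control band — the configured band is ±50%).
- The S5 column of the published table contains a non-monotone value at
  130 kg (1.05 MPa between 2.08 and 1.59 in the same row); it is preserved
  exactly as printed — it is what makes that scenario's stress–weight
  correlation 0.91 instead of ≈1 — and the packaged fixture makes no
  attempt to repair it.
- The published list of significant Wilcoxon pairs is internally
  inconsistent (one pair listed twice, one pair both significant and not);
  the report therefore always emits the full 21-pair matrix and leaves
  interpretation to the reader.
- Linear elasticity, static loading: no cyclic damage, no poroelastic
  fluid behaviour, no geometric nonlinearity.
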