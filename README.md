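# cystfem

Pixel-based 2-D finite-element modeling of ankle-joint stress in the
presence of subchondral bone cysts, together with the repeated-measures
statistics used to compare cyst scenarios across body weights.

Subchondral cysts — fluid-filled cavities beneath the articular cartilage —
are a hallmark of degenerative joint disease. This package asks a simple
biomechanical question: how do the number and location (central vs
peripheral, talus vs tibia) of such cysts change the von Mises stress
carried by the ankle joint as body weight rises from 70 to 170 kg? It is
aimed at computational-biomechanics researchers who want a fully scripted,
dependency-light re-run of that in-silico experiment.

The pipeline has three stages, each usable on its own:

1. **Synthetic geometry** (`cystfem.geometry`): a deterministic generator
   of labeled 250×250 bitmaps (pixel = 0.5 mm) of an idealized ankle
   cross-section in frontal and sagittal projections — tibia (+fibula),
   talus, calcaneus base, cortical shells, cartilage gaps, ligaments,
   medullary canal, soft tissue — with parametric cyst insertion for the
   seven standard scenarios S1..S7 (S1 = no cyst … S7 = four cysts).
2. **Image-based FEM** (`cystfem.materials`, `cystfem.fem`): each
   non-background pixel becomes one square bilinear (Q4) plane-strain
   element whose (E, ν) comes from its tissue class (cortical 20 GPa,
   trabecular 10 GPa, cartilage 1 MPa, ligament 10 MPa, fluid-like tissues
   1 kPa; ν = 0.3). The bottom edge is fully restrained and the top edge
   carries a uniform axial pressure p = 0.248 · W/70 MPa for body weight W.
   The solver is a sparse direct factorization of K·u = f; element
   stresses are recovered at centroids and reduced to the von Mises
   (Huber–Mises–Hencky) equivalent

   σ_vM = √(½[(σx−σy)² + (σy−σz)² + (σz−σx)²] + 3τxy²),  σz = ν(σx+σy).

3. **Statistics** (`cystfem.stats`): for a scenario × weight stress table —
   simulated, or the published one shipped as `cystfem/data/table1.csv` —
   per-scenario means with *population* SD (σ = √(Σ(x−x̄)²/n)), per-kg
   least-squares slopes, Pearson correlation with weight, the Friedman
   rank test across scenarios (weights as blocks), and all pairwise
   Wilcoxon matched-pairs tests (exact 2ⁿ enumeration by default, normal
   approximation optionally).

## Worked example

```python
>>> from cystfem import ExperimentConfig, run_grid
>>> result = run_grid(ExperimentConfig())      # 7 scenarios x 6 weights x 2 planes
>>> print(result.table.round(4).to_string())
            S1      S2      S3      S4      S5      S6      S7
weight
70.0    0.2796  0.6815  0.3752  0.7232  0.7856  0.6683  1.4151
90.0    0.3595  0.8762  0.4824  0.9299  1.0100  0.8592  1.8194
110.0   0.4394  1.0709  0.5896  1.1365  1.2344  1.0501  2.2237
130.0   0.5193  1.2656  0.6968  1.3432  1.4589  1.2411  2.6280
150.0   0.5992  1.4603  0.8040  1.5498  1.6833  1.4320  3.0323
170.0   0.6791  1.6550  0.9112  1.7564  1.9078  1.6229  3.4366
```

Each cell is the subchondral limb-axis SMax (MPa), averaged over the two
projections. Reading the 70 kg row: a central talus cyst (S2) raises the
stress 2.44× over the cyst-free control (S1); adding a central tibia cyst
(S4) raises it a further 6%; a peripheral cyst (S3) leaves the limb-axis
stress within 35% of control. Columns scale exactly with body weight
(0.6791/0.2796 = 170/70), the in-silico counterpart of the perfect
stress–weight correlation.

Statistics on the published stress table:

```text
$ cystfem stats --table src/cystfem/data/table1.csv --mode exact
scenario  mean±SD (MPa)   slope (MPa/kg)  Pearson r
      S1  1.24 ± 0.35     0.01 (0.0104)   1.0000
      S2  1.81 ± 0.52     0.02 (0.0152)   1.0000
      S3  1.26 ± 0.36     0.01 (0.0105)   0.9999
      S4  1.92 ± 0.55     0.02 (0.0160)   1.0000
      S5  1.32 ± 0.42     0.01 (0.0111)   0.9123
      S6  1.48 ± 0.42     0.01 (0.0123)   0.9999
      S7  1.70 ± 0.49     0.01 (0.0142)   0.9996
Friedman chi2(6) = 34.93, p = 4.45e-06
Wilcoxon (exact): all off-diagonal p < 0.03: False
```

The central-cyst scenarios S2 and S4 stand out (1.81 and 1.92 MPa against
1.24 MPa for the control) and gain 0.02 MPa per kilogram of body weight,
twice the rate of the other scenarios; the Friedman test confirms the
scenario effect. Note the exact two-sided Wilcoxon p at n = 6 cannot fall
below 2/2⁶ = 0.03125; only the normal-approximation mode (`--mode approx`)
reaches p < 0.03.

## Command line

```bash
cystfem generate --projection frontal --scenario S4 --seed 0 --out s4.png
cystfem batch --out results/grid            # full 84-solve grid [--fast]
cystfem stats --table results/grid/stress_table.csv --out report.json
```

The numbered drivers under `analysis/` run the same stages as a narrative
sequence: `01_generate_geometry.py` (phantom bitmaps),
`02_run_grid.py` (the 84-solve experiment and its findings),
`03_statistics.py` (reports for the published and simulated tables).

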