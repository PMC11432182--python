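# Default experiment configuration: the full study grid.
scenarios: [S1, S2, S3, S4, S5, S6, S7]
weights: [70, 90, 110, 130, 150, 170]
projections: [frontal, sagittal]
formulation: plane_strain
boundary_layer: 2
qualitative_band: 0.5
seed: 0
fast: false

# Homogenized tissue elastic properties, E in MPa, nu dimensionless.
materials:
  cortical:    {E: 20000.0, nu: 0.3}
  trabecular:  {E: 10000.0, nu: 0.3}
  cartilage:   {E: 1.0,     nu: 0.3}
  ligament:    {E: 10.0,    nu: 0.3}
  soft_tissue: {E: 0.001,   nu: 0.3}
  fluid:       {E: 0.001,   nu: 0.3}
  medullary:   {E: 0.001,   nu: 0.3}
  cyst:        {E: 0.001,   nu: 0.3}
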