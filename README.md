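# nirjoint

Voxel Monte Carlo simulation of dual-mode (reflectance + transmission)
near-infrared trans-illumination of a human finger joint, for studying the
optical signature of rheumatoid arthritis (RA) and the robustness of its
diagnostic metrics across skin phenotypes.

## Who this is for

Biomedical-optics researchers and instrument designers who want to
stress-test continuous-wave NIR probe geometries against a controllable
digital joint: how does the detected signal respond as clear synovial fluid
turns into turbid, vascularized pannus and the joint swells, and which
detector-side metrics survive strong epidermal melanin absorption?

## The model

A finger is a voxelized cylinder (bone core, joint annulus, generic soft
tissue, optional epidermis shell, ambient outside).  Disease severity
*s* ∈ [0, 100] % maps linearly onto the joint geometry: the annulus material
is clear synovial fluid at *s* = 0 and turbid pannus otherwise, with layer
thickness 0.5 + 0.01·s mm, local swelling 0.01·s mm (cosine-tapered), and
lateral extent 8 + 0.02·s mm.

Tissue absorption at 850 nm is composed from chromophore volume fractions,
µ_a = Σᵢ fᵢ µ_a,ᵢ(λ), with whole blood
µ_a = ln 10 · [S·ε_HbO₂ + (1−S)·ε_Hb] · C_Hb / M_Hb
(S = oxygen saturation, C_Hb = 150 g/L, M_Hb = 64 500 g/mol) and an
epidermis parameterized by the melanosome volume fraction f_mel
(light 0.03, medium 0.15, dark 0.35).

Photon transport is standard weighted hop–drop–spin in a voxel lattice:
dimensionless steps s = −ln ξ consumed against the local µ_t = µ_a + µ_s,
Henyey–Greenstein scattering with anisotropy g, unpolarized Fresnel
reflection/refraction at index-mismatched voxel crossings using surface
normals estimated from a Gaussian-smoothed refractive-index field (so
curved interfaces refract correctly), and Russian roulette below a weight
threshold.  Escaping photons are binned into a 128-pixel effective CCD
(0.224 mm pitch, 28.672 mm imaging length).

Diagnostic metrics:

- ȳ_c — mean detected transmission over the central 5 mm region of
  interest (the severity-grading metric);
- W = (∫ y(x) dx) / ȳ_c — equivalent beam width, a threshold-free
  broadening measure;
- reflectance ROI fluxes at fixed source–detector separations (the
  disease-onset discriminator);
- µ_eff = √(3 µ_a µ_s′) — effective attenuation coefficient.

## Worked example

```python
from nirjoint.experiments import CampaignConfig, run_progression

result = run_progression(CampaignConfig(
    severities=(0, 25, 50, 75, 100), initial_photons=100_000,
    max_photons=800_000, seed=1, voxel_size=0.2))
print(result.table[["severity", "y_bar_c", "W_mm", "refl_10mm"]].to_string(index=False))
print(result.summary.to_string(index=False))
```

prints (per-launched-photon units):

```
 severity  y_bar_c      W_mm  refl_10mm
      0.0 0.000071 15.025846   0.002330
     25.0 0.000038 17.303478   0.002008
     50.0 0.000029 19.010906   0.001818
     75.0 0.000026 17.539104   0.001660
    100.0 0.000022 17.916941   0.001632

phenotype  sensitivity_ratio  relative_drop_percent  W_change_percent
     none           0.307499              69.250083          19.24081
```

Read: the central transmission flux ȳ_c falls monotonically with severity
(a 69% drop from healthy to grade 2 — a volume proxy), the largest step in
the 10 mm reflectance ROI is the 0 → 25 % material transition (an onset
discriminator), and the transmitted beam broadens (W + 19%) as pannus
scattering grows.

A command-line interface mirrors the library
(`nirjoint compose-tissues`, `build-phantom`, `simulate`, `progression`,
`skin-sweep`, `metrics`, `synth`).

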