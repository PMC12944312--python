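# Material catalog for the finger-joint models, 850 nm.
# Each material is either a literal set of optical properties or a chromophore
# composition rule (volume fractions; remainder non-absorbing) plus literal
# scattering parameters.  Units: mm^-1 for mua/musp; g, n dimensionless.
wavelength_nm: 850
materials:
  ambient:
    literal: {mua: 0.0, musp: 0.0, g: 0.0, n: 1.0}
  generic_tissue:
    composition:
      components: {lipid: 0.85, water: 0.13, blood: 0.02}
      so2: 0.75
      chb_g_per_l: 150.0
    musp: 1.288
    g: 0.90
    n: 1.37
  bone:
    # dry bovine bone matrix row taken literally; not reproducible from the
    # embedded chromophores
    literal: {mua: 0.00724, musp: 1.760, g: 0.90, n: 1.55}
  synovial_fluid:
    # mostly water: protein/hyaluronic absorption neglected, 0.99 x water
    composition:
      components: {water: 0.99}
    musp: 0.020
    g: 0.80
    n: 1.34
  turbid_pannus:
    # vascularized hypoxic hypertrophic synovium
    composition:
      components: {water: 0.80, blood: 0.08}
      so2: 0.50
      chb_g_per_l: 150.0
    musp: 1.288
    g: 0.90
    n: 1.40
  epidermis_light:   # Fitzpatrick I-II, f_mel = 0.03
    composition:
      components: {melanosome: 0.03, skin_baseline: 0.97}
    musp: 2.353
    g: 0.90
    n: 1.37
  epidermis_medium:  # Fitzpatrick III-IV, f_mel = 0.15
    composition:
      components: {melanosome: 0.15, skin_baseline: 0.85}
    musp: 2.353
    g: 0.90
    n: 1.37
  epidermis_dark:    # Fitzpatrick V-VI, f_mel = 0.35
    composition:
      components: {melanosome: 0.35, skin_baseline: 0.65}
    musp: 2.353
    g: 0.90
    n: 1.37
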