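# Built-in material library.
#
# mass_attenuation: mu/rho in cm^2/g at the three Lu-177 photopeak energies,
# keyed by the nominal photopeak label (keV).  Water, soft tissue (ICRU-44)
# and cortical bone (ICRU-44) values are log-log interpolations of the
# standard NIST photon cross-section compilation to 55.8, 112.9 and
# 208.4 keV.  PMMA is pinned to the constants used for the camera's PMMA
# calibration series (rho = 1.18 g/cm^3; 0.20 / 0.16 / 0.13 cm^2/g).
materials:
  water:
    density_g_cm3: 0.998
    mass_attenuation:
      55: 0.2140
      113: 0.1644
      208: 0.1350
  soft_tissue:
    density_g_cm3: 1.06
    mass_attenuation:
      55: 0.2130
      113: 0.1631
      208: 0.1338
  cortical_bone:
    density_g_cm3: 1.92
    mass_attenuation:
      55: 0.3545
      113: 0.1734
      208: 0.1287
  pmma:
    density_g_cm3: 1.18
    mass_attenuation:
      55: 0.20
      113: 0.16
      208: 0.13
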