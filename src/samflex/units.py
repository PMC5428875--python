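"""Unit conversion constants.

Everything inside the package is strict SI (Pa, m, kg, s, Hz); practical
lab units (GPa, nm, μm, molecules/cm², Da) are converted at the interface
boundary with these constants.
"""

GPA = 1e9          # Pa per GPa
NM = 1e-9          # m per nm
UM = 1e-6          # m per μm
PER_CM2 = 1e4      # (molecules/m²) per (molecules/cm²)
DALTON = 1.66053906660e-27  # kg per unified atomic mass unit

#: Mass of one water molecule, kg.
WATER_MOLECULE_MASS = 2.9915e-26
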