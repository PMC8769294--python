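"""Unit conversion constants, centralized.

Internally the package works in SI: lengths in metres, amounts in moles,
volumes in litres, concentrations in mol/L (converted to mol/m^3 only
inside the Beer-Lambert fit so that epsilon carries m^2/mol). Output
tables use the presentation units common in cytometry: fmol per cell,
pL volumes, mmol/L molarities, micrometre geometry.
"""

M_PER_UM = 1e-6
M2_PER_UM2 = 1e-12
L_PER_UM3 = 1e-15  # 1 um^3 = 1e-18 m^3 = 1e-15 L

MOL_PER_M3_PER_MOL_PER_L = 1000.0  # 1 mol/L = 1000 mol/m^3

FMOL_PER_MOL = 1e15
PL_PER_L = 1e12
MMOL_PER_MOL = 1e3
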