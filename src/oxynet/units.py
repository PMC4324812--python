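"""Unit conventions and conversion constants.

Internal unit system (used by every module):

====================  =========================
quantity              internal unit
====================  =========================
length                µm
time                  s
pressure              mmHg
amount of substance   µmol
concentration         µmol/µm³
viscosity             mmHg·s
flow rate             µm³/s
====================  =========================

All literature parameter values quoted in CGS/molar units are converted at
configuration-construction time through the constants below, so each
conversion is visible in exactly one place (`oxynet.config`).
"""

#: centimetres → micrometres
CM_TO_UM = 1.0e4

#: cm² → µm²
CM2_TO_UM2 = 1.0e8

#: 1 centipoise expressed in mmHg·s  (1 cP = 1e-3 Pa·s, 1 mmHg = 133.322 Pa)
CP_TO_MMHG_S = 1.0e-3 / 133.322

#: mol/L → µmol/µm³   (1 L = 1e15 µm³, 1 mol = 1e6 µmol)
MOLAR_TO_UMOL_PER_UM3 = 1.0e-9

#: mol → µmol
MOL_TO_UMOL = 1.0e6

#: hours → seconds
HOUR_TO_S = 3600.0

#: mmHg → dyn/cm² (for reporting wall shear stress in CGS if desired)
MMHG_TO_DYN_PER_CM2 = 1333.22
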