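"""Empirical constants and defaults used across the package.

The pressure/flow and tissue-resistance correlations are empirical linear
fits; their unit conventions were fixed by back-calculation against the
printed anchor values (see each entry).  All conversions to SI happen at the
point of use — the correlations below are stated in the units in which they
were reported.
"""

import math

# --- pressure / flow correlations -------------------------------------------

#: Needle-tip pressure correlation  p [kPa] = 0.74 * q + 23,  q in uL/s.
#: With q in uL/s the correlation reproduces 23.3 kPa at 25 uL/min.
PRESSURE_FLOW_SLOPE_KPA_PER_UL_S = 0.74
PRESSURE_FLOW_INTERCEPT_KPA = 23.0

#: Tissue resistance pressure  TRP [kPa] = 10.4 * q + 1.14,  q in mL/min.
#: With q in mL/min the correlation reproduces 1.4 kPa at 0.025 mL/min.
TRP_SLOPE_KPA_PER_ML_MIN = 10.4
TRP_INTERCEPT_KPA = 1.14

#: Closed-form permeability constants derived from the two above:
#: k = 1/(2.96*pi*r_t) * q/(q + 31.08)  with q in uL/s, where
#: 2.96*pi = 4*pi*0.74 and 31.08 = 23/0.74.
PERMEABILITY_FORM_FACTOR = 2.96 * math.pi
PERMEABILITY_FLOW_OFFSET_UL_S = PRESSURE_FLOW_INTERCEPT_KPA / PRESSURE_FLOW_SLOPE_KPA_PER_UL_S  # 31.08...

# --- fracture mechanics ------------------------------------------------------

#: Geometry factor in the tunnelling-crack energy release rate J = P^2 h / (1.27 E).
FRACTURE_GEOMETRY_FACTOR = 1.27

#: Fracture threshold of subcutaneous tissue [kJ/m^2] at crack width h = 800 um.
DEFAULT_JA_KJ_M2 = 4.1

#: Average micro-crack width inside the tissue [um].
DEFAULT_CRACK_WIDTH_UM = 800.0

#: Effective Young's modulus [kPa]: least-squares value jointly consistent with
#: the two (P, J) anchor pairs (23.3 kPa, 340 J/m^2) and (94 kPa, 5.5 kJ/m^2)
#: at h = 800 um.  Not directly reported; configurable everywhere it is used.
DEFAULT_YOUNGS_MODULUS_KPA = 1.01

# --- depot geometry ----------------------------------------------------------

#: Effective volume fraction of solution filling the injection region.
DEFAULT_EPSILON = 1.0

# --- imaging -----------------------------------------------------------------

#: Effective detector pixel size [um].
DEFAULT_PIXEL_SIZE_UM = 9.0

#: Detector field of view [mm], (width, height).
DEFAULT_FIELD_OF_VIEW_MM = (36.0, 24.0)

#: Linear absorption coefficient of the iodinated drug solution [1/mm].
#: Not reported; representative of a ~25% iodine contrast dilution at 80 kVp.
DEFAULT_MU_ABS_PER_MM = 0.15

#: Sliding-window edge used for RCS profiles and C_v ROIs [mm].
DEFAULT_ROI_SIZE_MM = 0.9

# --- unit conversion helpers --------------------------------------------------

UL_PER_MIN_TO_M3_PER_S = 1e-9 / 60.0
UL_PER_S_TO_M3_PER_S = 1e-9
ML_PER_MIN_TO_M3_PER_S = 1e-6 / 60.0
KPA_TO_PA = 1e3
UM_TO_M = 1e-6
MM_TO_M = 1e-3
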