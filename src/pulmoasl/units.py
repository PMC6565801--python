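"""Unit conversion constants.

Internal convention throughout the package: lengths in mm, pressures in Pa,
flows in mm^3/s, time in ms where noted (MR timings) and s otherwise,
viscosity in Pa*s.  With lengths in mm and viscosity in Pa*s, the Poiseuille
resistance 8*mu*L/(pi*r^4) comes out directly in Pa*s/mm^3, so Q [mm^3/s]
times R gives Pa with no further factors.
"""

MMHG_TO_PA = 133.322387415
CMH2O_TO_PA = 98.0665
L_PER_MIN_TO_MM3_PER_S = 1.0e6 / 60.0

PA_TO_MMHG = 1.0 / MMHG_TO_PA
PA_TO_CMH2O = 1.0 / CMH2O_TO_PA
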