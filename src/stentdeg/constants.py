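"""Shared physical constants and unit conversions.

All mechanics is carried in mm / N / MPa; degradation time in days,
molecular-weight kinetics in months.
"""

#: Mean Gregorian month length used to convert month-scale observations
#: (molecular weight, diameter follow-up) to the day scale of the
#: degradation surface.
DAYS_PER_MONTH = 30.44

#: 1 mmHg in MPa (1 mmHg = 133.322 Pa).
MMHG_TO_MPA = 133.322e-6

#: Degradation degree at and above which material is considered fractured
#: (near-complete local degradation).
DEFAULT_FRACTURE_THRESHOLD = 0.9
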