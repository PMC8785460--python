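"""Centralized unit conventions and conversions.

Throughout the package: pressures in cmH2O, gas tensions in kPa, volumes in
ml, flows in L/min, saturations as fractions.  FiO2 is a percentage at every
public interface and a fraction internally.
"""

MMHG_PER_KPA = 7.50062


def kpa_to_mmhg(x):
    return x * MMHG_PER_KPA


def mmhg_to_kpa(x):
    return x / MMHG_PER_KPA


def fio2_pct_to_frac(fio2_pct):
    return fio2_pct / 100.0
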