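"""Physical constants and unit helpers.

Internal unit system: K, J, mol, s, Pa, m.  Degrees Celsius and minutes
appear only at I/O boundaries (database files store temperatures in °C,
chromatograms report retention times in minutes).
"""

#: Molar gas constant [J mol^-1 K^-1].  This value reproduces published
#: retention-parameter tables at their printed precision.
R_GAS = 8.31446

#: Unit temperature [K] used to non-dimensionalize temperature logarithms
#: (ln(T/T1)); makes the A coefficient and the Lambert-W argument
#: dimensionally clean.
T1_K = 1.0

#: 0 °C in kelvin.
T0_C = 273.15


def celsius_to_kelvin(t_c):
    return t_c + T0_C


def kelvin_to_celsius(t_k):
    return t_k - T0_C


def minutes_to_seconds(t_min):
    return t_min * 60.0


def seconds_to_minutes(t_s):
    return t_s / 60.0
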