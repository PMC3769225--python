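"""Physical constants and unit conventions.

The elastic networks work in kcal mol^-1 A^-2 spring constants and Angstrom
coordinates; free energies are reported in cal mol^-1 so that cooperativity
ratios K2/K1 = exp(ddG / (R*T)) use the gas constant in cal mol^-1 K^-1.
"""

#: Gas constant, cal mol^-1 K^-1.
R_CAL: float = 1.987

#: Gas constant, kcal mol^-1 K^-1 (used for kBT in B-factor profiles).
R_KCAL: float = R_CAL / 1000.0

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE: float = 300.0
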