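"""Physical constants shared across modules."""

#: Boltzmann constant in electron-volts per Kelvin (Arrhenius plots).
BOLTZMANN_EV = 8.617e-5

#: Volume of a sphere of unit diameter, V = (pi/6) d^3.
SPHERE_FACTOR = 0.5235987755982988

#: Celsius -> Kelvin offset.
KELVIN_OFFSET = 273.15
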